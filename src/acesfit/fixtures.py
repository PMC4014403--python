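"""Deterministic generators of test inputs for every module.

All fixtures are pure functions of their arguments and a seed, so any test
input — planted-truth targets aligned with a search grid, rate-set panels
pinned to a named expression regime, degenerate ensembles with one
conserved ratio — can be regenerated anywhere without shipping data files.
"""

from __future__ import annotations

import math

import numpy as np

from .model import CDRCRanges, CDRCSet, MomentVector, ValidationError, compute_ratios
from .moments import mean_protein, protein_central_moments, rna_moments
from .metrics import friedman_regime_screen
from .search import ACESConfig, DEFAULT_ORDER, SolutionEnsemble

__all__ = [
    "make_planted_target",
    "make_regime_panel",
    "make_conserved_ratio_ensemble",
    "REGIMES",
]

REGIMES = ("friedman", "bursting", "constitutive", "low-count")

_MAX_DRAWS = 10_000


def make_planted_target(
    ranges: CDRCRanges,
    resolution: int,
    seed: int,
    order: tuple[str, ...] = DEFAULT_ORDER,
    mean_window: tuple[float, float] = (20.0, 5e4),
) -> tuple[CDRCSet, MomentVector]:
    """A rate set recoverable by the search at the same resolution.

    The five enumerated coordinates (all but the last free parameter of
    ``order``) are placed exactly on nodes of the ``resolution``-point
    log lattice over ``ranges``; the last parameter is drawn inside the
    middle of its range, off-lattice, exactly as the search would solve it
    from the mean.  Draws are rejected until the protein mean falls in
    ``mean_window`` so targets stay in a realistic, well-conditioned
    regime.  Returns the set and its exact forward moments.
    """
    if resolution < 2:
        raise ValidationError("resolution must be >= 2")
    rng = np.random.default_rng(seed)
    enumerated = order[:-1]
    solved = order[-1]
    for _ in range(_MAX_DRAWS):
        values = {}
        for f in enumerated:
            lo, hi = ranges[f]
            node = rng.integers(0, resolution)
            values[f] = float(
                np.logspace(math.log10(lo), math.log10(hi), resolution)[node]
            )
        lo, hi = ranges[solved]
        # middle 80% of the log range, off-lattice
        u = rng.uniform(0.1, 0.9)
        values[solved] = 10 ** (math.log10(lo) + u * (math.log10(hi) - math.log10(lo)))
        cdrc = CDRCSet(**values)
        m = mean_protein(cdrc)
        if mean_window[0] <= m <= mean_window[1]:
            return cdrc, protein_central_moments(cdrc)
    raise ValidationError("could not draw a planted target in the mean window")


def _draw_loguniform(rng, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


def make_regime_panel(regime: str, n: int, seed: int) -> list[CDRCSet]:
    """``n`` rate sets verifiably inside a named expression regime.

    friedman      always-active gene, fast RNA turnover, high protein count
                  (the regime where the gamma model holds)
    bursting      slow promoter switching with large transcriptional bursts
                  (RNA Fano factor well above 1)
    constitutive  no OFF state (k_off = 0, RNA Fano factor exactly 1)
    low-count     mean RNA <= 5 and mean protein <= 25, small enough for a
                  brute-force truncated master-equation solution

    Membership is verified by the forward solver (not just by construction)
    and failing draws are rejected; the output is a pure function of
    (regime, n, seed).
    """
    if regime not in REGIMES:
        raise ValidationError(f"unknown regime {regime!r}; choose from {REGIMES}")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    panel: list[CDRCSet] = []
    draws = 0
    while len(panel) < n:
        draws += 1
        if draws > _MAX_DRAWS:
            raise ValidationError(f"regime {regime!r} unreachable under the draw windows")
        if regime == "constitutive":
            cdrc = CDRCSet(
                k_on=_draw_loguniform(rng, 0.1, 10.0),
                k_off=0.0,
                k_r=_draw_loguniform(rng, 0.5, 5.0),
                k_p=_draw_loguniform(rng, 0.2, 2.0),
                g_r=_draw_loguniform(rng, 0.5, 2.0),
                g_p=_draw_loguniform(rng, 0.05, 0.2),
            )
            if abs(rna_moments(cdrc)[2] - 1.0) > 1e-9:
                continue
        elif regime == "bursting":
            cdrc = CDRCSet(
                k_on=_draw_loguniform(rng, 0.01, 0.1),
                k_off=_draw_loguniform(rng, 0.2, 2.0),
                k_r=_draw_loguniform(rng, 5.0, 50.0),
                k_p=_draw_loguniform(rng, 0.2, 2.0),
                g_r=_draw_loguniform(rng, 0.5, 2.0),
                g_p=_draw_loguniform(rng, 0.05, 0.2),
            )
            if rna_moments(cdrc)[2] <= 1.5:
                continue
        elif regime == "friedman":
            cdrc = CDRCSet(
                k_on=_draw_loguniform(rng, 1.0, 10.0),
                k_off=_draw_loguniform(rng, 1e-3, 5e-3),
                k_r=_draw_loguniform(rng, 2.0, 20.0),
                k_p=_draw_loguniform(rng, 2.0, 20.0),
                g_r=_draw_loguniform(rng, 1.0, 5.0),
                g_p=_draw_loguniform(rng, 2e-3, 8e-3),
            )
            if not friedman_regime_screen(cdrc, protein_central_moments(cdrc)):
                continue
        else:  # low-count
            cdrc = CDRCSet(
                k_on=_draw_loguniform(rng, 0.2, 2.0),
                k_off=_draw_loguniform(rng, 0.2, 2.0),
                k_r=_draw_loguniform(rng, 0.5, 4.0),
                k_p=_draw_loguniform(rng, 0.3, 3.0),
                g_r=_draw_loguniform(rng, 0.8, 3.0),
                g_p=_draw_loguniform(rng, 0.3, 1.5),
            )
            rna_mean = rna_moments(cdrc)[0]
            if rna_mean > 5.0 or mean_protein(cdrc) > 25.0:
                continue
        panel.append(cdrc)
    return panel


def make_conserved_ratio_ensemble(
    ranges: CDRCRanges,
    n: int,
    seed: int,
) -> tuple[SolutionEnsemble, CDRCSet]:
    """A synthetic degenerate ensemble: burst size conserved, rates free.

    Emulates the canonical degeneracy pattern of the inverse problem —
    ``k_r`` and ``k_off`` each wander over about three decades while their
    ratio (the transcriptional burst size) stays pinned to the truth, so
    the ratio is sharply identified (MD near 0) while each constituent rate
    fails the MD < 0.75 success call.  The ensemble is constructed directly
    (it is not the output of a search run) and is meant for exercising
    ensemble-analysis code paths.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    rng = np.random.default_rng(seed)
    truth = CDRCSet(k_on=0.2, k_off=1.0, k_r=10.0, k_p=1.0, g_r=1.0, g_p=0.05)
    burst = truth.k_r / truth.k_off
    solutions = []
    for _ in range(n):
        f = 10 ** rng.uniform(-1.6, 1.6)  # ~3 decades of constituent spread
        solutions.append(truth.replace(k_off=truth.k_off * f, k_r=burst * truth.k_off * f))
    solutions = tuple(sorted(solutions, key=lambda s: s.as_tuple()))
    target = protein_central_moments(truth)
    ensemble = SolutionEnsemble(
        solutions=solutions,
        moments=tuple(protein_central_moments(s) for s in solutions),
        ratios=tuple(compute_ratios(s) for s in solutions),
        target=target,
        config=ACESConfig(ranges=ranges, resolution=2),
        n_tested=n,
        nominal_space=2**6,
        diagnostic="synthetic: constructed ensemble, not a search output",
    )
    return ensemble, truth
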