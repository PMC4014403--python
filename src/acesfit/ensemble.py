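"""What a solution ensemble reveals: fit quality per parameter and ratio.

An inverse fit here returns an *ensemble* of rate sets, not a point
estimate; the mechanistic information sits in how tightly each rate — or
each mechanistic ratio of rates — is constrained across the ensemble.  The
survey metric is the median log distance (MD): the median over solutions of
|log10(value) - log10(truth)|, in decades.  MD < 0.75 (the median solution
within an order of magnitude of truth) is the conventional "successful fit"
call; it is a survey device, the full histogram is always more informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .model import CDRC_FIELDS, RATIO_FIELDS, CDRCSet, ValidationError, compute_ratios
from .search import SolutionEnsemble

__all__ = [
    "MD_SUCCESS_THRESHOLD",
    "FitSummary",
    "md_metric",
    "summarize_ensemble",
    "max_distant_pair",
    "log_euclidean_cdrc",
    "summarize_library",
    "solution_histograms",
]

#: strict success cutoff: MD must be < 0.75 decades
MD_SUCCESS_THRESHOLD = 0.75

#: exact all-pairs search cap for max_distant_pair; larger ensembles are
#: deterministically subsampled
_PAIR_CAP_DEFAULT = 2000

PARAMETER_FIELDS = CDRC_FIELDS + RATIO_FIELDS


@dataclass(frozen=True)
class FitSummary:
    """Per-parameter fit quality of one ensemble against a known truth.

    For each of the 6 rates and 8 ratios: the MD value (decades), the
    success call (MD < 0.75, strict), the solution count and the min/max
    solution values.
    """

    md: dict[str, float]
    success: dict[str, bool]
    n_solutions: int
    value_range: dict[str, tuple[float, float]]

    @property
    def n_cdrc_success(self) -> int:
        return sum(self.success[f] for f in CDRC_FIELDS)

    @property
    def n_ratio_success(self) -> int:
        return sum(self.success[f] for f in RATIO_FIELDS)


def md_metric(values, truth: float) -> float:
    """Median of |log10(value_i) - log10(truth)| — the MD fitness, in decades."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("md_metric needs at least one value")
    if not truth > 0 or not np.all(v > 0):
        raise ValidationError("md_metric requires strictly positive values and truth")
    return float(np.median(np.abs(np.log10(v) - np.log10(truth))))


def summarize_ensemble(ensemble: SolutionEnsemble, truth: CDRCSet) -> FitSummary:
    """MD and success for every rate and ratio of an ensemble vs. the truth.

    Ratio entries that are degenerate for a constitutive truth (infinite
    burst size / zero burst frequency at k_off = 0) are reported as MD = inf
    and unsuccessful rather than erroring.
    """
    if len(ensemble) == 0:
        raise ValidationError(
            "empty ensemble: nothing to summarize — raise the search resolution "
            "or loosen the moment tolerance"
        )
    truth_vals = dict(zip(CDRC_FIELDS, truth.as_tuple()))
    truth_vals.update(compute_ratios(truth).as_dict())
    sol_vals: dict[str, np.ndarray] = {
        f: np.array([getattr(s, f) for s in ensemble.solutions]) for f in CDRC_FIELDS
    }
    for f in RATIO_FIELDS:
        sol_vals[f] = np.array([getattr(r, f) for r in ensemble.ratios])

    md: dict[str, float] = {}
    success: dict[str, bool] = {}
    vrange: dict[str, tuple[float, float]] = {}
    for f in PARAMETER_FIELDS:
        vals = sol_vals[f]
        vrange[f] = (float(vals.min()), float(vals.max()))
        t = truth_vals[f]
        finite = np.isfinite(vals) & (vals > 0)
        if not (t > 0 and np.isfinite(t)) or not finite.all():
            md[f] = float("inf")
            success[f] = False
            continue
        md[f] = md_metric(vals, t)
        success[f] = md[f] < MD_SUCCESS_THRESHOLD
    return FitSummary(md=md, success=success, n_solutions=len(ensemble), value_range=vrange)


def log_euclidean_cdrc(a: CDRCSet, b: CDRCSet) -> float:
    """Log-Euclidean distance over the six rates, in decades.

    sqrt(sum over rates of log10(a/b)^2); requires all rates positive
    (a constitutive k_off = 0 has no finite log coordinate).
    """
    va = np.asarray(a.as_tuple())
    vb = np.asarray(b.as_tuple())
    if np.any(va <= 0) or np.any(vb <= 0):
        raise ValidationError("log-Euclidean distance needs strictly positive rates")
    return float(np.sqrt(np.sum((np.log10(va) - np.log10(vb)) ** 2)))


def max_distant_pair(
    ensemble: SolutionEnsemble,
    pair_cap: int = _PAIR_CAP_DEFAULT,
    seed: int = 0,
) -> tuple[CDRCSet, CDRCSet, float]:
    """The two solutions farthest apart in log-Euclidean rate space.

    Exact over all pairs up to ``pair_cap`` solutions; beyond that a
    seeded, deterministic subsample of ``pair_cap`` solutions is searched
    instead (the result is then a high-probability, not certified, maximum).
    """
    n = len(ensemble)
    if n < 2:
        raise ValidationError("need at least two solutions for a most-distant pair")
    idx = np.arange(n)
    if n > pair_cap:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=pair_cap, replace=False))
    logs = np.log10(np.array([ensemble.solutions[i].as_tuple() for i in idx]))
    best = (0, 1, -1.0)
    for i, j in combinations(range(len(idx)), 2):
        d = float(np.sqrt(np.sum((logs[i] - logs[j]) ** 2)))
        if d > best[2]:
            best = (i, j, d)
    return ensemble.solutions[idx[best[0]]], ensemble.solutions[idx[best[1]]], best[2]


def summarize_library(
    summaries: list[FitSummary],
    condition: str,
    reference: list[FitSummary] | None = None,
) -> dict:
    """Library-level averages of per-member fit summaries.

    Returns, per parameter, the mean MD across members and the success
    rate, plus the average number of successfully fit rates and ratios per
    member; when a ``reference`` condition is given, delta columns hold
    this condition's mean MD minus the reference's.
    """
    if not summaries:
        raise ValidationError("need at least one summary")

    def column(fits: list[FitSummary], f: str) -> np.ndarray:
        return np.array([s.md[f] for s in fits])

    table: dict = {"condition": condition, "n_members": len(summaries)}
    mean_md = {}
    success_rate = {}
    for f in PARAMETER_FIELDS:
        col = column(summaries, f)
        mean_md[f] = float(np.mean(col))
        success_rate[f] = float(np.mean([s.success[f] for s in summaries]))
    table["mean_md"] = mean_md
    table["success_rate"] = success_rate
    table["avg_cdrcs_fit"] = float(np.mean([s.n_cdrc_success for s in summaries]))
    table["avg_ratios_fit"] = float(np.mean([s.n_ratio_success for s in summaries]))
    if reference is not None:
        table["delta_md"] = {
            f: mean_md[f] - float(np.mean(column(reference, f))) for f in PARAMETER_FIELDS
        }
    return table


def solution_histograms(
    ensemble: SolutionEnsemble,
    ranges,
    n_bins: int = 50,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-rate histograms of the ensemble over fixed log-spaced range bins.

    Bin edges span each rate's physiological range so histograms from
    different runs are directly comparable (the standard way to visualise
    which parameter values a distribution shape permits).
    """
    out = {}
    for f in CDRC_FIELDS:
        lo, hi = ranges[f]
        edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
        vals = np.array([getattr(s, f) for s in ensemble.solutions])
        counts, _ = np.histogram(vals, bins=edges)
        out[f] = (edges, counts)
    return out
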