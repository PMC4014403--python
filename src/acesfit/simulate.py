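"""Exact Gillespie sampling of the two-state gene-expression model.

The simulator is the package's validation oracle: it draws an ensemble of
independent cells (one exact stochastic trajectory per cell, sampled at a
fixed horizon after burn-in from the empty state) so that the resulting
protein histogram is directly comparable to a flow-cytometry-style
population snapshot and to the analytic steady-state moments.

It deliberately stays an exact SSA — no tau-leaping — and refuses runs
whose projected event count is excessive, since exact simulation scales
poorly with molecule number (that inefficiency is the reason the inverse
search works from moments instead of simulated distributions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import CDRCSet, ValidationError

__all__ = [
    "CountSample",
    "CountDistribution",
    "simulate_cells",
    "sample_moments",
    "histogram",
    "default_horizon",
]

#: default burn-in multiplier: trajectories run for RELAX_MULTIPLIER times
#: the slowest relaxation time before sampling
RELAX_MULTIPLIER = 10.0

#: refuse simulations whose projected total event count exceeds this
DEFAULT_EVENT_CAP = 2_000_000_000


@dataclass(frozen=True)
class CountDistribution:
    """A discrete count histogram: integer support and probabilities."""

    support: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.support)
        p = np.asarray(self.probabilities)
        if s.shape != p.shape or s.ndim != 1 or s.size == 0:
            raise ValidationError("support and probabilities must be equal-length 1-D arrays")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError("probabilities must be non-negative and sum to 1")
        if np.any(s[1:] <= s[:-1]):
            raise ValidationError("support must be strictly increasing")

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probabilities))

    @property
    def variance(self) -> float:
        m = self.mean
        return float(np.dot((self.support - m) ** 2, self.probabilities))

    def central_moment(self, order: int) -> float:
        m = self.mean
        return float(np.dot((self.support - m) ** order, self.probabilities))


@dataclass(frozen=True)
class CountSample:
    """Endpoint states of independently simulated cells.

    ``s``, ``m``, ``p`` hold the promoter state, RNA count and protein
    count of each cell at the sampling horizon ``T``.
    """

    s: np.ndarray
    m: np.ndarray
    p: np.ndarray
    n_cells: int
    seed: int
    horizon: float
    cdrc: CDRCSet | tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_cells < 1 or len(self.p) != self.n_cells:
            raise ValidationError("n_cells must be >= 1 and match array lengths")


def _as_theta(cdrc) -> np.ndarray:
    """Coerce a CDRCSet or raw six-rate sequence to a validated rate vector.

    The raw-sequence path relaxes CDRCSet's strict positivity so degenerate
    sub-models (k_r = 0, k_p = 0) remain simulable; degradation rates and
    k_on must still be positive and nothing may be negative.
    """
    theta = np.asarray(
        cdrc.as_tuple() if isinstance(cdrc, CDRCSet) else cdrc, dtype=float
    )
    if theta.shape != (6,):
        raise ValidationError("expected a CDRCSet or six rates in field order")
    if theta[0] <= 0 or theta[4] <= 0 or theta[5] <= 0 or np.any(theta < 0):
        raise ValidationError("k_on, g_r, g_p must be positive; no rate may be negative")
    return theta


def default_horizon(cdrc, multiplier: float = RELAX_MULTIPLIER) -> float:
    """Burn-in horizon: ``multiplier`` over the slowest relaxation rate.

    The slowest of protein decay, RNA decay and promoter equilibration
    (rate k_on + k_off) bounds the approach to stationarity; ten of those
    timescales leaves initial-condition bias far below Monte-Carlo noise.
    """
    k_on, k_off, _, _, g_r, g_p = _as_theta(cdrc)
    slowest = min(g_p, g_r, k_on + k_off)
    return multiplier / slowest


@njit(cache=False)
def _ssa_kernel(theta, n_cells, horizon, seed, max_events, out):
    np.random.seed(seed)
    k_on, k_off, k_r, k_p, g_r, g_p = theta
    events = 0
    for cell in range(n_cells):
        s = 0
        m = 0
        p = 0
        t = 0.0
        while True:
            a1 = k_on * (1 - s)
            a2 = k_off * s
            a3 = k_r * s
            a4 = g_r * m
            a5 = k_p * m
            a6 = g_p * p
            atot = a1 + a2 + a3 + a4 + a5 + a6
            if atot <= 0.0:
                break  # absorbing (possible only for degenerate rates)
            t += np.random.exponential(1.0 / atot)
            if t >= horizon:
                break
            events += 1
            if events > max_events:
                return -1
            u = np.random.random() * atot
            if u < a1:
                s = 1
            elif u < a1 + a2:
                s = 0
            elif u < a1 + a2 + a3:
                m += 1
            elif u < a1 + a2 + a3 + a4:
                m -= 1
            elif u < a1 + a2 + a3 + a4 + a5:
                p += 1
            else:
                p -= 1
        out[cell, 0] = s
        out[cell, 1] = m
        out[cell, 2] = p
    return events


def _projected_events(theta: np.ndarray, n_cells: int, horizon: float) -> float:
    """Expected event count from steady-state mean propensities (closed forms)."""
    k_on, k_off, k_r, k_p, g_r, g_p = theta
    p_on = k_on / (k_on + k_off)
    rna_mean = (k_r / g_r) * p_on
    flux = (
        2.0 * k_on * (1.0 - p_on)  # switching (balanced both ways)
        + 2.0 * k_r * p_on         # RNA birth/death balance
        + 2.0 * k_p * rna_mean     # protein birth/death balance
    )
    return flux * horizon * n_cells


def simulate_cells(
    cdrc,
    n_cells: int,
    seed: int,
    relax_multiplier: float = RELAX_MULTIPLIER,
    horizon: float | None = None,
    event_cap: int = DEFAULT_EVENT_CAP,
) -> CountSample:
    """Simulate ``n_cells`` independent cells and return their endpoints.

    Every cell starts at (s, m, p) = (0, 0, 0) and evolves by the exact
    stochastic simulation algorithm until the horizon (by default
    ``relax_multiplier`` slowest relaxation times), giving one independent
    draw from (approximately) the stationary law per cell.  Identical
    (cdrc, n_cells, seed) inputs give bit-identical output.
    """
    theta = _as_theta(cdrc)
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if not (0 <= seed < 2**32):
        raise ValidationError("seed must fit in 32 bits")
    T = float(horizon) if horizon is not None else default_horizon(theta, relax_multiplier)
    projected = _projected_events(theta, n_cells, T)
    if projected > event_cap:
        raise ValidationError(
            f"projected ~{projected:.2e} SSA events exceeds cap {event_cap:.2e}; "
            "exact simulation is impractical at these molecule counts — reduce "
            "n_cells or the horizon, rescale the rates, or raise event_cap"
        )
    out = np.zeros((n_cells, 3), dtype=np.int64)
    status = _ssa_kernel(theta, n_cells, T, seed, int(event_cap * 1.5) + 1000, out)
    if status < 0:
        raise ValidationError("SSA event cap exceeded mid-run; raise event_cap")
    return CountSample(
        s=out[:, 0].copy(),
        m=out[:, 1].copy(),
        p=out[:, 2].copy(),
        n_cells=n_cells,
        seed=seed,
        horizon=T,
        cdrc=cdrc,
    )


def sample_moments(sample: CountSample, max_order: int = 5) -> list[float]:
    """Central sample moments of the protein marginal through ``max_order``.

    Index k of the returned list is the (k+1)-th moment: the mean first,
    then central moments 2..max_order.  The fifth moment is included
    because it is the natural check of whether four moments exhaust the
    usable shape information in a sample.
    """
    if sample.n_cells < 2:
        raise ValidationError("need at least two cells for sample moments")
    if not 1 <= max_order <= 5:
        raise ValidationError("max_order must be in 1..5")
    p = sample.p.astype(np.float64)
    mean = p.mean()
    out = [float(mean)]
    centered = p - mean
    for order in range(2, max_order + 1):
        out.append(float(np.mean(centered**order)))
    return out


def histogram(sample: CountSample, species: str = "p") -> CountDistribution:
    """Empirical integer-bin distribution of one species' marginal."""
    if species not in ("s", "m", "p"):
        raise ValidationError(f"unknown species {species!r}")
    counts = np.bincount(getattr(sample, species))
    support = np.nonzero(counts)[0]
    probs = counts[support] / counts.sum()
    return CountDistribution(support=support.astype(np.int64), probabilities=probs)
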