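"""Distribution-level comparisons and the gamma/Friedman reference method.

Two count distributions are compared by Jensen-Shannon divergence with
base-2 logarithms, so the divergence lives on [0, 1]: 0 for identical
distributions, 1 for non-overlapping supports.  Moment vectors are compared
by log-Euclidean distance in decades.

The Friedman gamma model is the field's standard shortcut: in the regime of
an always-active gene with RNA turnover much faster than protein turnover
and high protein counts, the protein distribution is gamma with shape
a = k_r/g_p (RNAs per protein lifetime) and scale b = k_p/g_r
(translational burst size), so both ratios drop out of a method-of-moments
fit to the measured mean and variance.  The helpers here compute those
estimators, screen rate sets for the regime where the assumptions hold,
and test whether a histogram is gamma-shaped at all.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .model import CDRCSet, MomentVector, ValidationError
from .simulate import CountDistribution

__all__ = [
    "kl_divergence",
    "jsd",
    "log_euclidean_moments",
    "friedman_estimates",
    "friedman_regime_screen",
    "gamma_distributed",
    "gamma_reference",
]


def _aligned(P: CountDistribution, Q: CountDistribution):
    """Probability vectors of P and Q on the union of their supports."""
    support = np.union1d(P.support, Q.support)
    p = np.zeros(support.size)
    q = np.zeros(support.size)
    p[np.searchsorted(support, P.support)] = P.probabilities
    q[np.searchsorted(support, Q.support)] = Q.probabilities
    return p, q


def kl_divergence(P: CountDistribution, Q: CountDistribution) -> float:
    """Kullback-Leibler divergence KL(P || Q) in bits (base-2 logs).

    Zero-probability P bins contribute nothing; P mass where Q has none
    makes the divergence infinite (never the case against a mixture that
    includes P).
    """
    p, q = _aligned(P, Q)
    mask = p > 0
    if np.any(q[mask] == 0):
        return math.inf
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def jsd(P: CountDistribution, Q: CountDistribution) -> float:
    """Jensen-Shannon divergence: symmetrized KL against the half mixture.

    JSD(P, Q) = KL(P||M)/2 + KL(Q||M)/2 with M = (P+Q)/2, base-2 logs;
    always finite, symmetric and in [0, 1].
    """
    p, q = _aligned(P, Q)
    m = 0.5 * (p + q)
    out = 0.0
    for a in (p, q):
        mask = a > 0
        out += 0.5 * float(np.sum(a[mask] * np.log2(a[mask] / m[mask])))
    # clip float fuzz at the endpoints
    return min(max(out, 0.0), 1.0)


def log_euclidean_moments(A: MomentVector, B: MomentVector, include_mu3: bool = True) -> float:
    """Log-Euclidean distance between two moment vectors, in decades.

    sqrt(sum over {M, V, mu3, mu4} of log10(A/B)^2).  Log distance weighs a
    moment moving from .01 to .1 the same as one moving from 100 to 1000,
    so moments of very different scales are comparable.  Negative or zero
    mu3 has no log coordinate; pass ``include_mu3=False`` to compare on the
    remaining three moments.
    """
    fields = ("M", "V", "S", "K") if include_mu3 else ("M", "V", "K")
    total = 0.0
    for f in fields:
        a = getattr(A, f)
        b = getattr(B, f)
        if a <= 0 or b <= 0:
            raise ValidationError(
                f"moment {f} must be positive for a log distance (got {a}, {b}); "
                "exclude mu3 for near-symmetric distributions"
            )
        total += (math.log10(a) - math.log10(b)) ** 2
    return math.sqrt(total)


def friedman_estimates(M: float, V: float) -> tuple[float, float]:
    """Method-of-moments gamma fit: shape a = M^2/V, scale b = V/M.

    Under the gamma model of protein expression, a estimates k_r/g_p and b
    the translational burst size k_p/g_r.
    """
    if not (M > 0 and V > 0):
        raise ValidationError("mean and variance must be positive")
    return M * M / V, V / M


def friedman_regime_screen(
    cdrc: CDRCSet,
    moments: MomentVector,
    threshold_sep: float = 100.0,
    threshold_on: float = 0.99,
    threshold_count: float = 1000.0,
) -> bool:
    """Does a rate set satisfy the gamma-model assumptions?

    True iff RNA decay is much faster than protein decay
    (g_r/g_p >= threshold_sep), the mean protein count is high
    (M > threshold_count, so a continuous approximation holds), and the
    gene is effectively always active (p_on >= threshold_on).
    """
    sep = cdrc.g_r / cdrc.g_p
    p_on = cdrc.k_on / (cdrc.k_on + cdrc.k_off)
    return sep >= threshold_sep and moments.M > threshold_count and p_on >= threshold_on


def gamma_reference(M: float, V: float, support: np.ndarray) -> CountDistribution:
    """Moment-matched gamma discretized over integer bins by CDF differencing.

    Bin k receives the gamma mass on (k - 1/2, k + 1/2] (with the lower
    tail folded into the first bin), renormalized over the given support.
    """
    a, b = friedman_estimates(M, V)
    support = np.asarray(support, dtype=np.int64)
    lo = np.clip(support.astype(float) - 0.5, 0.0, None)
    hi = support.astype(float) + 0.5
    mass = stats.gamma.cdf(hi, a, scale=b) - stats.gamma.cdf(lo, a, scale=b)
    total = mass.sum()
    if total <= 0:
        raise ValidationError("gamma reference has no mass on the given support")
    return CountDistribution(support=support, probabilities=mass / total)


def gamma_distributed(dist: CountDistribution, threshold: float = 0.02) -> bool:
    """Is a histogram gamma-shaped, by JSD against its moment-matched gamma?

    The moment-matched gamma is discretized over the histogram's support
    extended to cover the fitted tail; True iff the JSD is below
    ``threshold``.  Degenerate (zero-variance) histograms are never gamma.
    """
    M = dist.mean
    V = dist.variance
    if not M > 0:
        raise ValidationError("distribution must have positive mean")
    if V <= 0:
        return False
    upper = int(max(dist.support.max(), math.ceil(M + 10 * math.sqrt(V))))
    support = np.arange(0, upper + 1, dtype=np.int64)
    ref = gamma_reference(M, V, support)
    return jsd(dist, ref) < threshold
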