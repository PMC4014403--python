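"""Exact steady-state moments of the two-state gene-expression model.

For the six-reaction network

    OFF -> ON   at k_on*(1-s)      ON -> OFF  at k_off*s
    m -> m+1    at k_r*s           m -> m-1   at g_r*m
    p -> p+1    at k_p*m           p -> p-1   at g_p*p

every propensity is linear in the state (s, m, p), so expectations of
monomials s^a m^i p^j satisfy a *closed* linear system: the time derivative
of an order-(i+j) moment only involves moments of order <= i+j.  Tracking
the promoter-partial moments E[s m^i p^j] alongside the totals E[m^i p^j]
for 1 <= i+j <= 4 gives 28 unknowns (14 index pairs x 2 layers); the
promoter occupancy E[s] = k_on/(k_on+k_off) has an autonomous equation and
is substituted in closed form.  Setting all derivatives to zero and solving
the linear system yields the exact protein mean, variance, and third and
fourth central moments — no moment-closure approximation is involved.

Numerics.  Two equivalent coordinate systems are generated from the same
expansion machinery (binomial shifts of the master-equation generator with
the idempotency reduction s^k -> s):

* the *raw* system in E[s^a m^i p^j] — the directly interpretable balance
  equations exposed by :func:`assemble_moment_system`;
* the *central* system in E[s^a dm^i dp^j] with dm = m - <m>, dp = p - <p>
  — what the solver actually solves.  Small central moments computed from
  large raw moments lose many digits to cancellation (a fourth raw moment
  can exceed mu4 by ~10^4), whereas the central system yields mu3 and mu4
  directly at near machine precision.

The system is block-triangular in total moment order, so it is solved in
four staged blocks (sizes 4, 6, 8, 10).  The staging is what makes the
inverse search fast: a candidate rate set can be rejected on variance
(orders 1-2) without ever assembling the order-3/4 blocks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
from numba import njit

from .model import CDRC_FIELDS, CDRCSet, MomentVector, ValidationError

__all__ = [
    "MomentSystem",
    "PartialMomentVector",
    "assemble_moment_system",
    "solve_partial_moments",
    "protein_central_moments",
    "moments_from_rates",
    "rna_moments",
    "mean_protein",
    "solve_mean_for_param",
    "CANONICAL_INDEX",
    "N_EQUATIONS",
]

# --------------------------------------------------------------------------
# index bookkeeping
#
# A tracked moment is identified by (a, i, j): E[s^a x^i y^j] with a in
# {0, 1} (a=1: ON-partial layer, a=0: total layer), 1 <= i+j <= 4, and
# (x, y) either the raw counts (m, p) or the centred counts (dm, dp).
#
# Canonical (documented, user-facing) order: layer-major with the
# ON-partial layer first, then total order ascending, then RNA order
# descending.  Internal order (used by the staged solver): block-major by
# total order, ON-partial layer first within a block.
# --------------------------------------------------------------------------

CANONICAL_INDEX: tuple[tuple[int, int, int], ...] = tuple(
    (a, t - j, j) for a in (1, 0) for t in range(1, 5) for j in range(0, t + 1)
)

_INTERNAL_INDEX: tuple[tuple[int, int, int], ...] = tuple(
    (a, t - j, j) for t in range(1, 5) for a in (1, 0) for j in range(0, t + 1)
)

N_EQUATIONS = len(CANONICAL_INDEX)
assert N_EQUATIONS == 28 == len(_INTERNAL_INDEX)

_INTERNAL_POS = {mono: k for k, mono in enumerate(_INTERNAL_INDEX)}
_CANONICAL_POS = {mono: k for k, mono in enumerate(CANONICAL_INDEX)}
# permutation: canonical[k] = internal[_CANON_FROM_INTERNAL[k]]
_CANON_FROM_INTERNAL = np.array(
    [_INTERNAL_POS[mono] for mono in CANONICAL_INDEX], dtype=np.int64
)

_BLOCK_OF = {mono: mono[1] + mono[2] - 1 for mono in _INTERNAL_INDEX}  # 0-based
_BLOCK_SIZES = np.array([4, 6, 8, 10], dtype=np.int64)
_BLOCK_STARTS = np.array([0, 4, 10, 18], dtype=np.int64)

# positions (internal order) of the moments the solver reads off
_POS_M1 = _INTERNAL_POS[(0, 1, 0)]
_POS_M2 = _INTERNAL_POS[(0, 2, 0)]
_POS_P1 = _INTERNAL_POS[(0, 0, 1)]
_POS_P2 = _INTERNAL_POS[(0, 0, 2)]
_POS_P3 = _INTERNAL_POS[(0, 0, 3)]
_POS_P4 = _INTERNAL_POS[(0, 0, 4)]

# scale factors multiplying structure coefficients: 1, <m>, <p>
_SCALE_ONE, _SCALE_MRNA, _SCALE_PROT = 0, 1, 2


def _reactions(central: bool):
    """The six reactions as (rate index, propensity terms, state shift).

    Propensity terms are (scale, monomial, coeff) triples; in central
    coordinates the degradation/translation propensities pick up constant
    terms proportional to the means (m = <m> + dm etc.).
    """
    one = _SCALE_ONE
    s = (1, 0, 0)
    x = (0, 1, 0)
    y = (0, 0, 1)
    const = (0, 0, 0)
    r4 = [(one, x, 1)] + ([(_SCALE_MRNA, const, 1)] if central else [])
    r5 = [(one, x, 1)] + ([(_SCALE_MRNA, const, 1)] if central else [])
    r6 = [(one, y, 1)] + ([(_SCALE_PROT, const, 1)] if central else [])
    return (
        (0, [(one, const, 1), (one, s, -1)], (1, 0, 0)),   # k_on*(1-s), s += 1
        (1, [(one, s, 1)], (-1, 0, 0)),                    # k_off*s,    s -= 1
        (2, [(one, s, 1)], (0, 1, 0)),                     # k_r*s,      x += 1
        (4, r4, (0, -1, 0)),                               # g_r*m,      x -= 1
        (3, r5, (0, 0, 1)),                                # k_p*m,      y += 1
        (5, r6, (0, 0, -1)),                               # g_p*p,      y -= 1
    )


def _shift_poly(order: int, delta: int) -> dict[int, int]:
    """(x + delta)^order as {power: coefficient}."""
    return {k: comb(order, k) * delta ** (order - k) for k in range(order + 1)}


def _mono_mul(m1, m2):
    """Product of monomials with the s-idempotency reduction s^k -> s."""
    return (min(m1[0] + m2[0], 1), m1[1] + m2[1], m1[2] + m2[2])


def _rhs_terms(mono, central: bool):
    """d/dt E[g] expanded: yields (rate, scale, coeff, monomial) terms."""
    a, i, j = mono
    for rate_idx, prop_terms, (ds, dx, dy) in _reactions(central):
        # g(state + shift) - g(state), expanded factor-wise
        shifted: dict[tuple[int, int, int], int] = {(0, 0, 0): 1}
        for order, delta, axis in ((a, ds, 0), (i, dx, 1), (j, dy, 2)):
            nxt: dict[tuple[int, int, int], int] = {}
            for power, coeff in _shift_poly(order, delta).items():
                key = [0, 0, 0]
                key[axis] = power
                factor_mono = (min(key[0], 1), key[1], key[2])
                for m0, c0 in shifted.items():
                    mm = _mono_mul(m0, factor_mono)
                    nxt[mm] = nxt.get(mm, 0) + c0 * coeff
            shifted = nxt
        shifted[mono] = shifted.get(mono, 0) - 1
        for scale, mono_p, cprop in prop_terms:
            for m2, c2 in shifted.items():
                c = cprop * c2
                if c != 0:
                    yield rate_idx, scale, c, _mono_mul(mono_p, m2)


def _build_structure(central: bool):
    """Flatten the 28 balance equations into block-sorted coefficient arrays.

    Matrix entries couple unknowns within one total-order block; every
    lower-order monomial, the constant E[1] = 1 and the substituted
    E[s] = p_on go to the right-hand side (sign flipped).  Exact closure
    (no monomial of combined order > 4) is asserted structurally here.
    """
    a_acc: dict[tuple, int] = {}
    r_acc: dict[tuple, int] = {}
    for mono in _INTERNAL_INDEX:
        block = _BLOCK_OF[mono]
        lrow = _INTERNAL_POS[mono] - _BLOCK_STARTS[block]
        for rate_idx, scale, coeff, other in _rhs_terms(mono, central):
            oa, oi, oj = other
            order = oi + oj
            if order > 4:  # pragma: no cover - closure guarantee
                raise AssertionError(f"moment closure violated: {other} in d/dt E{mono}")
            if order == 0:
                src = 1 if oa == 1 else 0
                key = (block, lrow, src, rate_idx, scale)
                r_acc[key] = r_acc.get(key, 0) - coeff
            elif order - 1 == block:
                lcol = _INTERNAL_POS[other] - _BLOCK_STARTS[block]
                key = (block, lrow, lcol, rate_idx, scale)
                a_acc[key] = a_acc.get(key, 0) + coeff
            else:
                assert order - 1 < block, "higher-order coupling breaks triangularity"
                key = (block, lrow, 2 + _INTERNAL_POS[other], rate_idx, scale)
                r_acc[key] = r_acc.get(key, 0) - coeff
    a_entries = sorted((*k, v) for k, v in a_acc.items() if v != 0)
    r_entries = sorted((*k, v) for k, v in r_acc.items() if v != 0)
    a_arr = np.array(a_entries, dtype=np.int64)
    r_arr = np.array(r_entries, dtype=np.int64)
    a_off = np.searchsorted(a_arr[:, 0], np.arange(5))
    r_off = np.searchsorted(r_arr[:, 0], np.arange(5))
    return a_arr, a_off, r_arr, r_off


# raw system: documentation/verification surface
_A_RAW, _A_RAW_OFF, _R_RAW, _R_RAW_OFF = _build_structure(central=False)
# central system: what the solver and search kernels use
_A_ENT, _A_OFF, _R_ENT, _R_OFF = _build_structure(central=True)


# --------------------------------------------------------------------------
# numba kernels (shared with the ACES search hot path)
# --------------------------------------------------------------------------


@njit(cache=False)
def _gauss_solve(A, b):
    """In-place Gaussian elimination with partial pivoting for tiny systems."""
    n = b.shape[0]
    for col in range(n):
        piv = col
        best = abs(A[col, col])
        for r in range(col + 1, n):
            if abs(A[r, col]) > best:
                best = abs(A[r, col])
                piv = r
        if best == 0.0:
            return False
        if piv != col:
            for c in range(col, n):
                tmp = A[col, c]
                A[col, c] = A[piv, c]
                A[piv, c] = tmp
            tmp = b[col]
            b[col] = b[piv]
            b[piv] = tmp
        inv = 1.0 / A[col, col]
        for r in range(col + 1, n):
            f = A[r, col] * inv
            if f != 0.0:
                for c in range(col, n):
                    A[r, c] -= f * A[col, c]
                b[r] -= f * b[col]
    for row in range(n - 1, -1, -1):
        acc = b[row]
        for c in range(row + 1, n):
            acc -= A[row, c] * b[c]
        b[row] = acc / A[row, row]
    return True


@njit(cache=False)
def _scales_from_theta(theta):
    """(p_on, scale vector [1, <m>, <p>]) from the closed-form means."""
    pon = theta[0] / (theta[0] + theta[1])
    scales = np.empty(3)
    scales[0] = 1.0
    scales[1] = theta[2] * pon / theta[4]                 # mean RNA
    scales[2] = theta[3] * scales[1] / theta[5]           # mean protein
    return pon, scales


@njit(cache=False)
def _solve_one_block(blk, theta, scales, known, x,
                     a_ent, a_off, r_ent, r_off, bsz, bst):
    n = bsz[blk]
    A = np.zeros((n, n))
    b = np.zeros(n)
    for e in range(a_off[blk], a_off[blk + 1]):
        A[a_ent[e, 1], a_ent[e, 2]] += theta[a_ent[e, 3]] * scales[a_ent[e, 4]] * a_ent[e, 5]
    for e in range(r_off[blk], r_off[blk + 1]):
        b[r_ent[e, 1]] += (theta[r_ent[e, 3]] * scales[r_ent[e, 4]]
                           * r_ent[e, 5] * known[r_ent[e, 2]])
    if not _gauss_solve(A, b):
        return False
    start = bst[blk]
    for r in range(n):
        x[start + r] = b[r]
        known[2 + start + r] = b[r]
    return True


@njit(cache=False)
def _solve_blocks(theta, upto, a_ent, a_off, r_ent, r_off, block_sizes, block_starts, x):
    """Solve the staged central-moment blocks 1..upto; fill x (internal order)."""
    pon, scales = _scales_from_theta(theta)
    known = np.empty(2 + 28)
    known[0] = 1.0
    known[1] = pon
    for g in range(28):
        known[2 + g] = 0.0
    for blk in range(upto):
        if not _solve_one_block(blk, theta, scales, known, x,
                                a_ent, a_off, r_ent, r_off,
                                block_sizes, block_starts):
            return False
    return True


@njit(cache=False)
def _rescale_theta(theta):
    """Divide by the geometric mean of the positive rates (time-unit change).

    Stationary moments are invariant under a uniform rescaling of all six
    rates, and centring the rates around 1 keeps the higher-order blocks
    well conditioned at extreme rate ratios.
    """
    logsum = 0.0
    npos = 0
    for k in range(6):
        if theta[k] > 0.0:
            logsum += np.log(theta[k])
            npos += 1
    gm = np.exp(logsum / npos)
    out = np.empty(6)
    for k in range(6):
        out[k] = theta[k] / gm
    return out


@njit(cache=False)
def _protein_moments_kernel(theta, a_ent, a_off, r_ent, r_off, block_sizes, block_starts):
    """(ok, M, V, mu3, mu4) for one rate vector, solving all four blocks."""
    th = _rescale_theta(theta)
    x = np.zeros(28)
    ok = _solve_blocks(th, 4, a_ent, a_off, r_ent, r_off, block_sizes, block_starts, x)
    if not ok:
        return False, 0.0, 0.0, 0.0, 0.0
    _, scales = _scales_from_theta(th)
    return True, scales[2], x[_POS_P2], x[_POS_P3], x[_POS_P4]


def _kernel_args():
    return (_A_ENT, _A_OFF, _R_ENT, _R_OFF, _BLOCK_SIZES, _BLOCK_STARTS)


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PartialMomentVector:
    """Solved steady-state moments E[s m^i p^j] and E[m^i p^j], 1 <= i+j <= 4.

    ``values`` follows the canonical index order in :data:`CANONICAL_INDEX`
    (ON-partial layer first, total order ascending, RNA order descending);
    ``p_on`` = E[s] is carried separately since it is solved in closed form.
    """

    values: np.ndarray
    p_on: float

    def __getitem__(self, mono: tuple[int, int, int]) -> float:
        return float(self.values[_CANONICAL_POS[mono]])

    def on_partial(self, i: int, j: int) -> float:
        return self[(1, i, j)]

    def total(self, i: int, j: int) -> float:
        return self[(0, i, j)]


@dataclass(frozen=True)
class MomentSystem:
    """The assembled 28 x 28 steady-state balance system A x = b.

    Rows/columns follow :data:`CANONICAL_INDEX` over the raw moments
    E[s^a m^i p^j].  Constant contributions (from E[1] = 1 and the
    substituted promoter occupancy p_on) live in b, so each row reads as a
    balance equation, e.g. the E[p] row is k_p*E[m] - g_p*E[p] = 0.
    """

    matrix: np.ndarray
    constant: np.ndarray
    cdrc: CDRCSet

    @property
    def n_equations(self) -> int:
        return self.matrix.shape[0]


def _dense_raw_system(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full 28x28 raw-moment matrix and constant vector, internal order."""
    pon = theta[0] / (theta[0] + theta[1])
    A = np.zeros((N_EQUATIONS, N_EQUATIONS))
    b = np.zeros(N_EQUATIONS)
    known = (1.0, pon)
    for blk, lrow, lcol, rate_idx, scale, coeff in _A_RAW:
        row = _BLOCK_STARTS[blk] + lrow
        A[row, _BLOCK_STARTS[blk] + lcol] += theta[rate_idx] * coeff
        assert scale == _SCALE_ONE
    for blk, lrow, src, rate_idx, scale, coeff in _R_RAW:
        row = _BLOCK_STARTS[blk] + lrow
        if src >= 2:
            # cross-block coupling: a matrix entry in the full view
            # (sign flipped back from the staged RHS convention)
            A[row, src - 2] += -theta[rate_idx] * coeff
        else:
            b[row] += theta[rate_idx] * coeff * known[src]
    return A, b


def assemble_moment_system(cdrc: CDRCSet) -> MomentSystem:
    """Assemble the closed linear system for the 28 tracked raw moments."""
    theta = np.asarray(cdrc.as_tuple())
    A, b = _dense_raw_system(theta)
    perm = _CANON_FROM_INTERNAL
    return MomentSystem(matrix=A[np.ix_(perm, perm)], constant=b[perm], cdrc=cdrc)


_COND_WARN_THRESHOLD = 1e12


def _central_to_raw(x_central: np.ndarray, pon: float, scales: np.ndarray) -> np.ndarray:
    """Convert solved central moments to raw moments, internal order.

    E[s^a m^i p^j] = sum over u <= i, v <= j of
    C(i,u) C(j,v) <m>^(i-u) <p>^(j-v) E[s^a dm^u dp^v], with the order-0
    entries E[s^a] = p_on or 1.  All summands are additive in magnitude, so
    the conversion loses no precision (unlike the reverse direction).
    """
    mbar, pbar = scales[1], scales[2]

    def central(a, u, v):
        if u == 0 and v == 0:
            return pon if a == 1 else 1.0
        return x_central[_INTERNAL_POS[(a, u, v)]]

    out = np.empty(N_EQUATIONS)
    for mono, k in _INTERNAL_POS.items():
        a, i, j = mono
        acc = 0.0
        for u in range(i + 1):
            for v in range(j + 1):
                acc += (comb(i, u) * comb(j, v)
                        * mbar ** (i - u) * pbar ** (j - v) * central(a, u, v))
        out[k] = acc
    return out


def solve_partial_moments(cdrc: CDRCSet) -> PartialMomentVector:
    """Solve the steady-state system for all 28 tracked raw moments.

    Rates are pre-scaled by their geometric mean (the stationary law is
    invariant under uniform time rescaling) and the solve runs in central
    coordinates for accuracy; a warning is emitted when the raw system is
    ill-conditioned enough that downstream use of the large raw moments may
    lose precision.
    """
    theta = np.asarray(cdrc.as_tuple())
    th = _rescale_theta(theta)
    x = np.zeros(28)
    if not _solve_blocks(th, 4, *_kernel_args(), x):
        raise np.linalg.LinAlgError("singular moment system (degenerate rates)")
    pon, scales = _scales_from_theta(th)
    raw = _central_to_raw(x, pon, scales)
    cond = _central_condition(th, pon, scales)
    if cond > _COND_WARN_THRESHOLD:
        warnings.warn(
            f"moment system condition number {cond:.2e} exceeds "
            f"{_COND_WARN_THRESHOLD:.0e}; solved moments may lose precision",
            RuntimeWarning,
            stacklevel=2,
        )
    return PartialMomentVector(values=raw[_CANON_FROM_INTERNAL].copy(), p_on=float(pon))


def _central_condition(theta: np.ndarray, pon: float, scales: np.ndarray) -> float:
    """Worst condition number over the four central solve blocks."""
    worst = 0.0
    for blk in range(4):
        n = int(_BLOCK_SIZES[blk])
        A = np.zeros((n, n))
        for e in range(_A_OFF[blk], _A_OFF[blk + 1]):
            ent = _A_ENT[e]
            A[ent[1], ent[2]] += theta[ent[3]] * scales[ent[4]] * ent[5]
        worst = max(worst, float(np.linalg.cond(A)))
    return worst


def moments_from_rates(rates) -> tuple[float, float, float, float]:
    """Raw (M, V, mu3, mu4) for a six-rate tuple in CDRC field order.

    Low-level entry point that skips :class:`CDRCSet` validation so
    degenerate edge cases (e.g. ``k_r = 0``, where every RNA/protein moment
    is zero) remain computable.  Degradation rates and ``k_on`` must still
    be positive.
    """
    theta = np.asarray(rates, dtype=float)
    if theta.shape != (6,):
        raise ValidationError("expected six rates in CDRC field order")
    if theta[0] <= 0 or theta[4] <= 0 or theta[5] <= 0 or np.any(theta < 0):
        raise ValidationError("k_on, g_r, g_p must be positive; no rate may be negative")
    ok, M, V, S, K = _protein_moments_kernel(theta, *_kernel_args())
    if not ok:
        raise np.linalg.LinAlgError("singular moment system")
    return float(M), float(V), float(S), float(K)


def protein_central_moments(cdrc: CDRCSet) -> MomentVector:
    """Exact protein mean, variance, mu3 and mu4 for one CDRC set."""
    M, V, S, K = moments_from_rates(cdrc.as_tuple())
    return MomentVector(M=M, V=V, S=S, K=K)


def rna_moments(cdrc: CDRCSet) -> tuple[float, float, float]:
    """Steady-state RNA (mean, variance, Fano factor).

    The Fano factor is 1 for constitutive transcription (k_off = 0) and
    exceeds 1 whenever promoter switching makes transcription bursty.
    """
    theta = np.asarray(cdrc.as_tuple())
    th = _rescale_theta(theta)
    x = np.zeros(28)
    if not _solve_blocks(th, 2, *_kernel_args(), x):
        raise np.linalg.LinAlgError("singular moment system")
    _, scales = _scales_from_theta(th)
    mean = scales[1]
    var = x[_POS_M2]
    if mean <= 0.0:
        raise ValidationError("RNA mean is zero; Fano factor undefined")
    return float(mean), float(var), float(var / mean)


def mean_protein(cdrc: CDRCSet) -> float:
    """Closed-form steady-state protein mean.

    M = k_r * k_p * k_on / (g_r * g_p * (k_on + k_off)) — the product of the
    mean RNA count and the proteins made per RNA lifetime.
    """
    k_on, k_off, k_r, k_p, g_r, g_p = cdrc.as_tuple()
    return (k_r * k_p * k_on) / (g_r * g_p * (k_on + k_off))


def solve_mean_for_param(M: float, fixed: dict[str, float], which: str) -> float | None:
    """Invert the closed-form mean for the one unspecified rate.

    ``fixed`` supplies the other five rates.  Returns the unique value of
    ``which`` that reproduces protein mean ``M``, or ``None`` when no
    non-negative value can (possible only for ``k_on``/``k_off``, where the
    promoter occupancy k_on/(k_on+k_off) is capped at 1).  ``None`` is a
    typed infeasibility signal so grid-search callers can prune branches
    without exception overhead.
    """
    if not (M > 0 and math.isfinite(M)):
        raise ValidationError(f"target mean must be positive and finite, got {M!r}")
    if which not in CDRC_FIELDS:
        raise ValidationError(f"unknown CDRC field {which!r}")
    missing = [f for f in CDRC_FIELDS if f != which and f not in fixed]
    if missing:
        raise ValidationError(f"fixed values missing for {missing}")
    f = {k: float(fixed[k]) for k in CDRC_FIELDS if k != which}
    if which in ("k_on", "k_off"):
        # occupancy demanded of the promoter: Q = p_on required
        Q = M * f["g_r"] * f["g_p"] / (f["k_r"] * f["k_p"])
        if which == "k_on":
            if Q >= 1.0:
                return None  # would need p_on >= 1 with k_off > 0
            return Q * f["k_off"] / (1.0 - Q)
        if Q > 1.0:
            return None  # p_on cannot exceed 1
        return f["k_on"] * (1.0 - Q) / Q
    p_on = f["k_on"] / (f["k_on"] + f["k_off"])
    if which == "k_r":
        return M * f["g_r"] * f["g_p"] / (f["k_p"] * p_on)
    if which == "k_p":
        return M * f["g_r"] * f["g_p"] / (f["k_r"] * p_on)
    if which == "g_r":
        return f["k_r"] * f["k_p"] * p_on / (M * f["g_p"])
    return f["k_r"] * f["k_p"] * p_on / (M * f["g_r"])  # g_p
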