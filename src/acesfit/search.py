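"""ACES: Analytically Constrained Exhaustive Search over rate-constant space.

The inverse problem — which six-rate sets reproduce a measured set of
protein-distribution moments — is solved by exhaustive enumeration of a
log-spaced grid, made tractable by the closed-form mean equation

    M = k_r * k_p * k_on / (g_r * g_p * (k_on + k_off)).

Parameters are assigned one at a time in a configurable order.  Each
assignment, together with the target mean and the physiological ranges of
the still-free parameters, analytically brackets the admissible interval of
the next parameter (the mean is monotone in every rate, so evaluating the
inversion at the corners of the free parameters' ranges is exact).  The
enumeration grid of the next parameter is then restricted to that interval,
and the *last* free parameter is never enumerated at all — it is solved
exactly from the mean.  Every candidate that reaches the moment screen
therefore already satisfies the mean equation; candidates are then screened
against the higher moments in increasing cost order (variance, then mu3,
then mu4), each at a per-moment relative tolerance, and survivors form the
returned solution ensemble.

The search is deterministic: for a given target and configuration the same
ensemble is returned, sorted by rate values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .model import (
    CDRC_FIELDS,
    CDRCRanges,
    CDRCSet,
    MomentVector,
    RatioSet,
    ValidationError,
    compute_ratios,
)
from .moments import (
    _A_ENT,
    _A_OFF,
    _BLOCK_SIZES,
    _BLOCK_STARTS,
    _POS_P2,
    _POS_P3,
    _POS_P4,
    _R_ENT,
    _R_OFF,
    _rescale_theta,
    _scales_from_theta,
    _solve_one_block,
    mean_protein,
    protein_central_moments,
    solve_mean_for_param,
)

__all__ = [
    "ACESConfig",
    "SolutionEnsemble",
    "aces_fit",
    "propagate_bounds",
    "rescale_resolution",
    "count_grid",
    "DEFAULT_ORDER",
]

#: default assignment order: switching rates first, translation late, protein
#: degradation solved exactly from the mean at the end
DEFAULT_ORDER: tuple[str, ...] = ("k_on", "k_off", "k_r", "g_r", "k_p", "g_p")

_MOMENT_SUBSETS = ("MV", "MVS", "MVSK")

# relative slack when intersecting analytic bounds / matching lattice nodes,
# guarding against float exclusion of exactly-on-boundary candidates
_EDGE_RTOL = 1e-9


@dataclass(frozen=True)
class ACESConfig:
    """Configuration of one ACES run.

    resolution   grid subdivisions per rate across its full range (the
                 default 83 makes the nominal space 83^6, about 327
                 billion sets)
    ranges       physiological (min, max) per rate; the search never leaves
                 these
    order        full assignment order over the six rates; the last *free*
                 entry is solved from the mean, the others are enumerated
    reverse      flip the enumerated parameters' order (the documented
                 remedy for targets resistant to the forward order)
    fixed        rates known a priori (e.g. measured degradation rates);
                 never enumerated
    tol          per-moment relative tolerance of the screen (default 1%)
    moments      which moments to screen: "MV" (variance only beyond the
                 mean), "MVS" (+ mu3) or "MVSK" (+ mu4)
    grid_mode    "lattice": enumerate the fixed full-range grid nodes that
                 fall inside each constrained interval (keeps every
                 candidate on one global lattice, so on-grid truths are
                 never missed); "respaced": re-subdivide each constrained
                 interval with a proportionally reduced number of points
    """

    ranges: CDRCRanges
    resolution: int = 83
    order: tuple[str, ...] = DEFAULT_ORDER
    reverse: bool = False
    fixed: dict[str, float] = field(default_factory=dict)
    tol: float = 0.01
    moments: str = "MVSK"
    grid_mode: str = "lattice"

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ValidationError("resolution must be >= 2")
        if tuple(sorted(self.order)) != tuple(sorted(CDRC_FIELDS)):
            raise ValidationError(f"order must be a permutation of {CDRC_FIELDS}")
        if not self.tol > 0:
            raise ValidationError("tolerance must be positive")
        if self.moments not in _MOMENT_SUBSETS:
            raise ValidationError(f"moments must be one of {_MOMENT_SUBSETS}")
        if self.grid_mode not in ("lattice", "respaced"):
            raise ValidationError("grid_mode must be 'lattice' or 'respaced'")
        for name, value in self.fixed.items():
            if name not in CDRC_FIELDS:
                raise ValidationError(f"unknown fixed parameter {name!r}")
            lo, hi = self.ranges[name]
            if not lo <= value <= hi:
                raise ValidationError(f"fixed {name}={value} outside its range ({lo}, {hi})")

    @property
    def enumerated(self) -> tuple[str, ...]:
        """Enumerated parameters, in the order they are assigned."""
        free = [f for f in self.order if f not in self.fixed]
        enum = free[:-1]
        if self.reverse:
            enum = enum[::-1]
        return tuple(enum)

    @property
    def solved(self) -> str | None:
        """The parameter solved exactly from the mean (None if all fixed)."""
        free = [f for f in self.order if f not in self.fixed]
        return free[-1] if free else None


@dataclass(frozen=True)
class SolutionEnsemble:
    """Everything one ACES run returns.

    ``solutions`` are sorted by rate values, each paired with its forward
    moments and mechanistic ratios.  ``diagnostic`` is empty on a normal
    run; an empty ensemble carries either "infeasible mean" (no point of
    the constrained space can reach the target mean) or "no moment match".
    """

    solutions: tuple[CDRCSet, ...]
    moments: tuple[MomentVector, ...]
    ratios: tuple[RatioSet, ...]
    target: MomentVector
    config: ACESConfig
    n_tested: int
    nominal_space: int
    diagnostic: str = ""

    def __len__(self) -> int:
        return len(self.solutions)


def count_grid(resolution: int, dims: int = 6) -> int:
    """Size of the unconstrained search space: resolution ** dims."""
    if resolution < 1:
        raise ValidationError("resolution must be >= 1")
    return resolution**dims


def rescale_resolution(n: int, full_logwidth: float, constrained_logwidth: float) -> int:
    """Shrink resolution by the fraction of (log) parameter space retained."""
    if not 0 <= constrained_logwidth <= full_logwidth * (1 + _EDGE_RTOL):
        raise ValidationError("constrained width must lie within the full width")
    return max(1, round(n * constrained_logwidth / full_logwidth))


def propagate_bounds(
    M: float,
    assigned: dict[str, float],
    ranges: CDRCRanges,
    next_param: str,
) -> tuple[float, float] | None:
    """Admissible interval of ``next_param`` given the mean and assignments.

    The mean equation is monotone in every rate, so solving it for
    ``next_param`` at the extreme corners of the remaining free parameters'
    ranges brackets its feasible values exactly; the bracket is then
    intersected with the parameter's own physiological range.  Returns
    ``None`` when the intersection is empty (the branch can be pruned).
    Corner inversions with no non-negative solution are the monotone limits
    of the bracket: +inf for k_on (occupancy saturating at 1) and 0 for
    k_off.
    """
    if next_param in assigned:
        raise ValidationError(f"{next_param!r} is already assigned")
    free = [f for f in CDRC_FIELDS if f not in assigned and f != next_param]
    vmin = math.inf
    vmax = -math.inf
    for mask in range(1 << len(free)):
        corner = dict(assigned)
        for b, f in enumerate(free):
            corner[f] = ranges[f][(mask >> b) & 1]
        v = solve_mean_for_param(M, corner, next_param)
        if v is None:
            v = math.inf if next_param == "k_on" else 0.0
        vmin = min(vmin, v)
        vmax = max(vmax, v)
    lo, hi = ranges[next_param]
    blo = max(vmin * (1 - _EDGE_RTOL), lo)
    bhi = min(vmax * (1 + _EDGE_RTOL), hi)
    if blo > bhi:
        return None
    return (blo, bhi)


# --------------------------------------------------------------------------
# numba kernels for the innermost enumeration levels
# --------------------------------------------------------------------------


@njit(cache=False)
def _solve_mean_idx(M, theta, which):
    """Mean-equation inversion by parameter index (see solve_mean_for_param).

    Infeasible corners return the monotone limit of the inversion: +inf for
    k_on, 0.0 for k_off.
    """
    if which == 0:
        Q = M * theta[4] * theta[5] / (theta[2] * theta[3])
        if Q >= 1.0:
            return np.inf
        return Q * theta[1] / (1.0 - Q)
    if which == 1:
        Q = M * theta[4] * theta[5] / (theta[2] * theta[3])
        if Q > 1.0:
            return 0.0
        return theta[0] * (1.0 - Q) / Q
    pon = theta[0] / (theta[0] + theta[1])
    if which == 2:
        return M * theta[4] * theta[5] / (theta[3] * pon)
    if which == 3:
        return M * theta[4] * theta[5] / (theta[2] * pon)
    if which == 4:
        return theta[2] * theta[3] * pon / (M * theta[5])
    return theta[2] * theta[3] * pon / (M * theta[4])


@njit(cache=False)
def _corner_bounds(M, theta, free_mask, next_idx, lo_arr, hi_arr):
    """Bracket next_idx over the corners of the free parameters' ranges."""
    free = np.empty(6, np.int64)
    nfree = 0
    for k in range(6):
        if free_mask[k] and k != next_idx:
            free[nfree] = k
            nfree += 1
    saved = np.empty(6)
    for t in range(nfree):
        saved[t] = theta[free[t]]
    vmin = np.inf
    vmax = -np.inf
    for mask in range(1 << nfree):
        for b in range(nfree):
            f = free[b]
            theta[f] = hi_arr[f] if (mask >> b) & 1 else lo_arr[f]
        v = _solve_mean_idx(M, theta, next_idx)
        if v < vmin:
            vmin = v
        if v > vmax:
            vmax = v
    for t in range(nfree):
        theta[free[t]] = saved[t]
    blo = vmin * (1.0 - _EDGE_RTOL)
    bhi = vmax * (1.0 + _EDGE_RTOL)
    if blo < lo_arr[next_idx]:
        blo = lo_arr[next_idx]
    if bhi > hi_arr[next_idx]:
        bhi = hi_arr[next_idx]
    return blo, bhi


@njit(cache=False)
def _level_points(pidx, blo, bhi, lattices, lat_off, lat_len, grid_mode,
                  resolution, lo_arr, hi_arr, buf):
    """Candidate values of parameter ``pidx`` inside [blo, bhi] -> buf; count."""
    n = 0
    if grid_mode == 0:  # lattice: full-range grid nodes inside the interval
        o = lat_off[pidx]
        for t in range(lat_len[pidx]):
            v = lattices[o + t]
            if blo * (1.0 - _EDGE_RTOL) <= v <= bhi * (1.0 + _EDGE_RTOL):
                buf[n] = v
                n += 1
    else:  # respaced: proportionally fewer points, re-spread over the interval
        full_lw = np.log10(hi_arr[pidx]) - np.log10(lo_arr[pidx])
        cw = np.log10(bhi) - np.log10(blo)
        if cw < 0.0:
            cw = 0.0
        npts = int(np.round(resolution * cw / full_lw))
        if npts < 1:
            npts = 1
        if npts == 1:
            buf[0] = np.sqrt(blo * bhi)
            n = 1
        else:
            llo = np.log10(blo)
            step = cw / (npts - 1)
            for t in range(npts):
                buf[n] = 10.0 ** (llo + t * step)
                n += 1
    return n


@njit(cache=False)
def _screen(theta, tV, tS, tK, n_moments, tol,
            a_ent, a_off, r_ent, r_off, bsz, bst):
    """Staged moment screen: variance, then mu3, then mu4, cheapest first.

    The central-coordinate blocks deliver V, mu3 and mu4 directly; the mean
    is exact by construction, so only the selected higher moments are
    checked, each stage solving one more block than the last.
    """
    th = _rescale_theta(theta)
    pon, scales = _scales_from_theta(th)
    known = np.zeros(30)
    known[0] = 1.0
    known[1] = pon
    x = np.zeros(28)
    for blk in range(2):
        if not _solve_one_block(blk, th, scales, known, x,
                                a_ent, a_off, r_ent, r_off, bsz, bst):
            return False
    if abs(x[_POS_P2] - tV) > tol * max(abs(tV), 1e-12):
        return False
    if n_moments >= 3:
        if not _solve_one_block(2, th, scales, known, x,
                                a_ent, a_off, r_ent, r_off, bsz, bst):
            return False
        if abs(x[_POS_P3] - tS) > tol * max(abs(tS), 1e-12):
            return False
    if n_moments >= 4:
        if not _solve_one_block(3, th, scales, known, x,
                                a_ent, a_off, r_ent, r_off, bsz, bst):
            return False
        if abs(x[_POS_P4] - tK) > tol * max(abs(tK), 1e-12):
            return False
    return True


@njit(cache=False)
def _scan_tail(M, tV, tS, tK, n_moments, tol, theta, free_mask,
               tail_idx, n_tail, solved_idx, lo_arr, hi_arr,
               lattices, lat_off, lat_len, grid_mode, resolution,
               buf_a, buf_b, out_buf,
               a_ent, a_off, r_ent, r_off, bsz, bst):
    """Enumerate the last 1 or 2 levels, solve the final rate, screen.

    Writes accepted six-rate rows into out_buf; returns (found, tested)
    where tested counts complete mean-satisfying candidates screened.
    """
    found = 0
    tested = 0
    p_a = tail_idx[0]
    if n_tail == 2:
        blo, bhi = _corner_bounds(M, theta, free_mask, p_a, lo_arr, hi_arr)
        if blo > bhi:
            return found, tested
        na = _level_points(p_a, blo, bhi, lattices, lat_off, lat_len,
                           grid_mode, resolution, lo_arr, hi_arr, buf_a)
        p_b = tail_idx[1]
        free_mask[p_a] = False
        for ia in range(na):
            theta[p_a] = buf_a[ia]
            blo_b, bhi_b = _corner_bounds(M, theta, free_mask, p_b, lo_arr, hi_arr)
            if blo_b > bhi_b:
                continue
            nb = _level_points(p_b, blo_b, bhi_b, lattices, lat_off, lat_len,
                               grid_mode, resolution, lo_arr, hi_arr, buf_b)
            free_mask[p_b] = False
            for ib in range(nb):
                theta[p_b] = buf_b[ib]
                v = _solve_mean_idx(M, theta, solved_idx)
                if not (lo_arr[solved_idx] * (1.0 - _EDGE_RTOL) <= v
                        <= hi_arr[solved_idx] * (1.0 + _EDGE_RTOL)):
                    continue
                theta[solved_idx] = v
                tested += 1
                if _screen(theta, tV, tS, tK, n_moments, tol,
                           a_ent, a_off, r_ent, r_off, bsz, bst):
                    for k in range(6):
                        out_buf[found, k] = theta[k]
                    found += 1
            free_mask[p_b] = True
        free_mask[p_a] = True
    else:
        blo, bhi = _corner_bounds(M, theta, free_mask, p_a, lo_arr, hi_arr)
        if blo > bhi:
            return found, tested
        na = _level_points(p_a, blo, bhi, lattices, lat_off, lat_len,
                           grid_mode, resolution, lo_arr, hi_arr, buf_a)
        free_mask[p_a] = False
        for ia in range(na):
            theta[p_a] = buf_a[ia]
            v = _solve_mean_idx(M, theta, solved_idx)
            if not (lo_arr[solved_idx] * (1.0 - _EDGE_RTOL) <= v
                    <= hi_arr[solved_idx] * (1.0 + _EDGE_RTOL)):
                continue
            theta[solved_idx] = v
            tested += 1
            if _screen(theta, tV, tS, tK, n_moments, tol,
                       a_ent, a_off, r_ent, r_off, bsz, bst):
                for k in range(6):
                    out_buf[found, k] = theta[k]
                found += 1
        free_mask[p_a] = True
    return found, tested


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------


def _mean_reachable(M: float, ranges: CDRCRanges, fixed: dict[str, float]) -> bool:
    """Is the target mean inside the image of the (fixed-respecting) box?

    The mean is monotone per rate, so the extremes sit at one corner each:
    increasing in k_on, k_r, k_p; decreasing in k_off, g_r, g_p.
    """
    sense = {"k_on": +1, "k_off": -1, "k_r": +1, "k_p": +1, "g_r": -1, "g_p": -1}

    def corner(direction: int) -> float:
        vals = {}
        for f in CDRC_FIELDS:
            if f in fixed:
                vals[f] = fixed[f]
            else:
                lo, hi = ranges[f]
                vals[f] = hi if sense[f] * direction > 0 else lo
        return mean_protein(CDRCSet(**vals))

    return corner(-1) * (1 - _EDGE_RTOL) <= M <= corner(+1) * (1 + _EDGE_RTOL)


def aces_fit(target: MomentVector, config: ACESConfig) -> SolutionEnsemble:
    """Run the constrained exhaustive search for one moment target.

    Returns every rate set on the constrained enumeration whose selected
    moments match ``target`` within the per-moment tolerance.  The mean is
    satisfied exactly by construction; accepted sets are re-evaluated
    through the full forward moment solver for the recorded per-solution
    moments.
    """
    ranges = config.ranges
    fixed = dict(config.fixed)
    enum = config.enumerated
    solved = config.solved
    n_moments = {"MV": 2, "MVS": 3, "MVSK": 4}[config.moments]
    nominal = count_grid(config.resolution, 6)

    lo_arr = np.array([ranges[f][0] for f in CDRC_FIELDS])
    hi_arr = np.array([ranges[f][1] for f in CDRC_FIELDS])
    res = config.resolution
    lattices = np.concatenate(
        [np.logspace(math.log10(ranges[f][0]), math.log10(ranges[f][1]), res)
         for f in CDRC_FIELDS]
    )
    lat_off = np.arange(6, dtype=np.int64) * res
    lat_len = np.full(6, res, dtype=np.int64)
    fidx = {f: k for k, f in enumerate(CDRC_FIELDS)}
    grid_mode = 0 if config.grid_mode == "lattice" else 1

    theta = np.zeros(6)
    free_mask = np.zeros(6, dtype=np.bool_)
    for f in CDRC_FIELDS:
        if f in fixed:
            theta[fidx[f]] = fixed[f]
        else:
            free_mask[fidx[f]] = True

    if not _mean_reachable(target.M, ranges, fixed):
        return SolutionEnsemble(
            solutions=(), moments=(), ratios=(), target=target, config=config,
            n_tested=0, nominal_space=nominal, diagnostic="infeasible mean",
        )

    rows: list[np.ndarray] = []
    tested_total = 0

    struct = (_A_ENT, _A_OFF, _R_ENT, _R_OFF, _BLOCK_SIZES, _BLOCK_STARTS)
    buf_a = np.zeros(res + 2)
    buf_b = np.zeros(res + 2)
    out_buf = np.zeros(((res + 2) * (res + 2), 6))

    def screen_single() -> None:
        """All parameters placed in theta; mean already guaranteed."""
        nonlocal tested_total
        tested_total += 1
        if _screen(theta, target.V, target.S, target.K, n_moments, config.tol, *struct):
            rows.append(theta.copy())

    if solved is None:
        # every rate fixed: the candidate is the fixed set itself, admitted
        # only if it reproduces the mean to float round-off
        if abs(mean_protein(CDRCSet(*theta)) - target.M) <= 1e-9 * target.M:
            screen_single()
    elif not enum:
        v = solve_mean_for_param(target.M, {f: theta[fidx[f]] for f in CDRC_FIELDS if f != solved}, solved)
        lo, hi = ranges[solved]
        if v is not None and lo * (1 - _EDGE_RTOL) <= v <= hi * (1 + _EDGE_RTOL):
            theta[fidx[solved]] = v
            screen_single()
    else:
        n_tail = min(len(enum), 2)
        head = enum[:-n_tail]
        tail_idx = np.array([fidx[f] for f in enum[-n_tail:]], dtype=np.int64)
        solved_idx = fidx[solved]

        def run_tail() -> None:
            nonlocal tested_total
            found, tested = _scan_tail(
                target.M, target.V, target.S, target.K, n_moments, config.tol,
                theta, free_mask, tail_idx, n_tail, solved_idx, lo_arr, hi_arr,
                lattices, lat_off, lat_len, grid_mode, res,
                buf_a, buf_b, out_buf, *struct,
            )
            tested_total += tested
            for r in range(found):
                rows.append(out_buf[r].copy())

        def descend(level: int) -> None:
            if level == len(head):
                run_tail()
                return
            pidx = fidx[head[level]]
            blo, bhi = _corner_bounds(target.M, theta, free_mask, pidx, lo_arr, hi_arr)
            if blo > bhi:
                return
            buf = np.zeros(res + 2)
            n = _level_points(pidx, blo, bhi, lattices, lat_off, lat_len,
                              grid_mode, res, lo_arr, hi_arr, buf)
            free_mask[pidx] = False
            for t in range(n):
                theta[pidx] = buf[t]
                descend(level + 1)
            free_mask[pidx] = True

        descend(0)

    if not rows:
        diag = "infeasible mean" if tested_total == 0 else "no moment match"
        return SolutionEnsemble(
            solutions=(), moments=(), ratios=(), target=target, config=config,
            n_tested=tested_total, nominal_space=nominal, diagnostic=diag,
        )

    order = np.lexsort(np.array(rows).T[::-1])
    solutions = tuple(CDRCSet(*rows[i]) for i in order)
    momvecs = tuple(protein_central_moments(s) for s in solutions)
    ratios = tuple(compute_ratios(s) for s in solutions)
    return SolutionEnsemble(
        solutions=solutions, moments=momvecs, ratios=ratios, target=target,
        config=config, n_tested=tested_total, nominal_space=nominal,
    )
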