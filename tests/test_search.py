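"""The constrained exhaustive search: bounds, grids, soundness, completeness."""

import math

import numpy as np
import pytest

from acesfit.fixtures import make_planted_target
from acesfit.model import CDRC_FIELDS, CDRCRanges, CDRCSet, MomentVector, ValidationError
from acesfit.moments import mean_protein, protein_central_moments, solve_mean_for_param
from acesfit.search import (
    ACESConfig,
    aces_fit,
    count_grid,
    propagate_bounds,
    rescale_resolution,
)


def lattice(ranges, field, resolution):
    lo, hi = ranges[field]
    return np.logspace(math.log10(lo), math.log10(hi), resolution)


def naive_ensemble(target, config):
    """Brute-force oracle: full 5-D lattice, last rate solved from the mean.

    Enumerates every combination of lattice nodes for the enumerated
    parameters with no analytic pruning, solves the final parameter from
    the mean, and screens all selected moments via the forward solver.
    """
    from itertools import product

    enum = config.enumerated
    solved = config.solved
    grids = [lattice(config.ranges, f, config.resolution) for f in enum]
    lo_s, hi_s = config.ranges[solved]
    n_check = {"MV": 2, "MVS": 3, "MVSK": 4}[config.moments]
    found = []
    for combo in product(*grids):
        fixed = dict(zip(enum, combo))
        fixed.update(config.fixed)
        v = solve_mean_for_param(target.M, fixed, solved)
        if v is None or not (lo_s * (1 - 1e-9) <= v <= hi_s * (1 + 1e-9)):
            continue
        cand = CDRCSet(**fixed, **{solved: v})
        mv = protein_central_moments(cand)
        calc = mv.as_tuple()[1:n_check]
        want = target.as_tuple()[1:n_check]
        if all(abs(c - w) <= config.tol * max(abs(w), 1e-12) for c, w in zip(calc, want)):
            found.append(cand.as_tuple())
    return sorted(found)


class TestGridArithmetic:
    def test_default_scale_space_is_327_billion(self):
        assert count_grid(83, 6) == 83**6
        assert round(count_grid(83, 6) / 1e9) == 327

    @pytest.mark.parametrize("res,dims,expected", [(1, 6, 1), (2, 3, 8)])
    def test_small_grids(self, res, dims, expected):
        assert count_grid(res, dims) == expected

    def test_rescale_keeps_full_width_resolution(self):
        assert rescale_resolution(83, 4.0, 4.0) == 83

    def test_rescale_halved_width_rounds(self):
        assert rescale_resolution(83, 4.0, 2.0) == 42  # round(41.5)

    def test_rescale_point_interval_is_one(self):
        assert rescale_resolution(83, 4.0, 0.0) == 1


class TestPropagateBounds:
    def test_nothing_assigned_wide_ranges_returns_full_range(self, two_decade_ranges):
        got = propagate_bounds(100.0, {}, two_decade_ranges, "k_r")
        assert got == pytest.approx(two_decade_ranges["k_r"], rel=1e-8)

    def test_five_assigned_pins_the_interval_to_the_solved_value(self, two_decade_ranges):
        c = CDRCSet(0.5, 0.5, 5.0, 1.0, 1.0, 0.05)
        M = mean_protein(c)
        assigned = {f: getattr(c, f) for f in CDRC_FIELDS if f != "k_p"}
        lo, hi = propagate_bounds(M, assigned, two_decade_ranges, "k_p")
        assert lo == pytest.approx(1.0, rel=1e-6)
        assert hi == pytest.approx(1.0, rel=1e-6)

    def test_out_of_reach_mean_is_infeasible(self, two_decade_ranges):
        # demanded mean above anything the ranges can produce, with the
        # other five parameters pinned at their minima
        assigned = {f: two_decade_ranges[f][0] for f in CDRC_FIELDS if f != "k_r"}
        assert propagate_bounds(1e9, assigned, two_decade_ranges, "k_r") is None

    def test_agrees_with_dense_feasibility_scan(self, two_decade_ranges):
        """Oracle: 200^2 grid over the two free parameters.

        With four parameters assigned, the bracket for the next one must
        match the set of values admitting any (k_p, g_p) completion that
        reproduces the mean inside the ranges.
        """
        M = 800.0
        assigned = dict(k_on=0.5, k_off=0.5, k_r=5.0, g_r=1.0)
        got = propagate_bounds(M, assigned, two_decade_ranges, "k_p")
        # dense scan: for which k_p does some g_p in range give the mean?
        kp_grid = np.logspace(*np.log10(two_decade_ranges["k_p"]), 200)
        glo, ghi = two_decade_ranges["g_p"]
        feasible = []
        for kp in kp_grid:
            g_p = solve_mean_for_param(M, {**assigned, "k_p": kp}, "g_p")
            if g_p is not None and glo <= g_p <= ghi:
                feasible.append(kp)
        assert got is not None
        lo, hi = got
        assert lo <= feasible[0] and feasible[-1] <= hi
        # the bracket is tight: no more than one grid step of slack
        assert lo == pytest.approx(feasible[0], rel=0.05)
        assert hi == pytest.approx(feasible[-1], rel=0.05)


class TestACESFit:
    def test_planted_truth_recovered_with_sound_moments(self, two_decade_ranges):
        truth, target = make_planted_target(two_decade_ranges, resolution=10, seed=5)
        ens = aces_fit(target, ACESConfig(ranges=two_decade_ranges, resolution=10))
        assert len(ens) >= 1
        assert ens.diagnostic == ""
        tt = np.asarray(truth.as_tuple())
        assert any(np.allclose(s.as_tuple(), tt, rtol=1e-9) for s in ens.solutions)
        for mv in ens.moments:
            for got, want in zip(mv.as_tuple(), target.as_tuple()):
                assert abs(got - want) <= 0.01 * max(abs(want), 1e-12)

    def test_all_six_fixed_returns_exactly_the_truth(self, two_decade_ranges):
        truth, target = make_planted_target(two_decade_ranges, resolution=8, seed=9)
        cfg = ACESConfig(
            ranges=two_decade_ranges, resolution=8,
            fixed={f: getattr(truth, f) for f in CDRC_FIELDS},
        )
        ens = aces_fit(target, cfg)
        assert len(ens) == 1
        assert ens.solutions[0].as_tuple() == pytest.approx(truth.as_tuple())

    def test_unreachable_mean_reports_infeasible(self, two_decade_ranges):
        r = two_decade_ranges
        too_high = (r["k_r"][1] * r["k_p"][1]) / (r["g_r"][0] * r["g_p"][0]) * 10
        target = MomentVector(M=too_high, V=too_high**2, S=0.0, K=too_high**4 * 3.1)
        ens = aces_fit(target, ACESConfig(ranges=r, resolution=6))
        assert len(ens) == 0
        assert ens.diagnostic == "infeasible mean"
        assert ens.n_tested == 0

    def test_matches_naive_full_grid_filter(self, two_decade_ranges):
        """Completeness + soundness against the brute-force oracle at n <= 8."""
        for seed in (1, 2):
            truth, target = make_planted_target(two_decade_ranges, resolution=6, seed=seed)
            cfg = ACESConfig(ranges=two_decade_ranges, resolution=6)
            got = sorted(s.as_tuple() for s in aces_fit(target, cfg).solutions)
            want = naive_ensemble(target, cfg)
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert g == pytest.approx(w, rel=1e-9)

    def test_moment_subsets_are_nested(self, two_decade_ranges):
        truth, target = make_planted_target(two_decade_ranges, resolution=8, seed=17)
        sols = {}
        for subset in ("MV", "MVS", "MVSK"):
            cfg = ACESConfig(ranges=two_decade_ranges, resolution=8, moments=subset)
            sols[subset] = {
                tuple(np.round(np.log10(s.as_tuple()), 9)) for s in aces_fit(target, cfg).solutions
            }
        assert sols["MVSK"] <= sols["MVS"] <= sols["MV"]
        assert len(sols["MV"]) >= 1

    def test_fixing_degradation_rates_never_widens_solution_ranges(self, two_decade_ranges):
        """Knowing g_r and/or g_p can only sharpen the remaining rates."""
        for seed in (3, 8, 23):
            truth, target = make_planted_target(two_decade_ranges, resolution=8, seed=seed)
            base_cfg = ACESConfig(ranges=two_decade_ranges, resolution=8)
            base = aces_fit(target, base_cfg)
            if len(base) == 0:
                continue
            for fixed in ({"g_r": truth.g_r}, {"g_p": truth.g_p},
                          {"g_r": truth.g_r, "g_p": truth.g_p}):
                cfg = ACESConfig(ranges=two_decade_ranges, resolution=8, fixed=fixed)
                constrained = aces_fit(target, cfg)
                if len(constrained) == 0:
                    continue
                for f in CDRC_FIELDS:
                    if f in fixed:
                        continue
                    b_vals = [getattr(s, f) for s in base.solutions]
                    c_vals = [getattr(s, f) for s in constrained.solutions]
                    width_b = math.log10(max(b_vals)) - math.log10(min(b_vals))
                    width_c = math.log10(max(c_vals)) - math.log10(min(c_vals))
                    assert width_c <= width_b + 1e-9

    def test_deterministic_and_sorted(self, two_decade_ranges):
        truth, target = make_planted_target(two_decade_ranges, resolution=8, seed=31)
        cfg = ACESConfig(ranges=two_decade_ranges, resolution=8)
        a = aces_fit(target, cfg)
        b = aces_fit(target, cfg)
        assert [s.as_tuple() for s in a.solutions] == [s.as_tuple() for s in b.solutions]
        assert sorted(s.as_tuple() for s in a.solutions) == [s.as_tuple() for s in a.solutions]

    def test_reverse_order_still_recovers_planted_truth(self, two_decade_ranges):
        truth, target = make_planted_target(two_decade_ranges, resolution=8, seed=12)
        cfg = ACESConfig(ranges=two_decade_ranges, resolution=8, reverse=True)
        ens = aces_fit(target, cfg)
        tt = np.asarray(truth.as_tuple())
        assert any(np.allclose(s.as_tuple(), tt, rtol=1e-9) for s in ens.solutions)

    def test_respaced_grid_mode_returns_sound_solutions(self, two_decade_ranges):
        truth, target = make_planted_target(two_decade_ranges, resolution=8, seed=2)
        cfg = ACESConfig(ranges=two_decade_ranges, resolution=8, grid_mode="respaced")
        ens = aces_fit(target, cfg)
        for mv in ens.moments:
            for got, want in zip(mv.as_tuple(), target.as_tuple()):
                assert abs(got - want) <= 0.01 * max(abs(want), 1e-12)

    def test_config_validation(self, two_decade_ranges):
        with pytest.raises(ValidationError):
            ACESConfig(ranges=two_decade_ranges, resolution=1)
        with pytest.raises(ValidationError):
            ACESConfig(ranges=two_decade_ranges, order=("k_on",) * 6)
        with pytest.raises(ValidationError):
            ACESConfig(ranges=two_decade_ranges, moments="MK")
        with pytest.raises(ValidationError):
            ACESConfig(ranges=two_decade_ranges, fixed={"g_r": 1e9})
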