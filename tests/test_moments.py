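"""The closed partial-moment system and its exact steady-state solution.

Two independent oracles back these tests: (1) the FSP stationary solution
of the truncated master equation (conftest), and (2) hand-derived balance
equations for the first two moment orders — the classical route to the
published mean/variance of the two-state model — typed out term by term,
independent of the package's programmatic assembly.
"""

import math

import numpy as np
import pytest

from acesfit.fixtures import make_regime_panel
from acesfit.model import CDRCSet, ValidationError
from acesfit.moments import (
    CANONICAL_INDEX,
    N_EQUATIONS,
    PartialMomentVector,
    assemble_moment_system,
    mean_protein,
    moments_from_rates,
    protein_central_moments,
    rna_moments,
    solve_mean_for_param,
    solve_partial_moments,
)

from conftest import FSP, random_cdrc


def hand_variance(c: CDRCSet) -> tuple[float, float]:
    """Protein mean and variance from hand-derived order-1/2 balances.

    Solves, in sequence: E[s] (closed form), E[m], E[p], then the coupled
    covariances E[sm], E[sp], E[m^2], E[mp], E[p^2] — each equation written
    from the reaction stoichiometry by hand.  Equivalent to the published
    analytical variance of the two-state model.
    """
    k_on, k_off, k_r, k_p, g_r, g_p = c.as_tuple()
    s = k_on / (k_on + k_off)
    m = k_r * s / g_r
    p = k_p * m / g_p
    sm = (k_on * m + k_r * s) / (k_on + k_off + g_r)
    m2 = (2 * k_r * sm + k_r * s + g_r * m) / (2 * g_r)
    sp = (k_on * p + k_p * sm) / (k_on + k_off + g_p)
    mp = (k_r * sp + k_p * m2) / (g_r + g_p)
    p2 = (2 * k_p * mp + k_p * m + g_p * p) / (2 * g_p)
    return p, p2 - p * p


class TestSystemStructure:
    def test_exactly_28_equations_and_unknowns(self):
        system = assemble_moment_system(CDRCSet(1.0, 1.0, 2.0, 1.0, 1.0, 0.5))
        assert N_EQUATIONS == 28
        assert system.matrix.shape == (28, 28)
        assert system.constant.shape == (28,)
        assert len(CANONICAL_INDEX) == 28

    def test_first_moment_rows_read_as_balance_equations(self):
        c = CDRCSet(0.3, 0.7, 2.0, 1.5, 1.1, 0.2)
        system = assemble_moment_system(c)
        pos = {mono: k for k, mono in enumerate(CANONICAL_INDEX)}
        # d<p>/dt = k_p<m> - g_p<p>: row has exactly those two entries
        row_p = system.matrix[pos[(0, 0, 1)]]
        expected = np.zeros(28)
        expected[pos[(0, 1, 0)]] = c.k_p
        expected[pos[(0, 0, 1)]] = -c.g_p
        np.testing.assert_allclose(row_p, expected, atol=1e-14)
        assert system.constant[pos[(0, 0, 1)]] == 0.0
        # d<m>/dt = k_r*p_on - g_r<m>: transcription sources from the
        # substituted promoter occupancy, so it sits in the constant vector
        row_m = system.matrix[pos[(0, 1, 0)]]
        expected = np.zeros(28)
        expected[pos[(0, 1, 0)]] = -c.g_r
        np.testing.assert_allclose(row_m, expected, atol=1e-14)
        p_on = c.k_on / (c.k_on + c.k_off)
        assert system.constant[pos[(0, 1, 0)]] == pytest.approx(-c.k_r * p_on)

    def test_rows_match_generator_action_on_arbitrary_distribution(self, rng):
        """Each assembled row must reproduce d/dt E[g] for *any* state law.

        The balance equations are linear identities in the underlying
        distribution, so for a random distribution pi supported well inside
        a truncated lattice, applying the CME generator to pi and reading
        off d/dt E[s^a m^i p^j] must agree with the row's coefficients
        applied to pi's moments.  This checks every coefficient of the
        assembly against direct differentiation.
        """
        c = CDRCSet(0.8, 1.3, 1.5, 0.9, 1.0, 0.6)
        fsp = FSP(c, mmax=14, pmax=30)
        # random distribution supported away from the truncation boundary
        pi = np.where((fsp.M <= 8) & (fsp.P <= 18), rng.random(fsp.pi.size), 0.0)
        pi /= pi.sum()
        dpi = fsp.generator @ pi

        def raw(dist, a, i, j):
            return float(np.sum(dist * fsp.S**a * fsp.M**i * fsp.P**j))

        system = assemble_moment_system(c)
        moments = np.array([raw(pi, *mono) for mono in CANONICAL_INDEX])
        p_on_pi = raw(pi, 1, 0, 0)
        for k, mono in enumerate(CANONICAL_INDEX):
            lhs = raw(dpi, *mono)  # d/dt E[g] via the generator
            # the assembled row assumes E[s] = p_on (its stationary value);
            # correct for the test distribution's actual E[s]
            rhs = float(system.matrix[k] @ moments) - system.constant[k]
            p_on_stat = c.k_on / (c.k_on + c.k_off)
            rhs += _pon_coefficient(system, k) * (p_on_pi - p_on_stat)
            assert lhs == pytest.approx(rhs, rel=1e-8, abs=1e-10)


def _pon_coefficient(system, row: int) -> float:
    """Coefficient on E[s] in a row, recovered from the constant vector."""
    from acesfit.moments import _R_RAW, _BLOCK_STARTS, _CANON_FROM_INTERNAL

    theta = np.asarray(system.cdrc.as_tuple())
    internal_row = int(_CANON_FROM_INTERNAL[row])
    coeff = 0.0
    for blk, lrow, src, rate_idx, scale, cval in _R_RAW:
        if src == 1 and _BLOCK_STARTS[blk] + lrow == internal_row:
            coeff += theta[rate_idx] * (-cval)  # stored sign-flipped for the RHS
    return coeff


class TestSolverAgainstOracles:
    def test_low_count_panel_matches_fsp_to_1e6(self):
        """Criterion oracle: all four protein central moments vs. dense CME."""
        panel = make_regime_panel("low-count", 5, seed=42)
        for c in panel:
            mv = protein_central_moments(c)
            mmax = 28
            pmax = int(max(60, mv.M + 16 * math.sqrt(mv.V)))
            fsp = FSP(c, mmax=mmax, pmax=pmax)
            assert fsp.boundary_mass < 1e-12
            ref = fsp.protein_central_moments()
            for got, want in zip(mv.as_tuple(), ref):
                assert got == pytest.approx(want, rel=1e-6)

    def test_all_28_moments_match_fsp(self):
        c = CDRCSet(0.6, 0.9, 2.0, 1.2, 1.0, 0.7)
        pm = solve_partial_moments(c)
        fsp = FSP(c, mmax=20, pmax=55)
        assert fsp.boundary_mass < 1e-12
        for mono in CANONICAL_INDEX:
            assert pm[mono] == pytest.approx(fsp.raw_moment(*mono), rel=1e-8, abs=1e-12)
        assert pm.p_on == pytest.approx(c.k_on / (c.k_on + c.k_off))

    def test_variance_matches_hand_derived_closed_form(self, rng):
        """The published mean/variance, rederived by hand, on 100 random sets."""
        for _ in range(100):
            c = random_cdrc(rng)
            mv = protein_central_moments(c)
            mean_ref, var_ref = hand_variance(c)
            assert mv.M == pytest.approx(mean_ref, rel=1e-9)
            assert mv.V == pytest.approx(var_ref, rel=1e-9)


class TestInvariantsAndLimits:
    def test_constitutive_rna_marginal_is_poisson(self):
        """k_off = 0: RNA is Poisson(k_r/g_r) — mu2 = mu3 = mu1, mu4 = mu1 + 3 mu1^2."""
        c = CDRCSet(1.0, 0.0, 3.0, 1.0, 1.0, 0.5)
        pm = solve_partial_moments(c)
        mu1 = pm.total(1, 0)
        assert mu1 == pytest.approx(3.0, rel=1e-12)
        m2, m3, m4 = pm.total(2, 0), pm.total(3, 0), pm.total(4, 0)
        cm2 = m2 - mu1**2
        cm3 = m3 - 3 * mu1 * m2 + 2 * mu1**3
        cm4 = m4 - 4 * mu1 * m3 + 6 * mu1**2 * m2 - 3 * mu1**4
        assert cm2 == pytest.approx(mu1, rel=1e-9)
        assert cm3 == pytest.approx(mu1, rel=1e-9)
        assert cm4 == pytest.approx(mu1 + 3 * mu1**2, rel=1e-9)

    def test_uniform_time_rescaling_leaves_moments_unchanged(self, rng):
        for _ in range(20):
            c = random_cdrc(rng)
            a = protein_central_moments(c)
            b = protein_central_moments(c.scaled(10.0))
            for x, y in zip(a.as_tuple(), b.as_tuple()):
                assert x == pytest.approx(y, rel=1e-12)

    def test_on_partial_never_exceeds_total(self, rng):
        for _ in range(25):
            pm = solve_partial_moments(random_cdrc(rng))
            for a, i, j in CANONICAL_INDEX:
                if a == 1:
                    assert 0.0 <= pm.on_partial(i, j) <= pm.total(i, j) * (1 + 1e-9)

    def test_zero_transcription_zeroes_every_moment(self):
        M, V, S, K = moments_from_rates((1.0, 0.5, 0.0, 1.0, 1.0, 0.5))
        assert (M, V, S, K) == (0.0, 0.0, 0.0, 0.0)


class TestRNAMoments:
    def test_constitutive_fano_is_one(self):
        _, _, fano = rna_moments(CDRCSet(1.0, 0.0, 5.0, 1.0, 1.0, 0.1))
        assert fano == pytest.approx(1.0, abs=1e-12)

    def test_fano_decreases_to_one_as_switching_accelerates(self):
        fanos = [
            rna_moments(CDRCSet(k_on, 1.0, 5.0, 1.0, 1.0, 0.1))[2]
            for k_on in (0.1, 1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(f >= 1.0 - 1e-12 for f in fanos)
        assert all(a > b for a, b in zip(fanos, fanos[1:]))
        assert fanos[-1] == pytest.approx(1.0, abs=0.01)

    def test_slow_switching_large_bursts_inflate_fano(self):
        # burst size k_r/k_off = 50 with rare activations
        _, _, fano = rna_moments(CDRCSet(0.01, 1.0, 50.0, 1.0, 1.0, 0.1))
        assert fano > 10.0


class TestMeanEquation:
    def test_symmetric_switching_halves_the_constitutive_mean(self):
        assert mean_protein(CDRCSet(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)) == pytest.approx(0.5)

    def test_constitutive_mean(self):
        assert mean_protein(CDRCSet(1.0, 0.0, 4.0, 3.0, 2.0, 1.5)) == pytest.approx(4.0)

    def test_closed_form_agrees_with_linear_system(self, rng):
        for _ in range(100):
            c = random_cdrc(rng)
            assert solve_partial_moments(c).total(0, 1) == pytest.approx(
                mean_protein(c), rel=1e-9
            )

    @pytest.mark.parametrize("which", ["k_on", "k_off", "k_r", "k_p", "g_r", "g_p"])
    def test_inversion_round_trips_through_the_mean(self, rng, which):
        for _ in range(20):
            c = random_cdrc(rng)
            M = mean_protein(c)
            fixed = {f: getattr(c, f) for f in c.__dataclass_fields__ if f != which}
            v = solve_mean_for_param(M, fixed, which)
            assert v is not None
            assert mean_protein(c.replace(**{which: v})) == pytest.approx(M, rel=1e-12)
            assert v == pytest.approx(getattr(c, which), rel=1e-9)

    def test_symmetric_occupancy_example(self):
        # Q = 1/2 demanded of the promoter with k_off = 3 gives k_on = 3
        fixed = dict(k_off=3.0, k_r=2.0, k_p=1.0, g_r=1.0, g_p=1.0)
        assert solve_mean_for_param(1.0, fixed, "k_on") == pytest.approx(3.0)

    def test_overdemanded_occupancy_is_infeasible(self):
        # Q = 1.2 > 1: no k_on can push occupancy beyond 1
        fixed = dict(k_off=1.0, k_r=1.0, k_p=1.0, g_r=1.0, g_p=1.2)
        assert solve_mean_for_param(1.0, fixed, "k_on") is None

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValidationError):
            solve_mean_for_param(-1.0, {}, "k_on")
        with pytest.raises(ValidationError):
            solve_mean_for_param(1.0, {"k_on": 1.0}, "k_off")
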