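"""Generative core: parameter decoding, component curves, psychometric link,
and the trial likelihood against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcffbayes import (
    MCFFParams,
    PriorBounds,
    PsychometricConfig,
    SessionStructure,
    component_curves,
    decode_params,
    pc_2afc_dprime,
    threshold_curve,
    trial_loglik,
    weibull_prob,
)

G, LAPSE, PREF = 0.5, 0.04, 0.856


class TestDecode:
    def test_k2_direct_exponentiation(self):
        c = decode_params(np.array([-1.0, -1.0]))
        assert c.gamma == pytest.approx(0.1)
        assert c.b == pytest.approx(-0.1)
        assert c.phi == 0.0 and c.tau == 0.0
        assert np.all(c.delta == 0) and np.all(c.d == 0)

    def test_k14_layout_and_session1_zeros(self, bounds14, rng):
        theta = bounds14.sample(rng)
        c = decode_params(theta)
        assert c.delta[0] == 0.0 and c.d[0] == 0.0
        np.testing.assert_allclose(c.delta[1:], 10.0 ** theta[3:8])
        np.testing.assert_allclose(c.d[1:], 10.0 ** theta[9:14])
        assert c.phi == pytest.approx(10.0 ** theta[2])
        assert c.tau == pytest.approx(10.0 ** theta[8])

    def test_k14_midbound_phi(self, bounds14):
        c = decode_params(bounds14.midpoint)
        assert c.phi == pytest.approx(10.0 ** -4.5, rel=1e-12)
        assert c.phi == pytest.approx(3.162e-5, rel=1e-3)

    def test_k6_broadcasts_shared_components(self, bounds6, rng):
        theta = bounds6.sample(rng)
        c = decode_params(theta)
        assert np.all(c.delta[1:] == 10.0 ** theta[3])
        assert np.all(c.d[1:] == 10.0 ** theta[5])

    @pytest.mark.parametrize("bad", [np.zeros(3), np.zeros(5), np.zeros(15)])
    def test_invalid_model_order(self, bad):
        with pytest.raises(ValueError, match="length 2, 6 or 14"):
            MCFFParams(bad)

    def test_nonfinite_theta_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            MCFFParams(np.array([np.nan, -1.0]))


class TestPriorBounds:
    def test_default_table_values(self):
        b = PriorBounds.default(14)
        expected = [(-3, -0.5)] * 2 + [(-6, -3)] + [(-3, -1)] * 5 + [(-4, -2)] + [(-3, -0.6)] * 5
        np.testing.assert_array_equal(b.lower, [e[0] for e in expected])
        np.testing.assert_array_equal(b.upper, [e[1] for e in expected])
        b6 = PriorBounds.default(6)
        np.testing.assert_array_equal(b6.lower, [-3, -3, -6, -3, -4, -3])
        np.testing.assert_array_equal(b6.upper, [-0.5, -0.5, -3, -1, -2, -0.6])

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            PriorBounds.default(5)
        with pytest.raises(ValueError, match="lower < upper"):
            PriorBounds(lower=np.array([0.0]), upper=np.array([0.0]))


class TestSessionStructure:
    def test_layout_is_bijection(self):
        s = SessionStructure(n_sessions=3, trials_per_session=[10, 20, 30], pretrain_trials=5)
        tglobal, session, tprime = s.trial_layout()
        assert s.n_trials == 65
        assert tglobal.tolist() == list(range(1, 66))
        # (session, tprime) pairs are unique -> bijective mapping
        assert len({(int(a), int(b)) for a, b in zip(session, tprime)}) == 65

    def test_pretraining_belongs_to_session_1(self):
        s = SessionStructure(n_sessions=2, trials_per_session=10, pretrain_trials=5)
        assert s.session_of(5) == 1
        assert s.session_of(15) == 1
        assert s.session_of(16) == 2
        assert s.tprime_of(16) == 0
        assert s.tprime_of(1) == 0

    def test_scalar_lookups_match_layout(self):
        s = SessionStructure(n_sessions=6, trials_per_session=50, pretrain_trials=7)
        tg, sess, tp = s.trial_layout()
        for t in (1, 7, 8, 57, 58, 200, s.n_trials):
            assert s.session_of(t) == sess[t - 1]
            assert s.tprime_of(t) == tp[t - 1]

    def test_validation(self):
        with pytest.raises(ValueError):
            SessionStructure(pretrain_trials=81)
        with pytest.raises(ValueError):
            SessionStructure(n_sessions=2, trials_per_session=[10])


class TestComponentCurves:
    def test_first_trial_only_general(self, structure6, bounds14, rng):
        theta = bounds14.sample(rng)
        curves = component_curves(theta, structure6)
        assert curves["general"][0] == pytest.approx(decode_params(theta).b)
        for name in ("forgetting", "relearning", "adaptation"):
            assert curves[name][0] == 0.0

    def test_k2_general_at_t10(self):
        s = SessionStructure(n_sessions=1, trials_per_session=20)
        comp = component_curves(np.array([-1.0, -0.5]), s)
        c = decode_params(np.array([-1.0, -0.5]))
        assert comp["general"][9] == pytest.approx(c.b - c.gamma)

    def test_relearning_elbow(self, structure6, bounds14):
        # tau = 1e-3, d_2 = 0.1: elbow at t' = 100
        theta = bounds14.midpoint.copy()
        theta[8] = -3.0   # tau
        theta[9] = -1.0   # d for session 2
        curves = component_curves(theta, structure6)
        _, session, tprime = structure6.trial_layout()
        i50 = np.flatnonzero((session == 2) & (tprime == 50))[0]
        i200 = np.flatnonzero((session == 2) & (tprime == 200))[0]
        assert curves["relearning"][i50] == pytest.approx(-0.05)
        assert curves["relearning"][i200] == pytest.approx(-0.1)

    def test_monotonicity_properties(self, structure6, bounds14, rng):
        theta = bounds14.sample(rng)
        curves = component_curves(theta, structure6)
        _, session, tprime = structure6.trial_layout()
        assert np.all(np.diff(curves["general"]) < 0)
        for s in range(1, 7):
            idx = session == s
            rel = curves["relearning"][idx]
            assert np.all(np.diff(rel) <= 0)
            adapt = curves["adaptation"][idx]
            assert np.all(np.diff(adapt) >= 0)
            assert adapt[0] == 0.0

    def test_additivity_over_random_draws(self, structure6, bounds14, rng):
        for theta in bounds14.sample(rng, size=200):
            total = sum(component_curves(theta, structure6).values())
            np.testing.assert_array_equal(total, threshold_curve(theta, structure6))

    def test_session_jump_finite_difference(self, structure6, bounds14, rng):
        """The jump of xi at a session boundary decomposes into the change
        of each component evaluated independently."""
        theta = bounds14.sample(rng)
        xi = threshold_curve(theta, structure6)
        comp = decode_params(theta)
        _, session, tprime = structure6.trial_layout()
        for s in (2, 4, 6):
            i_first = np.flatnonzero(session == s)[0]
            t_last, t_first = i_first, i_first + 1  # 1-based trials
            last_tprime = tprime[i_first - 1]
            expected = (
                -comp.gamma * math.log10(t_first / t_last)
                + (comp.delta[s - 1] - comp.delta[s - 2])
                + (0.0 - max(-comp.d[s - 2], -comp.tau * last_tprime))
                + (0.0 - comp.phi * last_tprime)
            )
            assert xi[i_first] - xi[i_first - 1] == pytest.approx(expected, abs=1e-12)

    def test_k_nesting(self, structure6, rng):
        theta6 = PriorBounds.default(6).sample(rng)
        theta14 = np.concatenate(
            [theta6[:3], np.full(5, theta6[3]), [theta6[4]], np.full(5, theta6[5])]
        )
        np.testing.assert_allclose(
            threshold_curve(theta14, structure6), threshold_curve(theta6, structure6)
        )
        # K=6 with vanishing extra components limits to K=2
        theta6_small = theta6.copy()
        theta6_small[2:] = [-30.0, -30.0, -30.0, -30.0]
        np.testing.assert_allclose(
            threshold_curve(theta6_small, structure6),
            threshold_curve(theta6[:2], structure6),
            atol=1e-12,
        )


class TestWeibull:
    def test_floor_and_ceiling(self):
        assert weibull_prob(-1.0, 1e-12, 2.0) == pytest.approx(0.50, abs=1e-6)
        assert weibull_prob(-1.0, 1e12, 2.0) == pytest.approx(0.98, abs=1e-12)

    def test_probability_at_threshold(self):
        # at contrast 10**xi the inner Weibull passes through p_ref
        assert weibull_prob(-1.3, 10.0 ** -1.3, 2.0) == pytest.approx(0.84176)

    @given(
        xi=st.floats(-3.0, -0.1),
        beta=st.floats(1.0, 4.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_reference_point_identity(self, xi, beta):
        expected = G * LAPSE + (1 - LAPSE) * PREF
        assert weibull_prob(xi, 10.0 ** xi, beta) == pytest.approx(expected, abs=1e-12)

    def test_strictly_increasing_in_contrast(self, rng):
        floor = G * LAPSE + (1 - LAPSE) * G
        grid = np.logspace(-4, 0, 60)
        for _ in range(100):
            xi = rng.uniform(-3, -0.1)
            beta = rng.uniform(1, 4)
            p = weibull_prob(xi, grid, beta)
            assert np.all(np.diff(p) >= 0)
            # strict between the numerical floor and ceiling of the curve
            ceiling = G * LAPSE + (1 - LAPSE)
            interior = (p > floor + 1e-12) & (p < ceiling - 1e-12)
            assert np.all(np.diff(p[interior]) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="positive"):
            weibull_prob(-1.0, 0.0, 2.0)
        with pytest.raises(ValueError, match="beta"):
            weibull_prob(-1.0, 0.5, -1.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PsychometricConfig(g=1.2)
        with pytest.raises(ValueError):
            PsychometricConfig(p_ref=0.4)

    def test_threshold_criterion_matches_dprime(self):
        # the p_ref constant is the 2AFC accuracy at d' = 1.5
        assert pc_2afc_dprime(1.5) == pytest.approx(PREF, abs=5e-4)


def _oracle_loglik(theta, beta, structure, contrast, response):
    """Brute-force per-trial product, independent scalar-math reimplementation."""
    K = len(theta)
    gamma = 10.0 ** theta[0]
    b = -(10.0 ** theta[1])
    total = 0.0
    for i in range(structure.n_trials):
        t = i + 1
        s = structure.session_of(t)
        tp = structure.tprime_of(t)
        xi = b - gamma * math.log10(t)
        if K >= 6:
            if K == 14:
                phi = 10.0 ** theta[2]
                delta = 10.0 ** theta[s + 1] if s >= 2 else 0.0
                tau = 10.0 ** theta[8]
                dd = 10.0 ** theta[s + 7] if s >= 2 else 0.0
            else:
                phi = 10.0 ** theta[2]
                delta = 10.0 ** theta[3] if s >= 2 else 0.0
                tau = 10.0 ** theta[4]
                dd = 10.0 ** theta[5] if s >= 2 else 0.0
            xi += delta + max(-dd, -tau * tp) + phi * tp
        scale = 10.0 ** (xi - math.log10(math.log((1 - G) / (1 - PREF))) / beta)
        p = G * LAPSE + (1 - LAPSE) * (G + (1 - G) * (1 - math.exp(-((contrast[i] / scale) ** beta))))
        p = min(max(p, 1e-9), 1 - 1e-9)
        total += math.log(p) if response[i] else math.log(1 - p)
    return total


class TestTrialLoglik:
    def test_empty_is_zero(self, structure6):
        assert trial_loglik(np.array([-1.0, -1.0]), 2.0, np.array([]), np.array([])) == 0.0

    def test_single_trial_at_threshold(self):
        s = SessionStructure(n_sessions=1, trials_per_session=1)
        ll = trial_loglik(
            np.array([0.0, math.log10(0.05)]),  # b = -0.05 -> xi(1) = -0.05...
            2.0,
            np.array([10.0 ** -0.05]),
            np.array([1]),
            s,
        )
        # gamma=1 contributes 0 at t=1; xi(1) = b = -0.05
        assert ll == pytest.approx(math.log(weibull_prob(-0.05, 10.0 ** -0.05, 2.0)))

    def test_matches_bruteforce_oracle(self, rng):
        structure = SessionStructure(n_sessions=2, trials_per_session=25)
        for i in range(100):
            K = [2, 6, 14][i % 3]
            bounds = PriorBounds.default(K)
            theta = bounds.sample(rng)
            beta = rng.uniform(1, 4)
            contrast = 10.0 ** rng.uniform(-3, 0, structure.n_trials)
            response = rng.integers(0, 2, structure.n_trials)
            got = trial_loglik(theta, beta, contrast, response, structure)
            want = _oracle_loglik(theta, beta, structure, contrast, response)
            assert got == pytest.approx(want, abs=1e-10)

    def test_length_mismatch(self, structure6):
        with pytest.raises(ValueError, match="trials"):
            trial_loglik(np.zeros(2), 2.0, np.array([0.5]), np.array([1]), structure6)
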