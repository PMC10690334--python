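"""Staircase dynamics, observer simulation, and the population generator."""

import numpy as np
import pytest

from mcffbayes import (
    GroupDesign,
    PopulationSpec,
    SessionStructure,
    StaircaseState,
    default_population_spec,
    observer_response,
    simulate_population,
    simulate_subject,
    staircase_step,
    threshold_curve,
    weibull_prob,
)


class TestStaircase:
    def test_all_correct_decreases_until_clip(self):
        st = StaircaseState(target_accuracy=0.85, log10_contrast=-0.5)
        xs = [st.log10_contrast]
        for _ in range(50):
            st = staircase_step(st, 1)
            xs.append(st.log10_contrast)
        assert all(b < a for a, b in zip(xs, xs[1:]))

    def test_all_incorrect_increases_until_clip(self):
        st = StaircaseState(target_accuracy=0.85, log10_contrast=-1.5)
        xs = [st.log10_contrast]
        clipped = False
        for _ in range(50):
            st = staircase_step(st, 0)
            xs.append(st.log10_contrast)
            clipped = clipped or st.log10_contrast == 0.0
        assert all(b > a or (b == 0.0 and a == 0.0) for a, b in zip(xs, xs[1:]))
        assert st.contrast <= 1.0

    def test_contrast_never_exceeds_one(self):
        st = StaircaseState(target_accuracy=0.65, log10_contrast=-0.1)
        for _ in range(30):
            st = staircase_step(st, 0)
            assert st.contrast <= 1.0

    def test_reversals_shrink_step(self):
        st = StaircaseState(target_accuracy=0.85)
        for r in (1, 0, 1, 0, 1, 0):
            st = staircase_step(st, r)
        assert st.reversal_count == 5
        x_before = st.log10_contrast
        st2 = staircase_step(st, 0)
        # step = s / (2 + m) with m = 6 reversals after this flip... bounded above
        assert abs(st2.log10_contrast - x_before) < 0.3 / (2 + st.reversal_count) * 0.9 + 0.05

    @pytest.mark.parametrize("target", [0.65, 0.85])
    def test_tracks_design_accuracy_of_stationary_observer(self, target):
        """Robbins-Monro convergence: long-run accuracy within +-0.02 of the
        target against a fixed-threshold Weibull observer."""
        xi, beta = -1.3, 2.0
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            st = StaircaseState(target_accuracy=target)
            hits = []
            for _ in range(6000):
                p = weibull_prob(xi, st.contrast, beta)
                r = int(rng.random() < p)
                hits.append(r)
                st = staircase_step(st, r)
            accs.append(np.mean(hits[3000:]))
        assert np.mean(accs) == pytest.approx(target, abs=0.02)

    def test_validation(self):
        with pytest.raises(ValueError):
            StaircaseState(target_accuracy=0.4)
        with pytest.raises(ValueError):
            StaircaseState(target_accuracy=0.85, initial_step=-1.0)


class TestObserver:
    def test_seeded_determinism(self, small_structure):
        theta = np.array([-1.3, -0.8])
        r1 = [observer_response(theta, 2.0, small_structure, t, 0.3,
                                np.random.default_rng(5)) for t in (1, 10, 50)]
        r2 = [observer_response(theta, 2.0, small_structure, t, 0.3,
                                np.random.default_rng(5)) for t in (1, 10, 50)]
        assert r1 == r2

    def test_accuracy_at_threshold_contrast(self, small_structure, rng):
        theta = np.array([-1.3, -0.8])
        xi = threshold_curve(theta, small_structure)[0]
        p = weibull_prob(xi, 10.0 ** xi, 2.0)
        draws = rng.random(100_000) < p
        # empirical accuracy at the threshold contrast ~ 0.84176
        assert draws.mean() == pytest.approx(0.84176, abs=0.004)

    def test_high_contrast_hits_ceiling(self, small_structure):
        # threshold ~ 10^-2, contrast 1.0: far above threshold -> lapse ceiling
        rng = np.random.default_rng(0)
        hits = [observer_response(np.array([-1.3, 0.3]), 2.0, small_structure,
                                  1, 1.0, rng) for _ in range(10_000)]
        assert np.mean(hits) == pytest.approx(0.98, abs=0.006)


class TestSimulateSubject:
    def test_bookkeeping(self):
        structure = SessionStructure(n_sessions=6, trials_per_session=40,
                                     pretrain_trials=10)
        frame, xi = simulate_subject(np.array([-1.3, -0.8]), 2.0, "high",
                                     structure, np.random.default_rng(1),
                                     subject=3, group=5)
        assert len(frame) == structure.n_trials == 250
        tglobal, session, _ = structure.trial_layout()
        np.testing.assert_array_equal(frame["session"].to_numpy(), session)
        np.testing.assert_array_equal(frame["global_trial"].to_numpy(), tglobal)
        assert (frame["subject"] == 3).all() and (frame["group"] == 5).all()
        assert xi.shape == (250,)

    def test_mixed_interleaves_two_staircases(self, small_structure):
        frame, _ = simulate_subject(np.array([-1.3, -0.8]), 2.0, "mixed",
                                    small_structure, np.random.default_rng(2))
        counts = frame["staircase_id"].value_counts()
        assert set(counts.index) == {"s65", "s85"}
        assert counts["s65"] == counts["s85"] == len(frame) // 2
        # strict alternation
        assert (frame["staircase_id"].iloc[::2] == "s65").all()

    def test_state_carries_over_sessions_by_default(self):
        structure = SessionStructure(n_sessions=2, trials_per_session=100)
        theta = np.array([-1.3, -0.8])
        rng = np.random.default_rng(3)
        frame, _ = simulate_subject(theta, 2.0, "high", structure, rng)
        c = frame["contrast"].to_numpy()
        # first trial of session 2 continues from session 1's end, not the start value
        assert abs(np.log10(c[100]) - np.log10(c[99])) < 0.05
        frame_r, _ = simulate_subject(theta, 2.0, "high", structure,
                                      np.random.default_rng(3),
                                      reset_between_sessions=True)
        assert frame_r["contrast"].iloc[100] == pytest.approx(10.0 ** -0.5)

    def test_unknown_condition(self, small_structure):
        with pytest.raises(ValueError, match="condition"):
            simulate_subject(np.array([-1, -1]), 2.0, "medium", small_structure,
                             np.random.default_rng(0))


class TestSimulatePopulation:
    def test_default_design_sizes(self):
        spec = default_population_spec(K=2, n_sessions=1, trials_per_session=2,
                                       pretrain_range=(0, 0))
        ds, truth = simulate_population(spec, 0)
        assert len(ds.subjects) == 60
        sizes = [sum(1 for s, g in truth.group_of.items() if g == gid)
                 for gid in range(1, 7)]
        assert sizes == [12, 12, 6, 6, 12, 12]

    def test_seed_determinism(self):
        spec = PopulationSpec(K=2, groups=(GroupDesign(1, 3, "high"),),
                              n_sessions=2, trials_per_session=30,
                              pretrain_range=(0, 0))
        ds1, _ = simulate_population(spec, 11)
        ds2, _ = simulate_population(spec, 11)
        assert ds1.df.equals(ds2.df)
        ds3, _ = simulate_population(spec, 12)
        assert not ds1.df.equals(ds3.df)

    def test_degenerate_covariances_pin_parameters(self):
        spec = PopulationSpec(K=2, mu=np.array([-1.3, -0.8]),
                              Sigma=np.eye(2) * 1e-18, phi_cov=np.eye(2) * 1e-18,
                              groups=(GroupDesign(1, 4, "high"),),
                              n_sessions=1, trials_per_session=5,
                              pretrain_range=(0, 0))
        _, truth = simulate_population(spec, 0)
        for th in truth.theta.values():
            np.testing.assert_allclose(th, spec.mu, atol=1e-6)

    def test_population_moments_match_spec(self):
        Sigma = np.array([[0.04, 0.012], [0.012, 0.02]])
        spec = PopulationSpec(K=2, Sigma=Sigma, phi_cov=np.eye(2) * 1e-12,
                              groups=(GroupDesign(1, 400, "high"),),
                              n_sessions=1, trials_per_session=1,
                              pretrain_range=(0, 0)).resolved()
        _, truth = simulate_population(spec, 7)
        rho = np.array(list(truth.rho.values()))
        np.testing.assert_allclose(rho.mean(axis=0), spec.mu, atol=0.03)
        np.testing.assert_allclose(np.cov(rho.T), Sigma, atol=0.012)

    def test_truth_curves_roundtrip(self):
        spec = PopulationSpec(K=6, groups=(GroupDesign(1, 2, "mixed"),),
                              n_sessions=2, trials_per_session=25,
                              pretrain_range=(0, 0))
        _, truth = simulate_population(spec, 4)
        for (s, j), th in truth.theta.items():
            np.testing.assert_array_equal(
                truth.curves[(s, j)], threshold_curve(th, truth.structures[s])
            )

    def test_pretraining_range_respected(self):
        spec = PopulationSpec(K=2, groups=(GroupDesign(1, 5, "low"),),
                              n_sessions=2, trials_per_session=10,
                              pretrain_range=(60, 80))
        ds, truth = simulate_population(spec, 3)
        for s in ds.subjects:
            pt = truth.structures[s].pretrain_trials
            assert 60 <= pt <= 80
            sub = ds.subject_frame(s)
            assert (sub["session"] == 1).sum() == 10 + pt

    def test_non_pd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            PopulationSpec(K=2, Sigma=bad, groups=(GroupDesign(1, 1, "low"),)).resolved()
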