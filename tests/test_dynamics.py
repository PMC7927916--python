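import numpy as np
import pandas as pd
import pytest
from scipy import stats

from onoffstate.dynamics import (att_mi, epochs_from_path, mean_epoch_duration,
                                 occupancy, pupil_coupling, rate_match,
                                 rt_by_state, state_at_event, transition_pdf,
                                 transitions_of)

from conftest import chain, make_counts, two_state_counts


class TestEpochs:
    def test_run_decomposition_with_censoring(self):
        eps = epochs_from_path(np.array([0, 0, 0, 1, 1, 1, 0]), 10.0)
        assert [(e.phase, e.duration) for e in eps] == \
            [(0, 30.0), (1, 30.0), (0, 10.0)]
        assert eps[0].censored_left and not eps[0].censored_right
        assert eps[-1].censored_right and not eps[-1].censored_left

    def test_constant_path_fully_censored(self):
        eps = epochs_from_path(np.ones(5, int), 10.0)
        assert len(eps) == 1
        assert eps[0].censored_left and eps[0].censored_right

    def test_geometric_mean_duration(self):
        # P(stay)=0.9 per 10 ms bin -> mean dwell w/(1-p) = 100 ms
        P = np.array([[0.9, 0.1], [0.1, 0.9]])
        path = chain(P, 10 ** 5, np.random.default_rng(0))
        eps = epochs_from_path(path, 10.0)
        m = mean_epoch_duration(eps, phase=0)
        assert m == pytest.approx(100.0, rel=0.03)

    def test_occupancy_equals_duration_weighted_epochs(self):
        path = np.array([0, 1, 1, 0, 0, 0, 1, 1])
        occ = occupancy(path)
        eps = epochs_from_path(path, 10.0)
        on = sum(e.duration for e in eps if e.phase == 1)
        assert occ[1] == pytest.approx(on / (len(path) * 10.0))
        assert occ.sum() == pytest.approx(1.0)

    def test_all_on(self):
        assert occupancy(np.ones(10, int))[1] == 1.0


class TestAttMi:
    @pytest.mark.parametrize("a,b,expected", [
        (2.0, 1.0, 1 / 3), (1.0, 1.0, 0.0), (5.0, 0.0, 1.0)])
    def test_values(self, a, b, expected):
        assert att_mi(a, b) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        assert np.isnan(att_mi(0.0, 0.0))


class TestTransitionPdf:
    def test_normalization_arithmetic(self):
        # 5 transitions in one 100 ms bin over 10 trials -> 5 / s / trial
        paths = []
        for i in range(10):
            p = np.zeros(30, int)
            if i < 5:
                p[10:] = 1      # Off->On at bin 10 => 100 ms
            paths.append(p)
        t, v = transition_pdf(paths, np.zeros(10), "off_to_on", w=100.0,
                              t_range=(0.0, 300.0))
        assert v[1] == pytest.approx(5.0 / (0.1 * 10))

    def test_time_homogeneous_is_flat(self):
        P = np.array([[0.95, 0.05], [0.05, 0.95]])
        rng = np.random.default_rng(1)
        paths = [chain(P, 200, rng) for _ in range(400)]
        t, v = transition_pdf(paths, np.zeros(400), "off_to_on",
                              t_range=(100.0, 1900.0))
        assert v.std() / v.mean() < 0.15

    def test_transition_times_offset(self):
        p = np.array([0, 0, 1, 1, 0])
        up = transitions_of(p, "off_to_on", 10.0, offset=500.0)
        dn = transitions_of(p, "on_to_off", 10.0, offset=500.0)
        np.testing.assert_allclose(up, [520.0])
        np.testing.assert_allclose(dn, [540.0])


class TestRateMatch:
    def test_equal_conditions_identical_output(self, rng):
        bc, *_ = two_state_counts(rng, n_trials=20, T=100)
        out = rate_match({"a": bc, "b": bc}, seed=0)
        for cond in ("a", "b"):
            for orig, thin in zip(bc.counts, out[cond].counts):
                np.testing.assert_array_equal(orig, thin)

    def test_double_rate_halved(self, rng):
        lo = make_counts([rng.poisson(0.5, size=(1, 2000))])
        hi = make_counts([rng.poisson(1.0, size=(1, 2000))])
        out = rate_match({"lo": lo, "hi": hi}, seed=0)
        kept = out["hi"].counts[0].sum()
        orig = hi.counts[0].sum()
        p = lo.channel_means()[0] / hi.channel_means()[0]
        sd = np.sqrt(orig * p * (1 - p))
        assert abs(kept - orig * p) < 3 * sd

    def test_thinned_counts_bounded_and_poisson(self, rng):
        hi = make_counts([rng.poisson(1.0, size=(1, 20000))])
        lo = make_counts([rng.poisson(0.5, size=(1, 20000))])
        out = rate_match({"lo": lo, "hi": hi}, seed=0)
        assert np.all(out["hi"].counts[0] <= hi.counts[0])
        c = out["hi"].counts[0].ravel()
        assert c.var(ddof=1) / c.mean() == pytest.approx(1.0, abs=0.03)


class TestStateAtEvent:
    def test_bin_lookup(self):
        path = np.array([0, 1, 0])
        assert state_at_event(path, 1405.0, (1400.0, 1430.0), 10.0) == 0
        assert state_at_event(path, 1410.0, (1400.0, 1430.0), 10.0) == 1

    def test_edge_belongs_to_starting_bin(self):
        path = np.array([0, 1])
        assert state_at_event(path, 1410.0, (1400.0, 1420.0), 10.0) == 1

    def test_outside_window_errors(self):
        with pytest.raises(ValueError, match="outside"):
            state_at_event(np.array([0, 1]), 100.0, (1400.0, 1420.0), 10.0)


class TestRtByState:
    def table(self, states, rts, in_rf=True):
        n = len(states)
        trials = pd.DataFrame(dict(
            trial_id=np.arange(n), condition=["attend_rf"] * n,
            t_fixation=0.0, t_stim_on=614.0, t_cue=1400.0,
            t_dim1=2000.0, t_dim2=3000.0, t_dim3=4000.0,
            target_dim=1, target_in_rf=in_rf, rt=rts, pupil_baseline=1.0))
        paths = [np.full(300, s) for s in states]
        wins = np.tile([0.0, 3000.0], (n, 1))
        return rt_by_state(trials, paths, wins, 10.0)

    def test_states_and_rts_collected(self):
        t = self.table([0, 1, 1], [400.0, 300.0, 320.0])
        assert t["state"].tolist() == [0, 1, 1]
        assert t["rt"].tolist() == [400.0, 300.0, 320.0]

    def test_non_rf_trials_excluded(self):
        t = self.table([0, 1], [300.0, 310.0], in_rf=False)
        assert t.empty

    def test_generator_offset_recovered(self):
        from onoffstate.experiments import rt_state_ordering
        out = rt_state_ordering(seed=0, n_sessions=5, n_trials=40)
        m = out["mean_rt_per_state"]
        assert m[0] > m[3]


class TestPupilCoupling:
    def test_exact_linear_relation(self):
        paths = []
        pupil = []
        rng = np.random.default_rng(0)
        for i in range(10):
            on_len = 5 + 2 * i
            p = np.concatenate([np.zeros(10, int), np.ones(on_len, int),
                                np.zeros(10, int)])
            paths.append(p)
            pupil.append(1.0 + 0.01 * on_len * 10.0)
        r, _ = pupil_coupling(np.array(pupil), paths)
        assert r == pytest.approx(1.0)

    def test_zero_coupling_near_zero_r(self):
        from onoffstate.synthetic import (GenConfig, build_joint_transitions,
                                          simulate_session)
        from onoffstate.joint import V1_PHASE, V4_PHASE
        cfg = GenConfig(n_trials=200, channels_per_area=2, seed=5,
                        transitions={"attend_rf": build_joint_transitions()},
                        pupil_coupling=0.0, include_eye=False, msacc_rate=0.0)
        b = simulate_session(cfg)
        paths = [np.asarray(p, int) for p in b.meta["true_paths"]]
        r, p = pupil_coupling(b.trials["pupil_baseline"].to_numpy(), paths,
                              on_of_state=(V1_PHASE | V4_PHASE))
        assert abs(r) < 0.2

    def test_constant_pupil_undefined(self):
        paths = [np.array([0, 1, 1, 0])] * 5
        r, p = pupil_coupling(np.ones(5), paths)
        assert np.isnan(r)
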