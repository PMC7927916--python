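import numpy as np
import pytest

from onoffstate.hmm import HmmFit, HmmParams, em_fit, loglik, viterbi
from onoffstate.joint import (canonicalize_states, em_fit_tied,
                              kronecker_product_transitions, marginal_path,
                              scenario_contrasts, time_in_states, tying_map)
from onoffstate.synthetic import build_joint_transitions, simulate_joint_latent

from conftest import make_counts


def tied_counts(rng, n_trials=40, T=150, ch_per_area=4,
                P4=None, off=20.0, on=100.0):
    if P4 is None:
        P4 = build_joint_transitions(0.97, 0.6)
    n_ch = 2 * ch_per_area
    areas = np.array(["V1"] * ch_per_area + ["V4"] * ch_per_area,
                     dtype=object)
    v1 = np.array([off, on, off, on])
    v4 = np.array([off, off, on, on])
    rates = np.array([v1] * ch_per_area + [v4] * ch_per_area)
    paths, arrays = [], []
    for _ in range(n_trials):
        s = simulate_joint_latent(P4, np.full(4, 0.25), T, rng)
        paths.append(s)
        arrays.append(rng.poisson(rates[:, s] * 0.01))
    return make_counts(arrays, areas=areas), paths, P4


def test_tying_map_partitions_states():
    areas = np.array(["V1", "V4"], dtype=object)
    g = tying_map(areas)
    np.testing.assert_array_equal(g[0], [0, 1, 0, 1])   # V1: ties {1,3},{2,4}
    np.testing.assert_array_equal(g[1], [0, 0, 1, 1])   # V4: ties {1,2},{3,4}


class TestTiedFit:
    def test_ties_hold_to_machine_precision(self, rng):
        bc, _, _ = tied_counts(rng, n_trials=20, T=80)
        fit = em_fit_tied(bc, n_restarts=2, seed=0)
        lam = fit.params.lam
        np.testing.assert_array_equal(lam[:4, 0], lam[:4, 2])
        np.testing.assert_array_equal(lam[:4, 1], lam[:4, 3])
        np.testing.assert_array_equal(lam[4:, 0], lam[4:, 1])
        np.testing.assert_array_equal(lam[4:, 2], lam[4:, 3])

    def test_transition_recovery(self, rng):
        bc, _, P4 = tied_counts(rng, n_trials=60, T=200, ch_per_area=8)
        fit = em_fit_tied(bc, n_restarts=5, seed=0)
        assert np.abs(fit.params.P - P4).max() < 0.02

    def test_independent_areas_give_kronecker_product(self, rng):
        # two independent 2-state area chains == a joint chain whose P is
        # the Kronecker-style product; the tied fit should recover it
        Pa = np.array([[0.96, 0.04], [0.06, 0.94]])
        Pb = np.array([[0.98, 0.02], [0.03, 0.97]])
        P4 = kronecker_product_transitions(Pa, Pb)
        np.testing.assert_allclose(P4.sum(axis=1), 1.0, atol=1e-12)
        bc, _, _ = tied_counts(rng, n_trials=60, T=200, ch_per_area=8, P4=P4)
        fit = em_fit_tied(bc, n_restarts=5, seed=0)
        assert np.abs(fit.params.P - P4).max() < 0.02

    def test_tied_loglik_not_above_untied(self, rng):
        bc, _, _ = tied_counts(rng, n_trials=15, T=80)
        tied = em_fit_tied(bc, n_restarts=3, seed=0)
        untied = em_fit(bc, K=4, n_restarts=3, seed=0, canonicalize=False)
        assert tied.loglik <= untied.loglik + 1e-6

    def test_marginal_agrees_with_single_area_decode(self, rng):
        bc, _, _ = tied_counts(rng, n_trials=30, T=150, ch_per_area=8)
        fit = em_fit_tied(bc, n_restarts=3, seed=0)
        jpaths = viterbi(bc, fit.params)
        v1 = bc.select_channels(np.arange(8))
        f1 = em_fit(v1, K=2, n_restarts=3, seed=1)
        p1 = viterbi(v1, f1.params)
        agree = np.mean([np.mean(marginal_path(j, "V1") == p)
                         for j, p in zip(jpaths, p1)])
        assert agree > 0.95


class TestCanonicalize:
    def canon_fit(self):
        lam = np.array([[0.2, 1.0, 0.2, 1.0],     # V1 channel
                        [0.3, 0.3, 1.2, 1.2]])    # V4 channel
        params = HmmParams(np.full(4, 0.25), np.full((4, 4), 0.25), lam)
        return HmmFit(params, 0.0, np.array([0.0]), True, 1, 0,
                      np.array([0.0]))

    @pytest.mark.parametrize("perm", [
        [0, 1, 2, 3], [1, 0, 3, 2], [3, 2, 1, 0], [2, 3, 0, 1],
    ])
    def test_any_permutation_restored(self, perm):
        fit = self.canon_fit()
        scrambled = HmmFit(fit.params.permuted(np.asarray(perm)), 0.0,
                           fit.loglik_trace, True, 1, 0, fit.restart_logliks)
        out = canonicalize_states(scrambled,
                                  np.array(["V1", "V4"], dtype=object))
        np.testing.assert_allclose(out.params.lam, fit.params.lam)

    def test_degenerate_rates_flagged(self):
        lam = np.array([[0.5, 0.5, 0.5, 0.5], [0.5, 0.5, 0.5, 0.5]])
        params = HmmParams(np.full(4, 0.25), np.full((4, 4), 0.25), lam)
        fit = HmmFit(params, 0.0, np.array([0.0]), True, 1, 0,
                     np.array([0.0]))
        with pytest.warns(RuntimeWarning, match="ambiguous"):
            out = canonicalize_states(fit,
                                      np.array(["V1", "V4"], dtype=object))
        assert out.info.get("degenerate_rates")


class TestSummaries:
    def test_contrasts_from_known_matrix(self):
        P = np.full((4, 4), 0.01)
        np.fill_diagonal(P, 0.97)
        P[0, 2] = 0.02   # V4 leaves Off first
        P[0, 1] = 0.01
        P[3, 1] = 0.03   # V4 leaves On first
        P[3, 2] = 0.01
        P /= P.sum(axis=1, keepdims=True)
        c = scenario_contrasts(P)
        assert c["yellow"] == pytest.approx(P[0, 2] - P[0, 1])
        assert c["purple"] == pytest.approx(P[3, 1] - P[3, 2])

    def test_identical_conditions_zero_difference(self):
        c = scenario_contrasts(np.eye(4))
        assert c["yellow"] == 0.0 and c["purple"] == 0.0

    def test_time_in_states_constant_path(self):
        f = time_in_states([np.full(30, 3)])
        np.testing.assert_allclose(f, [0, 0, 0, 1])

    def test_fractions_sum_to_one(self, rng):
        paths = [rng.integers(0, 4, size=50) for _ in range(5)]
        assert time_in_states(paths).sum() == pytest.approx(1.0)

    def test_matches_stationary_distribution(self):
        P4 = build_joint_transitions(0.97, 0.6)
        w, v = np.linalg.eig(P4.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1))])
        pi /= pi.sum()
        rng = np.random.default_rng(3)
        path = simulate_joint_latent(P4, pi, 10 ** 6, rng)
        f = time_in_states([path])
        assert np.abs(f - pi).max() < 0.01
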