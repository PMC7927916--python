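import numpy as np
import pytest

from onoffstate.core import BinnedCounts
from onoffstate.exhaustive import exhaustive_loglik, exhaustive_viterbi
from onoffstate.hmm import (HmmParams, em_fit, emission_logpmf, fit_all,
                            forward_backward, loglik, viterbi)

from conftest import make_counts, two_state_counts


def random_instance(rng, kmax=4, tmax=6, cmax=3):
    K = int(rng.integers(1, kmax + 1))
    T = int(rng.integers(2, tmax + 1))
    C = int(rng.integers(1, cmax + 1))
    params = HmmParams(rng.dirichlet(np.ones(K)),
                       rng.dirichlet(np.ones(K), size=K),
                       rng.uniform(0, 3, size=(C, K)))
    counts = rng.poisson(1.0, size=(C, T))
    return make_counts([counts]), counts, params


class TestEmissionLogpmf:
    @pytest.mark.parametrize("n,lam,expected", [
        (0, 1.0, -1.0),
        (0, 0.0, 0.0),
        (2, 2.0, np.log(2.0) - 2.0),
    ])
    def test_values(self, n, lam, expected):
        assert emission_logpmf(n, lam) == pytest.approx(expected, abs=1e-12)

    def test_zero_rate_positive_count(self):
        assert emission_logpmf(1, 0.0) == -np.inf

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            emission_logpmf(-1, 1.0)


class TestForwardBackward:
    def test_k1_is_sum_of_emissions(self, rng):
        c = rng.poisson(0.7, size=(2, 20))
        params = HmmParams([1.0], np.eye(1), np.array([[0.7], [0.7]]))
        expected = emission_logpmf(c, 0.7).sum()
        assert loglik(make_counts([c]), params) == pytest.approx(expected)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            bc, c, params = random_instance(rng)
            assert loglik(bc, params) == pytest.approx(
                exhaustive_loglik(c, params), abs=1e-10)

    def test_posteriors_normalized(self, rng):
        bc, _, params = random_instance(rng)
        gammas, _, _ = forward_backward(bc, params)
        np.testing.assert_allclose(gammas[0].sum(axis=1), 1.0, atol=1e-12)

    def test_impossible_data_raises(self):
        params = HmmParams([1.0], np.eye(1), np.array([[0.0]]))
        with pytest.raises(ValueError, match="impossible"):
            loglik(make_counts([np.array([[1]])]), params)

    def test_long_trial_no_underflow(self, rng):
        c = rng.poisson(0.5, size=(8, 10 ** 4))
        params = HmmParams([0.5, 0.5],
                           np.array([[0.99, 0.01], [0.01, 0.99]]),
                           np.tile([0.2, 1.0], (8, 1)))
        assert np.isfinite(loglik(make_counts([c]), params))


class TestViterbi:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            bc, c, params = random_instance(rng)
            np.testing.assert_array_equal(viterbi(bc, params)[0],
                                          exhaustive_viterbi(c, params))

    def test_identical_rates_decided_by_prior(self, rng):
        # with equal emissions and uniform transitions every path through
        # the argmax-prior start is equally likely; the first bin follows
        # pi0 and later ties break toward the lower phase index
        c = rng.poisson(0.5, size=(2, 10))
        params = HmmParams([0.2, 0.8], np.full((2, 2), 0.5),
                           np.tile([0.5, 0.5], (2, 1)))
        path = viterbi(make_counts([c]), params)[0]
        assert path[0] == 1
        assert np.all(path[1:] == 0)

    def test_high_separation_recovers_truth(self, rng):
        bc, paths, P, rates = two_state_counts(rng, n_trials=20, T=200,
                                               off_hz=10.0, on_hz=500.0)
        params = HmmParams([0.5, 0.5], P, rates * 0.01)
        decoded = viterbi(bc, params)
        agree = np.mean([np.mean(d == p) for d, p in zip(decoded, paths)])
        assert agree > 0.99


class TestEmFit:
    def test_k1_equals_channel_means(self, rng):
        bc, *_ = two_state_counts(rng, n_trials=10, T=50)
        fit = em_fit(bc, K=1, n_restarts=2, seed=0)
        np.testing.assert_allclose(fit.params.lam[:, 0], bc.channel_means(),
                                   rtol=0, atol=1e-12)

    def test_loglik_monotone(self, rng):
        bc, *_ = two_state_counts(rng, n_trials=10, T=80)
        fit = em_fit(bc, K=2, n_restarts=3, seed=0)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-9)

    def test_parameter_recovery_small(self, rng):
        bc, _, P, rates = two_state_counts(rng, n_trials=60, T=200, n_ch=16)
        fit = em_fit(bc, K=2, n_restarts=5, seed=0)
        assert np.abs(fit.params.P - P).max() < 0.02
        assert np.abs(fit.params.rates_hz() / rates - 1).max() < 0.08

    def test_canonical_order_on_before_off(self, rng):
        bc, *_ = two_state_counts(rng, n_trials=20, T=100)
        fit = em_fit(bc, K=2, n_restarts=3, seed=0)
        assert fit.params.lam.mean(axis=0)[1] > fit.params.lam.mean(axis=0)[0]

    def test_row_stochastic_exactly(self, rng):
        bc, *_ = two_state_counts(rng, n_trials=10, T=60)
        fit = em_fit(bc, K=3, n_restarts=2, seed=0, max_iter=20)
        np.testing.assert_allclose(fit.params.P.sum(axis=1), 1.0, atol=1e-12)
        assert fit.params.pi0.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            em_fit(make_counts([np.zeros((2, 0), int)]), K=2)

    def test_restarts_reproducible(self, rng):
        bc, *_ = two_state_counts(rng, n_trials=8, T=60)
        a = em_fit(bc, K=2, n_restarts=3, seed=42)
        b = em_fit(bc, K=2, n_restarts=3, seed=42)
        np.testing.assert_allclose(a.params.P, b.params.P, atol=0)
        assert a.restart == b.restart


class TestKernelEquivalence:
    def test_numpy_and_numba_paths_agree(self, rng):
        """The accelerated recursions must match the plain-numpy reference
        on the same padded inputs."""
        from onoffstate import _kernels as k
        logB = np.log(rng.random((4, 12, 3)) + 0.05)
        lengths = np.array([12, 7, 12, 3])
        pi0 = rng.dirichlet(np.ones(3))
        P = rng.dirichlet(np.ones(3), size=3)
        logB[np.arange(12)[None, :] >= lengths[:, None]] = 0.0
        g1, x1, l1 = k._fb_numpy(logB, lengths, pi0, P)
        g2, x2, l2 = k.forward_backward_kernel(logB, lengths, pi0, P)
        np.testing.assert_allclose(l1, l2, atol=1e-10)
        np.testing.assert_allclose(x1, x2, atol=1e-10)
        valid = np.arange(12)[None, :] < lengths[:, None]
        np.testing.assert_allclose(g1[valid], g2[valid], atol=1e-10)
        v1 = k._viterbi_numpy(logB, lengths, pi0, P)
        v2 = k.viterbi_kernel(logB, lengths, pi0, P)
        for a, b in zip(v1, v2):
            np.testing.assert_array_equal(a, b)


class TestFitAll:
    def test_one_fit_per_condition(self, rng):
        bc, *_ = two_state_counts(rng, n_trials=12, T=60)
        conds = np.array(["attend_rf"] * 6 + ["attend_away1"] * 6)
        out = fit_all(bc, conds, K=2, n_restarts=2, seed=0)
        assert set(out) == {"attend_rf", "attend_away1"}
        for fit, paths, idx in out.values():
            assert len(paths) == len(idx) == 6

    def test_trial_order_invariance(self, rng):
        bc, *_ = two_state_counts(rng, n_trials=12, T=60)
        conds = np.array(["a"] * 6 + ["b"] * 6)
        perm = np.random.default_rng(1).permutation(12)
        out1 = fit_all(bc, conds, K=2, n_restarts=2, seed=0)
        out2 = fit_all(bc.select_trials(perm), conds[perm], K=2,
                       n_restarts=2, seed=0)
        np.testing.assert_allclose(out1["a"][0].params.lam,
                                   out2["a"][0].params.lam, rtol=1e-8)

    def test_small_condition_skipped(self, rng):
        bc, *_ = two_state_counts(rng, n_trials=5, T=60)
        conds = np.array(["a"] * 4 + ["b"])
        with pytest.warns(RuntimeWarning, match="skipped"):
            out = fit_all(bc, conds, K=2, n_restarts=2, seed=0)
        assert "b" not in out
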