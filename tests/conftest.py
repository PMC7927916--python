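import numpy as np
import pytest

from onoffstate.core import BinnedCounts, SpikeTrainSet
from onoffstate.synthetic import (GenConfig, build_joint_transitions,
                                  simulate_session)

SEED = 0


def make_counts(count_arrays, w_bin=10.0, areas=None):
    """BinnedCounts from a list of (n_channels, n_bins) arrays."""
    n_ch = count_arrays[0].shape[0]
    if areas is None:
        areas = np.array(["V1"] * n_ch, dtype=object)
    windows = np.array([[0.0, c.shape[1] * w_bin] for c in count_arrays])
    return BinnedCounts(list(count_arrays), w_bin, windows, areas,
                        np.arange(len(count_arrays)))


def chain(P, T, rng):
    """Sample a Markov chain with uniform start."""
    K = P.shape[0]
    cum = P.cumsum(axis=1)
    s = np.empty(T, dtype=np.int64)
    s[0] = rng.integers(K)
    for t in range(1, T):
        s[t] = np.searchsorted(cum[s[t - 1]], rng.random())
    return s


def two_state_counts(rng, n_trials=40, T=150, n_ch=8,
                     off_hz=20.0, on_hz=100.0,
                     P=None, w_bin=10.0):
    """Counts from a 2-phase generator, plus the true paths."""
    if P is None:
        P = np.array([[0.97, 0.03], [0.05, 0.95]])
    rates = np.tile([off_hz, on_hz], (n_ch, 1))
    paths, arrays = [], []
    for _ in range(n_trials):
        s = chain(P, T, rng)
        paths.append(s)
        arrays.append(rng.poisson(rates[:, s] * (w_bin / 1000.0)))
    return make_counts(arrays, w_bin), paths, P, rates


@pytest.fixture(scope="session")
def small_session():
    """A small full synthetic session shared by read-only tests."""
    cfg = GenConfig(n_trials=8, channels_per_area=4, seed=SEED,
                    transitions={"attend_rf": build_joint_transitions(on_bias=0.25),
                                 "attend_away1": build_joint_transitions()},
                    msacc_rate=0.5)
    return cfg, simulate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
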