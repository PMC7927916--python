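"""Brute-force reference inference for tiny instances.

Enumerates all K^T latent paths to evaluate the exact data log-likelihood
and the exact maximum-probability path.  Only feasible for T and K small
(K^T paths); used as an independent oracle against the recursive
implementations, never as the production path.
"""

from __future__ import annotations

import itertools

import numpy as np

from .hmm import HmmParams, emission_logpmf


def _path_logprob(path, counts_2d, params: HmmParams) -> float:
    """log P(path, data): chain prior plus per-bin Poisson emissions."""
    with np.errstate(divide="ignore"):
        lp = np.log(params.pi0[path[0]])
        for a, b in zip(path[:-1], path[1:]):
            lp += np.log(params.P[a, b])
    for t, s in enumerate(path):
        lp += float(np.sum(emission_logpmf(counts_2d[:, t],
                                           params.lam[:, s])))
    return lp


def exhaustive_loglik(counts_2d: np.ndarray, params: HmmParams) -> float:
    """log sum over all K^T paths of P(path, data)."""
    T = counts_2d.shape[1]
    lps = [_path_logprob(p, counts_2d, params)
           for p in itertools.product(range(params.K), repeat=T)]
    lps = np.asarray(lps)
    m = lps.max()
    if not np.isfinite(m):
        return -np.inf
    return float(m + np.log(np.sum(np.exp(lps - m))))


def exhaustive_viterbi(counts_2d: np.ndarray, params: HmmParams) -> np.ndarray:
    """argmax over all paths, ties toward the lexicographically smallest."""
    T = counts_2d.shape[1]
    best_lp = -np.inf
    best_path = None
    for p in itertools.product(range(params.K), repeat=T):
        lp = _path_logprob(p, counts_2d, params)
        if lp > best_lp:
            best_lp = lp
            best_path = p
    return np.asarray(best_path)
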