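"""Inner recursions of the HMM, with optional numba acceleration.

Both implementations compute the scaled forward-backward pass and Viterbi
backtrack from per-bin emission log-probabilities ``logB`` padded to a
common length; padded bins carry logB = 0 for every state so their scaling
factors are exactly 1 and do not disturb the log-likelihood.  The numpy
fallback vectorizes across trials; the numba path loops per trial.
"""

from __future__ import annotations

import numpy as np

try:  # optional acceleration; the numpy path is exact but slower
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def _fb_numpy(logB, lengths, pi0, P):
    n_trials, Tmax, K = logB.shape
    m = logB.max(axis=2)
    bad = ~np.isfinite(m)
    if np.any(bad):
        i, t = np.argwhere(bad)[0]
        raise FloatingPointError(f"impossible data at trial {i}, bin {t}")
    B = np.exp(logB - m[:, :, None])
    alpha = np.empty((n_trials, Tmax, K))
    c = np.empty((n_trials, Tmax))
    a = pi0[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    if np.any(c[:, 0] == 0):
        raise FloatingPointError("impossible data at first bin")
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, Tmax):
        a = (alpha[:, t - 1] @ P) * B[:, t]
        s = a.sum(axis=1)
        if np.any(s == 0):
            raise FloatingPointError(f"impossible data at bin {t}")
        c[:, t] = s
        alpha[:, t] = a / s[:, None]
    valid = np.arange(Tmax)[None, :] < lengths[:, None]
    ll = ((np.log(c) + m) * valid).sum(axis=1)
    beta = np.empty((n_trials, Tmax, K))
    beta[:, -1] = 1.0
    xi_sum = np.zeros((K, K))
    pair_ok = np.arange(Tmax)[None, :] < (lengths[:, None] - 1)
    for t in range(Tmax - 2, -1, -1):
        bb = B[:, t + 1] * beta[:, t + 1]
        beta[:, t] = (bb @ P.T) / c[:, t + 1, None]
        w = pair_ok[:, t].astype(float)
        xi_sum += P * ((alpha[:, t] * w[:, None]).T @ (bb / c[:, t + 1, None]))
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    return gamma, xi_sum, ll


def _viterbi_numpy(logB, lengths, pi0, P):
    n_trials, Tmax, K = logB.shape
    with np.errstate(divide="ignore"):
        logP = np.log(P)
        logpi = np.log(pi0)
    paths = []
    for i in range(n_trials):
        L = int(lengths[i])
        delta = logpi + logB[i, 0]
        psi = np.zeros((L, K), dtype=np.int64)
        d = delta
        deltas = [d]
        for t in range(1, L):
            cand = d[:, None] + logP
            psi[t] = cand.argmax(axis=0)
            d = cand.max(axis=0) + logB[i, t]
            deltas.append(d)
        s = np.empty(L, dtype=np.int64)
        s[-1] = int(np.argmax(deltas[-1]))
        for t in range(L - 2, -1, -1):
            s[t] = psi[t + 1, s[t + 1]]
        paths.append(s)
    return paths


if HAVE_NUMBA:

    @numba.njit(cache=True)
    def _fb_numba(logB, lengths, pi0, P):  # pragma: no cover - numba
        n_trials, Tmax, K = logB.shape
        gamma = np.empty((n_trials, Tmax, K))
        xi_sum = np.zeros((K, K))
        ll = np.zeros(n_trials)
        alpha = np.empty((Tmax, K))
        beta = np.empty((Tmax, K))
        B = np.empty((Tmax, K))
        c = np.empty(Tmax)
        for i in range(n_trials):
            L = int(lengths[i])
            for t in range(L):
                m = -np.inf
                for k in range(K):
                    if logB[i, t, k] > m:
                        m = logB[i, t, k]
                if not np.isfinite(m):
                    raise FloatingPointError("impossible data under model")
                s = 0.0
                for k in range(K):
                    B[t, k] = np.exp(logB[i, t, k] - m)
                if t == 0:
                    for k in range(K):
                        alpha[0, k] = pi0[k] * B[0, k]
                        s += alpha[0, k]
                else:
                    for k in range(K):
                        a = 0.0
                        for j in range(K):
                            a += alpha[t - 1, j] * P[j, k]
                        alpha[t, k] = a * B[t, k]
                        s += alpha[t, k]
                if s == 0.0:
                    raise FloatingPointError("impossible data under model")
                c[t] = s
                for k in range(K):
                    alpha[t, k] /= s
                ll[i] += np.log(s) + m
            for k in range(K):
                beta[L - 1, k] = 1.0
            for t in range(L - 2, -1, -1):
                for j in range(K):
                    b = 0.0
                    for k in range(K):
                        b += P[j, k] * B[t + 1, k] * beta[t + 1, k]
                    beta[t, j] = b / c[t + 1]
                for j in range(K):
                    for k in range(K):
                        xi_sum[j, k] += (alpha[t, j] * P[j, k] * B[t + 1, k]
                                         * beta[t + 1, k] / c[t + 1])
            for t in range(L):
                s = 0.0
                for k in range(K):
                    gamma[i, t, k] = alpha[t, k] * beta[t, k]
                    s += gamma[i, t, k]
                for k in range(K):
                    gamma[i, t, k] /= s
            for t in range(L, Tmax):
                for k in range(K):
                    gamma[i, t, k] = 1.0 / K
        return gamma, xi_sum, ll

    @numba.njit(cache=True)
    def _viterbi_one_numba(logB_i, L, logpi, logP):  # pragma: no cover
        K = logB_i.shape[1]
        delta = np.empty((L, K))
        psi = np.zeros((L, K), dtype=np.int64)
        for k in range(K):
            delta[0, k] = logpi[k] + logB_i[0, k]
        for t in range(1, L):
            for k in range(K):
                best = -np.inf
                arg = 0
                for j in range(K):
                    v = delta[t - 1, j] + logP[j, k]
                    if v > best:
                        best = v
                        arg = j
                delta[t, k] = best + logB_i[t, k]
                psi[t, k] = arg
        s = np.empty(L, dtype=np.int64)
        best = -np.inf
        arg = 0
        for k in range(K):
            if delta[L - 1, k] > best:
                best = delta[L - 1, k]
                arg = k
        s[L - 1] = arg
        for t in range(L - 2, -1, -1):
            s[t] = psi[t + 1, s[t + 1]]
        return s


def forward_backward_kernel(logB, lengths, pi0, P):
    """gamma (normalized per valid bin), pooled xi_sum, loglik per trial."""
    logB = np.ascontiguousarray(logB, dtype=np.float64)
    lengths = np.asarray(lengths, dtype=np.int64)
    pi0 = np.ascontiguousarray(pi0, dtype=np.float64)
    P = np.ascontiguousarray(P, dtype=np.float64)
    if HAVE_NUMBA:
        return _fb_numba(logB, lengths, pi0, P)
    return _fb_numpy(logB, lengths, pi0, P)


def viterbi_kernel(logB, lengths, pi0, P):
    """Most probable path per trial, ties toward the lower state index."""
    logB = np.ascontiguousarray(logB, dtype=np.float64)
    lengths = np.asarray(lengths, dtype=np.int64)
    with np.errstate(divide="ignore"):
        logpi = np.log(np.ascontiguousarray(pi0, dtype=np.float64))
        logP = np.log(np.ascontiguousarray(P, dtype=np.float64))
    if HAVE_NUMBA:
        return [_viterbi_one_numba(logB[i], int(lengths[i]), logpi, logP)
                for i in range(logB.shape[0])]
    return _viterbi_numpy(logB, lengths,
                          np.asarray(pi0, float), np.asarray(P, float))
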