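"""Poisson hidden Markov model for multichannel spike counts.

The population's latent phase s_t (Off/On for K=2, 1..K generally) evolves
as a first-order Markov chain at the bin resolution; given the phase, each
channel's count in a bin is an independent Poisson draw with a phase- and
channel-specific mean.  Parameters are the initial distribution pi0, the
row-stochastic transition matrix P, and the emission matrix Lambda of
expected counts per bin (channels x phases).

Fitting uses Baum-Welch EM with random restarts; decoding uses Viterbi.
Trials are independent sequences sharing the parameters, each starting
from pi0.  The forward-backward pass is the scaled (linear-space) variant
with a per-bin log-shift, which keeps T up to 1e4 bins and many channels
free of underflow while returning the exact log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from ._kernels import forward_backward_kernel, viterbi_kernel
from .core import BinnedCounts

MAX_ITER = 500
TOL_LOGLIK = 1e-3   # relative log-likelihood change
TOL_PARAMS = 1e-5   # max-abs change of P and Lambda


@dataclass
class HmmParams:
    """pi0 (K,), P (K,K) row-stochastic, lam (channels x K) counts/bin."""

    pi0: np.ndarray
    P: np.ndarray
    lam: np.ndarray
    w_bin: float = 10.0

    def __post_init__(self) -> None:
        self.pi0 = np.asarray(self.pi0, float)
        self.P = np.asarray(self.P, float)
        self.lam = np.atleast_2d(np.asarray(self.lam, float))
        K = self.pi0.size
        if self.P.shape != (K, K):
            raise ValueError("P shape inconsistent with pi0")
        if self.lam.shape[1] != K:
            raise ValueError("lam must be (n_channels, K)")
        if not np.allclose(self.pi0.sum(), 1.0, atol=1e-9):
            raise ValueError("pi0 must sum to 1")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of P must sum to 1")
        if np.any(self.lam < 0):
            raise ValueError("emission rates must be non-negative")

    @property
    def K(self) -> int:
        return self.pi0.size

    @property
    def n_channels(self) -> int:
        return self.lam.shape[0]

    def rates_hz(self) -> np.ndarray:
        """Emission rates in spikes/s."""
        return self.lam * (1000.0 / self.w_bin)

    def permuted(self, order: np.ndarray) -> "HmmParams":
        order = np.asarray(order)
        return HmmParams(self.pi0[order], self.P[np.ix_(order, order)],
                         self.lam[:, order], self.w_bin)


@dataclass
class HmmFit:
    params: HmmParams
    loglik: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    restart: int
    restart_logliks: np.ndarray
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# packing and emissions

def _pack(counts: BinnedCounts):
    """Ragged trials -> padded (n_trials, Tmax, n_channels) plus lengths."""
    lengths = counts.n_bins
    Tmax = int(lengths.max())
    X = np.zeros((counts.n_trials, Tmax, counts.n_channels), dtype=np.int64)
    for i, c in enumerate(counts.counts):
        X[i, :c.shape[1]] = c.T
    return X, lengths


def emission_logpmf(n, lam):
    """log Poisson pmf, with the lam=0 convention log 1{n=0}.

    Broadcasts over arrays; negative counts raise.
    """
    n = np.asarray(n)
    lam = np.asarray(lam, float)
    if np.any(n < 0):
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = n * np.log(lam) - lam - gammaln(np.asarray(n, float) + 1.0)
    # lam == 0: probability 1 at n=0, 0 elsewhere
    zero = lam == 0
    if np.any(zero):
        out = np.where(zero & (n == 0), 0.0, out)
        out = np.where(zero & (n > 0), -np.inf, out)
    return out


def _log_emission_matrix(X, lengths, lam, lgn_sum=None):
    """logB[i, t, k] = sum_j log pmf(X[i,t,j]; lam[j,k]); 0 on padded bins.

    One matrix product per call: sum_j n_j log lam_jk - sum_j lam_jk -
    sum_j log n_j!.  Channels with lam exactly 0 get the degenerate
    convention (probability 1 at n=0, 0 otherwise) patched in afterwards.
    """
    n_trials, Tmax, n_ch = X.shape
    K = lam.shape[1]
    flat = X.reshape(-1, n_ch).astype(np.float64)
    if lgn_sum is None:
        lgn_sum = gammaln(flat + 1.0).sum(axis=1)
    zero = lam == 0
    with np.errstate(divide="ignore"):
        loglam = np.where(zero, 0.0, np.log(np.where(zero, 1.0, lam)))
    logB = flat @ loglam - lam.sum(axis=0)[None, :] - lgn_sum[:, None]
    if np.any(zero):
        # lam=0 contributes -inf when the observed count is positive
        for j, k in np.argwhere(zero):
            logB[flat[:, j] > 0, k] = -np.inf
    logB = logB.reshape(n_trials, Tmax, K)
    pad = np.arange(Tmax)[None, :] >= lengths[:, None]
    logB[pad] = 0.0
    return logB


# ---------------------------------------------------------------------------
# inference

def _forward_backward_packed(logB, lengths, pi0, P):
    """Scaled forward-backward on padded trials (see ``_kernels``)."""
    try:
        return forward_backward_kernel(logB, lengths, pi0, P)
    except FloatingPointError as e:
        raise ValueError(f"data impossible under model: {e}") from e


def forward_backward(counts: BinnedCounts, params: HmmParams):
    """Posterior phase probabilities, expected transitions, log-likelihood.

    Returns (gammas, xi_sum, loglik): gammas is a per-trial list of
    (n_bins, K) posteriors summing to 1 per bin; xi_sum the pooled (K, K)
    expected transition counts; loglik the total log data probability.
    """
    if counts.n_channels != params.n_channels:
        raise ValueError("channel count mismatch between counts and params")
    X, lengths = _pack(counts)
    logB = _log_emission_matrix(X, lengths, params.lam)
    gamma, xi_sum, ll = _forward_backward_packed(logB, lengths,
                                                 params.pi0, params.P)
    gammas = [gamma[i, :lengths[i]] for i in range(counts.n_trials)]
    return gammas, xi_sum, float(ll.sum())


def loglik(counts: BinnedCounts, params: HmmParams) -> float:
    return forward_backward(counts, params)[2]


def _viterbi_packed(logB, lengths, pi0, P):
    """Most probable path per trial; ties broken toward the lower index."""
    return viterbi_kernel(logB, lengths, pi0, P)


def viterbi(counts: BinnedCounts, params: HmmParams) -> list[np.ndarray]:
    """Decode the jointly most probable phase sequence per trial."""
    if counts.n_channels != params.n_channels:
        raise ValueError("channel count mismatch between counts and params")
    X, lengths = _pack(counts)
    logB = _log_emission_matrix(X, lengths, params.lam)
    return _viterbi_packed(logB, lengths, params.pi0, params.P)


# ---------------------------------------------------------------------------
# EM

def _init_params(counts: BinnedCounts, K: int, rng: np.random.Generator,
                 lam_groups: np.ndarray | None = None) -> HmmParams:
    """Random restart initialization.

    pi0 and P rows are flat-Dirichlet draws; each emission entry is uniform
    on (0, 2 x channel mean count).  ``lam_groups`` (channels x K of group
    labels) makes one draw per tied group so ties hold from the start.
    """
    pi0 = rng.dirichlet(np.ones(K))
    P = rng.dirichlet(np.ones(K), size=K)
    means = counts.channel_means()
    lam = np.empty((counts.n_channels, K))
    for j in range(counts.n_channels):
        if lam_groups is None:
            lam[j] = rng.uniform(0.0, 2.0 * max(means[j], 1e-12), size=K)
        else:
            for g in np.unique(lam_groups[j]):
                draw = rng.uniform(0.0, 2.0 * max(means[j], 1e-12))
                lam[j, lam_groups[j] == g] = draw
    return HmmParams(pi0, P, lam, counts.w_bin)


def _m_step(X2d, mask2d, gamma, xi_sum, prev_P, prev_lam,
            lam_groups: np.ndarray | None = None):
    """Exact maximizers; P rows and pi0 renormalized to sum to 1 exactly.

    ``X2d`` is (n_trials*Tmax, n_ch), ``mask2d`` the matching valid-bin
    mask.  With ``lam_groups`` the emission update pools expected counts
    and occupancies over tied states (the constrained maximizer).
    """
    n_trials, Tmax, K = gamma.shape
    g2 = gamma.reshape(-1, K) * mask2d[:, None]
    pi0 = gamma[:, 0, :].sum(axis=0)
    pi0 /= pi0.sum()
    rowsum = xi_sum.sum(axis=1, keepdims=True)
    P = np.where(rowsum > 0, xi_sum / np.where(rowsum > 0, rowsum, 1.0),
                 prev_P)
    P /= P.sum(axis=1, keepdims=True)
    occ = g2.sum(axis=0)                             # (K,)
    wc = X2d.T @ g2                                  # (n_ch, K)
    if lam_groups is None:
        lam = wc / np.where(occ > 0, occ, 1.0)[None, :]
        lam = np.where(occ[None, :] > 0, lam, prev_lam)
    else:
        lam = np.empty_like(wc)
        for j in range(wc.shape[0]):
            for gl in np.unique(lam_groups[j]):
                sel = lam_groups[j] == gl
                o = occ[sel].sum()
                lam[j, sel] = wc[j, sel].sum() / o if o > 0 \
                    else prev_lam[j, sel][0]
    return pi0, P, lam


def em_fit(counts: BinnedCounts, K: int, n_restarts: int = 10,
           seed: int | np.random.SeedSequence = 0,
           max_iter: int = MAX_ITER,
           lam_groups: np.ndarray | None = None,
           canonicalize: bool = True) -> HmmFit:
    """Baum-Welch EM with random restarts.

    Termination requires both criteria simultaneously: relative
    log-likelihood change below 1e-3 and max-abs change of P and Lambda
    below 1e-5; otherwise EM stops at ``max_iter`` (default 500) with
    ``converged=False``.  The best restart by final log-likelihood wins.
    ``lam_groups`` enables emission tying (see the joint two-area model).
    With ``canonicalize`` the phases are relabeled in increasing order of
    population-mean rate, so for K=2 phase 0 is Off and phase 1 is On.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if counts.n_trials == 0 or int(counts.n_bins.sum()) == 0:
        raise ValueError("empty counts")
    X, lengths = _pack(counts)
    n_trials, Tmax, n_ch = X.shape
    X2d = X.reshape(-1, n_ch).astype(np.float64)
    mask2d = (np.arange(Tmax)[None, :] < lengths[:, None]) \
        .reshape(-1).astype(np.float64)
    lgn_sum = gammaln(X2d + 1.0).sum(axis=1)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(n_restarts)
    best = None
    restart_lls = np.full(n_restarts, -np.inf)
    for r in range(n_restarts):
        rng = np.random.default_rng(children[r])
        init = _init_params(counts, K, rng, lam_groups)
        pi0, P, lam = init.pi0, init.P, init.lam
        trace = []
        converged = False
        for it in range(max_iter):
            logB = _log_emission_matrix(X, lengths, lam, lgn_sum)
            gamma, xi_sum, ll = _forward_backward_packed(logB, lengths,
                                                         pi0, P)
            ll_tot = float(ll.sum())
            trace.append(ll_tot)
            pi0n, Pn, lamn = _m_step(X2d, mask2d, gamma, xi_sum, P, lam,
                                     lam_groups)
            if len(trace) >= 2:
                old = trace[-2]
                rel = abs(ll_tot - old) / max(abs(old), 1e-300)
                dparam = max(np.abs(Pn - P).max(), np.abs(lamn - lam).max())
                if rel < TOL_LOGLIK and dparam < TOL_PARAMS:
                    pi0, P, lam = pi0n, Pn, lamn
                    converged = True
                    break
            pi0, P, lam = pi0n, Pn, lamn
        if not converged:
            warnings.warn(f"EM restart {r}: no convergence in {max_iter} "
                          "iterations", RuntimeWarning)
        restart_lls[r] = trace[-1]
        if best is None or trace[-1] > best.loglik:
            best = HmmFit(HmmParams(pi0, P, lam, counts.w_bin), trace[-1],
                          np.asarray(trace), converged, len(trace), r,
                          restart_lls)
    best.restart_logliks = restart_lls
    if canonicalize and K > 1 and lam_groups is None:
        order = np.argsort(best.params.lam.mean(axis=0), kind="stable")
        best.params = best.params.permuted(order)
    return best


def fit_all(counts: BinnedCounts, conditions: np.ndarray, K: int = 2,
            n_restarts: int = 10, seed: int = 0,
            min_trials: int = 2) -> dict:
    """One independent fit (and decode) per attention condition.

    Returns {condition: (HmmFit, paths, trial_index)}.  Conditions with
    fewer than ``min_trials`` trials are flagged and skipped.  Per-condition
    seeds derive from the condition name so trial order is irrelevant.
    """
    conditions = np.asarray(conditions)
    if len(conditions) != counts.n_trials:
        raise ValueError("one condition label per trial required")
    out = {}
    for cond in sorted(set(map(str, conditions))):
        idx = np.flatnonzero(conditions == cond)
        if len(idx) < min_trials:
            warnings.warn(f"condition {cond!r}: only {len(idx)} trials, "
                          "skipped", RuntimeWarning)
            continue
        sub = counts.select_trials(idx)
        ss = np.random.SeedSequence([seed, _stable_hash(cond)])
        fit = em_fit(sub, K, n_restarts=n_restarts, seed=ss)
        paths = viterbi(sub, fit.params)
        out[cond] = (fit, paths, idx)
    return out


def _stable_hash(s: str) -> int:
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h
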