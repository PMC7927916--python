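"""Model selection and variance explained.

Model selection follows a cross-validated prediction-error criterion: fit
HMMs with 1..K_max phases on 3/4 of trials, decode held-out trials with a
leave-one-channel-out rule (the held-out channel's emissions are removed
from the likelihood; transitions are untouched), and score the squared
difference between that channel's counts and the decoded phase's rate.
Errors are normalized to the 1-phase model; a recording counts as
two-phase when adding the second phase drops the normalized error by at
least 10% and no further phase drops it by another 10%.

Variance explained uses two-fold cross-validation: R^2 of held-out counts
against the decoded phase rates, with the ceiling Rmax^2 = 1 - 1/FF set by
the Poisson point-process variance through the Fano factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinnedCounts
from .hmm import HmmParams, em_fit, viterbi


@dataclass
class CvReport:
    k_values: np.ndarray
    normalized_error: np.ndarray   # mean across channels/folds, norm to K=1
    raw_error: np.ndarray          # per K, per channel, summed over folds
    selected_k: int
    included: bool                 # True iff the 2-phase elbow criterion held


@dataclass
class R2Report:
    r2: np.ndarray                 # per channel
    rmax2: np.ndarray
    fano: np.ndarray
    windows_ms: np.ndarray | None = None
    r2_by_window: np.ndarray | None = None      # (n_windows, n_channels)
    rmax2_by_window: np.ndarray | None = None


def _fold_assignment(n_trials: int, n_folds: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Seeded random partition of trials into roughly equal folds."""
    perm = rng.permutation(n_trials)
    folds = np.empty(n_trials, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        folds[chunk] = f
    return folds


def _loco_decode(test: BinnedCounts, params: HmmParams,
                 channel: int) -> list[np.ndarray]:
    """Decode with channel ``channel`` left out of the emission likelihood."""
    keep = np.arange(test.n_channels) != channel
    sub = test.select_channels(np.flatnonzero(keep))
    sub_params = HmmParams(params.pi0, params.P, params.lam[keep],
                           params.w_bin)
    return viterbi(sub, sub_params)


def cv_error(counts: BinnedCounts, K: int, n_folds: int = 4,
             seed: int = 0, n_restarts: int = 10) -> np.ndarray:
    """Leave-one-channel-out cross-validation error per channel.

    Returns CVvar[j] = sum over folds, held-out trials and bins of
    (n_tj - lam_{j, s_t})^2, with s_t decoded from all channels but j.
    """
    if counts.n_trials < n_folds:
        raise ValueError("fewer trials than folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, K]))
    folds = _fold_assignment(counts.n_trials, n_folds, rng)
    err = np.zeros(counts.n_channels)
    for f in range(n_folds):
        train = counts.select_trials(np.flatnonzero(folds != f))
        test = counts.select_trials(np.flatnonzero(folds == f))
        fit = em_fit(train, K, n_restarts=n_restarts,
                     seed=np.random.SeedSequence([seed, K, f]))
        lam = fit.params.lam
        for j in range(counts.n_channels):
            if K == 1:
                paths = [np.zeros(c.shape[1], dtype=int) for c in test.counts]
            else:
                paths = _loco_decode(test, fit.params, j)
            for c, s in zip(test.counts, paths):
                err[j] += float(np.sum((c[j] - lam[j, s]) ** 2))
    return err


def cv_curve(counts: BinnedCounts, k_max: int = 8, n_folds: int = 4,
             seed: int = 0, n_restarts: int = 10) -> CvReport:
    """CV error for K = 1..k_max, normalized to K=1, with elbow selection."""
    ks = np.arange(1, k_max + 1)
    raw = np.array([cv_error(counts, int(K), n_folds, seed, n_restarts)
                    for K in ks])
    return select_k(ks, raw)


def select_k(k_values: np.ndarray, raw_error: np.ndarray,
             drop_threshold: float = 0.10,
             relative_to_previous: bool = False) -> CvReport:
    """Apply the 10%-drop elbow rule to a CV error curve.

    The error curve (mean across channels) is normalized to the 1-phase
    error.  Incremental drops are differences of that normalized curve
    between consecutive K (set ``relative_to_previous`` to measure each
    drop relative to the previous K's error instead).  The selected K is
    the largest K whose incremental drop meets the threshold (1 if none);
    a recording is included as two-phase iff the drop at K=2 meets the
    threshold and no later drop does.
    """
    k_values = np.asarray(k_values)
    if k_values[0] != 1:
        raise ValueError("the K=1 error is required for normalization")
    mean_err = np.asarray(raw_error, float).mean(axis=1)
    norm = mean_err / mean_err[0]
    if relative_to_previous:
        drops = -np.diff(norm) / norm[:-1]
    else:
        drops = -np.diff(norm)
    big = np.flatnonzero(drops >= drop_threshold)
    selected = int(k_values[big[-1] + 1]) if big.size else 1
    included = selected == 2
    return CvReport(k_values, norm, np.asarray(raw_error, float),
                    selected, included)


def rmax2(counts_2d: np.ndarray | None = None,
          fano: np.ndarray | None = None) -> np.ndarray:
    """Maximal explainable variance 1 - 1/FF per channel.

    Either pass pooled counts (n_channels, n_bins) or precomputed Fano
    factors.  FF uses the unbiased variance estimator.  Zero-mean channels
    give NaN (undefined).
    """
    if fano is None:
        c = np.asarray(counts_2d, float)
        if c.shape[1] < 2:
            raise ValueError("need at least 2 bins")
        mean = c.mean(axis=1)
        var = c.var(axis=1, ddof=1)
        fano = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), np.nan)
    fano = np.asarray(fano, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 1.0 - 1.0 / fano


def _window_aggregate(x: np.ndarray, m: int) -> np.ndarray:
    """Sum consecutive groups of m bins (trailing partial group dropped)."""
    n = (x.shape[-1] // m) * m
    if n == 0:
        return x[..., :0]
    shape = x.shape[:-1] + (n // m, m)
    return x[..., :n].reshape(shape).sum(axis=-1)


def r2_explained(counts: BinnedCounts, n_folds: int = 2, seed: int = 0,
                 n_restarts: int = 10, K: int = 2,
                 unit_counts: BinnedCounts | None = None,
                 windows_ms: np.ndarray | None = None) -> R2Report:
    """Cross-validated fraction of variance explained by the decoded phases.

    The model is fit on half the trials and the held-out trials are decoded
    with it (all channels).  In multiunit mode the fitted rates predict the
    held-out counts directly.  Passing ``unit_counts`` switches to
    single-unit mode: the unit's On/Off rates are estimated as its mean
    rate over the training trials' decoded phases, then scored on test
    trials (the latent sequence still comes from the multiunit model).
    ``windows_ms`` adds an integration-window sweep where the prediction
    for a window is the summed phase rate across its bins.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    folds = _fold_assignment(counts.n_trials, n_folds, rng)
    target = unit_counts if unit_counts is not None else counts
    n_out = target.n_channels
    sse = np.zeros(n_out)
    sst = np.zeros(n_out)
    win_list = None
    if windows_ms is not None:
        windows_ms = np.asarray(windows_ms, float)
        win_list = [{"sse": np.zeros(n_out), "sst": np.zeros(n_out),
                     "data": [[] for _ in range(n_out)]}
                    for _ in windows_ms]
    pooled_pred = [[] for _ in range(n_out)]
    pooled_data = [[] for _ in range(n_out)]
    for f in range(n_folds):
        tr_idx = np.flatnonzero(folds != f)
        te_idx = np.flatnonzero(folds == f)
        train = counts.select_trials(tr_idx)
        test = counts.select_trials(te_idx)
        fit = em_fit(train, K, n_restarts=n_restarts,
                     seed=np.random.SeedSequence([seed, f]))
        if unit_counts is not None:
            tr_paths = viterbi(train, fit.params)
            lam = _unit_rates(unit_counts.select_trials(tr_idx), tr_paths, K)
        else:
            lam = fit.params.lam
        te_paths = viterbi(test, fit.params)
        te_target = target.select_trials(te_idx)
        for c, s in zip(te_target.counts, te_paths):
            pred = lam[:, s]                       # (n_out, n_bins)
            for j in range(n_out):
                pooled_pred[j].append(pred[j])
                pooled_data[j].append(c[j].astype(float))
            if win_list is not None:
                for wi, w in enumerate(windows_ms):
                    m = max(int(round(w / counts.w_bin)), 1)
                    pw = _window_aggregate(pred, m)
                    cw = _window_aggregate(c.astype(float), m)
                    for j in range(n_out):
                        win_list[wi]["data"][j].append((cw[j], pw[j]))
    r2 = np.empty(n_out)
    fano = np.empty(n_out)
    for j in range(n_out):
        d = np.concatenate(pooled_data[j])
        p = np.concatenate(pooled_pred[j])
        r2[j] = _r2(d, p)
        mean = d.mean()
        fano[j] = d.var(ddof=1) / mean if mean > 0 else np.nan
    rep = R2Report(r2, rmax2(fano=fano), fano)
    if win_list is not None:
        nw = len(windows_ms)
        rep.windows_ms = windows_ms
        rep.r2_by_window = np.empty((nw, n_out))
        rep.rmax2_by_window = np.empty((nw, n_out))
        for wi in range(nw):
            for j in range(n_out):
                d = np.concatenate([a for a, _ in win_list[wi]["data"][j]])
                p = np.concatenate([b for _, b in win_list[wi]["data"][j]])
                rep.r2_by_window[wi, j] = _r2(d, p)
                m = d.mean()
                ff = d.var(ddof=1) / m if m > 0 else np.nan
                rep.rmax2_by_window[wi, j] = 1.0 - 1.0 / ff if ff else np.nan
    return rep


def _r2(data: np.ndarray, pred: np.ndarray) -> float:
    sst = float(np.sum((data - data.mean()) ** 2))
    if sst == 0:
        return np.nan
    return 1.0 - float(np.sum((data - pred) ** 2)) / sst


def _unit_rates(units: BinnedCounts, paths: list[np.ndarray],
                K: int) -> np.ndarray:
    """Mean unit count per bin in each decoded phase (counts/bin)."""
    num = np.zeros((units.n_channels, K))
    den = np.zeros(K)
    for c, s in zip(units.counts, paths):
        for k in range(K):
            sel = s == k
            num[:, k] += c[:, sel].sum(axis=1)
            den[k] += sel.sum()
    return num / np.where(den > 0, den, 1.0)[None, :]
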