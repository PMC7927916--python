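"""Interareal coordination measures.

Cross-correlation of decoded On-Off series between two areas with a
trial-shuffle predictor, event-triggered cross-correlograms (state
transitions around microsaccades), transition-triggered averages of
spiking, and the two-line crossing-point estimate of when one area's rate
changes relative to the other's transitions.

Lag sign convention: with x the V1 series and y the V4 series,
CC(tau) averages x(t) * y(t + tau), so a peak at negative tau means the
y (V4) series leads (V4 transitions occur earlier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class CrossCorr:
    lags_ms: np.ndarray
    values: np.ndarray
    shuffle: np.ndarray | None = None
    n: int = 0                     # trials (or events) averaged

    @property
    def corrected(self) -> np.ndarray:
        if self.shuffle is None:
            return self.values
        return self.values - self.shuffle


@dataclass
class Tta:
    time_ms: np.ndarray
    rate: np.ndarray               # (n_channels, n_lags) mean counts/bin
    shuffle: np.ndarray | None
    n_transitions: int
    crossing_ms: float | None = None

    @property
    def corrected(self) -> np.ndarray:
        if self.shuffle is None:
            return self.rate
        return self.rate - self.shuffle


def _xcorr_one(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray | None:
    """Normalized cross-correlation sum_t x(t) y(t+tau) for |tau|<=max_lag.

    Per-trial normalization sqrt(sum x^2 * sum y^2), so a trial's value at
    zero lag for y=x is exactly 1.  Returns None for zero-variance input.
    """
    x = x - x.mean()
    y = y - y.mean()
    den = np.sqrt(np.sum(x ** 2) * np.sum(y ** 2))
    if den == 0:
        return None
    full = np.correlate(y, x, mode="full")   # index N-1+tau = sum x(t) y(t+tau)
    n = len(x)
    out = np.zeros(2 * max_lag + 1)
    for i, tau in enumerate(range(-max_lag, max_lag + 1)):
        idx = n - 1 + tau
        if 0 <= idx < len(full):
            out[i] = full[idx]
    return out / den


def _trim_pairs(x_paths, y_paths):
    """Mean-subtracted series pairs truncated to the common per-pair length."""
    pairs = []
    for x, y in zip(x_paths, y_paths):
        n = min(len(x), len(y))
        if n >= 2:
            pairs.append((np.asarray(x[:n], float), np.asarray(y[:n], float)))
    return pairs


def cc_hmm(x_paths: list[np.ndarray], y_paths: list[np.ndarray],
           max_lag_ms: float = 500.0, w_bin: float = 10.0) -> CrossCorr:
    """Trial-averaged normalized cross-correlation of two binary series.

    x and y are trial-matched decoded On-Off series (V1 and V4).  Each
    trial is mean-subtracted and normalized on its own; zero-variance
    trials are skipped with a warning.
    """
    max_lag = int(round(max_lag_ms / w_bin))
    acc = np.zeros(2 * max_lag + 1)
    n = 0
    for x, y in _trim_pairs(x_paths, y_paths):
        cc = _xcorr_one(x, y, max_lag)
        if cc is None:
            warnings.warn("zero-variance trial skipped in cc_hmm",
                          RuntimeWarning)
            continue
        acc += cc
        n += 1
    if n == 0:
        raise ValueError("no usable trials for cross-correlation")
    lags = np.arange(-max_lag, max_lag + 1) * w_bin
    return CrossCorr(lags, acc / n, None, n)


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def shuffle_predictor(x_paths, y_paths, max_lag_ms: float = 500.0,
                      w_bin: float = 10.0, n_shuffles: int = 100,
                      seed: int = 0) -> np.ndarray:
    """Cross-correlation expected from task-locked structure alone.

    Averages the trial-averaged CC over ``n_shuffles`` derangements of the
    y trials against unshuffled x; subtracting it from the raw CC removes
    event-locked common modulation.
    """
    if len(x_paths) < 2:
        raise ValueError("shuffle predictor needs at least 2 trials")
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    max_lag = int(round(max_lag_ms / w_bin))
    acc = np.zeros(2 * max_lag + 1)
    for _ in range(n_shuffles):
        perm = _derangement(len(y_paths), rng)
        y_shuf = [y_paths[p] for p in perm]
        acc += cc_hmm(x_paths, y_shuf, max_lag_ms, w_bin).values
    return acc / n_shuffles


def auc_split(cc: CrossCorr) -> tuple[float, float, float]:
    """Trapezoidal area of the (shuffle-subtracted) CC for tau<0 and tau>0.

    The zero-lag point is excluded from both halves.  Returns
    (area_neg, area_pos, area_neg - area_pos); mass at negative lags means
    the y (V4) series leads.
    """
    v = cc.corrected
    lags = cc.lags_ms
    neg = lags < 0
    pos = lags > 0
    a_neg = float(np.trapezoid(v[neg], lags[neg])) if neg.sum() > 1 else 0.0
    a_pos = float(np.trapezoid(v[pos], lags[pos])) if pos.sum() > 1 else 0.0
    return a_neg, a_pos, a_neg - a_pos


def cc_events(transition_times: list[np.ndarray], event_times: list[np.ndarray],
              max_lag_ms: float = 500.0, bin_ms: float = 20.0,
              n_shuffles: int = 100, seed: int = 0) -> CrossCorr:
    """Cross-correlogram of state transitions around events, per event.

    Counts transition-event time differences (transition minus event) in
    bins of ``bin_ms`` and divides by the total number of events, giving
    coincidences of state transitions per event.  A trial-shuffle predictor
    pairs transitions with events from other trials.
    """
    n_events = int(sum(len(e) for e in event_times))
    if n_events == 0:
        raise ValueError("no events")
    edges = np.arange(-max_lag_ms, max_lag_ms + bin_ms, bin_ms)
    centers = (edges[:-1] + edges[1:]) / 2.0

    def histo(trans_list, ev_list):
        h = np.zeros(len(centers))
        tot = 0
        for tt, ev in zip(trans_list, ev_list):
            tot += len(ev)
            for e in ev:
                h += np.histogram(np.asarray(tt) - e, bins=edges)[0]
        return h / max(tot, 1)

    values = histo(transition_times, event_times)
    shuffle = None
    if len(event_times) >= 2 and n_shuffles > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed]))
        acc = np.zeros(len(centers))
        for _ in range(n_shuffles):
            perm = _derangement(len(event_times), rng)
            acc += histo(transition_times, [event_times[p] for p in perm])
        shuffle = acc / n_shuffles
    return CrossCorr(centers, values, shuffle, n_events)


def _isolated(times: np.ndarray, all_times: np.ndarray,
              isolation_ms: float) -> np.ndarray:
    """Times with no other transition within the isolation window."""
    keep = []
    for t in times:
        d = np.abs(all_times - t)
        if np.sum(d < isolation_ms) <= 1:      # itself only
            keep.append(t)
    return np.asarray(keep)


def tta(counts: list[np.ndarray], windows: np.ndarray,
        transition_times: list[np.ndarray],
        all_transition_times: list[np.ndarray] | None = None,
        w_bin: float = 10.0, half_width_ms: float = 200.0,
        isolation_ms: float = 100.0, n_shuffles: int = 100,
        seed: int = 0, fit_crossing: bool = True) -> Tta:
    """Mean spike counts in one area around state transitions in the other.

    ``counts`` is per trial (n_channels, n_bins) with window starts in
    ``windows``; ``transition_times`` are the alignment transitions (ms,
    trial clock).  Only isolated transitions (no neighbor within
    ``isolation_ms`` among ``all_transition_times``) are used.  The shuffle
    predictor aligns each trial's counts to transitions drawn from other
    trials.  The mean rate is per transition, per channel.
    """
    L = int(round(half_width_ms / w_bin))
    time_ms = np.arange(-L, L + 1) * w_bin
    n_ch = counts[0].shape[0]

    def accumulate(count_list, trans_list):
        acc = np.zeros((n_ch, 2 * L + 1))
        n = 0
        for c, (start, _), tt in zip(count_list, windows, trans_list):
            nb = c.shape[1]
            for t in tt:
                b = int(np.floor((t - start) / w_bin))
                if b - L < 0 or b + L >= nb:
                    continue
                acc += c[:, b - L:b + L + 1]
                n += 1
        return acc, n

    if all_transition_times is None:
        all_transition_times = transition_times
    iso = [_isolated(np.asarray(tt), np.asarray(at), isolation_ms)
           for tt, at in zip(transition_times, all_transition_times)]
    acc, n = accumulate(counts, iso)
    if n == 0:
        warnings.warn("no isolated transitions for the TTA", RuntimeWarning)
        return Tta(time_ms, np.full((n_ch, 2 * L + 1), np.nan), None, 0)
    rate = acc / n
    shuffle = None
    if n_shuffles > 0 and len(counts) >= 2:
        rng = np.random.default_rng(np.random.SeedSequence([seed]))
        sh = np.zeros_like(rate)
        n_ok = 0
        for _ in range(n_shuffles):
            perm = _derangement(len(counts), rng)
            a, m = accumulate(counts, [iso[p] for p in perm])
            if m > 0:
                sh += a / m
                n_ok += 1
        shuffle = sh / n_ok if n_ok else None
    out = Tta(time_ms, rate, shuffle, n)
    if fit_crossing:
        pop = np.nanmean(out.rate, axis=0)
        out.crossing_ms = two_line_crossing(time_ms, pop)
    return out


def two_line_crossing(t: np.ndarray, y: np.ndarray) -> float | None:
    """Crossing point of two least-squares lines fit around a breakpoint.

    Grid-searches interior breakpoints, fits independent lines to the left
    and right segments, keeps the pair with the lowest total squared error
    and returns their intersection time (ms).  Parallel best-fit lines (or
    a flat trace) give None.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 4:
        raise ValueError("need at least 4 points")
    best = None
    for brk in range(2, len(t) - 1):
        tl, yl = t[:brk], y[:brk]
        tr, yr = t[brk:], y[brk:]
        al, bl = np.polyfit(tl, yl, 1)
        ar, br = np.polyfit(tr, yr, 1)
        sse = (np.sum((yl - (al * tl + bl)) ** 2)
               + np.sum((yr - (ar * tr + br)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, al, bl, ar, br)
    _, al, bl, ar, br = best
    if np.isclose(al, ar):
        return None
    return float((br - bl) / (al - ar))
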