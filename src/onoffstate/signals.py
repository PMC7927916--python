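"""Continuous-signal preprocessing and state-conditioned spectra.

Referencing (common-average, bipolar), multiunit envelope (MUAe), energy,
finite-difference current source density, SNR-based channel inclusion, the
visual response-latency model, multitaper spectra conditioned on decoded
On-Off states, Benjamini-Hochberg FDR, and receptive-field map summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal
from scipy.signal.windows import dpss
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .dynamics import epochs_from_path


# ---------------------------------------------------------------------------
# referencing and elementary measures

def common_average_reference(v: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean from every channel, per sample."""
    v = np.asarray(v, float)
    if v.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    return v - v.mean(axis=0, keepdims=True)


def bipolar_reref(v: np.ndarray, depth_um: np.ndarray | None = None) -> np.ndarray:
    """Differences between neighboring depth-ordered channels
    (superficial minus deep); n channels in, n-1 out."""
    v = np.asarray(v, float)
    if v.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if depth_um is not None and np.any(np.diff(np.asarray(depth_um)) <= 0):
        raise ValueError("channels must be depth-ordered")
    return v[:-1] - v[1:]


def energy(v: np.ndarray) -> float:
    """Sum of squared samples."""
    v = np.asarray(v, float)
    return float(np.sum(v ** 2))


def muae(v: np.ndarray, fs: float, cutoff: float = 300.0,
         order: int = 5) -> np.ndarray:
    """Multiunit activity envelope: rectify, then low-pass Butterworth
    (5th order, -3 dB at 300 Hz).  Input is the 0.6-9 kHz band signal."""
    if fs <= 2 * cutoff:
        raise ValueError("sampling rate too low for the 300 Hz low-pass")
    # second-order sections: the ba form of a 5th-order filter at
    # 300/30000 Hz is numerically fragile
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfilt(sos, np.abs(np.asarray(v, float)), axis=-1)


def csd_fd(phi: np.ndarray, h_um: float = 150.0) -> np.ndarray:
    """Finite-difference CSD: second spatial difference over the electrode
    spacing, CSD(x) = (phi(x+h) - 2 phi(x) + phi(x-h)) / h^2.

    ``phi`` is (n_channels, ...) ordered by depth; output has n-2 channels.
    No conductivity factor is applied; sinks/sources follow the raw second
    difference's sign.
    """
    phi = np.asarray(phi, float)
    if phi.shape[0] < 3:
        raise ValueError("CSD needs at least 3 channels")
    return (phi[2:] - 2 * phi[1:-1] + phi[:-2]) / h_um ** 2


# ---------------------------------------------------------------------------
# SNR and channel inclusion

SNR_WINDOWS = [(30.0 + 10.0 * i, 80.0 + 10.0 * i) for i in range(8)]
SNR_BASELINE = (-200.0, -50.0)


def snr(muae_trials: np.ndarray, fs: float, stim_onset_ms: float,
        threshold: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus-evoked SNR per channel, and the >3 inclusion flag.

    ``muae_trials`` is (n_trials, n_channels, n_samples) with the stimulus
    at ``stim_onset_ms``.  Signal is the trial-averaged MUAe amplitude in
    one of eight 50-ms windows from (30, 80) to (100, 150) ms after onset;
    Noise is the mean and sigma the SD of the trial-averaged baseline
    (-200 to -50 ms).  A channel is included iff its best window's SNR
    exceeds the threshold (strictly).
    """
    x = np.asarray(muae_trials, float)
    mean_tc = x.mean(axis=0)                       # (n_channels, n_samples)
    t = np.arange(mean_tc.shape[1]) / fs * 1000.0 - stim_onset_ms
    base = (t >= SNR_BASELINE[0]) & (t < SNR_BASELINE[1])
    if base.sum() < 2:
        raise ValueError("baseline window outside the trial")
    noise = mean_tc[:, base].mean(axis=1)
    sigma = mean_tc[:, base].std(axis=1, ddof=1)
    best = np.full(mean_tc.shape[0], -np.inf)
    for lo, hi in SNR_WINDOWS:
        sel = (t >= lo) & (t < hi)
        if not sel.any():
            raise ValueError("response window outside the trial")
        sig = mean_tc[:, sel].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (sig - noise) / sigma
        best = np.fmax(best, s)
    included = np.where(sigma > 0, best > threshold, False)
    best = np.where(sigma > 0, best, np.nan)
    return best, included


# ---------------------------------------------------------------------------
# response latency

def _latency_model(t, mu, sigma, alpha, c, d):
    """Exponentially modified Gaussian plus cumulative Gaussian."""
    expo = np.exp(np.clip(mu * alpha + 0.5 * sigma ** 2 * alpha ** 2
                          - alpha * t, -700, 700))
    return (d * expo * norm.cdf(t, loc=mu + sigma ** 2 * alpha, scale=sigma)
            + c * norm.cdf(t, loc=mu, scale=sigma))


@dataclass
class LatencyFit:
    params: dict | None
    latency_ms: float | None
    sse: float | None
    converged: bool


def latency_fit(mean_muae: np.ndarray, fs: float,
                onset_ms: float = 0.0, frac: float = 0.33) -> LatencyFit:
    """Fit the visual-response onset model and extract the latency.

    Nonlinear least squares from a small multi-start grid.  The latency is
    the earliest time the fitted curve reaches ``frac`` of the maximum of
    its first (non-dissipating cumulative-Gaussian) component, i.e. of c.
    A flat trace or non-convergence gives a missing latency.
    """
    y = np.asarray(mean_muae, float)
    t = np.arange(len(y)) / fs * 1000.0 - onset_ms
    y0 = y - np.median(y[t < 0]) if np.any(t < 0) else y - y.min()
    amp = float(y0.max())
    if amp <= 0 or np.ptp(y0) == 0:
        return LatencyFit(None, None, None, False)
    best = None
    for mu0 in (30.0, 60.0, 90.0):
        for alpha0 in (0.005, 0.02, 0.05):
            p0 = [mu0, 10.0, alpha0, amp * 0.5, amp * 0.5]
            try:
                popt, _ = optimize.curve_fit(
                    _latency_model, t, y0, p0=p0,
                    bounds=([0, 1e-3, 1e-5, 0, 0],
                            [t.max(), 200, 1.0, 10 * amp, 10 * amp]),
                    maxfev=5000)
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((y0 - _latency_model(t, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        return LatencyFit(None, None, None, False)
    sse, popt = best
    mu, sig, alpha, c, d = popt
    thresh = frac * c
    tf = np.linspace(t.min(), t.max(), 20 * len(t))
    yf = _latency_model(tf, *popt)
    above = np.flatnonzero(yf >= thresh)
    latency = float(tf[above[0]]) if above.size and c > 0 else None
    return LatencyFit(dict(mu=mu, sigma=sig, alpha=alpha, c=c, d=d),
                      latency, sse, True)


# ---------------------------------------------------------------------------
# state-conditioned multitaper spectra

@dataclass
class SpectrumSet:
    freqs: np.ndarray
    power: dict                    # state label -> (n_channels, n_freqs)
    n_epochs: dict
    percent_change: dict | None = None


def multitaper_psd(seg: np.ndarray, fs: float, nw: float = 4.0,
                   k_tapers: int = 7, pad_to: int = 1024) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper power spectrum of one segment, zero-padded to ``pad_to``.

    DPSS tapers with time-bandwidth NW (K = 2 NW - 1 gives the 7 tapers);
    power is the taper-averaged periodogram on the padded FFT grid.
    """
    seg = np.asarray(seg, float)
    n = seg.shape[-1]
    if n > pad_to:
        raise ValueError("segment longer than pad length; split it first")
    tapers = dpss(n, nw, Kmax=k_tapers)            # unit-norm rows
    tapered = seg[..., None, :] * tapers           # (..., K, n)
    spec = np.fft.rfft(tapered, n=pad_to, axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=-2) / fs
    freqs = np.fft.rfftfreq(pad_to, 1.0 / fs)
    return freqs, psd


def _epoch_segments(path, lfp_trial, w_bin, fs, min_epoch_ms, pad_to):
    """(state, segment) pairs from qualifying epochs; long epochs are split
    into non-overlapping pad_to-sample chunks."""
    out = []
    for ep in epochs_from_path(path, w_bin):
        if ep.duration <= min_epoch_ms:
            continue
        i0 = int(round(ep.start * fs / 1000.0))
        i1 = int(round(ep.end * fs / 1000.0))
        i1 = min(i1, lfp_trial.shape[-1])
        if i1 - i0 < int(min_epoch_ms * fs / 1000.0):
            continue
        seg = lfp_trial[..., i0:i1]
        n = seg.shape[-1]
        if n <= pad_to:
            out.append((ep.phase, seg))
        else:
            for s in range(0, n - pad_to + 1, pad_to):
                out.append((ep.phase, seg[..., s:s + pad_to]))
    return out


def state_spectra(lfp_trials: list[np.ndarray], paths: list[np.ndarray],
                  fs: float = 1000.0, w_bin: float = 10.0,
                  min_epoch_ms: float = 250.0, k_tapers: int = 7,
                  nw: float = 4.0, pad_to: int = 1024,
                  f_range: tuple[float, float] = (4.0, 200.0),
                  states: tuple = (0, 1),
                  contrast_pairs: dict | None = None) -> SpectrumSet:
    """LFP power per decoded state from epochs longer than ``min_epoch_ms``.

    Paths and LFP share the trial clock (path bin b covers
    [b*w_bin, (b+1)*w_bin) ms of the LFP trial).  Percent change is
    100 * (On - Off) / Off for 2-state paths, or the requested
    ``contrast_pairs`` {label: (state_a, state_b)} giving
    100 * (P_a - P_b) / P_b for joint-state analyses.
    """
    acc = {s: None for s in states}
    n_ep = {s: 0 for s in states}
    freqs = None
    for lfp_t, path in zip(lfp_trials, paths):
        for st, seg in _epoch_segments(path, lfp_t, w_bin, fs,
                                       min_epoch_ms, pad_to):
            if st not in acc:
                continue
            f, psd = multitaper_psd(seg, fs, nw, k_tapers, pad_to)
            freqs = f
            acc[st] = psd if acc[st] is None else acc[st] + psd
            n_ep[st] += 1
    if freqs is None:
        raise ValueError("no qualifying epochs in any state")
    sel = (freqs >= f_range[0]) & (freqs <= f_range[1])
    power = {}
    for s in states:
        if n_ep[s] == 0:
            warnings.warn(f"state {s}: no qualifying epochs", RuntimeWarning)
            power[s] = None
        else:
            power[s] = np.atleast_2d(acc[s])[:, sel] / n_ep[s]
    out = SpectrumSet(freqs[sel], power, n_ep)
    if contrast_pairs is None and set(states) == {0, 1}:
        contrast_pairs = {"on_vs_off": (1, 0)}
    if contrast_pairs:
        out.percent_change = {}
        for label, (a, b) in contrast_pairs.items():
            if power.get(a) is None or power.get(b) is None:
                out.percent_change[label] = None
            else:
                out.percent_change[label] = \
                    100.0 * (power[a] - power[b]) / power[b]
    return out


# ---------------------------------------------------------------------------
# FDR and receptive fields

def fdr_correct(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=q, method="fdr_bh")[0]


@dataclass
class RfSummary:
    population_z: dict             # area -> combined z-map
    center: dict                   # area -> (row, col) centroid or None
    overlap: float | None          # shared area / V1 RF area
    separation: float | None       # center-to-center distance (grid units)


def stouffer_combine(zmaps: np.ndarray, printed_variant: bool = False) -> np.ndarray:
    """Combine per-channel z-maps: sum(Z)/sqrt(k) (standard Stouffer), or
    the sum(Z)/k variant behind the flag."""
    z = np.asarray(zmaps, float)
    k = z.shape[0]
    denom = k if printed_variant else np.sqrt(k)
    return z.sum(axis=0) / denom


def rf_summary(zmaps_by_area: dict, z_threshold: float = 3.0,
               grid_spacing: float = 1.0,
               printed_variant: bool = False) -> RfSummary:
    """Population RF maps, centers, overlap and separation for two areas.

    The RF is the supra-threshold region of the Stouffer-combined z-map;
    its center is the region's centroid.  Overlap is the shared area as a
    proportion of the V1 RF; separation the center distance (in grid units
    times ``grid_spacing``).
    """
    pop, masks, centers = {}, {}, {}
    for area, zmaps in zmaps_by_area.items():
        pz = stouffer_combine(np.asarray(zmaps), printed_variant)
        pop[area] = pz
        m = pz > z_threshold
        masks[area] = m
        if m.any():
            idx = np.argwhere(m)
            centers[area] = idx.mean(axis=0)
        else:
            warnings.warn(f"area {area}: no supra-threshold RF region",
                          RuntimeWarning)
            centers[area] = None
    overlap = separation = None
    names = list(zmaps_by_area)
    if len(names) == 2:
        a, b = ("V1", "V4") if {"V1", "V4"} <= set(names) else names
        if masks[a].any() and masks[b].any():
            overlap = float((masks[a] & masks[b]).sum() / masks[a].sum())
            separation = float(np.linalg.norm(centers[a] - centers[b])
                               * grid_spacing)
    return RfSummary(pop, centers, overlap, separation)
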