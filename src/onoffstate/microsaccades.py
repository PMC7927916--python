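"""Microsaccade detection and statistics.

Velocity-threshold detection in the Engbert-Kliegl style: eye position is
differentiated, low-pass filtered (20 Hz, 2nd-order Butterworth, zero
phase), and an event requires the elliptical criterion
(vx / 6 sx)^2 + (vy / 6 sy)^2 > 1 for at least three consecutive samples,
where s is the robust median-based SD estimate per component and trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal


@dataclass
class Microsaccade:
    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    peak_velocity: float           # deg/s
    direction_deg: float           # [0, 360)


def eye_velocity(trace: np.ndarray, fs: float,
                 cutoff: float = 20.0) -> np.ndarray:
    """Central-difference velocity (deg/s) low-passed at 20 Hz, zero-phase.

    ``trace`` is (2, n_samples) of horizontal/vertical gaze in degrees.
    """
    x = np.asarray(trace, float)
    if x.ndim != 2 or x.shape[0] != 2:
        raise ValueError("trace must be (2, n_samples)")
    if x.shape[1] < 5:
        raise ValueError("trace too short for velocity estimation")
    v = np.empty_like(x)
    v[:, 1:-1] = (x[:, 2:] - x[:, :-2]) * fs / 2.0
    v[:, 0] = (x[:, 1] - x[:, 0]) * fs
    v[:, -1] = (x[:, -1] - x[:, -2]) * fs
    b, a = signal.butter(2, cutoff, btype="low", fs=fs)
    return signal.filtfilt(b, a, v, axis=1)


def _median_sd(v: np.ndarray) -> float:
    """Robust SD: sqrt(median(v^2) - median(v)^2)."""
    return float(np.sqrt(max(np.median(v ** 2) - np.median(v) ** 2, 0.0)))


def detect(velocity: np.ndarray, position: np.ndarray, fs: float,
           n_sd: float = 6.0, min_samples: int = 3,
           merge_ms: float = 20.0, edge_guard: int = 3) -> list[Microsaccade]:
    """Detect microsaccades in one trial's filtered velocity.

    Onset/offset are the first/last samples of each supra-threshold run;
    the amplitude and direction come from the position displacement between
    them.  Runs separated by less than ``merge_ms`` are merged (double
    counting at 220 Hz otherwise).  Runs touching the first or last
    ``edge_guard`` samples are discarded: the zero-phase filter and the
    one-sided difference are unreliable there and produce spurious
    crossings.  Degenerate (constant-velocity) trials are skipped with a
    warning.
    """
    v = np.asarray(velocity, float)
    pos = np.asarray(position, float)
    sx, sy = _median_sd(v[0]), _median_sd(v[1])
    if sx == 0 or sy == 0:
        warnings.warn("zero velocity spread; detection skipped for trial",
                      RuntimeWarning)
        return []
    crit = (v[0] / (n_sd * sx)) ** 2 + (v[1] / (n_sd * sy)) ** 2 > 1.0
    runs = _runs(crit)
    n = v.shape[1]
    runs = [r for r in runs if r[1] - r[0] >= min_samples
            and r[0] >= edge_guard and r[1] <= n - edge_guard]
    merged = []
    gap = merge_ms / 1000.0 * fs
    for r in runs:
        if merged and r[0] - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(r)
    out = []
    for a, b in merged:
        dx = pos[0, b - 1] - pos[0, a]
        dy = pos[1, b - 1] - pos[1, a]
        amp = float(np.hypot(dx, dy))
        direction = float(np.degrees(np.arctan2(dy, dx)) % 360.0)
        pv = float(np.max(np.hypot(v[0, a:b], v[1, a:b])))
        out.append(Microsaccade(a / fs * 1000.0, (b - 1) / fs * 1000.0,
                                amp, pv, direction))
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    m = np.asarray(mask, bool).astype(int)
    d = np.diff(np.concatenate([[0], m, [0]]))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def detect_all(eye: list[np.ndarray], fs: float,
               **kw) -> list[list[Microsaccade]]:
    """Detect per trial from raw eye traces (position -> velocity -> events)."""
    out = []
    for trace in eye:
        if trace is None:
            out.append([])
            continue
        v = eye_velocity(trace, fs)
        out.append(detect(v, trace, fs, **kw))
    return out


def msacc_stats(events: list[list[Microsaccade]],
                trial_durations_ms: np.ndarray) -> dict:
    """Amplitude/velocity summaries, occurrence fraction, rate, intervals."""
    amps = np.array([m.amplitude_deg for ev in events for m in ev])
    vels = np.array([m.peak_velocity for ev in events for m in ev])
    n_ev = np.array([len(ev) for ev in events])
    total_s = float(np.sum(trial_durations_ms)) / 1000.0
    ieis = []
    for ev in events:
        on = np.sort([m.onset_ms for m in ev])
        if len(on) > 1:
            ieis.extend(np.diff(on))
    return {
        "n_events": int(n_ev.sum()),
        "amplitude_mean": float(amps.mean()) if amps.size else np.nan,
        "amplitude_sd": float(amps.std(ddof=1)) if amps.size > 1 else np.nan,
        "velocity_mean": float(vels.mean()) if vels.size else np.nan,
        "fraction_trials_with_event": float((n_ev > 0).mean()),
        "rate_hz": float(n_ev.sum() / total_s) if total_s > 0 else 0.0,
        "inter_event_interval_mean_ms": float(np.mean(ieis)) if ieis else np.nan,
    }


def direction_analysis(events: list[list[Microsaccade]],
                       rf_direction_deg: float, n_bins: int = 8,
                       transition_followers: list[np.ndarray] | None = None,
                       follow_window_ms: float = 200.0) -> pd.DataFrame:
    """Direction histogram aligned so the RF direction is 0 degrees.

    Optionally, with per-trial transition times, adds the fraction of
    microsaccades followed by a transition within ``follow_window_ms`` per
    direction bin.
    """
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = np.zeros(n_bins)
    followed = np.zeros(n_bins)
    for i, ev in enumerate(events):
        for m in ev:
            rel = ((m.direction_deg - rf_direction_deg + 180.0) % 360.0) - 180.0
            b = min(int(np.digitize(rel, edges)) - 1, n_bins - 1)
            counts[b] += 1
            if transition_followers is not None:
                tt = np.asarray(transition_followers[i])
                dt = tt - m.onset_ms
                if np.any((dt > 0) & (dt <= follow_window_ms)):
                    followed[b] += 1
    frac = np.divide(followed, counts, out=np.full(n_bins, np.nan),
                     where=counts > 0)
    df = pd.DataFrame({"direction_deg": centers, "count": counts})
    if transition_followers is not None:
        df["fraction_followed"] = frac
    return df


def microsaccade_free_mask(events: list[list[Microsaccade]],
                           windows: np.ndarray) -> np.ndarray:
    """Boolean per trial: True when no microsaccade onset falls inside the
    trial's analysis window (rerun the pipeline on these clean trials)."""
    windows = np.asarray(windows, float)
    mask = np.ones(len(events), dtype=bool)
    for i, ev in enumerate(events):
        lo, hi = windows[i]
        for m in ev:
            if lo <= m.onset_ms < hi:
                mask[i] = False
                break
    if not mask.any():
        warnings.warn("every trial contains a microsaccade in its window",
                      RuntimeWarning)
    return mask
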