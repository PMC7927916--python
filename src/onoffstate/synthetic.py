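"""Ground-truth session generator.

Emulates the statistical structure the analyses assume: two areas x 16
channels of Poisson spike counts driven by a shared 4-state Markov latent
process (both areas' On-Off phases jointly), attention-condition-dependent
transition matrices with a configurable V4-leads-V1 asymmetry, task-event
delays drawn from uniform ranges, reaction times depending on the latent
state at target dimming, pupil baselines correlated with On-epoch
durations, eye traces with injected microsaccades, and laminar LFP-like
signals with state-dependent spectral content and a mid-layer dipole.

Every stochastic draw flows from the master seed through named substreams,
so equal configs reproduce sessions bit for bit.  All generative
parameters and latent ground truth are stored on the bundle's ``meta`` for
scoring downstream estimators.

Default rates echo the ~100 Hz multiunit regime the model targets
(Off 20 spikes/s, On 100 spikes/s); per-bin stay probabilities around
0.95-0.98 give epoch durations of a few hundred ms.  Task delays default
to monkey 1's ranges: fixed 614 ms fixation-to-stimulus delay, cue delay
U(618, 1131) ms, first dimming U(1162, 2133) ms after cue, and further
dimmings U(792, 1331) ms apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (BinnedCounts, LfpArray, SessionBundle, SpikeTrainSet,
                   analysis_window, bin_spikes, make_trial_table)
from .joint import V1_PHASE, V4_PHASE

_STREAMS = {"latent": 0, "counts": 1, "task": 2, "rt": 3, "pupil": 4,
            "eye": 5, "lfp": 6, "rates": 7}


def build_joint_transitions(stay: float = 0.97, lead: float = 0.6,
                            base_leave: float = 0.03,
                            on_bias: float = 0.0) -> np.ndarray:
    """A 4-state transition matrix with a V4-lead asymmetry.

    ``lead`` in [0, 1) skews single-area phase flips so that V4 changes
    first: from state 1 (both Off) the move to state 3 (V4 On) gets
    probability mass (1+lead)/2 of the single-flip budget and the move to
    state 2 gets (1-lead)/2; symmetrically from state 4 (both On) toward
    state 2 (V4 Off first).  ``on_bias`` shifts budget toward On-entering
    transitions (the attend-RF direction).  Rows sum to 1 exactly.
    """
    if not (0 <= lead < 1):
        raise ValueError("lead must be in [0, 1)")
    leave = 1.0 - stay
    P = np.zeros((4, 4))
    single = leave * 0.85
    double = leave * 0.15
    # state 0 (both Off): single flips to 1 (V1 On) or 2 (V4 On)
    up = single * (1 + on_bias)
    P[0, 2] = up * (1 + lead) / 2
    P[0, 1] = up * (1 - lead) / 2
    P[0, 3] = double * (1 + on_bias)
    # state 3 (both On): single flips to 1 (V4 Off) or 2 (V1 Off)
    down = single * (1 - on_bias)
    P[3, 1] = down * (1 + lead) / 2
    P[3, 2] = down * (1 - lead) / 2
    P[3, 0] = double * (1 - on_bias)
    # mixed states relax toward alignment; attention favors the On-aligned exit
    P[1, 3] = single * 0.5 * (1 + on_bias)
    P[1, 0] = single * 0.5 * (1 - on_bias)
    P[1, 2] = double
    P[2, 3] = single * 0.5 * (1 + on_bias)
    P[2, 0] = single * 0.5 * (1 - on_bias)
    P[2, 1] = double
    np.fill_diagonal(P, 0.0)
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    return P


def _default_transitions() -> dict[str, np.ndarray]:
    return {"attend_rf": build_joint_transitions(0.97, 0.6, on_bias=0.25),
            "attend_away1": build_joint_transitions(0.97, 0.6, on_bias=0.0),
            "attend_away2": build_joint_transitions(0.97, 0.6, on_bias=0.0)}


@dataclass
class GenConfig:
    """Generative parameters for one synthetic recording."""

    n_trials: int = 60                      # per condition
    channels_per_area: int = 16
    w_bin: float = 10.0                     # ms
    off_rate: float = 20.0                  # spikes/s
    on_rate: float = 100.0
    rate_jitter: float = 0.15               # lognormal sigma across channels
    transitions: dict[str, np.ndarray] = field(default_factory=_default_transitions)
    pi0: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    fixed_delay: float = 614.0              # fixation -> stimulus, ms
    cue_delay: tuple[float, float] = (618.0, 1131.0)
    dim1_delay: tuple[float, float] = (1162.0, 2133.0)
    interdim_delay: tuple[float, float] = (792.0, 1331.0)
    tail_ms: float = 400.0                  # simulated time past last dimming
    rt_base: float = 350.0                  # ms
    rt_state_offset: tuple[float, ...] = (60.0, 30.0, 15.0, 0.0)
    rt_noise_sd: float = 40.0
    pupil_base: float = 1.0
    pupil_coupling: float = 0.002           # units per ms of mean On duration
    pupil_noise_sd: float = 0.05
    eye_fs: float = 220.0
    eye_noise_sd: float = 0.01              # deg, per-sample white noise
    msacc_rate: float = 0.9                 # Hz
    msacc_amp_mean: float = 0.5             # deg (lognormal median)
    msacc_amp_sigma: float = 0.5
    msacc_duration: float = 20.0            # ms raised-cosine velocity pulse
    msacc_transition_coupling: float = 0.0  # P(force Off->On 60 ms after msacc)
    msacc_coupling_lag: float = 60.0        # ms
    include_eye: bool = True
    include_lfp: bool = False
    lfp_fs: float = 1000.0
    lfp_low_hz: float = 5.0                 # Off-gated band
    lfp_high_hz: float = 60.0               # On-gated band
    lfp_low_amp: float = 1.0
    lfp_high_amp: float = 0.5
    lfp_noise_amp: float = 0.1
    lfp_dipole_channel: int = 7             # mid-layer sink for the CSD check
    lfp_dipole_amp: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        for c, P in self.transitions.items():
            P = np.asarray(P, float)
            if P.shape != (4, 4) or np.any(P < 0) or \
                    not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"condition {c!r}: invalid transition matrix")
        if self.off_rate < 0 or self.on_rate < 0:
            raise ValueError("rates must be non-negative")
        for lo, hi in (self.cue_delay, self.dim1_delay, self.interdim_delay):
            if lo > hi:
                raise ValueError("delay range has low > high")


def _rng(cfg_seed: int, stream: str, *idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg_seed, _STREAMS[stream], *idx]))


def simulate_joint_latent(P4: np.ndarray, pi0: np.ndarray, n_bins: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Sample the joint 4-state Markov chain at bin resolution."""
    P4 = np.asarray(P4, float)
    pi0 = np.asarray(pi0, float)
    if P4.shape != (4, 4) or np.any(P4 < 0) or \
            not np.allclose(P4.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("rows of the transition matrix must sum to 1")
    cumP = P4.cumsum(axis=1)
    path = np.empty(n_bins, dtype=np.int64)
    u = rng.random(n_bins)
    path[0] = np.searchsorted(pi0.cumsum(), u[0], side="right")
    for t in range(1, n_bins):
        path[t] = np.searchsorted(cumP[path[t - 1]], u[t], side="right")
    return path


def simulate_counts(path: np.ndarray, rates_hz: np.ndarray, w_bin: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Poisson counts (n_channels, n_bins) given a latent path.

    ``rates_hz`` is (n_channels, K) in spikes/s; the expected count per bin
    is rate * w_bin / 1000, independent across channels and bins.
    """
    rates_hz = np.asarray(rates_hz, float)
    if np.any(rates_hz < 0):
        raise ValueError("rates must be non-negative")
    lam = rates_hz[:, np.asarray(path)] * (w_bin / 1000.0)
    return rng.poisson(lam)


def _spike_times_from_counts(counts_row: np.ndarray, w_bin: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Uniform spike times within each bin (Poisson process given counts)."""
    n = int(counts_row.sum())
    if n == 0:
        return np.empty(0)
    bins = np.repeat(np.arange(counts_row.size), counts_row)
    return np.sort((bins + rng.random(n)) * w_bin)


def _raised_cosine_pulse(n: int) -> np.ndarray:
    # integral-normalized biphasic would displace then return; we want a net
    # displacement, so use a unimodal raised-cosine velocity profile
    t = np.linspace(0, 1, n, endpoint=False)
    return 0.5 * (1 - np.cos(2 * np.pi * t))


def simulate_session(cfg: GenConfig) -> SessionBundle:
    """Generate one full synthetic recording."""
    cfg.validate()
    cfg_seed = cfg.seed
    conditions = sorted(cfg.transitions)
    n_ch = 2 * cfg.channels_per_area
    areas = np.array(["V1"] * cfg.channels_per_area
                     + ["V4"] * cfg.channels_per_area, dtype=object)

    # per-channel On/Off rates with mild lognormal heterogeneity
    rrng = _rng(cfg_seed, "rates")
    jit = np.exp(rrng.normal(0.0, cfg.rate_jitter, size=n_ch))
    off = cfg.off_rate * jit
    on = cfg.on_rate * jit
    # per-channel rate per joint state, respecting the area's phase
    rates4 = np.empty((n_ch, 4))
    for j in range(n_ch):
        ph = V1_PHASE if areas[j] == "V1" else V4_PHASE
        rates4[j] = np.where(ph == 1, on[j], off[j])

    rows, all_spikes, paths, eye, msacc_truth = [], [], [], [], []
    trial_id = 0
    for cond in conditions:
        P4 = np.asarray(cfg.transitions[cond], float)
        for k in range(cfg.n_trials):
            trng = _rng(cfg_seed, "task", trial_id)
            t_fix = 0.0
            t_stim = t_fix + cfg.fixed_delay
            t_cue = t_stim + trng.uniform(*cfg.cue_delay)
            t_dim1 = t_cue + trng.uniform(*cfg.dim1_delay)
            t_dim2 = t_dim1 + trng.uniform(*cfg.interdim_delay)
            t_dim3 = t_dim2 + trng.uniform(*cfg.interdim_delay)
            target_dim = int(trng.integers(1, 4))
            target_in_rf = bool(trng.random() < 0.5)
            t_end = t_dim3 + cfg.tail_ms
            n_bins = int(np.ceil(t_end / cfg.w_bin))

            lrng = _rng(cfg_seed, "latent", trial_id)
            path = simulate_joint_latent(P4, cfg.pi0, n_bins, lrng)

            # eye trace + microsaccades (before counts: may perturb the path)
            trace = None
            ms_times = np.empty(0)
            ms_amps = []
            if cfg.include_eye:
                erng = _rng(cfg_seed, "eye", trial_id)
                n_s = int(np.round(t_end / 1000.0 * cfg.eye_fs))
                trace = erng.normal(0.0, cfg.eye_noise_sd, size=(2, n_s))
                if cfg.msacc_rate > 0:
                    n_ms = erng.poisson(cfg.msacc_rate * t_end / 1000.0)
                    onsets = np.sort(erng.uniform(0, t_end - 2 * cfg.msacc_duration,
                                                  size=n_ms))
                    # enforce a refractory gap so events stay separable
                    keep = np.ones(n_ms, bool)
                    last = -1e9
                    for i, o in enumerate(onsets):
                        if o - last < 100.0:
                            keep[i] = False
                        else:
                            last = o
                    onsets = onsets[keep]
                    npulse = max(int(cfg.msacc_duration / 1000.0 * cfg.eye_fs), 2)
                    shape = _raised_cosine_pulse(npulse)
                    shape /= shape.sum()
                    ms_amps = []
                    for o in onsets:
                        amp = cfg.msacc_amp_mean * np.exp(
                            erng.normal(0.0, cfg.msacc_amp_sigma))
                        ms_amps.append(amp)
                        ang = erng.uniform(0, 2 * np.pi)
                        i0 = int(o / 1000.0 * cfg.eye_fs)
                        disp = np.cumsum(shape)[:min(npulse, n_s - i0)]
                        trace[0, i0:i0 + len(disp)] += amp * np.cos(ang) * disp
                        trace[0, i0 + len(disp):] += amp * np.cos(ang)
                        trace[1, i0:i0 + len(disp)] += amp * np.sin(ang) * disp
                        trace[1, i0 + len(disp):] += amp * np.sin(ang)
                    ms_times = onsets
                    if cfg.msacc_transition_coupling > 0:
                        crng = _rng(cfg_seed, "eye", trial_id, 1)
                        for o in ms_times:
                            if crng.random() < cfg.msacc_transition_coupling:
                                b = int((o + cfg.msacc_coupling_lag) / cfg.w_bin)
                                if b < n_bins and path[b] != 3:
                                    # force an Off->On flip: jump to both-On
                                    dur = 1 + crng.geometric(0.05)
                                    path[b:min(b + dur, n_bins)] = 3

            crng = _rng(cfg_seed, "counts", trial_id)
            counts = simulate_counts(path, rates4, cfg.w_bin, crng)
            trial_spikes = [_spike_times_from_counts(counts[j], cfg.w_bin, crng)
                            for j in range(n_ch)]

            # reaction time from the latent state at target dimming
            t_target = (t_dim1, t_dim2, t_dim3)[target_dim - 1]
            s_at = int(path[min(int(t_target / cfg.w_bin), n_bins - 1)])
            rtng = _rng(cfg_seed, "rt", trial_id)
            rt = max(cfg.rt_base + cfg.rt_state_offset[s_at]
                     + rtng.normal(0.0, cfg.rt_noise_sd), 0.0)

            # baseline pupil coupled to this trial's mean On-epoch duration
            prng = _rng(cfg_seed, "pupil", trial_id)
            on_mask = V1_PHASE[path] | V4_PHASE[path]
            mean_on = _mean_run_ms(on_mask, cfg.w_bin)
            pupil = (cfg.pupil_base + cfg.pupil_coupling * mean_on
                     + prng.normal(0.0, cfg.pupil_noise_sd))

            rows.append(dict(trial_id=trial_id, condition=cond,
                             t_fixation=t_fix, t_stim_on=t_stim, t_cue=t_cue,
                             t_dim1=t_dim1, t_dim2=t_dim2, t_dim3=t_dim3,
                             target_dim=target_dim, target_in_rf=target_in_rf,
                             rt=rt, pupil_baseline=pupil))
            all_spikes.append(trial_spikes)
            paths.append(path)
            eye.append(trace)
            msacc_truth.append((ms_times, np.asarray(ms_amps)))
            trial_id += 1

    trials = make_trial_table(pd.DataFrame(rows))
    sts = SpikeTrainSet(all_spikes, areas, trials["trial_id"].to_numpy())
    lfp = _simulate_lfp(cfg, paths) if cfg.include_lfp else None
    meta = {
        "seed": cfg_seed,
        "conditions": conditions,
        "w_bin": cfg.w_bin,
        "transitions": {c: np.asarray(P) for c, P in cfg.transitions.items()},
        "pi0": np.asarray(cfg.pi0),
        "rates4": rates4,
        "true_paths": [p for p in paths],
        "msacc_times": [m[0] for m in msacc_truth],
        "msacc_amps": [m[1] for m in msacc_truth],
        "rt_base": cfg.rt_base,
        "rt_state_offset": list(cfg.rt_state_offset),
        "pupil_coupling": cfg.pupil_coupling,
    }
    bundle = SessionBundle(sts, trials, {}, eye if cfg.include_eye else None,
                           cfg.eye_fs, lfp, meta)
    # standard analysis windows, ready-binned
    for wname in ("fixation", "cue_to_dim1"):
        win = analysis_window(trials, wname)
        bundle.counts[wname] = bin_spikes(sts, win, cfg.w_bin)
    return bundle


def _mean_run_ms(on_mask: np.ndarray, w_bin: float) -> float:
    """Mean duration (ms) of runs of 1 in a binary sequence (0 if none)."""
    m = np.asarray(on_mask, bool).astype(int)
    if m.sum() == 0:
        return 0.0
    d = np.diff(np.concatenate([[0], m, [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return float((ends - starts).mean() * w_bin)


def _simulate_lfp(cfg: GenConfig, paths: list[np.ndarray]) -> LfpArray:
    """Laminar LFP surrogate: 1/f background + state-gated bands + a fixed
    mid-layer dipole so the CSD has a known sink."""
    n_lam = cfg.channels_per_area
    data = []
    spacing = 150.0
    depth = spacing * np.arange(n_lam)
    dip = np.exp(-0.5 * ((np.arange(n_lam) - cfg.lfp_dipole_channel) / 1.0) ** 2)
    for i, path in enumerate(paths):
        rng = _rng(cfg.seed, "lfp", i)
        n_samp = int(len(path) * cfg.w_bin / 1000.0 * cfg.lfp_fs)
        t = np.arange(n_samp) / cfg.lfp_fs
        # V1 phase gates the bands (one laminar probe surrogate)
        on = np.repeat(V1_PHASE[path].astype(float),
                       int(cfg.w_bin / 1000.0 * cfg.lfp_fs))[:n_samp]
        lo = cfg.lfp_low_amp * np.sin(2 * np.pi * cfg.lfp_low_hz * t
                                      + rng.uniform(0, 2 * np.pi)) * (1 - on)
        hi = cfg.lfp_high_amp * np.sin(2 * np.pi * cfg.lfp_high_hz * t
                                       + rng.uniform(0, 2 * np.pi)) * on
        # 1/f noise via cumulative sum of white noise (leaky)
        w = rng.normal(0, cfg.lfp_noise_amp, size=(n_lam, n_samp))
        pink = np.empty_like(w)
        pink[:, 0] = w[:, 0]
        a = 0.98
        for s in range(1, n_samp):
            pink[:, s] = a * pink[:, s - 1] + w[:, s]
        v = pink + (lo + hi)[None, :] + cfg.lfp_dipole_amp * np.outer(dip, lo + hi)
        data.append(v)
    return LfpArray(data, cfg.lfp_fs, "raw", depth)
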