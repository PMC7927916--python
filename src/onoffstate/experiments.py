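"""End-to-end validation experiments on synthetic ground truth.

Each function builds a ground-truth scenario with the synthetic generator
(or a direct construction where that is the cleaner oracle), runs the
corresponding pipeline stage, and returns the measured quantities as a
plain dict.  The acceptance tests assert on these dicts; the acceptance
script reports them.  Problem sizes are chosen so the full battery runs
in minutes on one CPU; the methods note records them.

All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from . import coordination, dynamics, joint, microsaccades, signals, validation
from .core import BinnedCounts
from .hmm import HmmParams, em_fit, loglik, viterbi
from .joint import V1_PHASE, V4_PHASE, em_fit_tied
from .synthetic import (GenConfig, build_joint_transitions,
                        simulate_joint_latent, simulate_counts,
                        simulate_session)


def _counts_from_chain(P2, rates_hz, n_trials, T, w_bin, rng,
                       areas=None) -> tuple[BinnedCounts, list[np.ndarray]]:
    """Trials of a K-state chain (uniform start) with Poisson emissions."""
    K = P2.shape[0]
    paths, counts = [], []
    for i in range(n_trials):
        s = simulate_joint_latent(P2, np.full(K, 1.0 / K), T, rng) \
            if K == 4 else _chain(P2, T, rng)
        paths.append(s)
        counts.append(rng.poisson(rates_hz[:, s] * (w_bin / 1000.0)))
    if areas is None:
        areas = np.array(["V1"] * rates_hz.shape[0], dtype=object)
    bc = BinnedCounts(counts, w_bin, np.tile([0.0, T * w_bin], (n_trials, 1)),
                      areas, np.arange(n_trials))
    return bc, paths


def _chain(P, T, rng):
    K = P.shape[0]
    cum = P.cumsum(axis=1)
    s = np.empty(T, dtype=np.int64)
    s[0] = rng.integers(K)
    u = rng.random(T)
    for t in range(1, T):
        s[t] = np.searchsorted(cum[s[t - 1]], u[t])
    return s


# ---------------------------------------------------------------------------
# single-area recovery

def recovery_single_area(seed: int = 0, n_trials: int = 100, T: int = 300,
                         n_ch: int = 16, n_restarts: int = 10) -> dict:
    """Fit the 2-phase model to data from a known 2-phase generator.

    Generator: Off 20 / On 100 spikes/s on every channel, stay
    probabilities 0.97 (Off) and 0.95 (On) per 10 ms bin.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    P_true = np.array([[0.97, 0.03], [0.05, 0.95]])
    rates = np.tile([20.0, 100.0], (n_ch, 1))
    bc, _ = _counts_from_chain(P_true, rates, n_trials, T, 10.0, rng)
    fit = em_fit(bc, K=2, n_restarts=n_restarts,
                 seed=np.random.SeedSequence([seed, 2]))
    P_err = float(np.abs(fit.params.P - P_true).max())
    rate_rel = float(np.abs(fit.params.rates_hz() / rates - 1.0).max())
    return {"transition_max_abs_error": P_err,
            "rate_max_rel_error": rate_rel,
            "loglik_trace_monotone": bool(
                np.all(np.diff(fit.loglik_trace) >= -1e-9)),
            "n": n_trials * T}


def em_k1_closed_form(seed: int = 0) -> dict:
    """K=1 EM must return the per-channel mean count exactly."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    counts = [rng.poisson(0.5, size=(4, 50)) for _ in range(10)]
    bc = BinnedCounts(counts, 10.0, np.tile([0.0, 500.0], (10, 1)),
                      np.array(["V1"] * 4, dtype=object), np.arange(10))
    fit = em_fit(bc, K=1, n_restarts=2, seed=seed)
    err = float(np.abs(fit.params.lam[:, 0] - bc.channel_means()).max())
    return {"k1_rate_error": err, "n": 10 * 50}


# ---------------------------------------------------------------------------
# joint tied model

def recovery_joint(seed: int = 0, n_trials: int = 60, T: int = 200,
                   ch_per_area: int = 8, n_restarts: int = 10) -> dict:
    """Tied 4-state recovery from a V4-lead generator."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    P4 = build_joint_transitions(0.97, 0.6)
    rates4 = _tied_rates(ch_per_area)
    areas = np.array(["V1"] * ch_per_area + ["V4"] * ch_per_area,
                     dtype=object)
    bc, _ = _counts_from_chain(P4, rates4, n_trials, T, 10.0, rng, areas)
    fit = em_fit_tied(bc, n_restarts=n_restarts,
                      seed=np.random.SeedSequence([seed, 5]))
    lam = fit.params.lam
    v1 = slice(0, ch_per_area)
    v4 = slice(ch_per_area, None)
    tie_err = max(np.abs(lam[v1, 0] - lam[v1, 2]).max(),
                  np.abs(lam[v1, 1] - lam[v1, 3]).max(),
                  np.abs(lam[v4, 0] - lam[v4, 1]).max(),
                  np.abs(lam[v4, 2] - lam[v4, 3]).max())
    return {"transition_max_abs_error": float(np.abs(fit.params.P - P4).max()),
            "tied_rate_max_diff": float(tie_err),
            "n": n_trials * T}


def _tied_rates(ch_per_area, off=20.0, on=100.0):
    rates4 = np.empty((2 * ch_per_area, 4))
    for j in range(2 * ch_per_area):
        ph = V1_PHASE if j < ch_per_area else V4_PHASE
        rates4[j] = np.where(ph == 1, on, off)
    return rates4


def v4_lead_auc(seed: int = 0, n_sessions: int = 30, n_trials: int = 30,
                T: int = 150, ch_per_area: int = 8,
                n_restarts: int = 3) -> dict:
    """Decoded-path cross-correlation skew under a V4-lead generator.

    Per session: simulate the V4-lead joint chain, fit the tied model,
    decode, marginalize per area, and compare the area under the shuffle-
    subtracted cross-correlation for negative versus positive lags.
    Negative-lag mass means V4 leads.
    """
    P4 = build_joint_transitions(0.97, 0.6)
    rates4 = _tied_rates(ch_per_area)
    areas = np.array(["V1"] * ch_per_area + ["V4"] * ch_per_area,
                     dtype=object)
    wins = 0
    diffs = []
    for s in range(n_sessions):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 6, s]))
        bc, _ = _counts_from_chain(P4, rates4, n_trials, T, 10.0, rng, areas)
        fit = em_fit_tied(bc, n_restarts=n_restarts,
                          seed=np.random.SeedSequence([seed, 7, s]))
        paths = viterbi(bc, fit.params)
        x = [joint.marginal_path(p, "V1") for p in paths]
        y = [joint.marginal_path(p, "V4") for p in paths]
        cc = coordination.cc_hmm(x, y, max_lag_ms=300.0)
        cc.shuffle = coordination.shuffle_predictor(
            x, y, max_lag_ms=300.0, n_shuffles=20, seed=seed + s)
        a_neg, a_pos, d = coordination.auc_split(cc)
        diffs.append(d)
        if a_neg > a_pos:
            wins += 1
    p_sign = stats.binomtest(wins, n_sessions, 0.5,
                             alternative="greater").pvalue
    return {"sessions_v4_leading": wins, "n_sessions": n_sessions,
            "sign_test_p": float(p_sign),
            "mean_auc_diff": float(np.mean(diffs)), "n": n_sessions}


# ---------------------------------------------------------------------------
# model selection

def model_selection(seed: int = 0, n_recordings: int = 50, n_trials: int = 24,
                    T: int = 100, n_ch: int = 8, k_max: int = 3,
                    n_folds: int = 2, n_restarts: int = 2) -> dict:
    """Elbow-rule selection on 2-phase and homogeneous-Poisson recordings."""
    P_true = np.array([[0.97, 0.03], [0.05, 0.95]])
    rates2 = np.tile([20.0, 100.0], (n_ch, 1))
    rates1 = np.tile([60.0, 60.0], (n_ch, 1))
    hit2 = 0
    false2 = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for r in range(n_recordings):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 8, r]))
            bc, _ = _counts_from_chain(P_true, rates2, n_trials, T, 10.0, rng)
            rep = validation.cv_curve(bc, k_max, n_folds, seed=seed + r,
                                      n_restarts=n_restarts)
            if rep.selected_k == 2 and rep.included:
                hit2 += 1
            rng = np.random.default_rng(np.random.SeedSequence([seed, 9, r]))
            bc, _ = _counts_from_chain(np.array([[1.0]]), rates1[:, :1],
                                       n_trials, T, 10.0, rng)
            rep = validation.cv_curve(bc, k_max, n_folds, seed=seed + r,
                                      n_restarts=n_restarts)
            if rep.selected_k != 1:
                false2 += 1
    return {"two_phase_detected": hit2, "n_two_phase": n_recordings,
            "false_multiphase": false2, "n_homogeneous": n_recordings,
            "n": n_recordings}


# ---------------------------------------------------------------------------
# variance explained

def variance_explained(seed: int = 0, n_trials: int = 60, T: int = 200,
                       n_ch: int = 16) -> dict:
    """Cross-validated R^2 against the Fano-factor ceiling Rmax^2 at the
    50 ms integration window, on strongly separated synthetic data."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    # latent chain at 1 ms resolution (per-ms stay prob = per-bin**0.1), so
    # transitions straddle count bins as they do in real data
    P_ms = np.array([[0.97 ** 0.1, 1 - 0.97 ** 0.1],
                     [1 - 0.95 ** 0.1, 0.95 ** 0.1]])
    rates = np.tile([20.0, 100.0], (n_ch, 1))
    counts = []
    for _ in range(n_trials):
        s_ms = _chain(P_ms, T * 10, rng)
        # slow multiplicative excitability drift within states (as in real
        # populations) keeps R^2 strictly below the Poisson ceiling
        gain = np.exp(rng.normal(0.0, 0.10))
        lam_ms = gain * rates[:, s_ms] * 1e-3
        c_ms = rng.poisson(lam_ms)
        counts.append(c_ms.reshape(n_ch, T, 10).sum(axis=2))
    bc = BinnedCounts(counts, 10.0, np.tile([0.0, T * 10.0], (n_trials, 1)),
                      np.array(["V1"] * n_ch, dtype=object),
                      np.arange(n_trials))
    rep = validation.r2_explained(bc, n_folds=2, seed=seed, n_restarts=5,
                                  windows_ms=np.array([50.0]))
    r2 = float(np.nanmean(rep.r2_by_window[0]))
    rm = float(np.nanmean(rep.rmax2_by_window[0]))
    return {"r2_at_50ms": r2, "rmax2_at_50ms": rm,
            "ratio": r2 / rm, "n": n_trials * T}


# ---------------------------------------------------------------------------
# shuffle predictor

def shuffle_predictor_check(seed: int = 0, n_trials: int = 500,
                            T: int = 150) -> dict:
    """Independence and common-signal removal for the shuffle predictor.

    Two independent 2-state chains: after shuffle subtraction the CC must
    be statistically flat (|mean| < 3 SE at every lag).  Then an
    event-locked square pulse is injected into both series: the raw CC
    acquires a peak, which subtraction must remove.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    P2 = np.array([[0.97, 0.03], [0.05, 0.95]])
    x = [_chain(P2, T, rng) for _ in range(n_trials)]
    y = [_chain(P2, T, rng) for _ in range(n_trials)]
    cc = coordination.cc_hmm(x, y, max_lag_ms=300.0)
    sh = coordination.shuffle_predictor(x, y, max_lag_ms=300.0,
                                        n_shuffles=50, seed=seed)
    # per-trial values to get the SE of the mean at each lag
    per_trial = [coordination._xcorr_one(np.asarray(a, float),
                                         np.asarray(b, float), 30)
                 for a, b in zip(x, y)]
    per_trial = np.array([v for v in per_trial if v is not None])
    se = per_trial.std(axis=0, ddof=1) / np.sqrt(n_trials)
    zmax = float(np.max(np.abs(cc.values - sh) / se))
    # event-locked common signal: a pulse in the middle of every trial
    xc = [np.asarray(a, float).copy() for a in x]
    yc = [np.asarray(b, float).copy() for b in y]
    for a, b in zip(xc, yc):
        a[60:80] += 1.0
        b[60:80] += 1.0
    ccc = coordination.cc_hmm(xc, yc, max_lag_ms=300.0)
    shc = coordination.shuffle_predictor(xc, yc, max_lag_ms=300.0,
                                         n_shuffles=50, seed=seed)
    mid = len(ccc.values) // 2
    raw_peak = float(ccc.values[mid])
    corr_peak = float((ccc.values - shc)[mid])
    return {"max_abs_z": zmax, "raw_common_peak": raw_peak,
            "corrected_common_peak": corr_peak, "n": n_trials}


# ---------------------------------------------------------------------------
# transition-triggered average

def two_line_recovery(seed: int = 0, n_rep: int = 200,
                      kink_ms: float = -20.0, step: float = 1.0,
                      noise_frac: float = 0.10) -> dict:
    """Crossing-point recovery on noisy piecewise-linear traces.

    The trace mimics a transition-aligned rate rise: flat baseline, then a
    linear rise completing the ``step`` (the Off-to-On rate change, in
    counts/bin) within 30 ms of the kink, sampled at 10 ms bins over a
    +/- 150 ms window.  Noise SD is 10% of the step.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    t = np.arange(-150.0, 160.0, 10.0)
    slope = step / 30.0
    hits = 0
    for _ in range(n_rep):
        y = np.where(t < kink_ms, 0.0, (t - kink_ms) * slope)
        y = y + rng.normal(0, noise_frac * step, size=len(t))
        c = coordination.two_line_crossing(t, y)
        if c is not None and abs(c - kink_ms) <= 10.0:
            hits += 1
    return {"within_one_bin": hits, "n_rep": n_rep,
            "fraction": hits / n_rep, "n": n_rep}


def _lagged_paths(seed, n_trials, T, lag_range_ms=(20.0, 80.0),
                  w_bin=10.0):
    """V4 2-state chains; V1 repeats each V4 phase sequence after a
    per-trial lag.

    A first-order joint Markov chain cannot express a conduction delay
    (the follower's hazard is memoryless, so its mean rate starts moving
    the moment the leader flips); an explicit lag is the generative
    structure behind a nonzero transition-onset asymmetry.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    P2 = np.array([[0.985, 0.015], [0.02, 0.98]])
    v4_paths, v1_paths = [], []
    for _ in range(n_trials):
        v4 = _chain(P2, T, rng)
        lag_bins = int(round(rng.uniform(*lag_range_ms) / w_bin))
        v1 = np.concatenate([np.full(lag_bins, v4[0]), v4[:T - lag_bins]])
        v4_paths.append(v4)
        v1_paths.append(v1)
    return v1_paths, v4_paths


def tta_lead_asymmetry(seed: int = 0, n_trials: int = 200, T: int = 400,
                       ch_per_area: int = 8) -> dict:
    """TTA crossing times when V1 follows V4 with a 20-80 ms lag.

    V1 rates aligned to V4 transitions should change after the transition
    (positive crossing); V4 rates aligned to V1 transitions should change
    before it (negative crossing).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20]))
    v1_paths, v4_paths = _lagged_paths(seed, n_trials, T)
    rates = np.tile([20.0, 100.0], (ch_per_area, 1))
    w = 10.0
    v1_counts = [rng.poisson(rates[:, p] * (w / 1000.0)) for p in v1_paths]
    v4_counts = [rng.poisson(rates[:, p] * (w / 1000.0)) for p in v4_paths]
    wins = np.tile([0.0, T * w], (n_trials, 1))

    def trans_times(paths):
        up = [dynamics.transitions_of(p, "off_to_on", w) for p in paths]
        both = [np.sort(np.concatenate(
            [dynamics.transitions_of(p, "off_to_on", w),
             dynamics.transitions_of(p, "on_to_off", w)])) for p in paths]
        return up, both

    v4_up, v4_all = trans_times(v4_paths)
    v1_up, v1_all = trans_times(v1_paths)
    # +/-80 ms window: the 20-80 ms lag distribution fills it without a
    # saturated plateau, which the two-line model cannot represent
    t_v1_on_v4 = coordination.tta(v1_counts, wins, v4_up, v4_all,
                                  half_width_ms=80.0, n_shuffles=20,
                                  seed=seed)
    t_v4_on_v1 = coordination.tta(v4_counts, wins, v1_up, v1_all,
                                  half_width_ms=80.0, n_shuffles=20,
                                  seed=seed + 1)
    return {"crossing_v1_aligned_to_v4_ms": t_v1_on_v4.crossing_ms,
            "crossing_v4_aligned_to_v1_ms": t_v4_on_v1.crossing_ms,
            "n_transitions": t_v1_on_v4.n_transitions, "n": n_trials}


# ---------------------------------------------------------------------------
# microsaccades

def microsaccade_detection(seed: int = 0, n_trials: int = 200,
                           dur_ms: float = 2000.0, rate_hz: float = 0.9,
                           min_amp: float = 0.3) -> dict:
    """Detector recall and false alarms on injected events >= min_amp deg."""
    cfg = GenConfig(n_trials=n_trials, seed=seed + 14,
                    transitions={"attend_rf": build_joint_transitions()},
                    msacc_rate=rate_hz, msacc_amp_mean=0.5,
                    msacc_amp_sigma=0.3, include_eye=True)
    bundle = simulate_session(cfg)
    events = microsaccades.detect_all(bundle.eye, cfg.eye_fs)
    # the 20 Hz zero-phase filter spreads the 20 ms velocity pulse by
    # roughly +/- 25 ms, so detected onsets lead injected ones; 60 ms
    # covers that spread without reaching the 100 ms injection refractory
    tol = 60.0
    n_true = n_hit = n_fa = 0
    for ev, truth, amps in zip(events, bundle.meta["msacc_times"],
                               bundle.meta["msacc_amps"]):
        truth = np.asarray(truth)
        amps = np.asarray(amps)
        det = np.array([m.onset_ms for m in ev])
        used = np.zeros(len(det), bool)
        for t, a in zip(truth, amps):
            big = a >= min_amp
            n_true += int(big)
            if len(det):
                d = np.abs(det - t)
                j = int(np.argmin(d))
                if d[j] <= tol and not used[j]:
                    used[j] = True
                    n_hit += int(big)
        n_fa += int((~used).sum())
    return {"recall": n_hit / max(n_true, 1),
            "false_alarms_per_trial": n_fa / len(events),
            "n_true_events": n_true, "n": n_trials}


def microsaccade_transition_coupling(seed: int = 0, n_trials: int = 150,
                                     lag_ms: float = 60.0) -> dict:
    """Recover an injected event->Off-to-On coupling at +60 ms with the
    per-event transition cross-correlogram."""
    cfg = GenConfig(n_trials=n_trials, seed=seed + 15,
                    transitions={"attend_rf": build_joint_transitions()},
                    msacc_rate=0.9, msacc_transition_coupling=0.6,
                    msacc_coupling_lag=lag_ms)
    bundle = simulate_session(cfg)
    paths = bundle.meta["true_paths"]
    trans, ms = [], []
    for p, m in zip(paths, bundle.meta["msacc_times"]):
        on = (V1_PHASE[np.asarray(p, int)] | V4_PHASE[np.asarray(p, int)])
        trans.append(dynamics.transitions_of(on, "off_to_on", 10.0))
        ms.append(np.asarray(m))
    cc = coordination.cc_events(trans, ms, max_lag_ms=300.0, bin_ms=20.0,
                                n_shuffles=20, seed=seed)
    corrected = cc.corrected
    peak_lag = float(cc.lags_ms[int(np.argmax(corrected))])
    return {"peak_lag_ms": peak_lag,
            "peak_height": float(corrected.max()), "n": n_trials}


# ---------------------------------------------------------------------------
# behavior

def rt_state_ordering(seed: int = 0, n_sessions: int = 30,
                      n_trials: int = 40) -> dict:
    """Mean RT per joint state under generator offsets ordered
    state1 > state2 > state3 > state4 (both-Off slowest)."""
    on_faster = 0
    orderings = 0
    mean_rts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for s in range(n_sessions):
            cfg = GenConfig(
                n_trials=n_trials, seed=seed * 1000 + 16 + s,
                transitions={"attend_rf": build_joint_transitions()},
                rt_state_offset=(60.0, 30.0, 15.0, 0.0),
                include_eye=False, msacc_rate=0.0)
            bundle = simulate_session(cfg)
            # decode the full-trial paths with the true tied parameters
            full = _full_trial_counts(bundle, cfg)
            params = _true_params(bundle, cfg)
            paths = viterbi(full, params)
            wins = np.zeros((len(paths), 2))
            wins[:, 1] = [len(p) * cfg.w_bin for p in paths]
            table = dynamics.rt_by_state(bundle.trials, paths, wins,
                                         cfg.w_bin)
            m = table.groupby("state")["rt"].mean()
            if len(m) == 4:
                mean_rts.append(m.to_numpy())
                if np.all(np.diff(m.to_numpy()) < 0):
                    orderings += 1
            on2 = table.assign(on=(table["state"] > 0).astype(int))
            g = on2.groupby("on")["rt"].mean()
            if len(g) == 2 and g[1] < g[0]:
                on_faster += 1
    p_sign = stats.binomtest(on_faster, n_sessions, 0.5,
                             alternative="greater").pvalue
    return {"sessions_on_faster": on_faster, "n_sessions": n_sessions,
            "sign_test_p": float(p_sign),
            "monotone_orderings": orderings,
            "mean_rt_per_state": (np.mean(mean_rts, axis=0).tolist()
                                  if mean_rts else None), "n": n_sessions}


def _full_trial_counts(bundle, cfg) -> BinnedCounts:
    wins = np.array([[0.0, len(p) * cfg.w_bin]
                     for p in bundle.meta["true_paths"]])
    from .core import bin_spikes
    return bin_spikes(bundle.spikes, wins, cfg.w_bin)


def _true_params(bundle, cfg) -> HmmParams:
    rates4 = np.asarray(bundle.meta["rates4"], float)
    P4 = np.asarray(bundle.meta["transitions"]["attend_rf"], float)
    return HmmParams(np.full(4, 0.25), P4, rates4 * (cfg.w_bin / 1000.0),
                     cfg.w_bin)


# ---------------------------------------------------------------------------
# rate matching

def rate_matching(seed: int = 0, n_trials: int = 600, T: int = 300,
                  n_ch: int = 8) -> dict:
    """Thinning equalizes condition means, never raises a bin count, and a
    generator-built On-duration attention effect survives re-fitting."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    P_rf = np.array([[0.96, 0.04], [0.02, 0.98]])    # longer On epochs
    P_aw = np.array([[0.97, 0.03], [0.05, 0.95]])
    rates_rf = np.tile([25.0, 110.0], (n_ch, 1))     # higher rates too
    rates_aw = np.tile([20.0, 100.0], (n_ch, 1))
    bc_rf, _ = _counts_from_chain(P_rf, rates_rf, n_trials, T, 10.0, rng)
    bc_aw, _ = _counts_from_chain(P_aw, rates_aw, n_trials, T, 10.0, rng)
    matched = dynamics.rate_match({"attend_rf": bc_rf, "attend_away1": bc_aw},
                                  seed=seed)
    m_rf = matched["attend_rf"].channel_means()
    m_aw = matched["attend_away1"].channel_means()
    rel = float(np.abs(m_rf / m_aw - 1.0).max())
    monotone = all(
        np.all(a <= b) for a, b in zip(matched["attend_rf"].counts,
                                       bc_rf.counts))
    durs = {}
    for cond, bcm in matched.items():
        fit = em_fit(bcm, K=2, n_restarts=3,
                     seed=np.random.SeedSequence([seed, 18]))
        paths = viterbi(bcm, fit.params)
        d = [dynamics.mean_epoch_duration(
            dynamics.epochs_from_path(p, 10.0), phase=1) for p in paths]
        durs[cond] = float(np.nanmean(d))
    return {"post_match_max_rel_diff": rel,
            "counts_monotone": bool(monotone),
            "on_duration_attend_rf_ms": durs["attend_rf"],
            "on_duration_attend_away_ms": durs["attend_away1"],
            "effect_survives": durs["attend_rf"] > durs["attend_away1"],
            "n": n_trials * T}


# ---------------------------------------------------------------------------
# pupil

def pupil_coupling_recovery(seed: int = 0, n_sessions: int = 30,
                            n_trials: int = 60) -> dict:
    """Positive generator pupil coupling -> positive per-recording r."""
    rs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for s in range(n_sessions):
            cfg = GenConfig(
                n_trials=n_trials, seed=seed * 1000 + 19 + s,
                transitions={"attend_rf": build_joint_transitions()},
                pupil_coupling=0.002, include_eye=False, msacc_rate=0.0)
            bundle = simulate_session(cfg)
            paths = [np.asarray(p, int) for p in bundle.meta["true_paths"]]
            on_of_state = (V1_PHASE | V4_PHASE)
            r, _ = dynamics.pupil_coupling(
                bundle.trials["pupil_baseline"].to_numpy(), paths,
                w_bin=10.0, phase=1, on_of_state=on_of_state)
            if np.isfinite(r):
                rs.append(r)
    pos = int(np.sum(np.asarray(rs) > 0))
    p_sign = stats.binomtest(pos, len(rs), 0.5, alternative="greater").pvalue
    return {"mean_r": float(np.mean(rs)), "positive_sessions": pos,
            "n_sessions": len(rs), "sign_test_p": float(p_sign),
            "n": n_sessions}
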