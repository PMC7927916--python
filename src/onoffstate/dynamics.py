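"""Phase-level statistics of decoded On-Off dynamics.

Epoch durations, occupancy, attention modulation indices, time-resolved
transition densities, the rate-matching control, pupil coupling and the
state-at-dimming reaction-time tables.  Window-edge (censored) epochs are
excluded from duration statistics but included in occupancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinnedCounts


@dataclass
class Epoch:
    phase: int
    start: float        # ms, window-relative unless offset given
    end: float
    censored_left: bool
    censored_right: bool

    @property
    def duration(self) -> float:
        return self.end - self.start


def epochs_from_path(path: np.ndarray, w_bin: float = 10.0,
                     offset: float = 0.0) -> list[Epoch]:
    """Maximal constant-phase runs of a decoded path.

    The first and last runs touch the analysis-window edges and are flagged
    censored; their durations underestimate the true epoch lengths.
    """
    path = np.asarray(path)
    if path.size == 0:
        return []
    change = np.flatnonzero(np.diff(path) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [path.size]])
    out = []
    for i, (a, b) in enumerate(zip(starts, ends)):
        out.append(Epoch(int(path[a]), offset + a * w_bin, offset + b * w_bin,
                         i == 0, i == len(starts) - 1))
    return out


def mean_epoch_duration(epochs: list[Epoch], phase: int | None = None,
                        include_censored: bool = False) -> float:
    """Mean duration (ms) of (uncensored, by default) epochs."""
    durs = [e.duration for e in epochs
            if (phase is None or e.phase == phase)
            and (include_censored or not (e.censored_left or e.censored_right))]
    return float(np.mean(durs)) if durs else np.nan


def occupancy(path: np.ndarray, K: int = 2) -> np.ndarray:
    """Fraction of time per phase (equals duration-weighted epoch shares)."""
    path = np.asarray(path)
    if path.size == 0:
        raise ValueError("empty path")
    return np.bincount(path, minlength=K) / path.size


def att_mi(a_rf: float, a_out: float) -> float:
    """Attention modulation index (A_RF - A_out) / (A_RF + A_out)."""
    if a_rf < 0 or a_out < 0:
        raise ValueError("inputs must be non-negative")
    tot = a_rf + a_out
    if tot == 0:
        return np.nan
    return (a_rf - a_out) / tot


def transitions_of(path: np.ndarray, direction: str = "off_to_on",
                   w_bin: float = 10.0, offset: float = 0.0,
                   on_of_state=None) -> np.ndarray:
    """Transition times (ms) of a given direction in a decoded path.

    The transition time is the start of the first bin of the new phase.
    For joint 4-state paths pass ``on_of_state`` mapping state -> 0/1 for
    the area of interest.
    """
    path = np.asarray(path)
    binary = path if on_of_state is None else np.asarray(on_of_state)[path]
    d = np.diff(binary)
    if direction == "off_to_on":
        idx = np.flatnonzero(d > 0) + 1
    elif direction == "on_to_off":
        idx = np.flatnonzero(d < 0) + 1
    else:
        raise ValueError("direction must be 'off_to_on' or 'on_to_off'")
    return offset + idx * w_bin


def transition_pdf(paths: list[np.ndarray], align_times: np.ndarray,
                   direction: str = "off_to_on", w: float = 100.0,
                   w_bin: float = 10.0, t_range: tuple[float, float] = (0.0, 2000.0),
                   offsets: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Time-resolved transition density aligned to a task event.

    Counts transitions in bins of width ``w`` ms relative to each trial's
    ``align_time`` and normalizes per second and per trial:
    v_t = c_t / (w * n_trials), in transitions / s / trial.
    Returns (bin_centers_ms, density).
    """
    if len(paths) == 0:
        raise ValueError("no trials")
    if offsets is None:
        offsets = np.zeros(len(paths))
    edges = np.arange(t_range[0], t_range[1] + w, w)
    c = np.zeros(len(edges) - 1)
    for path, t0, off in zip(paths, align_times, offsets):
        tt = transitions_of(path, direction, w_bin, off) - t0
        c += np.histogram(tt, bins=edges)[0]
    v = c / (w / 1000.0) / len(paths)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, v


def transition_pdf_attmi(v_rf: np.ndarray, v_out: np.ndarray) -> np.ndarray:
    """Per-bin attention modulation index between two transition densities."""
    out = np.full(len(v_rf), np.nan)
    for i, (a, b) in enumerate(zip(v_rf, v_out)):
        if a + b > 0:
            out[i] = att_mi(a, b)
    return out


def rate_match(counts_by_condition: dict[str, BinnedCounts],
               seed: int = 0) -> dict[str, BinnedCounts]:
    """Equate trial-averaged rates across conditions by random spike deletion.

    Per channel, the target rate is the lowest condition mean; conditions
    above it have each spike deleted independently with probability
    1 - target/current (binomial thinning, which preserves Poissonness).
    Zero-rate channels are left untouched.  Thinned counts never exceed the
    originals bin-wise.
    """
    if len(counts_by_condition) < 2:
        raise ValueError("need at least 2 conditions")
    conds = sorted(counts_by_condition)
    means = {c: counts_by_condition[c].channel_means() for c in conds}
    target = np.min([means[c] for c in conds], axis=0)
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    out = {}
    for c in conds:
        bc = counts_by_condition[c]
        cur = means[c]
        keep_p = np.where(cur > 0, target / np.where(cur > 0, cur, 1.0), 1.0)
        new_counts = []
        for trial in bc.counts:
            thin = rng.binomial(trial, keep_p[:, None])
            new_counts.append(thin)
        out[c] = BinnedCounts(new_counts, bc.w_bin, bc.windows.copy(),
                              bc.areas.copy(), bc.trial_ids.copy())
    return out


def pupil_coupling(pupil: np.ndarray, paths: list[np.ndarray],
                   w_bin: float = 10.0, phase: int = 1,
                   on_of_state=None) -> tuple[float, float]:
    """Pearson correlation of baseline pupil with per-trial mean epoch
    duration of one phase (or joint state).

    Trials without an uncensored epoch of the phase, or without a pupil
    value, are skipped.  Returns (r, p); (nan, nan) when undefined.
    """
    durs, pup = [], []
    for p_t, path in zip(pupil, paths):
        if not np.isfinite(p_t):
            continue
        use = path if on_of_state is None else np.asarray(on_of_state)[path]
        eps = epochs_from_path(use, w_bin)
        d = mean_epoch_duration(eps, phase)
        if np.isfinite(d):
            durs.append(d)
            pup.append(p_t)
    if len(durs) < 3 or np.std(pup) == 0 or np.std(durs) == 0:
        return (np.nan, np.nan)
    r, p = stats.pearsonr(pup, durs)
    return float(r), float(p)


def state_at_event(path: np.ndarray, event_ms: float, window: np.ndarray,
                   w_bin: float = 10.0, trial_id=None) -> int:
    """Phase of the bin containing an event time (half-open bins).

    An event exactly at a bin edge belongs to the bin starting there.
    """
    start, end = window
    b = int(np.floor((event_ms - start) / w_bin))
    if event_ms < start or b >= len(path):
        raise ValueError(f"event at {event_ms} ms outside decoded window "
                         f"[{start}, {start + len(path) * w_bin}) "
                         f"(trial {trial_id})")
    return int(path[b])


def rt_by_state(trials: pd.DataFrame, paths: list[np.ndarray],
                windows: np.ndarray, w_bin: float = 10.0,
                on_of_state=None) -> pd.DataFrame:
    """Tidy table of (condition, state at target dimming, RT) per trial.

    Only trials with the target inside the RFs and a recorded reaction
    time qualify; trials whose dimming falls outside the decoded window
    are dropped.  The result feeds a standard mixed-effects fit
    (RT ~ attention * state with recording intercepts), which is delegated
    to general statistics packages.
    """
    rows = []
    for i, (_, tr) in enumerate(trials.iterrows()):
        if not tr["target_in_rf"] or not np.isfinite(tr["rt"]):
            continue
        t_dim = tr[f"t_dim{int(tr['target_dim'])}"]
        try:
            s = state_at_event(paths[i], t_dim, windows[i], w_bin,
                               tr["trial_id"])
        except ValueError:
            continue
        state = s if on_of_state is None else int(np.asarray(on_of_state)[s])
        rows.append(dict(trial_id=tr["trial_id"], condition=tr["condition"],
                         state=state, rt=tr["rt"]))
    if not rows:
        warnings.warn("no qualifying trials for the RT table", RuntimeWarning)
        return pd.DataFrame(columns=["trial_id", "condition", "state", "rt"])
    return pd.DataFrame(rows)


def mean_rt_per_state(table: pd.DataFrame) -> pd.DataFrame:
    """Per (condition, state) mean RT, the recording-level summary used for
    nonparametric comparisons across recordings."""
    if table.empty:
        return pd.DataFrame(columns=["condition", "state", "rt", "n"])
    g = table.groupby(["condition", "state"])["rt"]
    return g.agg(rt="mean", n="count").reset_index()
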