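"""Joint two-area 4-state HMM with tied emission rates.

The joint state enumerates both areas' phases in the canonical order
state 1 = V1off-V4off, 2 = V1on-V4off, 3 = V1off-V4on, 4 = V1on-V4on
(0-indexed 0..3 internally).  Each channel belongs to one area, so its
emission rate is constrained to be equal across the two joint states in
which its own area is in the same phase: V1 channels are tied across
states {1,3} and {2,4}, V4 channels across {1,2} and {3,4}.  The tied
M-step pools expected counts and occupancies over each tied pair, which is
the exact maximizer under the equality constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import BinnedCounts
from .hmm import HmmFit, HmmParams, em_fit, viterbi

# phase of each area in canonical joint states (0=Off, 1=On)
V1_PHASE = np.array([0, 1, 0, 1])
V4_PHASE = np.array([0, 0, 1, 1])
STATE_NAMES = ("V1off-V4off", "V1on-V4off", "V1off-V4on", "V1on-V4on")


def tying_map(areas: np.ndarray, area_x: str = "V1",
              area_y: str = "V4") -> np.ndarray:
    """Per-channel group labels over the 4 joint states.

    Returns (n_channels, 4) ints; states with equal label share one emission
    rate for that channel (each channel's groups partition the 4 states into
    two pairs).
    """
    areas = np.asarray(areas, dtype=object)
    groups = np.empty((len(areas), 4), dtype=np.int64)
    for j, a in enumerate(areas):
        if a == area_x:
            groups[j] = V1_PHASE
        elif a == area_y:
            groups[j] = V4_PHASE
        else:
            raise ValueError(f"channel {j}: unknown area {a!r}")
    return groups


def em_fit_tied(counts: BinnedCounts, n_restarts: int = 10,
                seed: int | np.random.SeedSequence = 0,
                area_x: str = "V1", area_y: str = "V4",
                max_iter: int = 500) -> HmmFit:
    """Fit the tied 4-state model to both areas' counts simultaneously.

    Same EM as the single-area model except that emission initialization
    makes one draw per tied group and the M-step pools over tied states.
    The returned fit is canonicalized to the state order above.
    """
    groups = tying_map(counts.areas, area_x, area_y)
    fit = em_fit(counts, K=4, n_restarts=n_restarts, seed=seed,
                 max_iter=max_iter, lam_groups=groups, canonicalize=False)
    return canonicalize_states(fit, counts.areas, area_x, area_y)


def canonicalize_states(fit: HmmFit, areas: np.ndarray,
                        area_x: str = "V1", area_y: str = "V4") -> HmmFit:
    """Permute an arbitrary tied 4-state labeling onto the canonical order.

    Each area's On phase is its higher mean-rate phase.  With ties enforced
    every channel takes exactly two rate values across states; the state
    whose (V1 phase, V4 phase) pair is (a, b) maps to canonical index
    a + 2b.  Exact rate ties break deterministically toward the original
    state index and raise a flag in ``fit.info``.
    """
    areas = np.asarray(areas, dtype=object)
    lam = fit.params.lam
    if lam.shape[1] != 4:
        raise ValueError("canonicalize_states expects a 4-state fit")
    jx = np.flatnonzero(areas == area_x)
    jy = np.flatnonzero(areas == area_y)
    if len(jx) == 0 or len(jy) == 0:
        raise ValueError("both areas must have channels")
    mx = lam[jx].mean(axis=0)   # area-x population rate per state
    my = lam[jy].mean(axis=0)
    degenerate = False
    phase = np.empty((4, 2), dtype=int)
    for means, col in ((mx, 0), (my, 1)):
        med = (means.min() + means.max()) / 2.0
        on = means > med
        if means.min() == means.max():
            degenerate = True
            on = np.array([False, True, False, True]) if col == 0 else \
                 np.array([False, False, True, True])
        elif on.sum() != 2:
            # tie at the median: assign the two largest as On, stable order
            order = np.argsort(means, kind="stable")
            on = np.zeros(4, bool)
            on[order[2:]] = True
            degenerate = True
        phase[:, col] = on.astype(int)
    canon = phase[:, 0] + 2 * phase[:, 1]
    if sorted(canon) != [0, 1, 2, 3]:
        raise ValueError("tying violated: states do not span all four "
                         "phase combinations")
    order = np.argsort(canon, kind="stable")
    out = HmmFit(fit.params.permuted(order), fit.loglik, fit.loglik_trace,
                 fit.converged, fit.n_iter, fit.restart,
                 fit.restart_logliks, dict(fit.info))
    out.info["state_order"] = order
    if degenerate:
        warnings.warn("ambiguous On/Off rates; tie broken by state index",
                      RuntimeWarning)
        out.info["degenerate_rates"] = True
    return out


@dataclass
class JointSummary:
    """Per-condition 4x4 transition matrices, occupancies and contrasts."""

    P: dict[str, np.ndarray]
    occupancy: dict[str, np.ndarray]
    contrasts: dict[str, dict[str, float]]
    attention_diff_P: np.ndarray | None = None
    attention_diff_occupancy: np.ndarray | None = None


def scenario_contrasts(P: np.ndarray) -> dict[str, float]:
    """Which area leaves a shared phase first, from the fitted transitions.

    Yellow scenario (both Off): P(1->3) - P(1->2) > 0 means the V4 phase
    flips On first.  Purple scenario (both On): P(4->2) - P(4->3) > 0 means
    the V4 phase flips Off first.
    """
    P = np.asarray(P, float)
    return {"yellow": float(P[0, 2] - P[0, 1]),
            "purple": float(P[3, 1] - P[3, 2])}


def time_in_states(paths: list[np.ndarray], K: int = 4) -> np.ndarray:
    """Occupancy fraction per state over all analyzed bins."""
    if not paths or sum(len(p) for p in paths) == 0:
        raise ValueError("no decoded bins")
    allbins = np.concatenate(paths)
    return np.bincount(allbins, minlength=K) / allbins.size


def summarize(fits: dict[str, HmmFit], paths: dict[str, list[np.ndarray]],
              attend_rf: str = "attend_rf") -> JointSummary:
    """Transition matrices, occupancies, scenario contrasts and the
    attend-RF minus attend-away difference matrices."""
    P = {c: f.params.P.copy() for c, f in fits.items()}
    occ = {c: time_in_states(paths[c]) for c in fits}
    contrasts = {c: scenario_contrasts(P[c]) for c in fits}
    away = [c for c in fits if c != attend_rf]
    dP = docc = None
    if attend_rf in fits and away:
        P_away = np.mean([P[c] for c in away], axis=0)
        occ_away = np.mean([occ[c] for c in away], axis=0)
        dP = P[attend_rf] - P_away
        docc = occ[attend_rf] - occ_away
    return JointSummary(P, occ, contrasts, dP, docc)


def marginal_path(path: np.ndarray, area: str,
                  area_x: str = "V1", area_y: str = "V4") -> np.ndarray:
    """Project a joint 4-state path onto one area's 2-phase path."""
    table = V1_PHASE if area == area_x else V4_PHASE
    return table[np.asarray(path)]


def kronecker_product_transitions(Px: np.ndarray, Py: np.ndarray) -> np.ndarray:
    """Joint transition matrix of two independent area chains, in the
    canonical state order (x phase varies fastest)."""
    Px = np.asarray(Px, float)
    Py = np.asarray(Py, float)
    P4 = np.empty((4, 4))
    for s in range(4):
        for t in range(4):
            P4[s, t] = (Px[V1_PHASE[s], V1_PHASE[t]]
                        * Py[V4_PHASE[s], V4_PHASE[t]])
    return P4


def fit_all_joint(counts: BinnedCounts, conditions: np.ndarray,
                  n_restarts: int = 10, seed: int = 0,
                  min_trials: int = 2) -> dict:
    """Per-condition tied 4-state fits and decoded joint paths."""
    conditions = np.asarray(conditions)
    out = {}
    for i, cond in enumerate(sorted(set(map(str, conditions)))):
        idx = np.flatnonzero(conditions == cond)
        if len(idx) < min_trials:
            warnings.warn(f"condition {cond!r}: only {len(idx)} trials, "
                          "skipped", RuntimeWarning)
            continue
        sub = counts.select_trials(idx)
        ss = np.random.SeedSequence([seed, i])
        fit = em_fit_tied(sub, n_restarts=n_restarts, seed=ss)
        paths = viterbi(sub, fit.params)
        out[cond] = (fit, paths, idx)
    return out
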