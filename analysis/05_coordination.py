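"""Interareal coordination of the decoded On-Off sequences.

Cross-correlation between V1 and V4 decoded phase series with the
trial-shuffle predictor, the negative/positive lag area split (negative
mass = V4 leads), and transition-triggered averages of each area's rates
around the other's transitions with the two-line crossing estimate.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from onoffstate.coordination import auc_split, cc_hmm, shuffle_predictor, tta
from onoffstate.core import read_bundle
from onoffstate.dynamics import transitions_of
from onoffstate.hmm import fit_all

SEED = 7


def main() -> None:
    bundle = read_bundle(str(ROOT / "scratch" / "session.h5"))
    bc = bundle.counts["cue_to_dim1"]
    decoded = {}
    for area in ("V1", "V4"):
        sub = bc.select_channels(bundle.spikes.channels_of(area))
        fits = fit_all(sub, bundle.conditions, K=2, n_restarts=5, seed=SEED)
        paths = [None] * bc.n_trials
        for cond, (fit, ps, idx) in fits.items():
            for i, p in zip(idx, ps):
                paths[i] = p
        decoded[area] = paths

    x = decoded["V1"]
    y = decoded["V4"]
    cc = cc_hmm(x, y, max_lag_ms=300.0, w_bin=bc.w_bin)
    cc.shuffle = shuffle_predictor(x, y, max_lag_ms=300.0, w_bin=bc.w_bin,
                                   n_shuffles=50, seed=SEED)
    a_neg, a_pos, diff = auc_split(cc)
    pd.DataFrame({"lag_ms": cc.lags_ms, "cc": cc.values,
                  "shuffle": cc.shuffle,
                  "corrected": cc.corrected}).to_csv(
        ROOT / "results" / "05_crosscorrelation.csv", index=False)
    print(f"cross-correlation peak (corrected): {cc.corrected.max():.3f} at "
          f"{cc.lags_ms[int(np.argmax(cc.corrected))]:+.0f} ms")
    print(f"AUC tau<0: {a_neg:.2f}, tau>0: {a_pos:.2f}, "
          f"difference {diff:+.2f} (positive = V4 leads)")

    # transition-triggered averages across areas
    rows = []
    for src, dst in (("V4", "V1"), ("V1", "V4")):
        up = [transitions_of(p, "off_to_on", bc.w_bin, off)
              for p, (off, _) in zip(decoded[src], bc.windows)]
        alltr = [np.sort(np.concatenate(
            [transitions_of(p, "off_to_on", bc.w_bin, off),
             transitions_of(p, "on_to_off", bc.w_bin, off)]))
            for p, (off, _) in zip(decoded[src], bc.windows)]
        dst_counts = [c[bundle.spikes.channels_of(dst)] for c in bc.counts]
        t = tta(dst_counts, bc.windows, up, alltr, w_bin=bc.w_bin,
                half_width_ms=80.0, n_shuffles=30, seed=SEED)
        cross = t.crossing_ms
        if cross is not None and abs(cross) > 80.0:
            cross = None       # intersection outside the fitted window
        rows.append(dict(aligned_to=f"{src} Off->On", rates_of=dst,
                         n_transitions=t.n_transitions, crossing_ms=cross))
        msg = (f"crossing at {cross:+.1f} ms" if cross is not None
               else "crossing not well-defined")
        print(f"{dst} rates aligned to {src} Off->On transitions: {msg} "
              f"({t.n_transitions} transitions)")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "05_tta_crossings.csv",
                              index=False)
    print("-> the corrected cross-correlation skews to negative lags: V4 "
          "state transitions lead V1. The crossing-point fit localizes the "
          "follower's latency only when the coupling has a real delay (the "
          "memoryless chain used here has none; see docs/methods.md)")


if __name__ == "__main__":
    main()
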