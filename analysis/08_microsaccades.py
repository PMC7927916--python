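"""Microsaccades and their relation to the On-Off dynamics.

Velocity-threshold detection on the eye traces, summary statistics,
direction histogram, the cross-correlogram between microsaccade onsets
and decoded Off->On transitions, and the microsaccade-free trial mask for
control reruns.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from onoffstate.coordination import cc_events
from onoffstate.core import read_bundle
from onoffstate.dynamics import transitions_of
from onoffstate.joint import V1_PHASE, V4_PHASE
from onoffstate.microsaccades import (detect_all, direction_analysis,
                                      microsaccade_free_mask, msacc_stats)

SEED = 7


def main() -> None:
    warnings.filterwarnings("ignore")
    bundle = read_bundle(str(ROOT / "scratch" / "session.h5"))
    events = detect_all(bundle.eye, bundle.eye_fs)
    durs = np.array([tr.shape[1] / bundle.eye_fs * 1000.0
                     for tr in bundle.eye])
    stats = msacc_stats(events, durs)
    print(f"{stats['n_events']} microsaccades, amplitude "
          f"{stats['amplitude_mean']:.2f} +/- {stats['amplitude_sd']:.2f} "
          f"deg, rate {stats['rate_hz']:.2f} Hz, on "
          f"{100 * stats['fraction_trials_with_event']:.0f}% of trials")

    df = direction_analysis(events, rf_direction_deg=0.0, n_bins=8)
    df.to_csv(ROOT / "results" / "08_directions.csv", index=False)

    on_any = (V1_PHASE | V4_PHASE)
    trans = [transitions_of(on_any[np.asarray(p, int)], "off_to_on", 10.0)
             for p in bundle.meta["true_paths"]]
    ev_times = [np.array([m.onset_ms for m in ev]) for ev in events]
    cc = cc_events(trans, ev_times, max_lag_ms=300.0, bin_ms=20.0,
                   n_shuffles=50, seed=SEED)
    pd.DataFrame({"lag_ms": cc.lags_ms, "coincidences_per_event": cc.values,
                  "shuffle": cc.shuffle,
                  "corrected": cc.corrected}).to_csv(
        ROOT / "results" / "08_msacc_transition_cc.csv", index=False)
    peak = cc.lags_ms[int(np.argmax(cc.corrected))]
    print(f"Off->On transition rate peaks {peak:+.0f} ms around "
          f"microsaccade onset (injected coupling at +60 ms)")

    mask = microsaccade_free_mask(events, bundle.counts["cue_to_dim1"].windows)
    print(f"{mask.sum()} of {len(mask)} trials are microsaccade-free in the "
          "analysis window (control reruns use these)")


if __name__ == "__main__":
    main()
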