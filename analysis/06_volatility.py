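#!/usr/bin/env python
"""Volatility adaptation: learning-rate shift vs signal-strength change.

Runs 17-subject groups under each generative regime and applies both group
tests — the LR-shift t-test and the beta-LR coupling change — showing that
each test responds to its own mechanism only.
"""

import json
import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from lrspectrum.pipeline import (PipelineConfig, _subsession_maps,  # noqa: E402
                                 simulate_group)
from lrspectrum.volatility import beta_lr_coupling, lr_shift  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main():
    warnings.filterwarnings("ignore")
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for mode in ("none", "shift", "gain", "combined"):
        cfg = PipelineConfig(n_subjects=17, region_a_shape=(4, 10, 1),
                             region_b_shape=(1, 1, 1), null_shape=(0, 0, 0),
                             regime_mode=mode, seed=SEED)
        group = simulate_group(cfg)
        ms, mv = [], []
        for g in group:
            m = _subsession_maps(g, whiten=True)
            ms.append(m["stable"])
            mv.append(m["volatile"])
        shift = lr_shift(ms, mv)
        coupling = beta_lr_coupling(ms, mv)
        rows.append(dict(mode=mode,
                         mean_delta_rank=round(float(
                             shift.subject_mean_delta.mean()), 2),
                         shift_p=round(shift.p, 4),
                         mean_delta_z=round(float(
                             coupling.delta_z.mean()), 3),
                         coupling_p=round(coupling.p, 4)))
        print(rows[-1])
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "volatility_modes.tsv", sep="\t", index=False)
    (OUT / "volatility_modes.json").write_text(
        json.dumps(rows, indent=1))
    print("\nThe shift test fires only when generative ranks jump at the "
          "sub-session boundary; the coupling test (more positive rank-beta "
          "correlation under volatility) fires only when relevant "
          "timescales gain signal strength; 'combined' triggers both.")


if __name__ == "__main__":
    main()
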