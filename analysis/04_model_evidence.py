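#!/usr/bin/env python
"""Group Bayesian model selection: is any learning-rate signal present?

Per voxel, compares the base GLM with a GLM that adds the three SVD
components of the 99 value traces, via AIC -> random-effects BMS, and
contrasts a signal region against a null region.
"""

import json
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from lrspectrum.benchmarks import (run_evidence_detection,  # noqa: E402
                                   run_svd_compression)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main():
    warnings.filterwarnings("ignore")
    OUT.mkdir(parents=True, exist_ok=True)
    svd = run_svd_compression(n_agents=17, seed=SEED)
    print(f"top-3 SVD variance of the 99 value traces: "
          f"{svd['top3_pct_mean']:.2f}% (99-LR bank is effectively "
          f"three-dimensional)")
    ev = run_evidence_detection(n_subjects=17, n_signal_vox=200,
                                n_null_vox=100, seed=SEED)
    print(f"median PXP, signal region: {ev['median_pxp_signal']:.4f}")
    print(f"median PXP, null region:   {ev['median_pxp_null']:.4f}")
    print(f"null voxels above 0.95:    {ev['frac_null_above_95']:.1%}")
    print("Voxels carrying value signal at any learning rate are flagged "
          "with near-certain evidence; null voxels almost never cross the "
          "0.95 threshold (the AIC penalty favors the base model there).")
    (OUT / "model_evidence.json").write_text(json.dumps(
        dict(svd=svd, evidence=ev), indent=1))


if __name__ == "__main__":
    main()
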