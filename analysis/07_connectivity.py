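#!/usr/bin/env python
"""Residual connectivity binned by best-fitting learning rate.

After projecting out the full design (base + all 30 value + all 30 PE
regressors, per segment), correlates same-rank and different-rank residual
bins between two regions and tests diagonal affinity, with and without an
injected rank-matched shared component.
"""

import json
import sys
import warnings
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from lrspectrum.connectivity import (bin_correlation_matrix,  # noqa: E402
                                     bin_residuals_by_lr,
                                     diagonal_affinity_test, residualize)
from lrspectrum.glm import map_best_lr  # noqa: E402
from lrspectrum.pipeline import PipelineConfig, simulate_group  # noqa: E402
from lrspectrum.simulate import subsession_masks  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def run(strength):
    cfg = PipelineConfig(n_subjects=17, region_a_shape=(4, 10, 1),
                         region_b_shape=(4, 10, 1), null_shape=(0, 0, 0),
                         connectivity_strength=strength, seed=SEED)
    group = simulate_group(cfg, inject_connectivity=strength > 0)
    zms = []
    for g in group:
        masks = subsession_masks(g.session, g.session.n_volumes)
        m = map_best_lr(g.dataset.Y, g.design, g.bank30)
        resid = residualize(g.dataset.Y, g.design, g.bank30,
                            segment_masks=masks)
        ba = bin_residuals_by_lr(resid, m, g.layout.region("regionA"))
        bb = bin_residuals_by_lr(resid, m, g.layout.region("regionB"))
        zms.append(bin_correlation_matrix(ba, bb))
    res = diagonal_affinity_test(zms)
    return res, np.nanmean(np.stack(zms), axis=0)


def main():
    warnings.filterwarnings("ignore")
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for strength in (0.0, 0.5):
        res, mean_z = run(strength)
        rows.append(dict(strength=strength,
                         mean_diag_corr=round(float(res.diag_corr.mean()), 3),
                         t=round(res.t, 2), p=round(res.p, 5)))
        np.savetxt(OUT / f"zmatrix_strength{strength:g}.tsv", mean_z,
                   delimiter="\t", fmt="%.4f")
        print(rows[-1])
    (OUT / "connectivity_summary.json").write_text(json.dumps(rows, indent=1))
    print("\nWith no shared component the diagonal statistic is null; with "
          "the rank-matched component injected, same-LR bins of the two "
          "regions correlate preferentially (bright diagonal).")


if __name__ == "__main__":
    main()
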