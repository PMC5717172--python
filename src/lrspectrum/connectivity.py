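"""Residual connectivity binned by best-fitting learning rate.

After regressing out everything the design knows about — the base columns
and all 30 value plus all 30 prediction-error regressors — the residual time
course of each voxel is averaged within its best-LR bin per region, the 30
bin series of one region are correlated with the 30 of another (Fisher z),
and *diagonal affinity* is tested: per subject, the correlation between the
z values and the negative rank distance -|i - j| across populated cells,
then a one-tailed one-sample t-test across subjects (affinity > 0 means
same-timescale bins interact preferentially).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .glm import LRMap
from .regressors import DesignMatrix, RegressorBank

__all__ = [
    "ConnectivityResult",
    "full_lr_design",
    "residualize",
    "bin_residuals_by_lr",
    "bin_correlation_matrix",
    "diagonal_affinity_test",
]


def full_lr_design(base: DesignMatrix, bank: RegressorBank,
                   segment_masks: list[np.ndarray] | None = None) -> np.ndarray:
    """Base columns plus every value and PE regressor.

    With ``segment_masks`` (boolean volume masks for the sub-sessions) each
    LR column enters once per segment, plus a per-segment intercept, so that
    segment-wise learning-rate structure — the granularity at which the
    sub-session analyses model the signal — is regressed out as well.
    """
    cols = [base.values]
    if segment_masks is None:
        cols += [bank.X_value, bank.X_pe]
    else:
        for mask in segment_masks:
            m = mask[:, None].astype(float)
            cols += [bank.X_value * m, bank.X_pe * m, m]
    return np.column_stack(cols)


@dataclass
class ConnectivityResult:
    z_matrices: np.ndarray   # (subjects, 30, 30), NaN where a bin is empty
    diag_corr: np.ndarray    # per subject
    t: float
    p: float                 # one-tailed, affinity > 0
    excluded_subjects: list


def residualize(Y: np.ndarray, base: DesignMatrix, bank: RegressorBank,
                segment_masks: list[np.ndarray] | None = None) -> np.ndarray:
    """OLS residuals of every voxel against base + all value + all PE columns
    (per sub-session segment if ``segment_masks`` is given).

    The 60 learning-rate columns are highly collinear; rank-revealing QR
    prunes dependent columns before projection (with a warning reporting the
    retained count).
    """
    import scipy.linalg
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = full_lr_design(base, bank, segment_masks)
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    keep = np.sort(piv[: int(np.sum(diag > tol))])
    if len(keep) < X.shape[1]:
        warnings.warn(f"pruned {X.shape[1] - len(keep)} dependent design columns; "
                      f"{len(keep)} retained for residualization")
    Q, _ = np.linalg.qr(X[:, keep])
    return Y - (Y @ Q) @ Q.T


def bin_residuals_by_lr(residuals: np.ndarray, lr_map: LRMap,
                        voxels: np.ndarray | None = None,
                        n_ranks: int = 30) -> np.ndarray:
    """Mean residual series per best-LR rank; empty ranks are NaN rows.

    Returns an (n_ranks, n_volumes) array.
    """
    residuals = np.atleast_2d(residuals)
    ranks = lr_map.best_rank
    if voxels is not None:
        residuals = residuals[voxels]
        ranks = ranks[voxels]
    out = np.full((n_ranks, residuals.shape[1]), np.nan)
    for r in range(1, n_ranks + 1):
        sel = ranks == r
        if np.any(sel):
            out[r - 1] = residuals[sel].mean(axis=0)
    return out


def bin_correlation_matrix(bins_a: np.ndarray, bins_b: np.ndarray) -> np.ndarray:
    """Fisher-z correlations between every rank bin of two regions.

    Cells touching an empty (NaN) bin are NaN; a perfect correlation (same
    series in both bins) is flagged NaN rather than +inf.
    """
    n = bins_a.shape[0]
    z = np.full((n, n), np.nan)
    ok_a = np.isfinite(bins_a).all(axis=1) & (np.std(bins_a, axis=1) > 0)
    ok_b = np.isfinite(bins_b).all(axis=1) & (np.std(bins_b, axis=1) > 0)
    if not ok_a.any() or not ok_b.any():
        return z

    def _standardize(x):
        xc = x - x.mean(axis=1, keepdims=True)
        return xc / np.linalg.norm(xc, axis=1, keepdims=True)

    r = _standardize(bins_a[ok_a]) @ _standardize(bins_b[ok_b]).T
    r = np.clip(r, -1.0, 1.0)
    zz = np.where(np.isclose(np.abs(r), 1.0), np.nan, np.arctanh(
        np.where(np.isclose(np.abs(r), 1.0), 0.0, r)))
    z[np.ix_(np.flatnonzero(ok_a), np.flatnonzero(ok_b))] = zz
    return z


def diagonal_affinity_test(z_matrices: list[np.ndarray],
                           min_cells: int = 10) -> ConnectivityResult:
    """Do same-rank bins correlate more than distant-rank bins?

    Per subject: Pearson correlation across populated cells between z and
    the negative rank distance -|i - j|; one-tailed one-sample t-test of the
    correlations > 0 across subjects.
    """
    n = z_matrices[0].shape[0]
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    closeness = -np.abs(ii - jj).astype(float)
    diag_corr, excluded = [], []
    for s, z in enumerate(z_matrices):
        ok = np.isfinite(z)
        if ok.sum() < min_cells:
            excluded.append(s)
            warnings.warn(f"subject {s}: only {ok.sum()} populated cells; excluded")
            continue
        zv = z[ok]
        if zv.std() <= 1e-12 * (1.0 + np.abs(zv).mean()):
            excluded.append(s)
            warnings.warn(f"subject {s}: constant z matrix; excluded")
            continue
        diag_corr.append(stats.pearsonr(zv, closeness[ok])[0])
    diag_corr = np.asarray(diag_corr)
    if len(diag_corr) < 3:
        raise ValueError("need at least 3 usable subjects")
    t, p = stats.ttest_1samp(diag_corr, 0.0, alternative="greater")
    return ConnectivityResult(z_matrices=np.stack(z_matrices),
                              diag_corr=diag_corr, t=float(t), p=float(p),
                              excluded_subjects=excluded)
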