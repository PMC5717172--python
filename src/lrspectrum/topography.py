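"""Spatial organization of best-fitting learning rates.

Per subject, the best-fitting rank (1..30) is regressed on the voxel's
(x, y, z) coordinates; explained variance r^2 is compared against the mean
r^2 of regressions with randomly permuted coordinates (default 10,000
permutations), and at the group level per-subject true r^2 is tested against
per-subject mean permuted r^2 with a paired t-test.  A directed gradient
along one axis is tested by a one-sample t-test of the per-subject slope of
that axis against zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TopographyResult",
    "fit_spatial_regression",
    "permutation_null",
    "group_topography_test",
    "group_gradient_test",
]

AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class TopographyResult:
    r2_true: np.ndarray        # per subject
    r2_perm_mean: np.ndarray   # per subject
    p_perm: np.ndarray         # per subject, one-sided exceedance
    coefficients: np.ndarray   # (subjects, 3) axis slopes
    group_t: float
    group_p: float
    n_perm: int


def _design(coords: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Coordinate design with intercept; collinear/flat axes dropped."""
    coords = np.asarray(coords, dtype=float)
    kept = []
    cols = []
    for a in range(3):
        c = coords[:, a]
        if np.ptp(c) == 0:
            warnings.warn(f"coordinate axis {'xyz'[a]} is constant; dropped")
            continue
        kept.append(a)
        cols.append(c)
    X = np.column_stack(cols + [np.ones(len(coords))])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear coordinate axes; falling back to pseudoinverse")
    return X, kept


def fit_spatial_regression(best_rank: np.ndarray,
                           coords: np.ndarray) -> tuple[float, np.ndarray]:
    """Least squares of rank on (x, y, z, intercept) -> (r^2, slopes).

    Slopes are reported for all three axes (0 for a dropped axis).
    """
    y = np.asarray(best_rank, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 voxels")
    X, kept = _design(coords)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 0.0 if sst == 0 else 1.0 - np.sum(resid ** 2) / sst
    slopes = np.zeros(3)
    for i, a in enumerate(kept):
        slopes[a] = beta[i]
    return float(r2), slopes


def permutation_null(best_rank: np.ndarray, coords: np.ndarray,
                     n_perm: int = 10_000, seed: int = 0) -> tuple[float, float, float]:
    """Permutation null for the spatial regression.

    Coordinates are permuted relative to ranks ``n_perm`` times (equivalent
    to permuting ranks).  Returns (r2_true, mean permuted r^2, one-sided
    exceedance p).
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(best_rank, dtype=float)
    X, _ = _design(coords)
    Q, _ = np.linalg.qr(X)
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0:
        warnings.warn("constant rank map; permutation test degenerate")
        return 0.0, 0.0, 1.0

    def r2_of(Y):            # Y: (V, m) columns of (permuted) rank vectors
        proj = Q.T @ Y
        return np.sum(proj ** 2, axis=0) / sst - (Y.sum(axis=0) ** 2 / len(y)) / sst

    r2_true = float(r2_of(y[:, None])[0])
    perms = np.empty(n_perm)
    chunk = 500
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        Yp = np.column_stack([y[rng.permutation(len(y))] for _ in range(m)])
        perms[start:start + m] = r2_of(Yp)
    p = (1 + np.sum(perms >= r2_true)) / (n_perm + 1)
    return r2_true, float(perms.mean()), float(p)


def group_topography_test(lr_maps: list, coords_list: list,
                          n_perm: int = 10_000, seed: int = 0) -> TopographyResult:
    """Run the spatial regression + permutation null for every subject and
    test true vs permuted r^2 across subjects (paired t-test)."""
    n_sub = len(lr_maps)
    r2_true = np.empty(n_sub)
    r2_perm = np.empty(n_sub)
    p_perm = np.empty(n_sub)
    slopes = np.empty((n_sub, 3))
    for s, (m, coords) in enumerate(zip(lr_maps, coords_list)):
        ranks = m.best_rank if hasattr(m, "best_rank") else np.asarray(m)
        _, slopes[s] = fit_spatial_regression(ranks, coords)
        r2_true[s], r2_perm[s], p_perm[s] = permutation_null(
            ranks, coords, n_perm=n_perm, seed=seed + s)
    t, p = stats.ttest_rel(r2_true, r2_perm)
    return TopographyResult(r2_true=r2_true, r2_perm_mean=r2_perm, p_perm=p_perm,
                            coefficients=slopes, group_t=float(t),
                            group_p=float(p), n_perm=n_perm)


def group_gradient_test(coefficients: np.ndarray, axis: str = "y") -> tuple[float, float]:
    """One-sample two-sided t-test of the chosen axis's slope against 0."""
    coefficients = np.atleast_2d(np.asarray(coefficients, dtype=float))
    if coefficients.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    slopes = coefficients[:, AXES[axis]]
    if np.allclose(slopes.std(ddof=1), 0):
        warnings.warn("zero-variance slopes; degenerate t-test")
        return (np.inf if slopes.mean() != 0 else 0.0,
                0.0 if slopes.mean() != 0 else 1.0)
    t, p = stats.ttest_1samp(slopes, 0.0)
    return float(t), float(p)
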