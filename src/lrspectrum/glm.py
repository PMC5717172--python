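"""Voxelwise GLM machinery: AR(1) prewhitening, least-squares fits, the 30
competing learning-rate GLMs, and sub-session splitting.

Each voxel is fit with 30 separate GLMs, each consisting of the base design
matrix plus one learning rate's value regressor (decision phase) and the
matching prediction-error regressor (outcome phase).  The voxel's
*best-fitting learning rate* is the rank (1..30) of the value regressor with
the highest signed beta.  The 30 fits share the base design, so the value
and PE betas are computed by the Frisch-Waugh-Lovell route: residualize the
voxel and the two added regressors against the base design once, then solve
a 2x2 system per learning rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .task import BehaviorSession
from .regressors import DesignMatrix, RegressorBank

__all__ = [
    "GLMResult",
    "LRMap",
    "estimate_ar1",
    "prewhiten",
    "fit_glm",
    "map_best_lr",
    "subsession_segments",
    "split_subsessions",
]

AR1_CLIP = 0.97


@dataclass
class GLMResult:
    betas: np.ndarray
    RSS: float
    n: int
    k: int
    residuals: np.ndarray
    columns: list[str] | None = None


@dataclass
class LRMap:
    """Best-fitting learning-rate map for one subject and (sub-)session."""

    best_rank: np.ndarray    # (V,), 1-based rank into the 30-grid
    best_beta: np.ndarray    # (V,), beta of the value regressor at best_rank
    all_betas: np.ndarray    # (V, 30) value-regressor betas
    alphas: np.ndarray       # the 30-grid
    session_tag: str = "whole"

    @property
    def n_voxels(self) -> int:
        return len(self.best_rank)


def estimate_ar1(residuals: np.ndarray) -> float | np.ndarray:
    """Lag-1 autocorrelation of residuals, clipped to +-0.97.

    Accepts (n,) or (n, V); returns a scalar or (V,).
    """
    r = np.asarray(residuals, dtype=float)
    one_d = r.ndim == 1
    if one_d:
        r = r[:, None]
    r = r - r.mean(axis=0)
    denom = np.sum(r * r, axis=0)
    denom = np.where(denom == 0, 1.0, denom)
    phi = np.sum(r[1:] * r[:-1], axis=0) / denom
    if np.any(np.abs(phi) > AR1_CLIP):
        warnings.warn(f"AR(1) estimate beyond +-{AR1_CLIP}; clipped")
    phi = np.clip(phi, -AR1_CLIP, AR1_CLIP)
    return float(phi[0]) if one_d else phi


def _quasi_difference(A: np.ndarray, phi: float) -> np.ndarray:
    """Exact AR(1) whitening transform (first row scaled by sqrt(1-phi^2))."""
    A = np.asarray(A, dtype=float)
    out = np.empty_like(A)
    out[0] = A[0] * np.sqrt(1.0 - phi ** 2)
    out[1:] = A[1:] - phi * A[:-1]
    return out


def prewhiten(y: np.ndarray, X: np.ndarray,
              phi: float | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Whiten one voxel's series and its design against AR(1) noise.

    If ``phi`` is not given it is estimated from the OLS residuals of
    ``y ~ X``.  Returns (y*, X*, phi).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if phi is None:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        phi = estimate_ar1(y - X @ beta)
    return _quasi_difference(y, phi), _quasi_difference(X, phi), phi


def fit_glm(y: np.ndarray, X: np.ndarray,
            columns: list[str] | None = None) -> GLMResult:
    """Ordinary least squares with rank-deficiency pruning.

    Dependent columns are detected by pivoted QR and dropped with a warning;
    their betas are reported as 0 so the coefficient vector keeps the design
    matrix's shape.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more volumes ({n}) than regressors ({k})")

    import scipy.linalg
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    keep = np.sort(piv[: int(np.sum(diag > tol))])
    if len(keep) < k:
        dropped = sorted(set(range(k)) - set(keep))
        names = ([columns[j] for j in dropped] if columns else dropped)
        warnings.warn(f"design rank deficient; dropped columns {names}")
    Xk = X[:, keep]
    beta_k, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    betas = np.zeros(k)
    betas[keep] = beta_k
    resid = y - Xk @ beta_k
    return GLMResult(betas=betas, RSS=float(resid @ resid), n=n, k=len(keep),
                     residuals=resid, columns=columns)


def map_best_lr(Y: np.ndarray,
                base: DesignMatrix,
                bank: RegressorBank,
                whiten: bool = True,
                criterion: str = "signed",
                session_tag: str = "whole") -> LRMap:
    """Assign each voxel its best-fitting learning rate.

    Parameters
    ----------
    Y:
        (V, n_volumes) voxel time series.
    base, bank:
        Base design matrix and the 30-LR regressor bank, built on the same
        volumes.
    whiten:
        Per-voxel AR(1) prewhitening (estimated from base-model residuals)
        applied to the voxel and all design columns.
    criterion:
        "signed" (the default; highest signed beta) or "abs".
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Xb = base.values
    n, _ = Xb.shape
    if Y.shape[1] != n or bank.X_value.shape[0] != n:
        raise ValueError("data, design and bank must share volume count")
    V = Y.shape[0]
    n_lr = bank.n_lr

    all_betas = np.empty((V, n_lr))
    for v in range(V):
        y = Y[v]
        if whiten:
            yw, Xbw, phi = prewhiten(y, Xb)
            XVw = _quasi_difference(bank.X_value, phi)
            XPw = _quasi_difference(bank.X_pe, phi)
        else:
            yw, Xbw, XVw, XPw = y, Xb, bank.X_value, bank.X_pe
        Q, _ = np.linalg.qr(Xbw)
        ry = yw - Q @ (Q.T @ yw)
        RV = XVw - Q @ (Q.T @ XVw)
        RP = XPw - Q @ (Q.T @ XPw)
        # per LR, 2x2 normal equations for (value, pe) betas given the base
        a = np.sum(RV * RV, axis=0)
        b = np.sum(RV * RP, axis=0)
        c = np.sum(RP * RP, axis=0)
        bv = RV.T @ ry
        bp = RP.T @ ry
        det = a * c - b * b
        det = np.where(np.abs(det) < 1e-12 * np.maximum(a * c, 1e-30), np.nan, det)
        all_betas[v] = (c * bv - b * bp) / det

    score = np.abs(all_betas) if criterion == "abs" else all_betas
    best_idx = np.nanargmax(score, axis=1)           # first (lowest rank) on ties
    best_rank = best_idx + 1
    best_beta = all_betas[np.arange(V), best_idx]
    return LRMap(best_rank=best_rank, best_beta=best_beta, all_betas=all_betas,
                 alphas=np.asarray(bank.alphas), session_tag=session_tag)


def subsession_segments(session: BehaviorSession) -> dict[str, dict]:
    """Volume slices and trial indices for the stable and volatile segments.

    The first segment runs up to and including the volume containing the
    last outcome onset of the first sub-session, plus two volumes for the
    hemodynamic delay; the second segment is the remainder (disjoint).
    """
    labels = session.schedule.subsession_label
    first_label = labels[0]
    second_label = "volatile" if first_label == "stable" else "stable"
    idx1 = np.flatnonzero(labels == first_label)
    idx2 = np.flatnonzero(labels == second_label)
    if len(idx1) == 0 or len(idx2) == 0:
        raise ValueError("session must contain both sub-sessions")

    last_out = session.outcome_onset[idx1].max()
    v_end = int(np.floor(last_out / session.TR))     # volume containing the onset
    stop1 = min(v_end + 3, session.n_volumes)        # + 2 extra volumes, exclusive
    seg1 = dict(volumes=slice(0, stop1), trials=idx1, label=first_label)
    seg2 = dict(volumes=slice(stop1, session.n_volumes), trials=idx2,
                label=second_label)
    return {first_label: seg1, second_label: seg2}


def split_subsessions(Y: np.ndarray, session: BehaviorSession,
                      min_volumes: int = 30) -> dict[str, np.ndarray]:
    """Split a (V, n_volumes) data matrix into the two sub-session segments."""
    segs = subsession_segments(session)
    out = {}
    for label, seg in segs.items():
        sl = seg["volumes"]
        if sl.stop - sl.start < min_volumes:
            raise ValueError(f"{label} segment too short ({sl.stop - sl.start} volumes)")
        out[label] = np.atleast_2d(Y)[:, sl]
    return out
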