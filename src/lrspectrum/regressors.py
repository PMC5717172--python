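"""GLM-ready regressors: HRF convolution, filtering, design matrices and the
correlation-equalized 30-learning-rate grid.

Every event regressor is built the same way: a continuous-time boxcar whose
height is the (demeaned) parametric value, convolved with the canonical
double-gamma HRF (peak 6 s, undershoot 16 s, dispersion 1, undershoot ratio
1/6), sampled at the volume times, then high-pass filtered by projection on
a discrete-cosine drift basis (default cutoff 100 s).  Value and
prediction-error regressors are additionally scaled to unit variance so
betas are comparable across learning rates.

The 99 convolved value regressors are highly collinear at high alpha, so the
mapping analyses use 30 learning rates chosen to be equally spaced in
*neighbor correlation*.  Because the regressors form a smooth one-parameter
family, 1 - corr between neighbors shrinks quadratically with the alpha
step; the additive distance along the family is therefore the correlation
metric sqrt(2 * (1 - corr)) (the chord length between unit-variance
regressors).  Thirty positions equally spaced along that cumulative arc
(endpoints included) yield selected neighbors with approximately equal
correlation; selections are mapped back to alpha and averaged across
subjects and sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import compute_regressor

from .task import BehaviorSession
from .value import ValueTraces

__all__ = [
    "CANONICAL_LR30",
    "DesignMatrix",
    "RegressorBank",
    "hrf_convolve",
    "cosine_drift_basis",
    "highpass_filter",
    "normalize",
    "build_design_matrix",
    "build_regressor_bank",
    "select_lr_grid",
]

#: The published 30-element correlation-equalized learning-rate grid; used as
#: the default mapping grid.  ``select_lr_grid`` recomputes it from data.
CANONICAL_LR30 = np.array([
    0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.11,
    0.12, 0.14, 0.15, 0.17, 0.20, 0.22, 0.25, 0.28, 0.32, 0.36,
    0.40, 0.46, 0.51, 0.57, 0.64, 0.71, 0.78, 0.85, 0.93, 0.99,
])

DEFAULT_HIGHPASS_CUTOFF = 100.0  # seconds


def hrf_convolve(onsets: np.ndarray,
                 durations: np.ndarray,
                 heights: np.ndarray,
                 TR: float,
                 n_volumes: int,
                 t0: float = 0.0,
                 oversampling: int = 50) -> np.ndarray:
    """Convolve weighted boxcar events with the double-gamma HRF.

    Returns the regressor sampled at the ``n_volumes`` volume times
    ``t0 + k * TR``.  Events must start within the scan.
    """
    if TR <= 0:
        raise ValueError("TR must be positive")
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    heights = np.asarray(heights, dtype=float)
    frame_times = t0 + np.arange(n_volumes) * TR
    if len(onsets) == 0 or np.all(heights == 0):
        return np.zeros(n_volumes)
    if onsets.min() < frame_times[0] - 1e-9 or onsets.max() > frame_times[-1] + TR:
        raise ValueError("event onsets fall outside the scan")
    exp_condition = np.vstack([onsets, durations, heights])
    reg, _ = compute_regressor(exp_condition, "spm", frame_times,
                               oversampling=oversampling)
    return reg[:, 0]


def cosine_drift_basis(n_volumes: int, TR: float,
                       cutoff: float = DEFAULT_HIGHPASS_CUTOFF) -> np.ndarray:
    """Unit-norm discrete-cosine drift basis for periods longer than ``cutoff``."""
    if cutoff <= 2 * TR:
        raise ValueError("cutoff must exceed 2 * TR")
    n_basis = int(np.floor(2.0 * n_volumes * TR / cutoff))
    t = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes)) for k in range(1, n_basis + 1)]
    if not cols:
        return np.empty((n_volumes, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0)


def highpass_filter(series: np.ndarray, TR: float,
                    cutoff: float = DEFAULT_HIGHPASS_CUTOFF) -> np.ndarray:
    """Remove slow drift: demean and project out the cosine drift basis.

    Operates on the last axis-0 (time) of a 1-D or (time x k) array.
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    basis = cosine_drift_basis(x.shape[0], TR, cutoff)
    x = x - x.mean(axis=0)
    if basis.shape[1]:
        x = x - basis @ (basis.T @ x)
    return x[:, 0] if squeeze else x


def normalize(series: np.ndarray) -> np.ndarray:
    """Demean and scale to unit standard deviation (per column)."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return x / sd


def _demean(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v - v.mean()


@dataclass
class DesignMatrix:
    """Named base design: task main effects, parametric modulators, their
    temporal derivatives, nuisance columns and an intercept."""

    frame: pd.DataFrame
    TR: float

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def _conv_slice(onsets, durations, heights, TR, n_total, v0, v1):
    """Convolve on the full-session grid, then slice a volume segment, so
    responses spilling into a segment from just before it are kept."""
    raw = hrf_convolve(onsets, durations, heights, TR, n_total, t0=0.0)
    return raw[v0:v1]


def build_design_matrix(session: BehaviorSession,
                        nuisance: np.ndarray | None = None,
                        volumes: slice | None = None,
                        trials: np.ndarray | None = None,
                        cutoff: float = DEFAULT_HIGHPASS_CUTOFF,
                        add_derivatives: bool = True) -> DesignMatrix:
    """Build the base (no learning-rate) design matrix for a (sub-)session.

    Seven task regressors — decision / predict / outcome phase main effects
    and four parametric modulators (chosen magnitude and log RT and
    stay-switch at decision, chosen magnitude at outcome) — each with its
    temporal derivative, plus nuisance columns and an intercept.

    ``volumes``/``trials`` restrict the matrix to a sub-session segment; the
    segment is filtered and demeaned on its own.
    """
    vol = volumes if volumes is not None else slice(0, session.n_volumes)
    v0, v1 = vol.start or 0, vol.stop if vol.stop is not None else session.n_volumes
    n_vol = v1 - v0
    idx = trials if trials is not None else np.arange(session.n_trials)

    dec_on = session.decision_onset[idx]
    dec_dur = session.response_time[idx] - session.decision_onset[idx]
    pred_on = session.response_time[idx]
    pred_dur = session.outcome_onset[idx] - session.response_time[idx]
    out_on = session.outcome_onset[idx]
    out_dur = np.full(len(idx), 3.0)

    specs = [
        ("decision", dec_on, dec_dur, np.ones(len(idx))),
        ("predict", pred_on, pred_dur, np.ones(len(idx))),
        ("outcome", out_on, out_dur, np.ones(len(idx))),
        ("dec_x_magnitude", dec_on, dec_dur, _demean(session.chosen_magnitude[idx])),
        ("dec_x_logrt", dec_on, dec_dur, _demean(np.log(session.rt[idx]))),
        ("dec_x_switch", dec_on, dec_dur, _demean(session.stay_switch[idx])),
        ("out_x_magnitude", out_on, out_dur, _demean(session.chosen_magnitude[idx])),
    ]

    cols: dict[str, np.ndarray] = {}
    for name, on, dur, h in specs:
        if np.allclose(h, 0):
            warnings.warn(f"design column {name!r} is degenerate (constant "
                          "modulator); dropped")
            continue
        raw = _conv_slice(on, dur, h, session.TR, session.n_volumes, v0, v1)
        cols[name] = highpass_filter(raw, session.TR, cutoff)
        if add_derivatives:
            cols[name + "_dt"] = highpass_filter(np.gradient(raw), session.TR, cutoff)

    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)[vol]
        for j in range(nuisance.shape[1]):
            cols[f"nuisance{j}"] = highpass_filter(nuisance[:, j], session.TR, cutoff)

    cols["intercept"] = np.ones(n_vol)
    frame = pd.DataFrame(cols)
    if not np.isfinite(frame.to_numpy()).all():
        raise ValueError("design matrix contains non-finite values")
    return DesignMatrix(frame=frame, TR=session.TR)


@dataclass
class RegressorBank:
    """Convolved, filtered, unit-variance value and PE regressors per LR."""

    alphas: np.ndarray   # (n_lr,)
    X_value: np.ndarray  # (n_volumes, n_lr) decision-phase p(chosen)
    X_pe: np.ndarray     # (n_volumes, n_lr) outcome-phase prediction error
    TR: float

    @property
    def n_lr(self) -> int:
        return len(self.alphas)


def build_regressor_bank(session: BehaviorSession,
                         traces: ValueTraces,
                         volumes: slice | None = None,
                         trials: np.ndarray | None = None,
                         cutoff: float = DEFAULT_HIGHPASS_CUTOFF) -> RegressorBank:
    """Convolve p(chosen) (decision phase) and PE (outcome phase) for every
    learning rate in ``traces``, then filter and scale to unit variance."""
    vol = volumes if volumes is not None else slice(0, session.n_volumes)
    v0, v1 = vol.start or 0, vol.stop if vol.stop is not None else session.n_volumes
    n_vol = v1 - v0
    idx = trials if trials is not None else np.arange(session.n_trials)

    dec_on = session.decision_onset[idx]
    dec_dur = session.response_time[idx] - session.decision_onset[idx]
    out_on = session.outcome_onset[idx]
    out_dur = np.full(len(idx), 3.0)

    n_lr = len(traces.alphas)
    Xv = np.empty((n_vol, n_lr))
    Xp = np.empty((n_vol, n_lr))
    for k in range(n_lr):
        Xv[:, k] = _conv_slice(dec_on, dec_dur, _demean(traces.p_chosen[idx, k]),
                               session.TR, session.n_volumes, v0, v1)
        Xp[:, k] = _conv_slice(out_on, out_dur, _demean(traces.PE[idx, k]),
                               session.TR, session.n_volumes, v0, v1)
    Xv = normalize(highpass_filter(Xv, session.TR, cutoff))
    Xp = normalize(highpass_filter(Xp, session.TR, cutoff))
    return RegressorBank(alphas=np.asarray(traces.alphas), X_value=Xv, X_pe=Xp,
                         TR=session.TR)


def neighbor_correlations(X: np.ndarray) -> np.ndarray:
    """corr(X_j, X_{j+1}) for consecutive columns of a regressor bank."""
    Xc = X - X.mean(axis=0)
    Xc = Xc / np.linalg.norm(Xc, axis=0)
    return np.sum(Xc[:, :-1] * Xc[:, 1:], axis=0)


def select_lr_grid(banks: list[np.ndarray],
                   alphas: np.ndarray,
                   k: int = 30) -> np.ndarray:
    """Select ``k`` learning rates equally spaced in neighbor correlation.

    For each bank (volumes x 99 convolved value regressors): neighbor
    distances d_j = sqrt(2 * (1 - corr(X_j, X_{j+1}))) — the correlation
    chord metric, additive along the smooth regressor family; cumulative arc
    length; ``k`` equally spaced positions including both endpoints mapped
    back to alpha (nearest grid alpha, ties toward the lower one).
    Selections are averaged across banks and rounded to two decimals.
    """
    alphas = np.asarray(alphas, dtype=float)
    selections = []
    for X in banks:
        if np.any(X.std(axis=0) == 0):
            warnings.warn("bank with constant regressor excluded from grid selection")
            continue
        d = np.sqrt(2.0 * np.clip(1.0 - neighbor_correlations(X), 0.0, None))
        s = np.concatenate([[0.0], np.cumsum(d)])
        targets = np.linspace(0.0, s[-1], k)
        a_cont = np.interp(targets, s, alphas)
        # snap to the nearest grid alpha; argmin takes the lower on ties
        snapped = alphas[np.argmin(np.abs(alphas[None, :] - a_cont[:, None]), axis=1)]
        selections.append(snapped)
    if not selections:
        raise ValueError("no usable banks for grid selection")
    return np.round(np.mean(selections, axis=0), 2)
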