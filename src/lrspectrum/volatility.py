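"""Adaptation of the learning-rate map to environmental volatility.

Two complementary group tests on the stable- vs volatile-sub-session maps:

* the *LR shift* test — per voxel, the rank difference (volatile - stable);
  per subject, its mean; one-sample t-test of subject means against zero
  (a positive mean = faster timescales under volatility);
* the *beta-LR coupling* test — per subject and sub-session, the Pearson
  correlation across voxels between best rank and best beta, Fisher
  z-transformed; paired t-test of (z_stable - z_volatile).  A gain-type
  adaptation boosts currently-relevant timescales, making the coupling more
  negative in the stable and more positive in the volatile sub-session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .glm import LRMap

__all__ = ["ShiftResult", "CouplingResult", "lr_shift", "beta_lr_coupling"]


@dataclass
class ShiftResult:
    delta_rank: np.ndarray          # (subjects, V) volatile - stable
    subject_mean_delta: np.ndarray  # (subjects,)
    t: float
    p: float
    normality_p: dict               # Lilliefors p per sub-session (pooled ranks)


@dataclass
class CouplingResult:
    r_stable: np.ndarray
    r_volatile: np.ndarray
    z_stable: np.ndarray
    z_volatile: np.ndarray
    delta_z: np.ndarray             # z_stable - z_volatile
    t: float
    p: float
    excluded_subjects: list


def _check_pairs(maps_stable, maps_volatile):
    if len(maps_stable) != len(maps_volatile):
        raise ValueError("need one stable and one volatile map per subject")
    for ms, mv in zip(maps_stable, maps_volatile):
        if ms.n_voxels != mv.n_voxels:
            raise ValueError("stable/volatile maps cover different voxel sets")


def lr_shift(maps_stable: list[LRMap], maps_volatile: list[LRMap],
             sign: str = "volatile_minus_stable") -> ShiftResult:
    """Group test of the change in best-fitting rank between sub-sessions."""
    _check_pairs(maps_stable, maps_volatile)
    flip = -1.0 if sign == "stable_minus_volatile" else 1.0
    delta = np.array([flip * (mv.best_rank.astype(float) - ms.best_rank)
                      for ms, mv in zip(maps_stable, maps_volatile)])
    subj_mean = delta.mean(axis=1)
    if np.allclose(delta, 0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_1samp(subj_mean, 0.0)
        t, p = float(t), float(p)

    norm_p = {}
    for tag, maps in (("stable", maps_stable), ("volatile", maps_volatile)):
        pooled = np.concatenate([m.best_rank for m in maps]).astype(float)
        try:
            _, norm_p[tag] = lilliefors(pooled, dist="norm")
        except Exception:       # tiny or constant samples
            norm_p[tag] = np.nan
    return ShiftResult(delta_rank=delta, subject_mean_delta=subj_mean,
                       t=t, p=p, normality_p=norm_p)


def beta_lr_coupling(maps_stable: list[LRMap],
                     maps_volatile: list[LRMap]) -> CouplingResult:
    """Change in the rank-beta correlation between sub-sessions."""
    _check_pairs(maps_stable, maps_volatile)
    rs, rv, keep, excluded = [], [], [], []
    for s, (ms, mv) in enumerate(zip(maps_stable, maps_volatile)):
        if ms.n_voxels < 10:
            excluded.append(s)
            warnings.warn(f"subject {s}: fewer than 10 voxels; excluded")
            continue
        ok = True
        pair = []
        for m in (ms, mv):
            ranks = m.best_rank.astype(float)
            betas = m.best_beta
            if ranks.std() == 0 or betas.std() == 0:
                ok = False
                break
            pair.append(stats.pearsonr(ranks, betas)[0])
        if not ok:
            excluded.append(s)
            warnings.warn(f"subject {s}: zero-variance ranks or betas; excluded")
            continue
        rs.append(pair[0])
        rv.append(pair[1])
        keep.append(s)
    rs, rv = np.asarray(rs), np.asarray(rv)
    zs, zv = np.arctanh(rs), np.arctanh(rv)
    dz = zs - zv
    if len(dz) < 3:
        raise ValueError("need at least 3 usable subjects")
    t, p = stats.ttest_1samp(dz, 0.0)
    return CouplingResult(r_stable=rs, r_volatile=rv, z_stable=zs, z_volatile=zv,
                          delta_z=dz, t=float(t), p=float(p),
                          excluded_subjects=excluded)
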