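"""Synthetic BOLD data with known per-voxel generative learning rates.

Each voxel carries a decision-phase value signal computed at a
voxel-specific learning rate (one of the 30 grid ranks) plus the matching
outcome-phase prediction-error signal, loadings on six smooth motion-like
nuisance series, and AR(1) Gaussian noise.  Regions are laid out on integer
coordinate grids with an optional affine learning-rate gradient along one
axis.  Two regime modes encode the volatility-adaptation hypotheses as
generative truth:

* ``shift`` — the generative rank jumps by a configured amount at the
  sub-session boundary (voxels change their preferred timescale);
* ``gain`` — ranks stay fixed but the value-signal amplitude is boosted
  when the voxel's rank matches the regime (low ranks in the stable
  sub-session, high ranks in the volatile one);
* ``combined`` does both; ``none`` does neither.

For connectivity studies a *shared bin component* can be injected: one
latent series per learning-rate rank, correlated across neighboring ranks,
orthogonalized against the full design (base columns plus all value and PE
regressors) so it survives residualization, and added to matching-rank
voxels of two regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import BehaviorSession
from .regressors import RegressorBank, DesignMatrix
from .glm import subsession_segments

__all__ = [
    "RegionSpec",
    "VoxelLayout",
    "SyntheticDataset",
    "make_nuisance",
    "make_region_layout",
    "synthesize_bold",
    "inject_shared_bins",
]

N_RANKS = 30


@dataclass(frozen=True)
class RegionSpec:
    """Geometry and learning-rate gradient of one synthetic region."""

    name: str
    shape: tuple[int, int, int] = (5, 10, 4)     # voxel grid (x, y, z)
    origin: tuple[int, int, int] = (0, 0, 0)
    gradient_axis: str = "y"
    gradient_slope: float = 0.0                  # ranks per voxel step
    intercept_rank: float = 15.0                 # rank at the axis minimum
    rank_jitter_sd: float = 0.0                  # ranks
    is_null: bool = False                        # no value/PE signal if True

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class VoxelLayout:
    """Voxel coordinates, region labels and generative learning-rate ranks."""

    coords: np.ndarray        # (V, 3) integer
    region_label: np.ndarray  # (V,) str
    gen_lr_rank: np.ndarray   # (V,) int in 1..30
    null_mask: np.ndarray     # (V,) bool — True where no signal is generated

    @property
    def n_voxels(self) -> int:
        return len(self.gen_lr_rank)

    def region(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.region_label == name)


@dataclass
class SyntheticDataset:
    """Voxel x volume signal matrix plus lossless ground truth."""

    Y: np.ndarray             # (V, n_volumes)
    layout: VoxelLayout
    truth: dict = field(default_factory=dict)
    regime_mode: str = "none"
    seed: int = 0


def make_nuisance(n_volumes: int, n_series: int = 6, seed: int = 0,
                  smooth: float = 10.0) -> np.ndarray:
    """Six smooth motion-like nuisance series (unit variance)."""
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n_volumes + 4 * int(smooth), n_series))
    kernel = np.exp(-0.5 * (np.arange(-3 * smooth, 3 * smooth + 1) / smooth) ** 2)
    kernel /= kernel.sum()
    sm = np.column_stack([np.convolve(w[:, j], kernel, mode="same")
                          for j in range(n_series)])
    sm = sm[2 * int(smooth): 2 * int(smooth) + n_volumes]
    sm -= sm.mean(axis=0)
    sd = sm.std(axis=0)
    return sm / np.where(sd == 0, 1.0, sd)


def make_region_layout(specs: list[RegionSpec], seed: int = 0) -> VoxelLayout:
    """Lay out regions on integer grids with affine rank gradients.

    ranks = clip(round(intercept + slope * (axis coordinate - min) + jitter),
    1, 30).
    """
    rng = np.random.default_rng(seed)
    coords_all, labels, ranks, nulls = [], [], [], []
    axis_idx = {"x": 0, "y": 1, "z": 2}
    for spec in specs:
        if min(spec.shape) < 1:
            raise ValueError(f"degenerate geometry for region {spec.name!r}")
        ax = axis_idx[spec.gradient_axis]
        grid = np.indices(spec.shape).reshape(3, -1).T + np.asarray(spec.origin)
        rel = grid[:, ax] - grid[:, ax].min()
        jitter = rng.normal(0.0, spec.rank_jitter_sd, size=len(grid)) \
            if spec.rank_jitter_sd > 0 else 0.0
        r = np.clip(np.round(spec.intercept_rank + spec.gradient_slope * rel
                             + jitter), 1, N_RANKS).astype(int)
        coords_all.append(grid)
        labels.append(np.full(len(grid), spec.name))
        ranks.append(r)
        nulls.append(np.full(len(grid), spec.is_null))
    return VoxelLayout(coords=np.vstack(coords_all),
                       region_label=np.concatenate(labels),
                       gen_lr_rank=np.concatenate(ranks),
                       null_mask=np.concatenate(nulls))


def _ar1_noise(rng, V, n, sigma, phi):
    eps = rng.standard_normal((V, n)) * sigma
    if phi == 0:
        return eps
    out = np.empty_like(eps)
    out[:, 0] = eps[:, 0] / np.sqrt(1.0 - phi ** 2)
    for t in range(1, n):
        out[:, t] = phi * out[:, t - 1] + eps[:, t]
    return out


def synthesize_bold(layout: VoxelLayout,
                    bank: RegressorBank,
                    session: BehaviorSession | None = None,
                    regime_mode: str = "none",
                    value_r2: float = 0.08,
                    pe_r2: float = 0.02,
                    shift_delta: int = 5,
                    gain_factor: float = 2.0,
                    nuisance: np.ndarray | None = None,
                    nuisance_amp: float = 0.5,
                    noise_sd: float = 1.0,
                    ar1_phi: float = 0.3,
                    seed: int = 0) -> SyntheticDataset:
    """Generate voxel time series from a layout and a 30-LR regressor bank.

    Signal amplitudes are calibrated per voxel so the value regressor
    explains ``value_r2`` of the non-value variance (default ~8%, a weak
    fMRI-like effect) and the PE regressor ``pe_r2``.  ``regime_mode``
    requires ``session`` for the sub-session boundary (shift/gain/combined).
    """
    if regime_mode not in ("none", "shift", "gain", "combined"):
        raise ValueError(f"unknown regime_mode {regime_mode!r}")
    if regime_mode != "none" and session is None:
        raise ValueError("regime modes need the behavior session for the boundary")
    if layout.gen_lr_rank.min() < 1 or layout.gen_lr_rank.max() > bank.n_lr:
        raise ValueError("generative ranks outside the bank's grid")

    rng = np.random.default_rng(seed)
    V = layout.n_voxels
    n = bank.X_value.shape[0]

    if nuisance is None:
        nuisance = make_nuisance(n, seed=seed + 1)
    loadings = rng.normal(0.0, nuisance_amp, size=(V, nuisance.shape[1]))
    base_part = loadings @ nuisance.T
    noise = _ar1_noise(rng, V, n, noise_sd, ar1_phi)
    Y = base_part + noise

    # segment masks at volume resolution
    if session is not None:
        segs = subsession_segments(session)
        stable_mask = np.zeros(n, dtype=bool)
        sl = segs["stable"]["volumes"]
        stable_mask[sl] = True
        volatile_mask = ~stable_mask
    else:
        stable_mask = volatile_mask = None

    ranks = layout.gen_lr_rank.copy()
    ranks_volatile = ranks.copy()
    if regime_mode in ("shift", "combined"):
        ranks_volatile = np.clip(ranks + shift_delta, 1, bank.n_lr)

    rest_var = base_part.var(axis=1) + noise_sd ** 2 / (1.0 - ar1_phi ** 2)
    a_value = np.sqrt(value_r2 / (1.0 - value_r2) * rest_var)
    a_pe = np.sqrt(pe_r2 / (1.0 - pe_r2) * rest_var)
    a_value[layout.null_mask] = 0.0
    a_pe[layout.null_mask] = 0.0

    def _segment_standardize(x):
        # hold the *standardized* effect size constant within each segment:
        # amplitude in raw units may differ across segments, the beta of a
        # unit-variance segment regressor does not
        if stable_mask is None:
            return x
        out = x.copy()
        for mask in (stable_mask, volatile_mask):
            seg = out[mask]
            sd = seg.std()
            out[mask] = (seg - seg.mean()) / (sd if sd > 0 else 1.0)
        return out

    high = ranks > bank.n_lr // 2
    for v in range(V):
        if a_value[v] == 0 and a_pe[v] == 0:
            continue
        xv = bank.X_value[:, ranks[v] - 1].copy()
        xp = bank.X_pe[:, ranks[v] - 1].copy()
        if regime_mode in ("shift", "combined") and ranks_volatile[v] != ranks[v]:
            xv[volatile_mask] = bank.X_value[volatile_mask, ranks_volatile[v] - 1]
            xp[volatile_mask] = bank.X_pe[volatile_mask, ranks_volatile[v] - 1]
        xv = _segment_standardize(xv)
        xp = _segment_standardize(xp)
        gain = np.ones(n)
        if regime_mode in ("gain", "combined"):
            gain[volatile_mask if high[v] else stable_mask] = gain_factor
        Y[v] += a_value[v] * gain * xv + a_pe[v] * xp

    truth = dict(a_value=a_value, a_pe=a_pe, noise_sd=noise_sd, ar1_phi=ar1_phi,
                 nuisance_loadings=loadings, gen_rank_stable=ranks,
                 gen_rank_volatile=ranks_volatile, shift_delta=shift_delta,
                 gain_factor=gain_factor, value_r2=value_r2, pe_r2=pe_r2)
    return SyntheticDataset(Y=Y, layout=layout, truth=truth,
                            regime_mode=regime_mode, seed=seed)


def subsession_masks(session: BehaviorSession, n_volumes: int) -> list[np.ndarray]:
    """Boolean volume masks [stable, volatile] for a session's segments."""
    segs = subsession_segments(session)
    masks = []
    for label in ("stable", "volatile"):
        m = np.zeros(n_volumes, dtype=bool)
        m[segs[label]["volumes"]] = True
        masks.append(m)
    return masks


def inject_shared_bins(dataset: SyntheticDataset,
                       base: DesignMatrix,
                       bank: RegressorBank,
                       regions: tuple[str, str],
                       strength: float = 0.5,
                       rank_corr_sd: float = 1.5,
                       temporal_smooth: float = 2.0,
                       segment_masks: list[np.ndarray] | None = None,
                       seed: int = 0) -> SyntheticDataset:
    """Add rank-matched shared fluctuations to two regions (in place).

    One latent series per rank, correlated across neighboring ranks (Gaussian
    kernel of width ``rank_corr_sd`` ranks), temporally smoothed, then
    orthogonalized against the base design and all 60 LR/PE regressors (per
    segment, if ``segment_masks`` is given) so the component is invisible to
    the GLM and survives residualization.  ``strength`` is the component's
    standard deviation in voxel-signal units.
    """
    rng = np.random.default_rng(seed)
    n = dataset.Y.shape[1]
    n_ranks = bank.n_lr

    lat = rng.standard_normal((n_ranks + 12, n + 40))
    # correlate across the rank axis
    rk = np.exp(-0.5 * (np.arange(-6, 7) / rank_corr_sd) ** 2)
    rk /= np.sqrt(np.sum(rk ** 2))
    lat = np.apply_along_axis(lambda c: np.convolve(c, rk, mode="valid"), 0, lat)
    # light temporal smoothing for a plausible spectrum
    tk = np.exp(-0.5 * (np.arange(-6, 7) / temporal_smooth) ** 2)
    tk /= np.sqrt(np.sum(tk ** 2))
    lat = np.apply_along_axis(lambda r: np.convolve(r, tk, mode="same"), 1, lat)
    lat = lat[:n_ranks, 20: 20 + n]

    from .connectivity import full_lr_design
    design = full_lr_design(base, bank, segment_masks)
    Q, _ = np.linalg.qr(design)
    lat = lat - (lat @ Q) @ Q.T
    lat -= lat.mean(axis=1, keepdims=True)
    lat /= lat.std(axis=1, keepdims=True)

    for name in regions:
        vox = dataset.layout.region(name)
        r = dataset.layout.gen_lr_rank[vox]
        dataset.Y[vox] += strength * lat[r - 1]
    dataset.truth.setdefault("shared_bins", {})[regions] = dict(
        strength=strength, rank_corr_sd=rank_corr_sd, seed=seed, latent=lat)
    return dataset
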