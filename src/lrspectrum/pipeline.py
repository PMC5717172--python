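"""End-to-end orchestration: simulate a group, map learning rates, and run
the evidence, topography, volatility and connectivity analyses.

The pipeline is deterministic given the config's master seed: subject s
draws its task, agent, layout and noise seeds from ``seed + s`` offsets.
Every stage is also callable on its own from the per-subject intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import AgentParams, TimingConfig, make_schedule, simulate_agent
from .value import LR_GRID_FULL, compute_value_traces
from .regressors import (CANONICAL_LR30, build_design_matrix,
                         build_regressor_bank)
from .glm import map_best_lr, subsession_segments
from .simulate import (RegionSpec, make_nuisance, make_region_layout,
                       subsession_masks, synthesize_bold, inject_shared_bins)
from .evidence import component_regressors, evidence_map, svd_components
from .topography import group_gradient_test, group_topography_test
from .volatility import beta_lr_coupling, lr_shift
from .connectivity import (bin_correlation_matrix, bin_residuals_by_lr,
                           diagonal_affinity_test, residualize)

logger = logging.getLogger("lrspectrum")

__all__ = ["PipelineConfig", "SubjectData", "simulate_subject",
           "simulate_group", "run_full_pipeline", "export_map_tsv",
           "export_map_nifti", "generate_fixture"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips through YAML losslessly."""

    n_subjects: int = 17
    n_volatile_trials: int = 60
    # regions: (name, shape, slope, intercept, jitter, is_null)
    region_a_shape: tuple[int, int, int] = (4, 10, 5)
    region_b_shape: tuple[int, int, int] = (4, 10, 5)
    null_shape: tuple[int, int, int] = (4, 5, 5)
    gradient_slope: float = 2.5
    intercept_rank: float = 4.0
    rank_jitter_sd: float = 3.0
    value_r2: float = 0.08
    pe_r2: float = 0.02
    regime_mode: str = "none"
    shift_delta: int = 5
    gain_factor: float = 2.0
    noise_sd: float = 1.0
    ar1_phi: float = 0.3
    connectivity_strength: float = 0.5
    n_perm: int = 10_000
    whiten: bool = True
    seed: int = 0
    stages: tuple[str, ...] = ("map", "evidence", "topography",
                               "volatility", "connectivity")

    def __post_init__(self):
        if not isinstance(self.n_subjects, int) or self.n_subjects < 1:
            raise ValueError(f"n_subjects must be a positive int, got "
                             f"{self.n_subjects!r}")
        if not isinstance(self.n_perm, int) or self.n_perm < 1:
            raise ValueError(f"n_perm must be a positive int, got "
                             f"{self.n_perm!r}")
        if self.regime_mode not in ("none", "shift", "gain", "combined"):
            raise ValueError(f"unknown regime_mode {self.regime_mode!r}")
        for name in ("value_r2", "pe_r2", "noise_sd", "ar1_phi",
                     "connectivity_strength", "gradient_slope"):
            if not isinstance(getattr(self, name), (int, float)):
                raise ValueError(f"{name} must be numeric")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("region_a_shape", "region_b_shape", "null_shape", "stages"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SubjectData:
    """All per-subject intermediates."""

    session: object
    traces: object
    design: object            # base DesignMatrix (whole session)
    bank30: object            # RegressorBank on the 30-grid (whole session)
    layout: object
    dataset: object
    nuisance: np.ndarray
    subject_id: int


def _region_specs(cfg: PipelineConfig) -> list[RegionSpec]:
    specs = [
        RegionSpec("regionA", shape=cfg.region_a_shape, origin=(0, 0, 0),
                   gradient_axis="y", gradient_slope=cfg.gradient_slope,
                   intercept_rank=cfg.intercept_rank,
                   rank_jitter_sd=cfg.rank_jitter_sd),
        RegionSpec("regionB", shape=cfg.region_b_shape, origin=(20, 0, 0),
                   gradient_axis="y", gradient_slope=cfg.gradient_slope,
                   intercept_rank=cfg.intercept_rank,
                   rank_jitter_sd=cfg.rank_jitter_sd),
    ]
    if np.prod(cfg.null_shape) > 0:
        specs.append(RegionSpec("null_region", shape=cfg.null_shape,
                                origin=(40, 0, 0), is_null=True))
    return specs


def simulate_subject(cfg: PipelineConfig, s: int,
                     inject_connectivity: bool = False) -> SubjectData:
    """Simulate one subject: behavior, regressors, layout, voxel data."""
    base_seed = cfg.seed + 1000 * s
    order = "stable_first" if s % 2 == 0 else "volatile_first"
    rng = np.random.default_rng(base_seed)
    schedule = make_schedule(order, cfg.n_volatile_trials, seed=base_seed + 1)
    params = AgentParams(agent_lr=float(rng.uniform(0.15, 0.5)),
                         inverse_temperature=float(rng.uniform(3.0, 8.0)))
    session = simulate_agent(schedule, params, TimingConfig(), seed=base_seed + 2)
    traces = compute_value_traces(session, CANONICAL_LR30)
    nuisance = make_nuisance(session.n_volumes, seed=base_seed + 3)
    design = build_design_matrix(session, nuisance=nuisance)
    bank30 = build_regressor_bank(session, traces)
    layout = make_region_layout(_region_specs(cfg), seed=base_seed + 4)
    dataset = synthesize_bold(layout, bank30, session=session,
                              regime_mode=cfg.regime_mode,
                              value_r2=cfg.value_r2, pe_r2=cfg.pe_r2,
                              shift_delta=cfg.shift_delta,
                              gain_factor=cfg.gain_factor,
                              nuisance=nuisance, noise_sd=cfg.noise_sd,
                              ar1_phi=cfg.ar1_phi, seed=base_seed + 5)
    if inject_connectivity and cfg.connectivity_strength > 0:
        masks = subsession_masks(session, session.n_volumes)
        inject_shared_bins(dataset, design, bank30, ("regionA", "regionB"),
                           strength=cfg.connectivity_strength,
                           segment_masks=masks, seed=base_seed + 6)
    return SubjectData(session=session, traces=traces, design=design,
                       bank30=bank30, layout=layout, dataset=dataset,
                       nuisance=nuisance, subject_id=s)


def simulate_group(cfg: PipelineConfig,
                   inject_connectivity: bool = False) -> list[SubjectData]:
    return [simulate_subject(cfg, s, inject_connectivity)
            for s in range(cfg.n_subjects)]


def _subsession_maps(sub: SubjectData, whiten: bool):
    """Best-LR maps for the stable and volatile segments of one subject."""
    session = sub.session
    segs = subsession_segments(session)
    maps = {}
    for label, seg in segs.items():
        vol, idx = seg["volumes"], seg["trials"]
        design = build_design_matrix(session, nuisance=sub.nuisance,
                                     volumes=vol, trials=idx)
        bank = build_regressor_bank(session, sub.traces, volumes=vol, trials=idx)
        Y = sub.dataset.Y[:, vol]
        maps[label] = map_best_lr(Y, design, bank, whiten=whiten,
                                  session_tag=label)
    return maps


def run_full_pipeline(cfg: PipelineConfig,
                      outdir: str | Path | None = None) -> dict:
    """Run every enabled stage in dependency order; returns the run report."""
    t_start = time.time()
    report: dict = {"config": dataclasses.asdict(cfg), "stages": {}, "outputs": {}}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(outdir / "config.yaml")

    need_conn = "connectivity" in cfg.stages
    logger.info("simulating %d subjects", cfg.n_subjects)
    group = simulate_group(cfg, inject_connectivity=need_conn)
    signal_vox = [np.flatnonzero(~g.layout.null_mask) for g in group]

    maps_whole = None
    if "map" in cfg.stages:
        t0 = time.time()
        maps_whole = [map_best_lr(g.dataset.Y, g.design, g.bank30,
                                  whiten=cfg.whiten) for g in group]
        report["stages"]["map"] = {
            "mean_abs_rank_error": float(np.mean([
                np.mean(np.abs(m.best_rank[v] - g.layout.gen_lr_rank[v]))
                for m, g, v in zip(maps_whole, group, signal_vox)])),
            "wall_s": round(time.time() - t0, 2)}
        if outdir is not None:
            for m, g in zip(maps_whole, group):
                export_map_tsv(m, g.layout,
                               outdir / f"sub-{g.subject_id:02d}_lrmap.tsv")
            report["outputs"]["lr_maps"] = str(outdir)
        logger.info("map stage done: %s", report["stages"]["map"])

    if "evidence" in cfg.stages:
        t0 = time.time()
        subject_data = []
        for g in group:
            traces99 = compute_value_traces(g.session, LR_GRID_FULL)
            svd = svd_components(traces99.p_chosen, m=3)
            comps = component_regressors(svd, g.session, g.session.TR)
            subject_data.append(dict(Y=g.dataset.Y, base=g.design,
                                     components=comps))
        ev = evidence_map(subject_data, whiten=cfg.whiten)
        null_vox = np.flatnonzero(group[0].layout.null_mask)
        report["stages"]["evidence"] = {
            "median_pxp_signal": float(np.median(ev["pxp"][signal_vox[0]])),
            "frac_null_above_95": float(np.mean(ev["pxp"][null_vox] > 0.95))
            if len(null_vox) else None,
            "wall_s": round(time.time() - t0, 2)}
        report["outputs"]["pxp"] = ev["pxp"].tolist() if outdir is None else None
        if outdir is not None:
            pd.DataFrame({"voxel": np.arange(len(ev["pxp"])),
                          "pxp": ev["pxp"], "bor": ev["bor"]}).to_csv(
                outdir / "pxp_map.tsv", sep="\t", index=False)
            report["outputs"]["pxp"] = str(outdir / "pxp_map.tsv")
        logger.info("evidence stage done: %s", report["stages"]["evidence"])

    if "topography" in cfg.stages:
        if maps_whole is None:
            raise RuntimeError("topography stage needs the map stage enabled")
        t0 = time.time()
        lrm = [type("M", (), {"best_rank": m.best_rank[v]})()
               for m, v in zip(maps_whole, signal_vox)]
        coords = [g.layout.coords[v] for g, v in zip(group, signal_vox)]
        topo = group_topography_test(lrm, coords, n_perm=cfg.n_perm,
                                     seed=cfg.seed + 77)
        gt, gp = group_gradient_test(topo.coefficients, axis="y")
        report["stages"]["topography"] = {
            "mean_r2_true": float(topo.r2_true.mean()),
            "mean_r2_perm": float(topo.r2_perm_mean.mean()),
            "group_t": topo.group_t, "group_p": topo.group_p,
            "gradient_t": gt, "gradient_p": gp,
            "wall_s": round(time.time() - t0, 2)}
        logger.info("topography stage done: %s", report["stages"]["topography"])

    if "volatility" in cfg.stages:
        t0 = time.time()
        maps_stable, maps_volatile = [], []
        for g in group:
            m = _subsession_maps(g, cfg.whiten)
            maps_stable.append(m["stable"])
            maps_volatile.append(m["volatile"])
        shift = lr_shift(maps_stable, maps_volatile)
        coupling = beta_lr_coupling(maps_stable, maps_volatile)
        report["stages"]["volatility"] = {
            "mean_delta_rank": float(shift.subject_mean_delta.mean()),
            "shift_t": shift.t, "shift_p": shift.p,
            "mean_delta_z": float(coupling.delta_z.mean()),
            "coupling_t": coupling.t, "coupling_p": coupling.p,
            "wall_s": round(time.time() - t0, 2)}
        logger.info("volatility stage done: %s", report["stages"]["volatility"])

    if "connectivity" in cfg.stages:
        if maps_whole is None:
            raise RuntimeError("connectivity stage needs the map stage enabled")
        t0 = time.time()
        z_mats = []
        for g, m in zip(group, maps_whole):
            masks = subsession_masks(g.session, g.session.n_volumes)
            resid = residualize(g.dataset.Y, g.design, g.bank30,
                                segment_masks=masks)
            bins_a = bin_residuals_by_lr(resid, m, g.layout.region("regionA"))
            bins_b = bin_residuals_by_lr(resid, m, g.layout.region("regionB"))
            z_mats.append(bin_correlation_matrix(bins_a, bins_b))
        conn = diagonal_affinity_test(z_mats)
        report["stages"]["connectivity"] = {
            "mean_diag_corr": float(conn.diag_corr.mean()),
            "t": conn.t, "p": conn.p,
            "wall_s": round(time.time() - t0, 2)}
        if outdir is not None:
            np.savetxt(outdir / "group_mean_zmatrix.tsv",
                       np.nanmean(np.stack(z_mats), axis=0), delimiter="\t")
            report["outputs"]["zmatrix"] = str(outdir / "group_mean_zmatrix.tsv")
        logger.info("connectivity stage done: %s", report["stages"]["connectivity"])

    report["wall_s_total"] = round(time.time() - t_start, 2)
    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report


def export_map_tsv(lr_map, layout, path: str | Path) -> None:
    """Write a best-LR map as TSV (voxel_id, x, y, z, region, rank, beta)."""
    df = pd.DataFrame({
        "voxel_id": np.arange(layout.n_voxels),
        "x": layout.coords[:, 0], "y": layout.coords[:, 1],
        "z": layout.coords[:, 2], "region": layout.region_label,
        "best_rank": lr_map.best_rank, "best_beta": lr_map.best_beta,
    })
    df.to_csv(path, sep="\t", index=False)


def export_map_nifti(values: np.ndarray, layout, path: str | Path) -> None:
    """Write per-voxel values as a NIfTI volume on the layout's integer grid."""
    import nibabel as nib
    coords = layout.coords - layout.coords.min(axis=0)
    shape = coords.max(axis=0) + 1
    vol = np.zeros(shape, dtype=float)
    if len(np.unique(coords, axis=0)) != len(coords):
        raise ValueError("layout voxels do not form a unique grid; use TSV export")
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = values
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def generate_fixture(cfg: PipelineConfig, outdir: str | Path) -> list[Path]:
    """Write per-subject events TSV, voxel data and ground truth to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in range(cfg.n_subjects):
        sub = simulate_subject(cfg, s)
        d = outdir / f"sub-{s:02d}"
        d.mkdir(exist_ok=True)
        sub.session.to_tsv(d / "events.tsv")
        np.save(d / "bold.npy", sub.dataset.Y)
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in sub.dataset.truth.items()
                 if not isinstance(v, dict)}
        truth["gen_lr_rank"] = sub.layout.gen_lr_rank.tolist()
        truth["seed"] = int(sub.dataset.seed)
        (d / "truth.json").write_text(json.dumps(truth, indent=1))
        paths.append(d)
    return paths
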