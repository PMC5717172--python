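"""Reference simulation studies: the recomputable headline numbers.

Each function simulates a full study from scratch at the task's standard
conditions (17 subjects, 60 stable + 60 volatile trials, TR 3 s) and
returns the summary quantity the pipeline is built around:

* ``run_svd_compression`` — how much of the 99 trial-level value traces'
  variance the first three singular vectors capture (about 99.6%);
* ``run_grid_selection`` — the 30-element correlation-equalized
  learning-rate grid averaged over subjects and (sub-)sessions;
* ``run_evidence_detection`` — group protected exceedance probabilities in
  a signal region versus a null region;
* ``run_lr_recovery`` — how well the 30-GLM mapping recovers generative
  learning-rate ranks at a given signal strength.
"""

from __future__ import annotations

import numpy as np

from .task import AgentParams, TimingConfig, make_schedule, simulate_agent
from .value import LR_GRID_FULL, compute_value_traces
from .regressors import build_design_matrix, build_regressor_bank, select_lr_grid
from .glm import map_best_lr, subsession_segments
from .simulate import RegionSpec, make_nuisance, make_region_layout, synthesize_bold
from .evidence import component_regressors, evidence_map, svd_components

__all__ = ["simulate_agent_session", "run_svd_compression",
           "run_grid_selection", "run_evidence_detection", "run_lr_recovery"]


def simulate_agent_session(s: int, seed: int):
    """One synthetic subject's behavior session (heterogeneous agents,
    counterbalanced sub-session order)."""
    base = seed + 1000 * s
    rng = np.random.default_rng(base)
    order = "stable_first" if s % 2 == 0 else "volatile_first"
    schedule = make_schedule(order, 60, seed=base + 1)
    params = AgentParams(agent_lr=float(rng.uniform(0.15, 0.5)),
                         inverse_temperature=float(rng.uniform(3.0, 8.0)))
    return simulate_agent(schedule, params, TimingConfig(), seed=base + 2)


def run_svd_compression(n_agents: int = 17, seed: int = 0) -> dict:
    """Top-3 SVD variance fraction of the 99 trial-level p(chosen) traces."""
    fracs = []
    for s in range(n_agents):
        session = simulate_agent_session(s, seed)
        traces = compute_value_traces(session, LR_GRID_FULL)
        fracs.append(svd_components(traces.p_chosen, m=3).top_fraction)
    fracs = np.asarray(fracs)
    return {"top3_pct_mean": float(100.0 * fracs.mean()),
            "top3_pct_per_agent": (100.0 * fracs).tolist()}


def run_grid_selection(n_agents: int = 17, seed: int = 0) -> dict:
    """The correlation-equalized 30-LR grid from whole-session and
    sub-session regressor banks of every agent."""
    banks = []
    for s in range(n_agents):
        session = simulate_agent_session(s, seed)
        traces = compute_value_traces(session, LR_GRID_FULL)
        banks.append(build_regressor_bank(session, traces).X_value)
        for seg in subsession_segments(session).values():
            bank = build_regressor_bank(session, traces,
                                        volumes=seg["volumes"],
                                        trials=seg["trials"])
            banks.append(bank.X_value)
    grid = select_lr_grid(banks, LR_GRID_FULL, k=30)
    return {"grid": grid.tolist(),
            "position_15": float(grid[14]),
            "position_20": float(grid[19]),
            "n_banks": len(banks)}


def run_evidence_detection(n_subjects: int = 17, n_signal_vox: int = 200,
                           n_null_vox: int = 100, value_r2: float = 0.08,
                           seed: int = 0) -> dict:
    """Group PXP of the LR-component model in signal vs null voxels."""
    subs = []
    for s in range(n_subjects):
        base = seed + 1000 * s
        session = simulate_agent_session(s, seed)
        traces30 = compute_value_traces(session)
        bank = build_regressor_bank(session, traces30)
        nuis = make_nuisance(session.n_volumes, seed=base + 3)
        design = build_design_matrix(session, nuisance=nuis)
        layout = make_region_layout(
            [RegionSpec("signal", shape=(n_signal_vox, 1, 1),
                        gradient_slope=0.0, intercept_rank=15.0,
                        rank_jitter_sd=8.0),
             RegionSpec("null_region", shape=(n_null_vox, 1, 1),
                        origin=(n_signal_vox + 10, 0, 0), is_null=True)],
            seed=base + 4)
        ds = synthesize_bold(layout, bank, value_r2=value_r2, nuisance=nuis,
                             seed=base + 5)
        traces99 = compute_value_traces(session, LR_GRID_FULL)
        svd = svd_components(traces99.p_chosen, m=3)
        comps = component_regressors(svd, session, session.TR)
        subs.append(dict(Y=ds.Y, base=design, components=comps,
                         layout=layout))
    ev = evidence_map(subs)
    sig = subs[0]["layout"].region("signal")
    nul = subs[0]["layout"].region("null_region")
    return {"median_pxp_signal": float(np.median(ev["pxp"][sig])),
            "frac_null_above_95": float(np.mean(ev["pxp"][nul] > 0.95)),
            "median_pxp_null": float(np.median(ev["pxp"][nul]))}


def run_lr_recovery(value_r2: float = 0.08, n_voxels: int = 500,
                    seed: int = 0) -> dict:
    """Spearman correlation and mean error of recovered vs generative ranks."""
    from scipy.stats import spearmanr
    session = simulate_agent_session(0, seed)
    traces30 = compute_value_traces(session)
    bank = build_regressor_bank(session, traces30)
    nuis = make_nuisance(session.n_volumes, seed=seed + 3)
    design = build_design_matrix(session, nuisance=nuis)
    layout = make_region_layout(
        [RegionSpec("r", shape=(n_voxels, 1, 1), gradient_slope=0.0,
                    intercept_rank=15.0, rank_jitter_sd=8.0)], seed=seed + 4)
    ds = synthesize_bold(layout, bank, value_r2=value_r2, nuisance=nuis,
                         seed=seed + 5)
    m = map_best_lr(ds.Y, design, bank)
    rho = spearmanr(m.best_rank, layout.gen_lr_rank).statistic
    err = float(np.mean(np.abs(m.best_rank - layout.gen_lr_rank)))
    return {"spearman": float(rho), "mean_abs_rank_error": err}
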