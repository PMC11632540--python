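"""Desk-scale reproduction protocols for the published scenario table.

The published headline numbers are medians/IQRs over an unpublished
sensitivity design, so reproduction is statistical, not exact: sweep 64
quasi-random draws of the published parameter ranges, 3 replicates with
common random numbers, at population scale 0.1, and compare scenario-group
medians with the published medians/IQRs. These helpers exist so that the
validation suite and any external re-run use one protocol.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import ModelConfig, load_config
from .outcomes import per_draw_metrics, summarize_over_draws
from .params import default_ranges, sample_parameter_draws, scenario_grid
from .runner import SweepDesign, run_sweep

__all__ = ["reference_sweep", "pooled_median", "scenario_median"]


def _desk_config(scale: float, replicates: int, seed: int) -> ModelConfig:
    cfg = load_config(None)
    return dataclasses.replace(
        cfg, sim=dataclasses.replace(cfg.sim, population_scale=scale,
                                     replicates=replicates, seed=seed))


def reference_sweep(seed: int, n_draws: int = 64, replicates: int = 3,
                    scale: float = 0.1, scenario_ids=None,
                    method: str = "sobol_sequence",
                    fix: dict | None = None, progress: bool = False):
    """Run the desk-scale sweep protocol.

    Returns (per-draw metrics frame, per-scenario summary frame). `fix`
    collapses named parameter ranges to points (e.g. a bystander-presence
    probability pinned at its upper bound).
    """
    cfg = _desk_config(scale, replicates, seed)
    ranges = default_ranges()
    if fix:
        ranges = ranges.fix(**fix)
    draws = sample_parameter_draws(ranges, n_draws, method=method, seed=seed)
    grid = scenario_grid()
    scens = grid if scenario_ids is None else [s for s in grid
                                              if s.id in set(scenario_ids)]
    design = SweepDesign(param_draws=draws, scenarios=scens,
                         replicates=replicates, base_seed=seed)
    sweep = run_sweep(design, cfg, progress=progress)
    metrics = per_draw_metrics(sweep, cfg.economics)
    summaries = summarize_over_draws(sweep, cfg.economics)
    return metrics, summaries


def pooled_median(metrics: pd.DataFrame, scenario_ids, column: str) -> float:
    """Median of per-draw metric values pooled over a scenario group."""
    v = metrics[metrics["scenario_id"].isin(set(scenario_ids))][column]
    v = v.dropna()
    return float(np.median(v)) if len(v) else float("nan")


def scenario_median(summaries: pd.DataFrame, scenario_id: int,
                    column: str) -> float:
    row = summaries[summaries["scenario_id"] == scenario_id]
    return float(row[f"{column}_median"].iloc[0])
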