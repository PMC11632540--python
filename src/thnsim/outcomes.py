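"""Outcome metrics: deaths averted, cost per death averted, NNT, summaries.

All comparisons are against the no-distribution baseline (scenario 1) at
matched parameter draws and common random numbers. Metrics are computed per
draw on replicate-averaged counts, then summarised across draws as median and
IQR (25th/75th percentile, linear interpolation); draws with zero baseline
deaths propagate as missing and are excluded with their count reported.
Per draw, cost per death averted = kit cost x NNT exactly, and both use the
kit total *including* immediate replacements; the replacement-free total is
reported alongside. Kit counts are rescaled to the unscaled population when
a desk-scale run used population_scale < 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import BASELINE_SCENARIO_ID, EconomicParams
from .runner import RunResult

__all__ = [
    "deaths_averted_pct",
    "nnt",
    "cost_per_death_averted",
    "per_draw_metrics",
    "summarize_over_draws",
    "table2_report",
]


def _check_provenance(run: RunResult, baseline: RunResult) -> None:
    if (run.param_draw_id != baseline.param_draw_id
            or run.replicate_id != baseline.replicate_id
            or run.seed != baseline.seed):
        raise ValueError("run and baseline must share (draw, replicate, seed) provenance")


def deaths_averted_pct(run: RunResult, baseline: RunResult,
                       population: str = "all") -> float:
    """100 x (baseline deaths - scenario deaths) / baseline deaths.

    `population` selects 'all' or 'released' (persons with >=1 release during
    the horizon). Returns NaN when the baseline has zero deaths.
    """
    _check_provenance(run, baseline)
    if population == "all":
        b, r = baseline.deaths_total, run.deaths_total
    elif population == "released":
        b, r = baseline.deaths_released, run.deaths_released
    else:
        raise ValueError("population must be 'all' or 'released'")
    if b == 0:
        return float("nan")
    return 100.0 * (b - r) / b


def nnt(run: RunResult, baseline: RunResult) -> float:
    """Kits distributed (incl. replacements) per death averted vs baseline."""
    _check_provenance(run, baseline)
    averted = baseline.deaths_total - run.deaths_total
    if averted <= 0:
        return float("nan")
    return run.ledger.total / averted


def cost_per_death_averted(run: RunResult, baseline: RunResult,
                           econ: EconomicParams) -> float:
    """kit_cost x kits / deaths averted; equals the ICER vs the zero-cost
    baseline. Missing when no deaths are averted."""
    return econ.kit_cost * nnt(run, baseline)


def per_draw_metrics(sweep: pd.DataFrame, econ: EconomicParams) -> pd.DataFrame:
    """Per-(draw, scenario) metrics from a tidy sweep table.

    Requires baseline rows (scenario 1) for every draw. Kit totals are
    rescaled by 1/scale so they refer to the unscaled population.
    """
    base = sweep[sweep["scenario_id"] == BASELINE_SCENARIO_ID]
    if base.empty:
        raise ValueError("sweep table has no baseline (scenario 1) rows")
    base = base.set_index("param_draw_id")
    df = sweep.copy()
    df["base_deaths"] = df["param_draw_id"].map(base["deaths_total"])
    df["base_deaths_released"] = df["param_draw_id"].map(base["deaths_released"])
    upscale = 1.0 / df["scale"]
    df["kits_total_upscaled"] = df["kits_total"] * upscale
    df["kits_initial_upscaled"] = (df["kits_total"] - df["kits_replacement"]) * upscale

    averted = df["base_deaths"] - df["deaths_total"]
    averted_rel = df["base_deaths_released"] - df["deaths_released"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["pct_deaths_averted"] = np.where(
            df["base_deaths"] > 0, 100.0 * averted / df["base_deaths"], np.nan)
        df["pct_deaths_averted_released"] = np.where(
            df["base_deaths_released"] > 0,
            100.0 * averted_rel / df["base_deaths_released"], np.nan)
        df["nnt"] = np.where(averted > 0, df["kits_total_upscaled"]
                             / (averted * upscale), np.nan)
    df["cost_per_death_averted"] = econ.kit_cost * df["nnt"]
    df["icer"] = df["cost_per_death_averted"]
    # the baseline compared with itself averts nothing, by definition
    is_base = df["scenario_id"] == BASELINE_SCENARIO_ID
    df.loc[is_base, ["pct_deaths_averted", "pct_deaths_averted_released"]] = 0.0
    df.loc[is_base, ["nnt", "cost_per_death_averted", "icer"]] = np.nan
    return df


_METRICS = ["kits_total_upscaled", "pct_deaths_averted",
            "pct_deaths_averted_released", "cost_per_death_averted", "nnt", "icer"]


def summarize_over_draws(sweep: pd.DataFrame, econ: EconomicParams) -> pd.DataFrame:
    """Median and IQR across parameter draws, one row per scenario."""
    df = per_draw_metrics(sweep, econ)
    if df["param_draw_id"].nunique() < 2:
        raise ValueError("summaries require at least 2 parameter draws")
    rows = []
    for sid, g in df.groupby("scenario_id"):
        row = {"scenario_id": sid,
               "cov_community": g["cov_community"].iloc[0],
               "cov_jail": g["cov_jail"].iloc[0],
               "cov_network": g["cov_network"].iloc[0]}
        for m in _METRICS:
            v = g[m].to_numpy(dtype=float)
            ok = v[~np.isnan(v)]
            if ok.size == 0:
                row[f"{m}_median"] = np.nan
                row[f"{m}_q1"] = np.nan
                row[f"{m}_q3"] = np.nan
            else:
                row[f"{m}_median"] = float(np.percentile(ok, 50))
                row[f"{m}_q1"] = float(np.percentile(ok, 25))
                row[f"{m}_q3"] = float(np.percentile(ok, 75))
            row[f"{m}_n_missing"] = int(np.isnan(v).sum())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("scenario_id").reset_index(drop=True)


def _fmt_cost(x: float) -> str:
    return "NA" if np.isnan(x) else f"{int(round(x / 100.0) * 100)}"


def _fmt_nnt(x: float) -> str:
    return "NA" if np.isnan(x) else f"{x:.1f}"


def _fmt_kits(x: float) -> str:
    return "NA" if np.isnan(x) else f"{int(round(x))}"


def _fmt_pct(x: float) -> str:
    return "NA" if np.isnan(x) else f"{x:.2f}"


def table2_report(summaries: pd.DataFrame) -> pd.DataFrame:
    """Formatted scenario table: coverage triple (as %), kit counts, percent
    deaths averted, cost per death averted rounded to the nearest $100, NNT
    to one decimal — each as 'median (q1-q3)'."""
    out = []
    for _, r in summaries.iterrows():
        out.append({
            "scenario": int(r["scenario_id"]),
            "community_pct": f"{100 * r['cov_community']:g}",
            "jail_release_pct": f"{100 * r['cov_jail']:g}",
            "social_network_pct": f"{100 * r['cov_network']:g}",
            "kits_distributed": "%s (%s-%s)" % tuple(
                _fmt_kits(r[f"kits_total_upscaled_{k}"]) for k in ("median", "q1", "q3")),
            "pct_deaths_averted": "%s (%s-%s)" % tuple(
                _fmt_pct(r[f"pct_deaths_averted_{k}"]) for k in ("median", "q1", "q3")),
            "cost_per_death_averted": "%s (%s-%s)" % tuple(
                _fmt_cost(r[f"cost_per_death_averted_{k}"]) for k in ("median", "q1", "q3")),
            "nnt": "%s (%s-%s)" % tuple(
                _fmt_nnt(r[f"nnt_{k}"]) for k in ("median", "q1", "q3")),
        })
    return pd.DataFrame(out)
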