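"""Daily-tick orchestration: warm-up, horizon, replicates, scenario sweeps.

Day ordering (fixed): bookings -> releases -> jail/network kit distribution
-> overdose draws -> event resolution -> ledger and tallies. The warm-up
(default 90 days) runs jail dynamics and overdoses with no naloxone and its
tallies are discarded; the community kit assignment happens once at horizon
start; horizon tallies cover exactly the 365 reporting days.

Scenario comparisons use common random numbers: every run of the same
(parameter draw, replicate) cell shares one counter-based run key, so the
baseline and each intervention see identical bookings, stays, overdose draws
and bystander behaviour, diverging only where a kit changes an outcome. The
sweep exploits the fact that warm-up dynamics are scenario-independent:
each (draw, replicate) simulates the warm-up once, snapshots the state, and
replays every scenario's horizon from that snapshot.

A `population_scale` knob scales population sizes, the booking rate and the
census target jointly for desk-scale runs; counts in RunResult stay on the
scaled ledger and carry the scale so that downstream metrics can report
per-unscaled-population numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .config import ModelConfig, apply_draw
from .jail import JailState, fit_stay_lognormal, initialize_steady_state, step_bookings, step_releases
from .kits import (KitLedger, apply_community_distribution,
                   apply_jail_release_distribution, apply_network_distribution,
                   availability_and_use)
from .overdose import resolve_events, static_relative_risk
from .params import (BASELINE_SCENARIO_ID, InterventionScenario, ParamDraw,
                     scenario_grid)
from .population import NEVER, build_population
from .rng import (STREAM_BOOK_PICK, STREAM_OVERDOSE, STREAM_OVERDOSE_DYN,
                  STREAM_POPULATION, CrnSource, counter_uniform_matrix,
                  counter_uniforms, derive_run_key)

logger = logging.getLogger("thnsim")

__all__ = ["RunResult", "SweepDesign", "Simulation", "run_simulation",
           "run_replicates", "run_sweep", "scale_config"]


@dataclass
class RunResult:
    """Per-run tallies over the reporting horizon (scaled population)."""

    scenario_id: int
    param_draw_id: int
    replicate_id: int
    seed: int
    overdoses_total: float = 0.0
    deaths_total: float = 0.0
    overdoses_released: float = 0.0   # events among persons released during horizon
    deaths_released: float = 0.0
    ledger: KitLedger = field(default_factory=KitLedger)
    census_mean: float = 0.0
    scale: float = 1.0

    def check(self) -> None:
        assert self.deaths_total <= self.overdoses_total
        assert self.deaths_released <= self.overdoses_released <= self.overdoses_total

    def to_row(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "param_draw_id": self.param_draw_id,
            "replicate_id": self.replicate_id,
            "seed": self.seed,
            "overdoses_total": self.overdoses_total,
            "deaths_total": self.deaths_total,
            "overdoses_released": self.overdoses_released,
            "deaths_released": self.deaths_released,
            "kits_community": self.ledger.distributed_community,
            "kits_jail": self.ledger.distributed_jail,
            "kits_network": self.ledger.distributed_network,
            "kits_replacement": self.ledger.replacements,
            "kits_used": self.ledger.used,
            "kits_total": self.ledger.total,
            "census_mean": self.census_mean,
            "scale": self.scale,
        }


@dataclass(frozen=True)
class SweepDesign:
    """Parameter draws x scenarios x replicates, with derived seeds."""

    param_draws: list[ParamDraw]
    scenarios: list[InterventionScenario]
    replicates: int = 10
    base_seed: int = 1

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.param_draws:
            raise ValueError("at least one parameter draw is required")


def scale_config(cfg: ModelConfig) -> ModelConfig:
    """Apply sim.population_scale to population sizes and jail throughput."""
    s = cfg.sim.population_scale
    if s == 1.0:
        return cfg
    pop = dc_replace(cfg.population,
                     n_iou=int(round(cfg.population.n_iou * s)),
                     n_niou=int(round(cfg.population.n_niou * s)),
                     n_cli=int(round(cfg.population.n_cli * s)))
    jail = dc_replace(cfg.jail,
                      booking_rate=cfg.jail.booking_rate * s,
                      census_target=int(round(cfg.jail.census_target * s)))
    return dc_replace(cfg, population=pop, jail=jail)


class Simulation:
    """One run: build population, warm up, then play a scenario horizon.

    The split into `run_warmup` / `snapshot` / `run_horizon` lets a sweep
    reuse one warm-up across all scenarios of a (draw, replicate) cell.
    """

    def __init__(self, cfg: ModelConfig, run_key: int):
        self.cfg = scale_config(cfg)
        self.key = int(run_key)
        self.rand = CrnSource(self.key)
        self.pop = build_population(
            self.cfg.population,
            np.random.SeedSequence((self.key, STREAM_POPULATION)))
        self.state = JailState(self.pop)
        initialize_steady_state(self.pop, self.state, self.cfg.jail, self.rand)
        self.mu_sigma = fit_stay_lognormal(self.cfg.jail)
        ndays = self.cfg.sim.warmup + self.cfg.sim.horizon
        self.bookings_by_day = self.rand.poisson_counts(
            np.arange(ndays), self.cfg.jail.booking_rate)
        # precomputed per-(day, pid) booking scores (pure function of the run
        # key, hence identical across paired scenario runs)
        self._book_scores = counter_uniform_matrix(
            self.key, STREAM_BOOK_PICK, np.arange(ndays),
            self.pop.cli_ids).astype(np.float32)  # float32 halves the footprint
        rp = self.cfg.risk
        self._rr_static = static_relative_risk(self.pop, rp)
        self._p_static = np.minimum(1.0, rp.p0_daily_od * self._rr_static)
        self._ever_rel_u = np.zeros(len(self.pop.user_ids), dtype=bool)
        self._schedule = self._build_overdose_schedule(ndays)
        self._warmed = False

    def _build_overdose_schedule(self, ndays: int) -> dict[int, np.ndarray]:
        """Pre-draw overdose days for users on the static (never-released)
        hazard via geometric skip-ahead — distributionally identical to daily
        Bernoulli draws at constant p, and a pure function of (run key, pid)
        so paired scenario runs share every event. Users switch to per-day
        draws (STREAM_OVERDOSE_DYN) once released and their scheduled events
        are ignored from then on; events while in custody are masked."""
        p = self._p_static
        idx = np.where(p > 0)[0]
        if idx.size == 0:
            return {}
        with np.errstate(divide="ignore"):
            log1mp = np.log1p(-np.minimum(p, 1.0 - 1e-15))
        next_day = np.full(p.size, -1, dtype=np.int64)
        days_out, users_out = [], []
        r = 0
        pids = self.pop.user_ids
        while idx.size:
            u = counter_uniforms(self.key, STREAM_OVERDOSE, r, pids[idx])
            gap = np.floor(np.log1p(-u) / log1mp[idx]).astype(np.int64) + 1
            next_day[idx] += gap
            keep = next_day[idx] < ndays
            idx = idx[keep]
            days_out.append(next_day[idx])
            users_out.append(idx.copy())
            r += 1
        days = np.concatenate(days_out)
        users = np.concatenate(users_out)
        order = np.argsort(days, kind="stable")
        days, users = days[order], users[order]
        bounds = np.searchsorted(days, np.arange(ndays + 1))
        return {d: users[bounds[d]:bounds[d + 1]]
                for d in range(ndays) if bounds[d] < bounds[d + 1]}

    # ------------------------------------------------------------------ state
    def snapshot(self) -> dict:
        p = self.pop
        return {
            "alive": p.alive.copy(), "in_jail": p.in_jail.copy(),
            "release_day": p.release_day.copy(),
            "last_release_day": p.last_release_day.copy(),
            "released_horizon": p.released_horizon.copy(),
            "has_kit": p.has_kit.copy(), "peer_kit": p.peer_kit.copy(),
            "calendar": self.state.snapshot_calendar(),
            "census": self.state.census,
            "census_history": list(self.state.census_history),
            "ever_rel_u": self._ever_rel_u.copy(),
            "warmed": self._warmed,
        }

    def restore(self, snap: dict) -> None:
        p = self.pop
        p.alive[:] = snap["alive"]; p.in_jail[:] = snap["in_jail"]
        p.release_day[:] = snap["release_day"]
        p.last_release_day[:] = snap["last_release_day"]
        p.released_horizon[:] = snap["released_horizon"]
        p.has_kit[:] = snap["has_kit"]; p.peer_kit[:] = snap["peer_kit"]
        self.state.calendar = {d: [a.copy() for a in lst]
                               for d, lst in snap["calendar"].items()}
        self.state.census = snap["census"]
        self.state.census_history = list(snap["census_history"])
        self._ever_rel_u[:] = snap["ever_rel_u"]
        self._warmed = snap["warmed"]

    # ------------------------------------------------------------------ steps
    def _step(self, day: int, scenario: InterventionScenario | None,
              tally: RunResult | None) -> None:
        pop, state, cfg = self.pop, self.state, self.cfg
        step_bookings(pop, state, day, cfg.jail, self.rand,
                      n_bookings=int(self.bookings_by_day[day]),
                      mu_sigma=self.mu_sigma, _scores=self._book_scores[day])
        released = step_releases(pop, state, day, horizon=tally is not None)
        release_kits = None
        if released.size:
            uloc = pop.user_index[released]
            uloc = uloc[uloc >= 0]
            self._ever_rel_u[uloc] = True
            if tally is not None and scenario is not None and uloc.size:
                rel_users = pop.user_ids[uloc]
                if scenario.cov_jail > 0 or scenario.cov_network > 0:
                    def release_kits(users=rel_users):
                        kit_u = self.rand.kit_uniforms(day, users)
                        apply_jail_release_distribution(
                            users, pop, scenario, tally.ledger, self.rand,
                            day, _kit_u=kit_u)
                        apply_network_distribution(
                            users, pop, scenario, tally.ledger, self.rand,
                            day, _kit_u=kit_u)
        if release_kits is not None and cfg.sim.thn_before_overdose:
            release_kits()
            release_kits = None
        state.census_history.append(state.census)
        # --- overdoses: scheduled events for static-hazard users, daily
        # draws for the (small) ever-released subset
        u = pop.user_ids
        parts = []
        sched = self._schedule.get(day)
        if sched is not None:
            sel = sched[~self._ever_rel_u[sched]]
            pids = u[sel]
            parts.append(pids[pop.alive[pids] & ~pop.in_jail[pids]])
        if self._ever_rel_u.any():
            idx = np.where(self._ever_rel_u)[0]
            pids = u[idx]
            ds = day - pop.last_release_day[pids]
            rp = cfg.risk
            w = np.where(ds < 14, rp.rr_release_wk0_2,
                         np.where(ds < 28, rp.rr_release_wk3_4,
                                  rp.rr_release_wk5plus))
            p = np.minimum(1.0, self._p_static[idx] * w)
            active = pop.alive[pids] & ~pop.in_jail[pids]
            hit = active & (counter_uniforms(self.key, STREAM_OVERDOSE_DYN,
                                             day, pids) < p)
            parts.append(pids[hit])
        ev = (np.concatenate(parts) if len(parts) > 1
              else parts[0] if parts else np.empty(0, dtype=np.int64))
        if ev.size:
            scratch = KitLedger()
            ledger = tally.ledger if tally is not None else scratch
            avail = availability_and_use(pop, ev, None, ledger)
            uniforms = self.rand.tree_uniforms(day, ev)
            bystander, administered, ems, fatal = resolve_events(
                avail, cfg.bystander, cfg.risk, uniforms)
            availability_and_use(pop, ev, administered, ledger)
            pop.alive[ev[fatal]] = False
            if tally is not None:
                tally.overdoses_total += ev.size
                tally.deaths_total += int(fatal.sum())
                rel = pop.released_horizon[ev]
                tally.overdoses_released += int(rel.sum())
                tally.deaths_released += int((rel & fatal).sum())
        if release_kits is not None:
            release_kits()  # ordering flag off: kits follow the day's events

    def run_warmup(self) -> None:
        for day in range(self.cfg.sim.warmup):
            self._step(day, None, None)
        self._warmed = True

    def run_horizon(self, scenario: InterventionScenario,
                    draw_id: int = 0, replicate_id: int = 0) -> RunResult:
        if not self._warmed and self.cfg.sim.warmup > 0:
            raise RuntimeError("run_warmup must precede run_horizon")
        cfg = self.cfg
        result = RunResult(scenario_id=scenario.id, param_draw_id=draw_id,
                           replicate_id=replicate_id, seed=self.key,
                           scale=cfg.sim.population_scale)
        apply_community_distribution(self.pop, scenario, result.ledger, self.rand)
        start = cfg.sim.warmup
        for day in range(start, start + cfg.sim.horizon):
            self._step(day, scenario, result)
        result.census_mean = float(np.mean(self.state.census_history[start:]))
        result.check()
        return result


def run_simulation(cfg: ModelConfig, scenario: InterventionScenario,
                   seed: int) -> RunResult:
    """Execute one full run (warm-up + horizon) for one scenario."""
    sim = Simulation(cfg, derive_run_key(seed))
    sim.run_warmup()
    return sim.run_horizon(scenario)


def _average_results(results: list[RunResult]) -> RunResult:
    n = len(results)
    first = results[0]
    avg = RunResult(scenario_id=first.scenario_id,
                    param_draw_id=first.param_draw_id,
                    replicate_id=-1, seed=first.seed, scale=first.scale)
    for f in ("overdoses_total", "deaths_total", "overdoses_released",
              "deaths_released", "census_mean"):
        setattr(avg, f, float(np.mean([getattr(r, f) for r in results])))
    for f in ("distributed_community", "distributed_jail", "distributed_network",
              "replacements", "used"):
        setattr(avg.ledger, f, float(np.mean([getattr(r.ledger, f) for r in results])))
    return avg


def run_replicates(cfg: ModelConfig, scenario: InterventionScenario,
                   n: int | None = None, base_seed: int | None = None
                   ) -> tuple[RunResult, list[RunResult]]:
    """n independent replicates (default from config, published default 10);
    returns (replicate-mean, per-replicate list)."""
    n = cfg.sim.replicates if n is None else n
    base_seed = cfg.sim.seed if base_seed is None else base_seed
    if n < 1:
        raise ValueError("n must be >= 1")
    results = []
    for rep in range(n):
        sim = Simulation(cfg, derive_run_key(base_seed, 0, rep))
        sim.run_warmup()
        results.append(sim.run_horizon(scenario, replicate_id=rep))
    return _average_results(results), results


def run_sweep(design: SweepDesign, cfg: ModelConfig,
              progress: bool = False) -> pd.DataFrame:
    """Scenario x draw sweep with common random numbers per (draw, replicate).

    Returns a tidy frame with one replicate-averaged row per (draw, scenario);
    the baseline scenario is always included (prepended when absent) so that
    deaths-averted comparisons are possible for every draw.
    """
    scenarios = list(design.scenarios)
    if not any(s.is_baseline for s in scenarios):
        scenarios = [next(s for s in scenario_grid() if s.is_baseline)] + scenarios
    rows = []
    for draw_id, draw in enumerate(design.param_draws):
        cfg_d = apply_draw(cfg, draw)
        per_scen: dict[int, list[RunResult]] = {s.id: [] for s in scenarios}
        for rep in range(design.replicates):
            key = derive_run_key(design.base_seed, draw_id, rep)
            sim = Simulation(cfg_d, key)
            sim.run_warmup()
            snap = sim.snapshot()
            for scen in scenarios:
                sim.restore(snap)
                per_scen[scen.id].append(
                    sim.run_horizon(scen, draw_id=draw_id, replicate_id=rep))
        for scen in scenarios:
            avg = _average_results(per_scen[scen.id])
            row = avg.to_row()
            row.update(cov_community=scen.cov_community, cov_jail=scen.cov_jail,
                       cov_network=scen.cov_network)
            rows.append(row)
        if progress:
            logger.info("sweep: draw %d/%d done", draw_id + 1, len(design.param_draws))
    return pd.DataFrame(rows)
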