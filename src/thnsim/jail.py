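"""Jail circulation: bookings, in-custody stays, releases, warm-start seeding.

Stays follow a log-normal fitted to the published mean/median pair
(median 12 d, mean 54.1 d): location mu = ln(median) and shape sigma solving
exp(mu + sigma^2/2) = mean, i.e. sigma = sqrt(2 ln(mean/median)). Durations
are rounded up to at least one day. Bookings are Poisson (mean 132/day at
full scale) sampled uniformly without replacement from CLI members not
currently in custody; overdose hazard is zero while in custody.

Little's law puts the implied steady-state census at booking_rate x mean stay
= 132 x 54.1 ~ 7141, while the published nightly census is ~6000; the
warm-start seeds custody at the configurable ``census_target`` (default 6000)
with length-biased residual stays and lets the 90-day warm-up relax the
census toward its own steady state. Both numbers are reported, not
reconciled.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .params import JailParams, fitted_stay_sigma
from .population import Population
from .rng import as_source

__all__ = [
    "JailState",
    "fit_stay_lognormal",
    "sample_stay_duration",
    "step_bookings",
    "step_releases",
    "initialize_steady_state",
]


def fit_stay_lognormal(jp: JailParams) -> tuple[float, float]:
    """(mu, sigma) of the log-normal matching the stay median and mean."""
    if jp.stay_mean < jp.stay_median:
        raise ValueError("stay_mean < stay_median: no log-normal fits")
    return math.log(jp.stay_median), fitted_stay_sigma(jp)


def sample_stay_duration(jp: JailParams, rng, size=None):
    """Draw stay durations in whole days (>= 1) from the fitted log-normal."""
    mu, sigma = fit_stay_lognormal(jp)
    z = np.random.default_rng(rng).standard_normal(size) if not isinstance(
        rng, np.random.Generator) else rng.standard_normal(size)
    stay = np.ceil(np.exp(mu + sigma * np.asarray(z))).astype(np.int64)
    stay = np.maximum(stay, 1)
    return int(stay) if size is None else stay


class JailState:
    """Custody bookkeeping: who is inside, when they leave, census history."""

    def __init__(self, pop: Population | None = None):
        self.pop = pop
        self.calendar: dict[int, list[np.ndarray]] = {}   # release day -> pid arrays
        self.census = 0
        self.census_history: list[int] = []
        self.pool_exhausted_warned = False

    @property
    def in_custody(self) -> np.ndarray:
        if self.pop is None:
            raise ValueError("JailState has no population attached")
        return np.where(self.pop.in_jail)[0]

    @property
    def scheduled_release(self) -> dict[int, int]:
        pids = self.in_custody
        return {int(p): int(self.pop.release_day[p]) for p in pids}

    def schedule(self, pids: np.ndarray, day: int) -> None:
        self.calendar.setdefault(day, []).append(np.asarray(pids, dtype=np.int64))

    def snapshot_calendar(self) -> dict[int, list[np.ndarray]]:
        return {d: [a.copy() for a in lst] for d, lst in self.calendar.items()}


def step_bookings(pop: Population, state: JailState, day: int, jp: JailParams,
                  rand, n_bookings: int | None = None,
                  mu_sigma: tuple[float, float] | None = None,
                  _scores: np.ndarray | None = None) -> np.ndarray:
    """Book K ~ Poisson(booking_rate) CLI persons; returns booked pids.

    If the eligible pool is smaller than K the whole pool is booked and a
    warning is emitted once per run (signals an under-sized CLI pool).
    """
    rand = as_source(rand)
    if n_bookings is None:
        n_bookings = int(rand.poisson_counts(np.array([day]), jp.booking_rate)[0])
    if n_bookings <= 0:
        return np.empty(0, dtype=np.int64)
    cli_ids = pop.cli_ids
    eligible = pop.alive[cli_ids] & ~pop.in_jail[cli_ids]
    n_elig = int(eligible.sum())
    if n_elig == 0:
        if not state.pool_exhausted_warned:
            warnings.warn("booking pool empty: CLI pool under-sized for the booking rate")
            state.pool_exhausted_warned = True
        return np.empty(0, dtype=np.int64)
    elig_ids = cli_ids[eligible]
    if n_bookings >= n_elig:
        if not state.pool_exhausted_warned:
            warnings.warn(
                f"booking pool exhausted on day {day}: wanted {n_bookings}, "
                f"only {n_elig} eligible — CLI pool under-sized")
            state.pool_exhausted_warned = True
        booked = elig_ids
    else:
        # per-(day, pid) scores: the K winners are stable across paired
        # scenario runs even when eligibility differs slightly
        scores = (_scores[eligible] if _scores is not None
                  else rand.booking_scores(day, elig_ids))
        booked = elig_ids[np.argpartition(scores, n_bookings)[:n_bookings]]
    mu, sigma = mu_sigma if mu_sigma is not None else fit_stay_lognormal(jp)
    stays = np.maximum(np.ceil(np.exp(mu + sigma * rand.stay_normals(day, booked))), 1.0)
    rel = day + stays.astype(np.int64)
    pop.in_jail[booked] = True
    pop.release_day[booked] = rel
    for d in np.unique(rel):
        state.schedule(booked[rel == d], int(d))
    state.census += len(booked)
    return booked


def step_releases(pop: Population, state: JailState, day: int,
                  horizon: bool = False) -> np.ndarray:
    """Release everyone scheduled for `day`; returns released pids.

    Sets days-since-release to 0 (the highest-risk window starts immediately)
    and, during the reporting horizon, marks the person as released for the
    jail-subgroup tallies and the jail/network kit channels.
    """
    chunks = state.calendar.pop(day, None)
    if not chunks:
        return np.empty(0, dtype=np.int64)
    pids = np.concatenate(chunks)
    pids = pids[pop.in_jail[pids]]  # guard against stale entries after restore
    pop.in_jail[pids] = False
    pop.release_day[pids] = -1
    pop.last_release_day[pids] = day
    if horizon:
        pop.released_horizon[pids] = True
    state.census -= len(pids)
    return pids


def initialize_steady_state(pop: Population, state: JailState, jp: JailParams,
                            rand) -> JailState:
    """Seed custody at census_target with length-biased residual stays.

    A person found in custody at a random time was drawn with probability
    proportional to stay length; for a log-normal(mu, sigma) the length-biased
    total stay is log-normal(mu + sigma^2, sigma), and the residual is uniform
    on the total. Seeding this way puts the census near steady state from day
    0 of the warm-up instead of filling from empty (90 days is short relative
    to the 54.1-day mean stay).
    """
    rand = as_source(rand)
    rng = rand.stream_generator(1)  # STREAM_INIT_JAIL
    target = min(int(jp.census_target), len(pop.cli_ids))
    if target <= 0:
        return state
    seeded = rng.choice(pop.cli_ids, size=target, replace=False)
    mu, sigma = fit_stay_lognormal(jp)
    total = np.exp(mu + sigma**2 + sigma * rng.standard_normal(target))
    residual = np.maximum(np.ceil(rng.random(target) * total), 1.0).astype(np.int64)
    pop.in_jail[seeded] = True
    pop.release_day[seeded] = residual
    for d in np.unique(residual):
        state.schedule(seeded[residual == d], int(d))
    state.census += target
    return state
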