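"""Overdose hazard and the bystander behaviour tree.

A person's daily overdose probability is the baseline probability times the
product of their relative risks (sex, injection route, post-release window,
age), clamped at 1. Post-release windows use 0-based days since release with
half-open intervals: [0, 14) -> week 0-2 multiplier, [14, 28) -> week 3-4,
[28, inf) -> week >=5, which persists indefinitely after any incarceration;
never-released persons carry multiplier 1.

Survival of an overdose follows the witnessed-event tree: with no bystander
the event is fatal with probability f_fatal; with a bystander present,
naloxone is administered (when a kit is available at the scene) with
probability p_administer and EMS is called independently with probability
p_ems. Naloxone administration multiplies the fatality probability by
(1 - eff_naloxone); otherwise an EMS call multiplies it by (1 - eff_ems);
the two effects deliberately do not stack (administration dominates, to
avoid double-counting reversal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import BystanderParams, RiskParams
from .population import NEVER, USE_IOU, USE_NONE, Person, Population
from .rng import as_source

__all__ = [
    "OverdoseEvent",
    "relative_risk",
    "daily_overdose_probability",
    "draw_overdoses",
    "resolve_overdose",
    "resolve_events",
    "analytic_death_probability",
    "static_relative_risk",
    "release_window_multiplier",
]


@dataclass(frozen=True)
class OverdoseEvent:
    pid: int
    day: int
    bystander_present: bool
    naloxone_available: bool
    naloxone_administered: bool
    ems_called: bool
    fatal: bool
    victim_released_ever: bool

    def __post_init__(self):
        if self.naloxone_administered and not (self.naloxone_available and self.bystander_present):
            raise ValueError("naloxone administered without availability and a bystander")
        if self.ems_called and not self.bystander_present:
            raise ValueError("EMS called without a bystander")


def _window_multiplier_scalar(days_since_release: int | None, rp: RiskParams) -> float:
    if days_since_release is None:
        return 1.0
    if days_since_release < 14:
        return rp.rr_release_wk0_2
    if days_since_release < 28:
        return rp.rr_release_wk3_4
    return rp.rr_release_wk5plus


def relative_risk(person: Person, rp: RiskParams) -> float:
    """Product of the person's hazard multipliers (1.0 for all-reference)."""
    if person.use_type == "NONE":
        raise ValueError("relative_risk is defined only for opioid users")
    rr = 1.0
    if person.sex == "female":
        rr *= rp.rr_female
    if person.use_type == "IOU":
        rr *= rp.rr_iou
    rr *= _window_multiplier_scalar(person.days_since_release, rp)
    if person.age_group == "25-29":
        rr *= rp.rr_age_25_29
    elif person.age_group == ">=30":
        rr *= rp.rr_age_30plus
    return rr


def daily_overdose_probability(person: Person, rp: RiskParams) -> float:
    """min(1, p0 x relative risk); the clamp covers pathological sweep corners."""
    return min(1.0, rp.p0_daily_od * relative_risk(person, rp))


def static_relative_risk(pop: Population, rp: RiskParams) -> np.ndarray:
    """Time-invariant risk product (sex x route x age) for each opioid user."""
    u = pop.user_ids
    rr = np.where(pop.female[u], rp.rr_female, 1.0)
    rr *= np.where(pop.use_type[u] == USE_IOU, rp.rr_iou, 1.0)
    age = pop.age_group[u]
    rr *= np.choose(age, [1.0, rp.rr_age_25_29, rp.rr_age_30plus])
    return rr


def release_window_multiplier(days_since_release: np.ndarray, rp: RiskParams) -> np.ndarray:
    """Vectorised window multiplier; negative inputs mean 'never released'."""
    ds = np.asarray(days_since_release)
    return np.where(ds < 0, 1.0,
                    np.where(ds < 14, rp.rr_release_wk0_2,
                             np.where(ds < 28, rp.rr_release_wk3_4,
                                      rp.rr_release_wk5plus)))


def draw_overdoses(pop: Population, day: int, rp: RiskParams, rand,
                   _p_static: np.ndarray | None = None,
                   _ever_released_u: np.ndarray | None = None) -> np.ndarray:
    """Independent daily Bernoulli overdose draws; returns pids (at most one
    event per person per day). Only alive, out-of-custody opioid users are at
    risk. `_p_static` / `_ever_released_u` are optional precomputed fast-path
    arrays used by the runner."""
    rand = as_source(rand)
    u = pop.user_ids
    if _p_static is None:
        p = np.minimum(1.0, rp.p0_daily_od * static_relative_risk(pop, rp))
    else:
        p = _p_static.copy()
    lrd = pop.last_release_day[u]
    if _ever_released_u is None:
        ever = lrd != NEVER
    else:
        ever = _ever_released_u
    if ever.any():
        idx = np.where(ever)[0]
        w = release_window_multiplier(day - lrd[idx], rp)
        p[idx] = np.minimum(1.0, p[idx] * w)
    active = pop.alive[u] & ~pop.in_jail[u]
    hit = active & (rand.overdose_uniforms(day, u) < p)
    return u[hit]


def resolve_overdose(person: Person, availability: bool, bp: BystanderParams,
                     rp: RiskParams, rng: np.random.Generator,
                     day: int = 0) -> OverdoseEvent:
    """Resolve one overdose through the bystander tree (scalar reference path)."""
    bystander = rng.random() < bp.p_bystander
    administered = bool(bystander and availability and rng.random() < bp.p_administer)
    ems = bool(bystander and rng.random() < bp.p_ems)
    if administered:
        m = 1.0 - bp.eff_naloxone
    elif ems:
        m = 1.0 - bp.eff_ems
    else:
        m = 1.0
    fatal = rng.random() < rp.f_fatal * m
    return OverdoseEvent(
        pid=person.pid, day=day, bystander_present=bool(bystander),
        naloxone_available=bool(availability), naloxone_administered=administered,
        ems_called=ems, fatal=bool(fatal),
        victim_released_ever=person.days_since_release is not None,
    )


def resolve_events(availability: np.ndarray, bp: BystanderParams, rp: RiskParams,
                   uniforms: np.ndarray):
    """Vectorised bystander tree on precomputed uniforms (n, 4).

    Lane order: bystander presence, administration, EMS call, fatality.
    Returns boolean arrays (bystander, administered, ems, fatal).
    """
    avail = np.asarray(availability, dtype=bool)
    bystander = uniforms[:, 0] < bp.p_bystander
    administered = bystander & avail & (uniforms[:, 1] < bp.p_administer)
    ems = bystander & (uniforms[:, 2] < bp.p_ems)
    m = np.where(administered, 1.0 - bp.eff_naloxone,
                 np.where(ems, 1.0 - bp.eff_ems, 1.0))
    fatal = uniforms[:, 3] < rp.f_fatal * m
    return bystander, administered, ems, fatal


def analytic_death_probability(availability: bool, bp: BystanderParams,
                               rp: RiskParams) -> float:
    """Closed-form P(fatal | overdose) under the bystander tree.

    f x [ (1-p_by) + p_by x ( a(1-eff_nx) + (1-a)(p_ems(1-eff_ems) + 1-p_ems) ) ]
    with a = p_administer when a kit is available at the scene, else 0.
    """
    a = bp.p_administer if availability else 0.0
    no_nalox = bp.p_ems * (1.0 - bp.eff_ems) + (1.0 - bp.p_ems)
    present = a * (1.0 - bp.eff_naloxone) + (1.0 - a) * no_nalox
    return rp.f_fatal * ((1.0 - bp.p_bystander) + bp.p_bystander * present)
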