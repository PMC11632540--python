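"""Synthetic agent population: opioid users, the CLI pool, and their overlap.

The population is stored struct-of-arrays (one numpy array per person field)
for speed; ``Person`` is a per-row view used by the scalar operations and for
serialization. Opioid-using members of the criminal-legal-involved (CLI) pool
are drawn as subsets of the injection (IOU) and non-injection (NIOU) user
pools so that uniform booking from the pool reproduces the published inmate
composition in expectation; the remainder of the CLI pool never uses opioids
and carries zero overdose hazard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import PopulationParams

__all__ = ["Person", "Population", "build_population", "population_summary"]

USE_NONE, USE_NIOU, USE_IOU = 0, 1, 2
USE_LABELS = np.array(["NONE", "NIOU", "IOU"])
AGE_LABELS = np.array(["18-24", "25-29", ">=30"])
NEVER = np.int32(-(10**9))  # sentinel for "never released"


@dataclass(frozen=True)
class Person:
    """Read-only view of one agent at a given simulation day."""

    pid: int
    use_type: str            # "IOU" | "NIOU" | "NONE"
    sex: str                 # "male" | "female"
    age_group: str           # "18-24" | "25-29" | ">=30"
    cli: bool
    in_jail: bool
    release_day: int | None          # scheduled release if in custody
    days_since_release: int | None   # None = never released
    has_kit: bool
    peer_kit: bool
    alive: bool


class Population:
    """All agents of one simulation, held as parallel arrays."""

    def __init__(self, use_type, female, age_group, cli):
        n = len(use_type)
        self.n = n
        self.use_type = np.asarray(use_type, dtype=np.int8)
        self.female = np.asarray(female, dtype=bool)
        self.age_group = np.asarray(age_group, dtype=np.int8)
        self.cli = np.asarray(cli, dtype=bool)
        # time-varying state
        self.alive = np.ones(n, dtype=bool)
        self.in_jail = np.zeros(n, dtype=bool)
        self.release_day = np.full(n, -1, dtype=np.int32)
        self.last_release_day = np.full(n, NEVER, dtype=np.int32)
        self.released_horizon = np.zeros(n, dtype=bool)
        self.has_kit = np.zeros(n, dtype=bool)
        self.peer_kit = np.zeros(n, dtype=bool)
        self.current_day = 0
        # subgroup index sets
        self.user_ids = np.where(self.use_type != USE_NONE)[0]
        self.cli_ids = np.where(self.cli)[0]
        self.user_index = np.full(n, -1, dtype=np.int64)
        self.user_index[self.user_ids] = np.arange(len(self.user_ids))

    # -- subgroup index sets -------------------------------------------------
    @property
    def iou_ids(self) -> np.ndarray:
        return np.where(self.use_type == USE_IOU)[0]

    @property
    def niou_ids(self) -> np.ndarray:
        return np.where(self.use_type == USE_NIOU)[0]

    @property
    def jailed_ids(self) -> np.ndarray:
        return np.where(self.in_jail)[0]

    def person(self, pid: int, day: int | None = None) -> Person:
        day = self.current_day if day is None else day
        lrd = int(self.last_release_day[pid])
        return Person(
            pid=int(pid),
            use_type=str(USE_LABELS[self.use_type[pid]]),
            sex="female" if self.female[pid] else "male",
            age_group=str(AGE_LABELS[self.age_group[pid]]),
            cli=bool(self.cli[pid]),
            in_jail=bool(self.in_jail[pid]),
            release_day=int(self.release_day[pid]) if self.in_jail[pid] else None,
            days_since_release=None if (lrd == NEVER or self.in_jail[pid]) else day - lrd,
            has_kit=bool(self.has_kit[pid]),
            peer_kit=bool(self.peer_kit[pid]),
            alive=bool(self.alive[pid]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """One row per person, for audit/CSV export (deterministic layout)."""
        return pd.DataFrame({
            "pid": np.arange(self.n),
            "use_type": USE_LABELS[self.use_type],
            "sex": np.where(self.female, "female", "male"),
            "age_group": AGE_LABELS[self.age_group],
            "cli": self.cli,
            "in_jail": self.in_jail,
            "release_day": self.release_day,
            "last_release_day": self.last_release_day,
            "has_kit": self.has_kit,
            "peer_kit": self.peer_kit,
            "alive": self.alive,
        })


def build_population(pp: PopulationParams, seed) -> Population:
    """Construct the synthetic population; deterministic given (pp, seed).

    Raises ValueError if the CLI pool demands more opioid users than exist.
    """
    rng = np.random.default_rng(seed)
    n_iou, n_niou, n_cli = pp.n_iou, pp.n_niou, pp.n_cli
    k_iou = int(round(pp.frac_inmates_iou * n_cli))
    k_niou = int(round(pp.frac_inmates_niou * n_cli))
    if k_iou > n_iou:
        raise ValueError(
            f"infeasible CLI composition: {k_iou} CLI injection users requested "
            f"but only {n_iou} injection users exist")
    if k_niou > n_niou:
        raise ValueError(
            f"infeasible CLI composition: {k_niou} CLI non-injection users requested "
            f"but only {n_niou} non-injection users exist")
    n_none = n_cli - k_iou - k_niou
    n = n_iou + n_niou + n_none

    use_type = np.empty(n, dtype=np.int8)
    use_type[:n_iou] = USE_IOU
    use_type[n_iou:n_iou + n_niou] = USE_NIOU
    use_type[n_iou + n_niou:] = USE_NONE

    cli = np.zeros(n, dtype=bool)
    if k_iou:
        cli[rng.choice(n_iou, size=k_iou, replace=False)] = True
    if k_niou:
        cli[n_iou + rng.choice(n_niou, size=k_niou, replace=False)] = True
    cli[n_iou + n_niou:] = True

    female = rng.random(n) < pp.sex_female_frac
    age = rng.choice(3, size=n, p=np.asarray(pp.age_dist, dtype=float))
    return Population(use_type, female, age, cli)


def population_summary(pop: Population) -> pd.DataFrame:
    """Counts by (use_type, cli, in_jail, sex, age_group); cells sum to pop.n."""
    df = pd.DataFrame({
        "use_type": USE_LABELS[pop.use_type],
        "cli": pop.cli,
        "in_jail": pop.in_jail,
        "sex": np.where(pop.female, "female", "male"),
        "age_group": AGE_LABELS[pop.age_group],
    })
    out = (df.groupby(["use_type", "cli", "in_jail", "sex", "age_group"], observed=True)
             .size().rename("count").reset_index())
    return out
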