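"""Model parameters, published uncertainty ranges, and the scenario grid.

All probabilities are stored as fractions; published percentage inputs are
converted exactly once, in the constants below, never downstream. Point
defaults for parameters that the sensitivity analysis sweeps are the interval
midpoints (a single-run default consistent with reporting medians over the
swept space); structural constants (population sizes, booking rate, stay
statistics, kit cost) are the published point values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.stats import qmc

__all__ = [
    "RiskParams",
    "BystanderParams",
    "JailParams",
    "PopulationParams",
    "EconomicParams",
    "SimulationSettings",
    "InterventionScenario",
    "ParamRanges",
    "ParamDraw",
    "default_ranges",
    "scenario_grid",
    "sample_parameter_draws",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class RiskParams:
    """Baseline overdose hazard and the multiplicative relative risks.

    Reference categories (male, non-injection use, never incarcerated,
    age 18-24) carry an implicit multiplier of 1 and have no field.
    """

    p0_daily_od: float = 0.00033      # baseline daily overdose probability
    f_fatal: float = 0.10             # fatality probability per overdose
    rr_female: float = 0.81
    rr_iou: float = 4.75              # injection vs non-injection use
    rr_release_wk0_2: float = 6.0     # days 0-13 after jail release
    rr_release_wk3_4: float = 4.0     # days 14-27
    rr_release_wk5plus: float = 1.5   # day 28 onward, indefinitely
    rr_age_25_29: float = 2.085
    rr_age_30plus: float = 2.935

    def __post_init__(self):
        for name in ("p0_daily_od", "f_fatal"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{name} must be a probability in [0,1], got {v}")
        for f in fields(self):
            if f.name.startswith("rr_"):
                v = getattr(self, f.name)
                _require(v > 0.0, f"{f.name} must be a positive ratio, got {v}")


@dataclass(frozen=True)
class BystanderParams:
    """Bystander-tree probabilities and reversal effectiveness.

    ``eff_naloxone`` is the mortality reduction when naloxone is administered
    (0.95 for proper and prompt use; at least 0.80 is defensible —
    imperfect use is already captured by ``p_administer``). ``eff_ems`` is the
    reduction when EMS is called but no naloxone is given; no published point
    value exists in the main analysis, so it is an explicit, visible
    configuration key defaulting to 0.50.
    """

    p_bystander: float = 0.60
    p_administer: float = 0.70
    p_ems: float = 0.50
    eff_naloxone: float = 0.95
    eff_ems: float = 0.50

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            _require(0.0 <= v <= 1.0, f"{f.name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class JailParams:
    booking_rate: float = 132.0    # persons/day, Poisson mean
    stay_median: float = 12.0      # days
    stay_mean: float = 54.1        # days
    census_target: int = 6000      # warm-start custody size (validation/seeding)

    def __post_init__(self):
        _require(self.booking_rate >= 0.0, "booking_rate must be >= 0")
        _require(self.stay_median > 0.0, "stay_median must be > 0")
        _require(
            self.stay_mean >= self.stay_median,
            f"stay_mean ({self.stay_mean}) must be >= stay_median ({self.stay_median}); "
            "no log-normal matches otherwise",
        )
        _require(self.census_target >= 0, "census_target must be >= 0")


@dataclass(frozen=True)
class PopulationParams:
    """Synthetic-population sizes and demographic marginals.

    The sex and age marginals are configurable placeholders (the calibrated
    values are not published in the main text); defaults: 25% female,
    age distribution (0.10, 0.15, 0.75) over 18-24 / 25-29 / >=30.
    """

    n_iou: int = 24_000
    n_niou: int = 66_000
    n_cli: int = 50_000
    frac_inmates_iou: float = 0.035
    frac_inmates_niou: float = 0.105
    sex_female_frac: float = 0.25
    age_dist: tuple = (0.10, 0.15, 0.75)

    def __post_init__(self):
        _require(self.n_iou >= 0 and self.n_niou >= 0 and self.n_cli >= 0,
                 "population counts must be non-negative")
        _require(0.0 <= self.frac_inmates_iou <= 1.0, "frac_inmates_iou must be in [0,1]")
        _require(0.0 <= self.frac_inmates_niou <= 1.0, "frac_inmates_niou must be in [0,1]")
        _require(self.frac_inmates_iou + self.frac_inmates_niou < 1.0,
                 "frac_inmates_iou + frac_inmates_niou must be < 1")
        _require(0.0 <= self.sex_female_frac <= 1.0, "sex_female_frac must be in [0,1]")
        object.__setattr__(self, "age_dist", tuple(float(a) for a in self.age_dist))
        _require(len(self.age_dist) == 3, "age_dist needs 3 entries (18-24, 25-29, >=30)")
        _require(all(a >= 0 for a in self.age_dist), "age_dist entries must be >= 0")
        _require(abs(sum(self.age_dist) - 1.0) < 1e-9, "age_dist must sum to 1")


@dataclass(frozen=True)
class EconomicParams:
    kit_cost: float = 76.0   # 2017 USD per intranasal naloxone kit

    def __post_init__(self):
        _require(self.kit_cost >= 0.0, "kit_cost must be >= 0")


@dataclass(frozen=True)
class SimulationSettings:
    horizon: int = 365
    warmup: int = 90
    replicates: int = 10
    seed: int = 1
    population_scale: float = 1.0   # joint scale on population sizes and booking rate
    thn_before_overdose: bool = True  # hand out release-day kits before that day's events

    def __post_init__(self):
        _require(self.horizon > 0, "horizon must be > 0")
        _require(self.warmup >= 0, "warmup must be >= 0")
        _require(self.replicates >= 1, "replicates must be >= 1")
        _require(0.0 < self.population_scale <= 1.0,
                 "population_scale must be in (0, 1]")


@dataclass(frozen=True)
class InterventionScenario:
    """Coverage triple for the three kit-distribution channels."""

    id: int
    cov_community: float = 0.0   # fraction of the opioid-user population
    cov_jail: float = 0.0        # fraction of opioid-using persons at release
    cov_network: float = 0.0     # probability of a peer kit for released persons

    def __post_init__(self):
        for name in ("cov_community", "cov_jail", "cov_network"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{name} must be in [0,1], got {v}")

    @property
    def is_baseline(self) -> bool:
        return self.cov_community == self.cov_jail == self.cov_network == 0.0


BASELINE_SCENARIO_ID = 1

# Coverage levels of the published 3x3x3 grid (jail varies slowest, then
# community, then social network — matching the published row order in which
# scenario 1 is the all-zero baseline, 2 = (0, 0, .15), 19 = (0, 1, 0),
# 27 = (.30, 1, .30)).
_JAIL_LEVELS = (0.0, 0.50, 1.00)
_COMMUNITY_LEVELS = (0.0, 0.15, 0.30)
_NETWORK_LEVELS = (0.0, 0.15, 0.30)


def scenario_grid() -> list[InterventionScenario]:
    """The 27-scenario grid; scenario 1 is the no-distribution baseline."""
    out = []
    sid = 0
    for cj in _JAIL_LEVELS:
        for cc in _COMMUNITY_LEVELS:
            for cn in _NETWORK_LEVELS:
                sid += 1
                out.append(InterventionScenario(sid, cov_community=cc,
                                                cov_jail=cj, cov_network=cn))
    return out


# Published sensitivity bounds (percentages already converted to fractions).
_TABLE_BOUNDS = {
    "frac_inmates_iou": (0.02, 0.05),
    "frac_inmates_niou": (0.06, 0.15),
    "p0_daily_od": (0.00016, 0.00050),
    "f_fatal": (0.07, 0.13),
    "rr_female": (0.21, 1.41),
    "rr_iou": (0.50, 9.00),
    "rr_release_wk0_2": (2.00, 10.0),
    "rr_release_wk3_4": (2.00, 6.00),
    "rr_release_wk5plus": (1.00, 2.00),
    "rr_age_25_29": (0.39, 3.78),
    "rr_age_30plus": (0.72, 5.15),
    "p_bystander": (0.30, 0.90),
    "p_administer": (0.50, 0.90),
    "p_ems": (0.20, 0.80),
}


@dataclass(frozen=True)
class ParamRanges:
    """(lower, upper) sweep intervals for each uncertain parameter."""

    bounds: dict = field(default_factory=lambda: dict(_TABLE_BOUNDS))

    def __post_init__(self):
        unknown = set(self.bounds) - set(_TABLE_BOUNDS)
        _require(not unknown, f"unknown range keys: {sorted(unknown)}")
        for name, (lo, hi) in self.bounds.items():
            _require(lo <= hi, f"range for {name} has lower > upper: ({lo}, {hi})")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in self.bounds])

    def fix(self, **values) -> "ParamRanges":
        """Collapse named ranges to points (e.g. fix(p_bystander=0.9))."""
        new = dict(self.bounds)
        for name, v in values.items():
            _require(name in new, f"unknown parameter {name!r}")
            new[name] = (float(v), float(v))
        return ParamRanges(new)

    def midpoints(self) -> dict:
        return {n: 0.5 * (lo + hi) for n, (lo, hi) in self.bounds.items()}


def default_ranges() -> ParamRanges:
    """The published lower/upper sensitivity bounds, verbatim (as fractions)."""
    return ParamRanges()


@dataclass(frozen=True)
class ParamDraw:
    """One point of the sensitivity hypercube."""

    risk: RiskParams
    bystander: BystanderParams
    frac_inmates_iou: float
    frac_inmates_niou: float


_RISK_FIELDS = {f.name for f in fields(RiskParams)}
_BYSTANDER_FIELDS = {f.name for f in fields(BystanderParams)}


def draw_from_vector(names: list[str], x: np.ndarray,
                     base_risk: RiskParams = RiskParams(),
                     base_bystander: BystanderParams = BystanderParams(),
                     base_population: PopulationParams = PopulationParams()) -> ParamDraw:
    """Map one hypercube point (ordered like `names`) onto parameter objects."""
    risk_kw, byst_kw = {}, {}
    fi, fn = base_population.frac_inmates_iou, base_population.frac_inmates_niou
    for name, v in zip(names, x):
        v = float(v)
        if name in _RISK_FIELDS:
            risk_kw[name] = v
        elif name in _BYSTANDER_FIELDS:
            byst_kw[name] = v
        elif name == "frac_inmates_iou":
            fi = v
        elif name == "frac_inmates_niou":
            fn = v
        else:  # pragma: no cover - guarded by ParamRanges
            raise ValueError(f"unknown parameter {name!r}")
    return ParamDraw(risk=replace(base_risk, **risk_kw),
                     bystander=replace(base_bystander, **byst_kw),
                     frac_inmates_iou=fi, frac_inmates_niou=fn)


def sample_parameter_draws(ranges: ParamRanges, n: int,
                           method: str = "sobol_sequence",
                           seed: int = 0) -> list[ParamDraw]:
    """Sample n uniform (or low-discrepancy uniform) points of the hypercube.

    method: 'sobol_sequence' (default), 'latin_hypercube', or 'uniform_random'.
    The same seed always reproduces the same draws.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    names = ranges.names
    d = len(names)
    lo, hi = ranges.lower, ranges.upper
    if method == "sobol_sequence":
        sampler = qmc.Sobol(d=d, scramble=True, seed=seed)
        # random(n) warns for non-powers of two; accuracy is unaffected here
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            unit = sampler.random(n)
    elif method == "latin_hypercube":
        unit = qmc.LatinHypercube(d=d, seed=seed).random(n)
    elif method == "uniform_random":
        unit = np.random.default_rng(seed).random((n, d))
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    pts = lo + unit * (hi - lo)
    return [draw_from_vector(names, pts[i]) for i in range(n)]


def fitted_stay_sigma(jp: JailParams) -> float:
    """Closed-form log-normal shape matching the stay mean/median pair."""
    return math.sqrt(2.0 * math.log(jp.stay_mean / jp.stay_median))
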