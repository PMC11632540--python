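"""Deterministic randomness for paired-scenario simulation.

Two kinds of sources are provided:

``CrnSource``
    A *stateless*, counter-based source. Every variate is a pure function of
    ``(run key, stream id, day, person id, lane)`` obtained by hashing the
    tuple with splitmix64. Because no state advances, two simulation runs that
    share a run key see byte-identical bookings, stay lengths, overdose draws
    and bystander behaviour regardless of how their populations diverge — the
    common-random-numbers (CRN) property that makes paired deaths-averted
    comparisons low-variance. A run whose intervention changes nothing
    reproduces the baseline exactly.

``GeneratorSource``
    A thin adapter over a ``numpy.random.Generator`` exposing the same method
    surface, for unit-level use of the jail/overdose operations outside the
    CRN runner.

Run keys are derived from ``(base_seed, draw_id, replicate_id)`` through
``numpy.random.SeedSequence`` (a documented, platform-stable hash — never an
arithmetic offset) and truncated below 2**31.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri
from scipy.stats import poisson

__all__ = [
    "derive_run_key",
    "counter_uniforms",
    "CrnSource",
    "GeneratorSource",
]

# Stream identifiers: one per independent source of randomness in a run.
STREAM_POPULATION = 0   # population build (demographics, CLI membership)
STREAM_INIT_JAIL = 1    # warm-start custody seeding
STREAM_BOOK_COUNT = 2   # daily Poisson booking counts
STREAM_BOOK_PICK = 3    # who gets booked
STREAM_STAY = 4         # stay durations
STREAM_OVERDOSE = 5     # daily overdose Bernoulli draws
STREAM_TREE = 6         # bystander behaviour tree
STREAM_KITS = 7         # kit-distribution coin flips
STREAM_OVERDOSE_DYN = 8  # daily overdose draws for post-release (dynamic) hazard

_U64 = np.uint64
_GAMMA = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)
_INV53 = 1.0 / (1 << 53)


def derive_run_key(base_seed: int, draw_id: int = 0, replicate_id: int = 0) -> int:
    """Hash (base_seed, draw_id, replicate_id) into a 31-bit run key."""
    ss = np.random.SeedSequence((int(base_seed), int(draw_id), int(replicate_id)))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def _splitmix(z: np.ndarray) -> np.ndarray:
    # splitmix64 finaliser; operates elementwise on uint64.
    z = z ^ (z >> _U64(30))
    z = z * _MIX1
    z = z ^ (z >> _U64(27))
    z = z * _MIX2
    z = z ^ (z >> _U64(31))
    return z


def counter_uniforms(key: int, stream: int, day: int, pids, lanes: int = 1) -> np.ndarray:
    """Uniform(0,1) variates indexed by (key, stream, day, pid, lane).

    Returns shape ``(len(pids),)`` when ``lanes == 1`` else ``(len(pids), lanes)``.
    The counter layout packs pid (32 bits), day+1 (17 bits) and stream (6 bits)
    into one 64-bit word; two splitmix64 rounds whiten it against the key.
    """
    pid = np.asarray(pids, dtype=np.uint64)
    with np.errstate(over="ignore"):  # uint64 wraparound is the point
        counter = pid + (_U64(int(day) + 1) << _U64(32)) + (_U64(int(stream)) << _U64(49))
        seeded = _splitmix(counter ^ (_U64(int(key) & 0x7FFFFFFF) * _MIX1))
        if lanes == 1:
            return (_splitmix(seeded + _GAMMA) >> _U64(11)) * _INV53
        out = np.empty((pid.size, lanes), dtype=np.float64)
        for lane in range(lanes):
            out[:, lane] = (_splitmix(seeded + _U64(lane + 1) * _GAMMA) >> _U64(11)) * _INV53
    return out


def counter_uniform_matrix(key: int, stream: int, days, pids) -> np.ndarray:
    """Vectorised ``counter_uniforms`` over a (day, pid) grid.

    Returns shape ``(len(days), len(pids))``; entry [i, j] equals
    ``counter_uniforms(key, stream, days[i], [pids[j]])[0]`` exactly.
    """
    pid = np.asarray(pids, dtype=np.uint64)[None, :]
    day = (np.asarray(days, dtype=np.uint64) + _U64(1))[:, None]
    with np.errstate(over="ignore"):
        counter = pid + (day << _U64(32)) + (_U64(int(stream)) << _U64(49))
        seeded = _splitmix(counter ^ (_U64(int(key) & 0x7FFFFFFF) * _MIX1))
        return (_splitmix(seeded + _GAMMA) >> _U64(11)) * _INV53


class CrnSource:
    """Counter-based variate source keyed to one simulation run."""

    def __init__(self, key: int):
        self.key = int(key)

    def stream_generator(self, stream: int) -> np.random.Generator:
        """A bulk Generator for one-off draws (population build, warm start)."""
        return np.random.default_rng(np.random.SeedSequence((self.key, stream)))

    def poisson_counts(self, days: np.ndarray, rate: float) -> np.ndarray:
        """Daily booking counts: same (key, day) always yields the same count."""
        if rate <= 0:
            return np.zeros(len(days), dtype=np.int64)
        u = counter_uniforms(self.key, STREAM_BOOK_COUNT, 0, np.asarray(days) + 1)
        return poisson.ppf(np.clip(u, 1e-12, 1 - 1e-12), rate).astype(np.int64)

    def booking_scores(self, day: int, pids) -> np.ndarray:
        return counter_uniforms(self.key, STREAM_BOOK_PICK, day, pids)

    def stay_normals(self, day: int, pids) -> np.ndarray:
        u = counter_uniforms(self.key, STREAM_STAY, day, pids)
        return ndtri(np.clip(u, 1e-12, 1 - 1e-12))

    def overdose_uniforms(self, day: int, pids) -> np.ndarray:
        return counter_uniforms(self.key, STREAM_OVERDOSE, day, pids)

    def tree_uniforms(self, day: int, pids) -> np.ndarray:
        return counter_uniforms(self.key, STREAM_TREE, day, pids, lanes=4)

    def kit_uniforms(self, day: int, pids) -> np.ndarray:
        return counter_uniforms(self.key, STREAM_KITS, day, pids, lanes=2)

    def community_uniforms(self, pids) -> np.ndarray:
        # day slot 0 is reserved for the one-time community assignment
        return counter_uniforms(self.key, STREAM_KITS, 0, pids)


class GeneratorSource:
    """Adapter giving a plain numpy Generator the CrnSource method surface.

    Draws are sequential (stateful); day/pid arguments are ignored.
    """

    def __init__(self, rng: np.random.Generator):
        self.rng = rng

    def stream_generator(self, stream: int) -> np.random.Generator:
        return self.rng

    def poisson_counts(self, days, rate):
        if rate <= 0:
            return np.zeros(len(days), dtype=np.int64)
        return self.rng.poisson(rate, size=len(days)).astype(np.int64)

    def booking_scores(self, day, pids):
        return self.rng.random(len(pids))

    def stay_normals(self, day, pids):
        return self.rng.standard_normal(len(pids))

    def overdose_uniforms(self, day, pids):
        return self.rng.random(len(pids))

    def tree_uniforms(self, day, pids):
        return self.rng.random((len(pids), 4))

    def kit_uniforms(self, day, pids):
        return self.rng.random((len(pids), 2))

    def community_uniforms(self, pids):
        return self.rng.random(len(pids))


def as_source(rand) -> "CrnSource | GeneratorSource":
    """Coerce an int key, Generator, or existing source into a source."""
    if isinstance(rand, (CrnSource, GeneratorSource)):
        return rand
    if isinstance(rand, np.random.Generator):
        return GeneratorSource(rand)
    return CrnSource(int(rand))
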