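"""Take-home naloxone kit channels and the kit-count ledger.

Three distribution channels: a one-time community assignment at the start of
the reporting horizon, direct handout to opioid-using persons at jail
release, and a peer ("social network") kit probability for released persons.
A person holds at most one own kit and one peer-kit flag; re-receipt is
idempotent and never double-counted (the ledger counts kits, not offers).
Kits persist through re-incarceration. After an administered reversal the
kit is replaced immediately: possession flags stay true and the replacement
is tallied so that total kits = community + jail + network + replacements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import InterventionScenario
from .population import USE_NONE, Population
from .rng import as_source

__all__ = [
    "KitLedger",
    "apply_community_distribution",
    "apply_jail_release_distribution",
    "apply_network_distribution",
    "availability_and_use",
]


@dataclass
class KitLedger:
    distributed_community: int = 0
    distributed_jail: int = 0
    distributed_network: int = 0
    replacements: int = 0
    used: int = 0

    @property
    def total(self) -> int:
        """Kits handed out including immediate replacements after use."""
        return (self.distributed_community + self.distributed_jail
                + self.distributed_network + self.replacements)

    @property
    def total_initial(self) -> int:
        """Kits handed out excluding replacements."""
        return (self.distributed_community + self.distributed_jail
                + self.distributed_network)


def apply_community_distribution(pop: Population, scenario: InterventionScenario,
                                 ledger: KitLedger, rand) -> np.ndarray:
    """One-time community assignment: each opioid user independently receives
    a kit with probability cov_community. Returns recipient pids."""
    if scenario.cov_community <= 0:
        return np.empty(0, dtype=np.int64)
    rand = as_source(rand)
    u = pop.user_ids
    got = rand.community_uniforms(u) < scenario.cov_community
    recipients = u[got & ~pop.has_kit[u]]
    pop.has_kit[u[got]] = True
    ledger.distributed_community += len(recipients)
    return recipients


def _released_users(released_pids: np.ndarray, pop: Population) -> np.ndarray:
    pids = np.asarray(released_pids, dtype=np.int64)
    return pids[pop.use_type[pids] != USE_NONE]


def apply_jail_release_distribution(released_pids, pop: Population,
                                    scenario: InterventionScenario,
                                    ledger: KitLedger, rand, day: int = 0,
                                    _kit_u: np.ndarray | None = None) -> np.ndarray:
    """Hand kits to opioid-using persons on the day's release list with
    probability cov_jail each. Non-users are never eligible."""
    users = _released_users(released_pids, pop)
    if scenario.cov_jail <= 0 or len(users) == 0:
        return np.empty(0, dtype=np.int64)
    u = _kit_u[:, 0] if _kit_u is not None else as_source(rand).kit_uniforms(day, users)[:, 0]
    got = u < scenario.cov_jail
    new = users[got & ~pop.has_kit[users]]
    pop.has_kit[users[got]] = True
    ledger.distributed_jail += len(new)
    return new


def apply_network_distribution(released_pids, pop: Population,
                               scenario: InterventionScenario,
                               ledger: KitLedger, rand, day: int = 0,
                               _kit_u: np.ndarray | None = None) -> np.ndarray:
    """Set the peer-kit flag for released opioid users with probability
    cov_network; each newly set flag counts as one distributed kit."""
    users = _released_users(released_pids, pop)
    if scenario.cov_network <= 0 or len(users) == 0:
        return np.empty(0, dtype=np.int64)
    u = _kit_u[:, 1] if _kit_u is not None else as_source(rand).kit_uniforms(day, users)[:, 1]
    got = u < scenario.cov_network
    new = users[got & ~pop.peer_kit[users]]
    pop.peer_kit[users[got]] = True
    ledger.distributed_network += len(new)
    return new


def availability_and_use(pop: Population, pids: np.ndarray,
                         administered: np.ndarray | None,
                         ledger: KitLedger) -> np.ndarray:
    """Availability = own kit or peer kit. When called with the administration
    outcome, tallies use and the immediate replacement; possession flags are
    left true (a new kit is obtained immediately after use)."""
    pids = np.atleast_1d(np.asarray(pids, dtype=np.int64))
    avail = pop.has_kit[pids] | pop.peer_kit[pids]
    if administered is not None:
        n = int(np.sum(administered))
        ledger.used += n
        ledger.replacements += n
    return avail
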