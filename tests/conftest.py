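"""Shared fixtures: small, fast configurations built programmatically."""

import numpy as np
import pytest

import thnsim


@pytest.fixture(scope="session")
def default_cfg():
    return thnsim.load_config(None)


@pytest.fixture()
def small_cfg():
    """A desk-size world: ~2200 users, 1200-person CLI pool, 6 bookings/day."""
    return thnsim.load_config({
        "n_iou": 600, "n_niou": 1600, "n_cli": 1200,
        "booking_rate": 6.0, "census_target": 150,
        "replicates": 2, "seed": 7,
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
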