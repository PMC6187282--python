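"""Shared fixtures.

The Monte Carlo scenario runs are expensive, so they are session-scoped and
shared between the physics tests and the acceptance tests.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import deantrack as dt

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from deantrack.scenarios import SHALLOW, VERIFICATION, ML_PER_H, run_scenario


@pytest.fixture(scope="session")
def water():
    return dt.WATER


@pytest.fixture(scope="session")
def ar2_channel():
    return VERIFICATION.channel


@pytest.fixture(scope="session")
def square_channel():
    return dt.make_channel(80e-6, 80e-6, 3e-3, 200e-6, 5)


@pytest.fixture(scope="session")
def ar2_bank(ar2_channel, water):
    return dt.FieldBank(ar2_channel, water, 0.6 * ML_PER_H)


@pytest.fixture(scope="session")
def ar2_run_large(ar2_bank):
    """Verification spiral, 7.2 um particles, 0.6 mL/h, 100 particles."""
    return run_scenario(
        VERIFICATION, 7.2e-6, 0.6 * ML_PER_H, n_particles=100, seed=1, bank=ar2_bank
    )


@pytest.fixture(scope="session")
def ar2_run_small(ar2_bank):
    """Verification spiral, 1.9 um particles, 0.6 mL/h, 100 particles."""
    return run_scenario(
        VERIFICATION, 1.9e-6, 0.6 * ML_PER_H, n_particles=100, seed=1, bank=ar2_bank
    )


@pytest.fixture(scope="session")
def ar9_run():
    """Shallow spiral, 10 um particles, 80 mL/h, 100 particles."""
    return run_scenario(SHALLOW, 10e-6, 80 * ML_PER_H, n_particles=100, seed=1)
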