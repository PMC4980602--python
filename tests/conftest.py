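"""Shared fixtures: beams, models and simulated datasets.

Session-scoped where construction is expensive; every stochastic object is
built from a fixed seed so the suite is fully reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

from nsad import crystal, merging, physics


@pytest.fixture(scope="session")
def beam():
    return physics.energy_from_wavelength(1.17)


@pytest.fixture(scope="session")
def cell():
    return crystal.RUBREDOXIN_CELL


@pytest.fixture(scope="session")
def small_model(cell):
    """A 20-atom toy crystal for oracle comparisons."""
    return crystal.generate_toy_structure(20, cell, seed=3)


@pytest.fixture(scope="session")
def default_model(cell):
    """The full-size 706-atom reference model."""
    return crystal.generate_toy_structure(706, cell, seed=1)


@pytest.fixture(scope="session")
def noiseless_obs(default_model, beam):
    """Noiseless single-observation data to 2.3 Å."""
    return crystal.simulate_unmerged(
        default_model, beam, 2.3, multiplicity=1, noise_frac=0.0, seed=1
    )


@pytest.fixture(scope="session")
def noisy_obs(default_model, beam):
    """Reference-condition data: multiplicity 13, ~13 merged I/σ, 2.3 Å."""
    return crystal.simulate_unmerged(
        default_model, beam, 2.3, multiplicity=13, noise_frac=0.28, seed=1
    )


@pytest.fixture(scope="session")
def noiseless_merged(noiseless_obs):
    return merging.merge(noiseless_obs)


@pytest.fixture(scope="session")
def noisy_merged(noisy_obs):
    return merging.merge(noisy_obs)
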