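"""Shared fixtures: small synthetic systems exercised by most suites."""

import numpy as np
import pytest

import scrambletrack as st
from scrambletrack.synth import LINING_RANGES


@pytest.fixture(scope="session")
def small_scenario():
    """Noise-free scripted scenario small enough for exact brute-force checks."""
    return st.SyntheticScenario(
        n_lipids_per_leaflet=32,
        n_frames=200,
        water_per_slab=2,
        n_background_ions=6,
        noise_sigma=0.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_system(small_scenario):
    return st.generate(small_scenario)


@pytest.fixture(scope="session")
def small_centered(small_system):
    """(atoms, centered frames, phosphorus map, cylinders) for the small system."""
    atoms, frames, truth = small_system
    pmap = st.lipid_phosphorus_map(atoms)
    centered = st.center_membrane(frames, np.fromiter(pmap.values(), dtype=int))
    cylinders = st.define_cylinder(atoms, centered, LINING_RANGES)
    return atoms, centered, pmap, cylinders


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)
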