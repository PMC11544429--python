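"""Shared fixtures: small synthetic crystals sized for fast unit tests."""

import numpy as np
import pytest

import cryphase as cp

# Small crystal used by most engine/projection tests: 30 A cubic cell on a
# 32^3 grid at 3.0 A. Large enough for the solvent-flattening constraint to
# be strong, small enough that a 150-iteration run takes ~2 s.
SMALL_CELL = cp.UnitCellGrid((30.0, 30.0, 30.0), (90.0, 90.0, 90.0), (32, 32, 32), 3.0)

# Tiny grid for brute-force DFT cross-checks (8^3 voxels).
TINY_CELL = cp.UnitCellGrid((16.0, 16.0, 16.0), (90.0, 90.0, 90.0), (8, 8, 8), 4.0)


@pytest.fixture(scope="session")
def small_crystal():
    """(truth map, true envelope, prior) for the small toy crystal."""
    spec = cp.ToyCrystalSpec(cell=SMALL_CELL, seed=1, n_blobs=40, blob_width=1.8)
    return cp.make_toy_crystal(spec)


@pytest.fixture(scope="session")
def small_refl(small_crystal):
    truth, _, _ = small_crystal
    return cp.simulate_data(truth, seed=1)


@pytest.fixture(scope="session")
def tiny_crystal():
    spec = cp.ToyCrystalSpec(cell=TINY_CELL, seed=3, n_blobs=6, blob_width=1.6, solvent_fraction=0.6)
    return cp.make_toy_crystal(spec)


@pytest.fixture(scope="session")
def tiny_refl(tiny_crystal):
    truth, _, _ = tiny_crystal
    return cp.simulate_data(truth, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
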