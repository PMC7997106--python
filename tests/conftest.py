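"""Shared fixtures: small configurations and cached expensive descriptors."""

from __future__ import annotations

import numpy as np
import pytest

from zernipatch.config import RunConfig
from zernipatch.fixtures import FixtureSpec, make_atomset, make_complementary_pair
from zernipatch.structure_io import ResidueSelection
from zernipatch.zernike import describe_patch


@pytest.fixture(scope="session")
def fast_config() -> RunConfig:
    """Coarse settings for tests that exercise plumbing, not accuracy."""
    return RunConfig(order=8, dim=32, samples_per_atom=60)


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def helix_atoms():
    return make_atomset(FixtureSpec("helix_like", params={"n_atoms": 20}))


@pytest.fixture(scope="session")
def helix_descriptor(helix_atoms, fast_config):
    return describe_patch(helix_atoms, None, fast_config)


@pytest.fixture(scope="session")
def patch_selection() -> ResidueSelection:
    """The residue-1 lining of the capped-feature fixtures."""
    return ResidueSelection.from_string("1")


@pytest.fixture(scope="session")
def complementary_descriptors(patch_selection, default_config):
    """Descriptors of the planted cavity/bump pair and its mismatched control,
    at default (full-accuracy) settings; computed once per session."""
    receptor, ligand = make_complementary_pair(seed=1)
    control = make_atomset(
        FixtureSpec(
            "bump",
            params={"feature_radius": 14.0, "half_angle_deg": 40.0, "lining_charge": 0.4},
        )
    )
    return {
        "receptor": describe_patch(receptor, patch_selection, default_config),
        "ligand": describe_patch(ligand, patch_selection, default_config),
        "control": describe_patch(control, patch_selection, default_config),
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
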