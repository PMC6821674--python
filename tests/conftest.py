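"""Shared fixtures: small deterministic synthetic inputs."""
from __future__ import annotations

import pytest

from metaproteo.simulate import (
    generate_reference_proteomes,
    simulate_community,
)
from metaproteo.taxonomy import generate_taxonomy


@pytest.fixture(scope="session")
def tree4():
    return generate_taxonomy(4, branching=(2, 1, 2, 1, 1), seed=0)


@pytest.fixture(scope="session")
def tree8():
    return generate_taxonomy(8, branching=(2, 2, 2, 1, 1), seed=0)


@pytest.fixture(scope="session")
def proteomes4(tree4):
    return generate_reference_proteomes(
        tree4, n_proteins_per_genus=6, n_families=8,
        within_family_identity=0.9, seed=11)


@pytest.fixture(scope="session")
def singleton_proteomes4(tree4):
    """Independent random proteins (no homolog families)."""
    return generate_reference_proteomes(
        tree4, n_proteins_per_genus=6, n_families=0,
        within_family_identity=1.0, seed=12)


@pytest.fixture(scope="session")
def community4(tree4):
    return simulate_community(tree4, n_present=4, skew=1.0, seed=5)
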