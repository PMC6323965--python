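import numpy as np
import pytest

from allokit import (
    AllostericModel,
    FixtureSpec,
    build_contact_network,
    generate_fixture,
)


@pytest.fixture(scope="session")
def helix30():
    """30-residue ideal α-helix: model + PDB text."""
    return generate_fixture(FixtureSpec("ideal_helix", 30))


@pytest.fixture(scope="session")
def cluster5():
    """Compact 5-bead jittered cluster with a simple spectrum."""
    return generate_fixture(FixtureSpec("cubic_cluster", 5, seed=11, jitter=0.4))


@pytest.fixture(scope="session")
def cluster4():
    """Non-planar jittered 4-bead cluster (complete contact graph)."""
    return generate_fixture(FixtureSpec("cubic_cluster", 4, seed=11, jitter=0.4))


@pytest.fixture(scope="session")
def dimer24():
    """Exactly two-fold symmetric homodimer, 12 residues per chain."""
    return generate_fixture(FixtureSpec("symmetric_dimer", 24))


@pytest.fixture(scope="session")
def dumbbell20():
    """Two lattice domains bridged by a triangulated prism linker."""
    return generate_fixture(
        FixtureSpec("two_domain_dumbbell", 20, linker_length=2, seed=5, jitter=0.2)
    )


@pytest.fixture(scope="session")
def helix_model(helix30):
    model, _ = helix30
    return AllostericModel(model)


@pytest.fixture(scope="session")
def helix_network(helix30):
    model, _ = helix30
    return build_contact_network(model)


def structure_from_coords(coords, chains=None):
    """StructureModel straight from coordinates (full float precision)."""
    from allokit.structure import ResidueRecord, StructureModel

    coords = np.asarray(coords, dtype=float)
    if chains is None:
        chains = ["A"] * len(coords)
    counters: dict = {}
    records = []
    for xyz, ch in zip(coords, chains):
        counters[ch] = counters.get(ch, 0) + 1
        records.append(
            ResidueRecord(chain_id=ch, seq_number=counters[ch], insertion_code="",
                          residue_name="ALA", ca_position=np.array(xyz))
        )
    return StructureModel(records)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(rng.normal(size=3)).as_matrix()


def c2_permutation(n: int) -> np.ndarray:
    """Chain-swap permutation of the symmetric dimer (A_i <-> B_i)."""
    half = n // 2
    return np.concatenate([np.arange(half, n), np.arange(half)])
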