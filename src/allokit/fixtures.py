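"""Deterministic synthetic Cα structures with known geometric properties.

These toy structures (bead chains, ideal helices, compact lattice clusters,
two-domain dumbbells, exactly two-fold-symmetric dimers) exercise every
stage of the pipeline without external data.  Coordinates are deterministic
given the spec and seed; optional uniform jitter breaks accidental spectral
degeneracies (e.g. collinear chains) without changing the topology
qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .structure import StructureModel, parse_structure

FIXTURE_KINDS = (
    "linear_chain",
    "ideal_helix",
    "cubic_cluster",
    "two_domain_dumbbell",
    "symmetric_dimer",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic structure.

    Geometry defaults follow standard coarse-grained practice: 3.8 Å
    consecutive-Cα spacing, α-helix rise 1.5 Å / twist 100° / radius 2.3 Å.
    """

    kind: str
    n_residues: int
    spacing: float = 3.8
    rise: float = 1.5
    twist_deg: float = 100.0
    radius: float = 2.3
    lattice_spacing: float = 3.8
    linker_length: int = 4
    dimer_offset: float = 5.0
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValidationError(
                f"unknown fixture kind {self.kind!r}; choose from {FIXTURE_KINDS}"
            )
        if self.n_residues < 2:
            raise ValidationError("n_residues must be >= 2")
        for name in ("spacing", "rise", "radius", "lattice_spacing", "dimer_offset"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.jitter < 0:
            raise ValidationError("jitter must be non-negative")
        if self.kind == "symmetric_dimer" and self.n_residues % 2:
            raise ValidationError("symmetric_dimer needs an even n_residues")
        if self.kind == "two_domain_dumbbell" and self.linker_length < 1:
            raise ValidationError("linker_length must be >= 1")


def _linear_chain(spec: FixtureSpec) -> np.ndarray:
    return np.column_stack(
        [
            spec.spacing * np.arange(spec.n_residues),
            np.zeros(spec.n_residues),
            np.zeros(spec.n_residues),
        ]
    )


def _ideal_helix(spec: FixtureSpec, n: int | None = None) -> np.ndarray:
    n = spec.n_residues if n is None else n
    t = np.deg2rad(spec.twist_deg) * np.arange(n)
    return np.column_stack(
        [spec.radius * np.cos(t), spec.radius * np.sin(t), spec.rise * np.arange(n)]
    )


def _cubic_cluster(spec: FixtureSpec, n: int | None = None) -> np.ndarray:
    n = spec.n_residues if n is None else n
    side = int(np.ceil(n ** (1 / 3)))
    pts = []
    for a in range(side):
        for b in range(side):
            for c in range(side):
                pts.append((a, b, c))
                if len(pts) == n:
                    return np.array(pts, dtype=float) * spec.lattice_spacing
    return np.array(pts[:n], dtype=float) * spec.lattice_spacing


def _two_domain_dumbbell(spec: FixtureSpec) -> np.ndarray:
    """Two lattice domains bridged by a triangulated-prism linker.

    ``linker_length`` counts prism segments of three beads each; a
    single-strand linker would leave floppy torsional mechanisms (extra
    zero modes) in a central-force network, a triangulated prism is
    generically rigid.
    """
    s = spec.lattice_spacing
    n_link = min(3 * spec.linker_length, max(0, spec.n_residues - 4))
    n_link -= n_link % 3
    n_segments = n_link // 3
    n_dom = spec.n_residues - n_link
    n1 = n_dom // 2 + n_dom % 2
    n2 = n_dom - n1
    dom1 = _cubic_cluster(spec, n1)
    x0 = dom1[:, 0].max()
    tri = np.array([[0.0, 0.0], [s, 0.0], [0.5 * s, 0.87 * s]])
    linker = np.array(
        [
            [x0 + (t + 1) * s, tri[c, 0], tri[c, 1]]
            for t in range(n_segments)
            for c in range(3)
        ]
    ).reshape(n_link, 3)
    dom2 = _cubic_cluster(spec, n2) + np.array([x0 + (n_segments + 1) * s, 0.0, 0.0])
    return np.vstack([dom1, linker, dom2])


def _symmetric_dimer(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Chain A is a short helix offset from the z axis; chain B is its exact
    180°-about-z copy. Returns (coords, chain assignment)."""
    half = spec.n_residues // 2
    a = _ideal_helix(spec, half) + np.array([spec.dimer_offset, 0.0, 0.0])
    rot = np.diag([-1.0, -1.0, 1.0])  # C2 about z
    b = a @ rot.T
    coords = np.vstack([a, b])
    chains = np.array(["A"] * half + ["B"] * half)
    return coords, chains


def fixture_coordinates(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic coordinates and chain assignment for a fixture spec.

    Jitter (uniform in a cube of half-width ``spec.jitter`` Å) is applied
    after the ideal geometry, so it breaks the symmetry/collinearity of the
    ideal shapes; with ``jitter=0`` the geometry is exact.
    """
    if spec.kind == "linear_chain":
        coords = _linear_chain(spec)
    elif spec.kind == "ideal_helix":
        coords = _ideal_helix(spec)
    elif spec.kind == "cubic_cluster":
        coords = _cubic_cluster(spec)
    elif spec.kind == "two_domain_dumbbell":
        coords = _two_domain_dumbbell(spec)
    else:
        coords, chains = _symmetric_dimer(spec)
        coords = _apply_jitter(coords, spec)
        return coords, chains
    chains = np.array(["A"] * spec.n_residues)
    return _apply_jitter(coords, spec), chains


def _apply_jitter(coords: np.ndarray, spec: FixtureSpec) -> np.ndarray:
    if spec.jitter == 0:
        return coords
    rng = np.random.default_rng(spec.seed)
    return coords + rng.uniform(-spec.jitter, spec.jitter, size=coords.shape)


def coords_to_pdb(coords: np.ndarray, chains=None, resnames=None) -> str:
    """Serialize Cα coordinates as fixed-column poly-alanine PDB text."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if chains is None:
        chains = ["A"] * n
    if resnames is None:
        resnames = ["ALA"] * n
    lines = []
    resnum = 0
    prev_chain = None
    for serial, (xyz, ch, rn) in enumerate(zip(coords, chains, resnames), start=1):
        if ch != prev_chain:
            resnum = 0
            prev_chain = ch
        resnum += 1
        x, y, z = xyz
        lines.append(
            f"ATOM  {serial:>5d}  CA  {rn:<3s} {ch}{resnum:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{'C':>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_fixture(spec: FixtureSpec) -> tuple[StructureModel, str]:
    """Build a fixture and its PDB text; the model is re-parsed from the text
    so that fixtures exercise the same I/O path as real structures."""
    coords, chains = fixture_coordinates(spec)
    pdb_text = coords_to_pdb(coords, chains)
    return parse_structure(pdb_text), pdb_text


# -- convenience constructors ------------------------------------------------

def linear_chain(n: int, spacing: float = 3.8, seed: int = 0, jitter: float = 0.0):
    return generate_fixture(
        FixtureSpec("linear_chain", n, spacing=spacing, seed=seed, jitter=jitter)
    )


def ideal_helix(n: int, seed: int = 0, jitter: float = 0.0):
    return generate_fixture(FixtureSpec("ideal_helix", n, seed=seed, jitter=jitter))


def cubic_cluster(n: int, seed: int = 0, jitter: float = 0.0):
    return generate_fixture(FixtureSpec("cubic_cluster", n, seed=seed, jitter=jitter))


def two_domain_dumbbell(n: int, linker_length: int = 4, seed: int = 0,
                        jitter: float = 0.0):
    return generate_fixture(
        FixtureSpec("two_domain_dumbbell", n, linker_length=linker_length,
                    seed=seed, jitter=jitter)
    )


def symmetric_dimer(n: int, dimer_offset: float = 5.0, seed: int = 0,
                    jitter: float = 0.0):
    return generate_fixture(
        FixtureSpec("symmetric_dimer", n, dimer_offset=dimer_offset, seed=seed,
                    jitter=jitter)
    )
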