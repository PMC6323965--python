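"""Cα elastic network model: contact network, Hessian, normal modes.

The protein is coarse-grained to its Cα atoms connected by harmonic springs
within a distance cutoff (anisotropic network model).  The normal modes of
the resulting 3N×3N Hessian are the orthonormal basis in which the
allosteric potential is written; a connected, non-collinear structure has
exactly six zero-frequency rigid-body modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import DisconnectedStructureError, ValidationError
from .structure import StructureModel, compute_distance_matrix

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 11.0          # Å, Cα contact cutoff
DEFAULT_BASE_K = 1.0           # spring constant, arbitrary energy/Å² units
DEFAULT_RIGID_TOL = 1e-9       # relative eigenvalue threshold for rigid modes
N_RIGID_EXPECTED = 6


class ContactNetwork:
    """Cutoff-based spring network over Cα atoms.

    Edges are unordered pairs ``(i, j)`` with ``i < j``, each carrying a
    positive spring constant ``k`` and an equilibrium distance ``r0`` (Å).
    """

    def __init__(self, n_residues: int, cutoff: float, base_k: float = DEFAULT_BASE_K):
        self.n_residues = int(n_residues)
        self.cutoff = float(cutoff)
        self.base_k = float(base_k)
        self._k: dict[tuple[int, int], float] = {}
        self._r0: dict[tuple[int, int], float] = {}

    @staticmethod
    def _canon(i: int, j: int) -> tuple[int, int]:
        if i == j:
            raise ValidationError(f"self-edge ({i},{i}) not allowed")
        return (i, j) if i < j else (j, i)

    def set_edge(self, i: int, j: int, k: float, r0: float) -> None:
        if k <= 0:
            raise ValidationError(f"spring constant must be positive, got {k}")
        e = self._canon(i, j)
        self._k[e] = float(k)
        self._r0[e] = float(r0)

    def has_edge(self, i: int, j: int) -> bool:
        return self._canon(i, j) in self._k

    def spring_constant(self, i: int, j: int) -> float:
        return self._k[self._canon(i, j)]

    def rest_length(self, i: int, j: int) -> float:
        return self._r0[self._canon(i, j)]

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(self._k)

    @property
    def n_edges(self) -> int:
        return len(self._k)

    def edge_arrays(self):
        """(i, j, k, r0) as parallel numpy arrays, edges sorted."""
        es = self.edges
        i = np.array([e[0] for e in es], dtype=int)
        j = np.array([e[1] for e in es], dtype=int)
        k = np.array([self._k[e] for e in es])
        r0 = np.array([self._r0[e] for e in es])
        return i, j, k, r0

    def neighbors(self, i: int) -> list[int]:
        out = []
        for (a, b) in self._k:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_residues, dtype=int)
        for (a, b) in self._k:
            deg[a] += 1
            deg[b] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        """Boolean N×N adjacency matrix."""
        a = np.zeros((self.n_residues, self.n_residues), dtype=bool)
        for (i, j) in self._k:
            a[i, j] = a[j, i] = True
        return a

    def copy(self) -> "ContactNetwork":
        new = ContactNetwork(self.n_residues, self.cutoff, self.base_k)
        new._k = dict(self._k)
        new._r0 = dict(self._r0)
        return new

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ContactNetwork)
            and self.n_residues == other.n_residues
            and self._k == other._k
            and self._r0 == other._r0
        )


def build_contact_network(
    model: StructureModel,
    cutoff: float = DEFAULT_CUTOFF,
    base_k: float = DEFAULT_BASE_K,
) -> ContactNetwork:
    """Connect every Cα pair within ``cutoff`` Å by a spring of stiffness ``base_k``."""
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    d = compute_distance_matrix(model)
    net = ContactNetwork(model.n_residues, cutoff, base_k)
    ii, jj = np.nonzero(np.triu(d <= cutoff, k=1))
    for i, j in zip(ii, jj):
        net.set_edge(int(i), int(j), base_k, float(d[i, j]))
    return net


def build_hessian(network: ContactNetwork, model: StructureModel) -> np.ndarray:
    """Assemble the 3N×3N anisotropic-network Hessian.

    Each edge contributes the block ``k · d dᵀ / |d|²`` with ``d`` the
    inter-Cα vector at equilibrium; row-block sums vanish, so uniform
    translations cost no energy.
    """
    n = model.n_residues
    if network.n_residues != n:
        raise ValidationError("network and model sizes differ")
    X = model.coords
    i, j, k, _ = network.edge_arrays()
    H = np.zeros((n, 3, n, 3))
    if len(i):
        d = X[j] - X[i]
        d2 = np.einsum("ec,ec->e", d, d)
        blocks = -(k / d2)[:, None, None] * np.einsum("ea,eb->eab", d, d)
        # off-diagonal blocks: each (i,j) pair unique → direct assignment
        H[i, :, j, :] = blocks
        H[j, :, i, :] = blocks
        diag = np.zeros((n, 3, 3))
        np.add.at(diag, i, -blocks)
        np.add.at(diag, j, -blocks)
        idx = np.arange(n)
        H[idx, :, idx, :] = diag
    return H.reshape(3 * n, 3 * n)


@dataclass
class ModeSet:
    """Eigendecomposition of the ENM Hessian with rigid-mode bookkeeping.

    ``vectors`` has shape (3N, N, 3): mode index μ (ascending eigenvalue),
    then per-residue 3-vectors e_{μ,i}.
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray
    rigid_mask: np.ndarray

    @property
    def n_residues(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_rigid(self) -> int:
        return int(self.rigid_mask.sum())

    @property
    def nonrigid_values(self) -> np.ndarray:
        return self.eigenvalues[~self.rigid_mask]

    @property
    def nonrigid_vectors(self) -> np.ndarray:
        return self.vectors[~self.rigid_mask]


def _components_from_hessian(hessian: np.ndarray, n: int) -> list[list[int]]:
    blocks = np.abs(hessian.reshape(n, 3, n, 3)).sum(axis=(1, 3))
    np.fill_diagonal(blocks, 0.0)
    ncomp, labels = connected_components(csr_matrix(blocks > 0), directed=False)
    return [sorted(np.nonzero(labels == c)[0].tolist()) for c in range(ncomp)]


def compute_modes(
    hessian: np.ndarray,
    rigid_tolerance: float = DEFAULT_RIGID_TOL,
    allow_degenerate: bool = False,
) -> ModeSet:
    """Full eigendecomposition with rigid modes flagged.

    Modes with λ ≤ rigid_tolerance × max λ are rigid.  More than six rigid
    modes means the spring network is disconnected or the geometry is
    degenerate (e.g. perfectly collinear) and raises, except for the
    two-bead system (five rigid + one stretch mode) or when
    ``allow_degenerate`` is set.
    """
    dim = hessian.shape[0]
    if hessian.shape != (dim, dim) or dim % 3:
        raise ValidationError(f"hessian must be 3N×3N, got {hessian.shape}")
    if not np.allclose(hessian, hessian.T, atol=1e-10):
        raise ValidationError("hessian is not symmetric")
    n = dim // 3
    w, v = scipy.linalg.eigh(hessian)
    scale = max(float(w.max()), 0.0)
    rigid = w <= rigid_tolerance * scale if scale > 0 else np.ones_like(w, dtype=bool)
    n_rigid = int(rigid.sum())
    if n_rigid > N_RIGID_EXPECTED and n > 2 and not allow_degenerate:
        comps = _components_from_hessian(hessian, n)
        if len(comps) > 1:
            raise DisconnectedStructureError(
                f"disconnected structure: {len(comps)} components "
                f"(sizes {[len(c) for c in comps]}); {n_rigid} rigid modes",
                components=comps,
            )
        raise DisconnectedStructureError(
            f"degenerate structure: {n_rigid} rigid modes for a connected "
            "network (collinear or under-constrained geometry)",
            components=comps,
        )
    vectors = v.T.reshape(dim, n, 3)
    return ModeSet(eigenvalues=w, vectors=vectors, rigid_mask=rigid)


def modes_for(
    model: StructureModel,
    network: ContactNetwork,
    rigid_tolerance: float = DEFAULT_RIGID_TOL,
    allow_degenerate: bool = False,
) -> ModeSet:
    """Convenience: Hessian assembly + eigendecomposition in one call."""
    return compute_modes(
        build_hessian(network, model), rigid_tolerance, allow_degenerate
    )
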