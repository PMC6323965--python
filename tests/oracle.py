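"""Independent brute-force oracle for the allosteric free energy.

Everything here is deliberately naive and separate from the package's
implementation path: Hessian assembled by an explicit python loop, ε by a
triple loop over modes/residues/neighbors, and the per-mode free-energy
contribution obtained by numerical quadrature of the one-dimensional
Gaussian configuration integral Z(ε) = ∫ exp(−ε σ²/(2 k_B T)) dσ rather
than from the closed-form log-ratio.
"""

import numpy as np
from scipy.integrate import quad


def naive_hessian(coords, springs):
    """springs: dict {(i, j): k} with i < j."""
    n = len(coords)
    h = np.zeros((3 * n, 3 * n))
    for (i, j), k in springs.items():
        d = np.asarray(coords[j]) - np.asarray(coords[i])
        u = d / np.linalg.norm(d)
        b = k * np.outer(u, u)
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= b
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= b
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] += b
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] += b
    return h


def naive_modes(coords, springs, n_rigid=6):
    """Eigenvectors as (mode, residue, 3) with the lowest n_rigid dropped."""
    h = naive_hessian(coords, springs)
    w, v = np.linalg.eigh(h)
    n = len(coords)
    order = np.argsort(w)
    keep = order[n_rigid:]
    return w[keep], v[:, keep].T.reshape(len(keep), n, 3)


def naive_epsilon(vectors, neighbor_sets):
    """ε_{μ,i} = Σ_{j∈neighbors(i)} |e_{μ,i} − e_{μ,j}|², explicit loops."""
    m, n, _ = vectors.shape
    eps = np.zeros((m, n))
    for mu in range(m):
        for i in range(n):
            for j in neighbor_sets[i]:
                diff = vectors[mu, i] - vectors[mu, j]
                eps[mu, i] += float(diff @ diff)
    return eps


def gaussian_log_z(epsilon, kt=1.0):
    """ln ∫ exp(−ε σ² / (2 kT)) dσ by adaptive quadrature."""
    val, _ = quad(lambda s: np.exp(-epsilon * s * s / (2.0 * kt)),
                  -np.inf, np.inf)
    return np.log(val)


def oracle_delta_g(coords, springs0, springs_p, neighbor_sets, kt=1.0):
    """Per-residue Δg = −kT Σ_μ [ln Z(ε_P) − ln Z(ε_0)], quadrature per mode."""
    _, vec0 = naive_modes(coords, springs0)
    _, vec_p = naive_modes(coords, springs_p)
    eps0 = naive_epsilon(vec0, neighbor_sets)
    eps_p = naive_epsilon(vec_p, neighbor_sets)
    m, n = eps0.shape
    dg = np.zeros(n)
    for i in range(n):
        for mu in range(m):
            dg[i] -= kt * (gaussian_log_z(eps_p[mu, i], kt)
                           - gaussian_log_z(eps0[mu, i], kt))
    return dg


def naive_springs(coords, cutoff=11.0, base_k=1.0):
    """Distance-cutoff spring dict by double loop."""
    n = len(coords)
    springs = {}
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(np.asarray(coords[i]) - np.asarray(coords[j])) <= cutoff:
                springs[(i, j)] = base_k
    return springs


def neighbor_sets_from_springs(springs, n):
    out = [set() for _ in range(n)]
    for (i, j) in springs:
        out[i].add(j)
        out[j].add(i)
    return [sorted(s) for s in out]
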