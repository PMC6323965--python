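"""Allosteric free energy and modulation from normal-mode ensembles.

The allosteric potential of residue i is U_i(σ) = ½ Σ_μ ε_{μ,i} σ_μ², with
ε_{μ,i} = Σ_{j∈neighbors(i)} |e_{μ,i} − e_{μ,j}|² measuring the elastic work
residue i experiences from the displacement of its contact neighbors along
mode μ.  Integrating the Gaussian variables σ_μ out analytically, the
per-residue free energy difference between the unperturbed (0) and
perturbed (P) ensembles is

    Δg_i = ½ k_B T Σ_μ ln( ε_{μ,i}^{(P)} / ε_{μ,i}^{(0)} )

and the allosteric modulation Δh_i = Δg_i − ⟨Δg⟩_chain is its deviation
from the chain background.  Site-level modulation averages Δh over the
site's residues; the modulation range Δh(UP) − Δh(DOWN) summarizes the
allosteric leverage of a sequence position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .enm import ContactNetwork, ModeSet
from .errors import DisconnectedStructureError, ValidationError
from .perturbation import SiteDefinition
from .structure import StructureModel

logger = logging.getLogger(__name__)

DEFAULT_EPSILON_FLOOR = 1e-12  # relative to each residue's max ε
KB_KCAL_PER_MOL_K = 0.0019872041
DEFAULT_TEMPERATURE_K = 300.0


def kt_to_kcal_per_mol(values, temperature_k: float = DEFAULT_TEMPERATURE_K):
    """Convert energies in units of k_B T to kcal/mol at the given temperature."""
    return np.asarray(values) * KB_KCAL_PER_MOL_K * temperature_k


def epsilon_from_vectors(vectors: np.ndarray, network: ContactNetwork) -> np.ndarray:
    """ε_{μ,i} = Σ_{j∈neighbors(i)} |e_{μ,i} − e_{μ,j}|² for each mode row.

    ``vectors`` has shape (M, N, 3).  The sum runs over the contact-network
    neighbors of i and is exactly zero for a uniform-translation row.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 3 or vectors.shape[1] != network.n_residues:
        raise ValidationError(
            f"vectors shape {vectors.shape} incompatible with N={network.n_residues}"
        )
    m, n, _ = vectors.shape
    i, j, _, _ = network.edge_arrays()
    eps_t = np.zeros((n, m))
    if len(i):
        diff = vectors[:, i, :] - vectors[:, j, :]
        d2 = np.einsum("mec,mec->me", diff, diff)  # (M, E)
        np.add.at(eps_t, i, d2.T)
        np.add.at(eps_t, j, d2.T)
    return eps_t.T


@dataclass
class AllostericPotentialParams:
    """The ε_{μ,i} matrix (non-rigid modes × residues) plus its provenance."""

    epsilon: np.ndarray
    mode_eigenvalues: np.ndarray
    n_residues: int

    @property
    def n_modes(self) -> int:
        return self.epsilon.shape[0]


def allosteric_potential_params(
    modes: ModeSet,
    topology: ContactNetwork,
    mode_count: int | str = "all",
) -> AllostericPotentialParams:
    """Compute ε over the non-rigid modes, neighbors taken from ``topology``.

    ``mode_count`` retains only the lowest-frequency non-rigid modes when an
    integer is given.
    """
    if modes.n_residues != topology.n_residues:
        raise ValidationError("mode set and topology sizes differ")
    deg = topology.degrees()
    if np.any(deg == 0):
        lonely = np.nonzero(deg == 0)[0].tolist()
        raise DisconnectedStructureError(
            f"residues with no contact neighbors: {lonely}", components=[lonely]
        )
    vectors = modes.nonrigid_vectors
    values = modes.nonrigid_values
    if mode_count != "all":
        mc = int(mode_count)
        if not 1 <= mc <= len(values):
            raise ValidationError(
                f"mode_count={mc} out of range 1..{len(values)}"
            )
        vectors = vectors[:mc]
        values = values[:mc]
    eps = epsilon_from_vectors(vectors, topology)
    return AllostericPotentialParams(
        epsilon=eps, mode_eigenvalues=values.copy(), n_residues=topology.n_residues
    )


@dataclass
class FreeEnergyProfile:
    """Per-residue allosteric free energy Δg in units of k_B T."""

    delta_g: np.ndarray
    description: str = ""
    skipped_modes: np.ndarray | None = None  # per residue, below-floor count

    def in_kcal_per_mol(self, temperature_k: float = DEFAULT_TEMPERATURE_K) -> np.ndarray:
        return kt_to_kcal_per_mol(self.delta_g, temperature_k)


def free_energy_profile(
    params0: AllostericPotentialParams,
    paramsP: AllostericPotentialParams,
    temperature_kt: float = 1.0,
    epsilon_floor: float = DEFAULT_EPSILON_FLOOR,
    description: str = "",
) -> FreeEnergyProfile:
    """Δg_i = ½ k_B T Σ_μ ln(ε^{(P)}_{μ,i} / ε^{(0)}_{μ,i}).

    Modes are paired by ascending-eigenvalue rank.  For each residue, mode
    terms where either ε falls below ``epsilon_floor`` × that residue's
    maximum ε (in its own state) are skipped symmetrically; the skip count
    is recorded.
    """
    if params0.n_modes != paramsP.n_modes:
        raise ValidationError(
            f"mode-count mismatch: {params0.n_modes} vs {paramsP.n_modes}"
        )
    if params0.n_residues != paramsP.n_residues:
        raise ValidationError("residue-count mismatch between states")
    e0, eP = params0.epsilon, paramsP.epsilon
    floor0 = epsilon_floor * e0.max(axis=0, keepdims=True)
    floorP = epsilon_floor * eP.max(axis=0, keepdims=True)
    valid = (e0 > floor0) & (eP > floorP)
    ratio = np.ones_like(e0)
    np.divide(eP, e0, out=ratio, where=valid)
    delta_g = 0.5 * temperature_kt * np.where(valid, np.log(ratio), 0.0).sum(axis=0)
    skipped = (~valid).sum(axis=0)
    total_skipped = int(skipped.sum())
    if total_skipped:
        logger.info("epsilon floor skipped %d mode terms", total_skipped)
    return FreeEnergyProfile(
        delta_g=delta_g, description=description, skipped_modes=skipped
    )


@dataclass
class ModulationProfile:
    """Per-residue allosteric modulation Δh (mean-zero per chain), k_B T units."""

    delta_h: np.ndarray
    description: str = ""

    def in_kcal_per_mol(self, temperature_k: float = DEFAULT_TEMPERATURE_K) -> np.ndarray:
        return kt_to_kcal_per_mol(self.delta_h, temperature_k)


def modulation_profile(
    fe: FreeEnergyProfile,
    chain_ids,
    scope: str = "chain",
) -> ModulationProfile:
    """Δh_i = Δg_i minus the mean Δg over residue i's chain (or globally)."""
    g = np.asarray(fe.delta_g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValidationError("delta_g contains non-finite values")
    if scope == "global":
        h = g - g.mean()
    elif scope == "chain":
        chain_ids = np.asarray(chain_ids)
        if chain_ids.shape != g.shape:
            raise ValidationError("chain assignment length mismatch")
        h = np.empty_like(g)
        for c in np.unique(chain_ids):
            mask = chain_ids == c
            h[mask] = g[mask] - g[mask].mean()
    else:
        raise ValidationError(f"scope must be 'chain' or 'global', got {scope!r}")
    return ModulationProfile(delta_h=h, description=fe.description)


@dataclass(frozen=True)
class SiteModulation:
    site_label: str
    delta_h_site: float


def site_modulation(
    mod: ModulationProfile, site: SiteDefinition, model: StructureModel
) -> SiteModulation:
    """Δh_SITE: arithmetic mean of Δh over the site's member residues."""
    idx = site.resolve(model)
    if not idx:
        raise ValidationError(f"site {site.label!r} resolves to no residues")
    return SiteModulation(site.label, float(np.mean(mod.delta_h[idx])))


def modulation_range_profile(
    up: ModulationProfile, down: ModulationProfile
) -> ModulationProfile:
    """Δh(m↕) = Δh(m↑) − Δh(m↓): allosteric leverage of a sequence position."""
    if up.delta_h.shape != down.delta_h.shape:
        raise ValidationError("UP and DOWN profiles have different lengths")
    return ModulationProfile(
        delta_h=up.delta_h - down.delta_h,
        description=f"range[{up.description} - {down.description}]",
    )


def flag_extreme_residues(
    mod: ModulationProfile,
    threshold: float | None = None,
    rule: str = "std",
):
    """Split residues into strongly positively / negatively modulated lists.

    ``rule`` selects the threshold τ: ``"std"`` (τ = ``threshold`` × the
    standard deviation of Δh, default multiplier 1), ``"absolute"``
    (τ = ``threshold`` in k_B T), or ``"quantile"`` (τ = the
    ``threshold``-quantile of |Δh|).  Returns ``(high, low)`` index lists
    with Δh > +τ and Δh < −τ.
    """
    h = np.asarray(mod.delta_h, dtype=float)
    if rule == "std":
        mult = 1.0 if threshold is None else float(threshold)
        tau = mult * h.std()
    elif rule == "absolute":
        if threshold is None:
            raise ValidationError("absolute rule requires a threshold value")
        tau = float(threshold)
    elif rule == "quantile":
        q = 0.9 if threshold is None else float(threshold)
        if not 0 < q < 1:
            raise ValidationError(f"quantile must be in (0,1), got {q}")
        tau = float(np.quantile(np.abs(h), q))
    else:
        raise ValidationError(f"unknown flagging rule {rule!r}")
    if tau < 0:
        raise ValidationError(f"threshold must be non-negative, got {tau}")
    high = np.nonzero(h > tau)[0].tolist()
    low = np.nonzero(h < -tau)[0].tolist()
    return high, low
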