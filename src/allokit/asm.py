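"""Exhaustive mutation scanning and allosteric signaling maps.

An Allosteric Signaling Map (ASM) is the N×N matrix whose row m is the Δh
response profile to perturbing position m: rows are the perturbing
(mutated) positions, columns the responding residues.  UP and DOWN maps
scan stabilizing and destabilizing mutations; their difference is the
modulation-range map.  Site-directed aggregates (mean response of a site
per mutated position, signaling from liganded sites to other sites) follow
by averaging columns.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allostery import (
    allosteric_potential_params,
    free_energy_profile,
    modulation_profile,
    site_modulation,
    DEFAULT_EPSILON_FLOOR,
)
from .enm import ContactNetwork, modes_for, DEFAULT_RIGID_TOL
from .errors import ValidationError
from .perturbation import (
    PerturbationKind,
    PerturbationSpec,
    SiteDefinition,
    apply_perturbation,
    enumerate_site_combinations,
    DEFAULT_ALPHA_BINDING,
    DEFAULT_ALPHA_UP,
    DEFAULT_ALPHA_DOWN,
    DEFAULT_BINDING_PAIR_CUTOFF,
)
from .structure import StructureModel, compute_distance_matrix, matrix_to_json

logger = logging.getLogger(__name__)


@dataclass
class AllostericSignalingMap:
    """N×N map: entry [m, i] = Δh_i under perturbation of position m."""

    values: np.ndarray
    kind: str  # "up" | "down" | "range"
    alphas: dict
    labels: list
    distance_matrix: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self) -> str:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.index.name = "mutated\\responding"
        buf = io.StringIO()
        df.to_csv(buf, float_format="%.8g", lineterminator="\n")
        return buf.getvalue()

    def to_json(self) -> str:
        return matrix_to_json(
            self.labels,
            self.values,
            kind=self.kind,
            alphas=self.alphas,
            distance_matrix=self.distance_matrix.tolist(),
            convention="rows = mutated position m, columns = responding residue i",
        )


def delta_h_for_spec(
    model: StructureModel,
    network: ContactNetwork,
    spec: PerturbationSpec,
    params0=None,
    scope: str = "chain",
    mode_count="all",
    epsilon_floor: float = DEFAULT_EPSILON_FLOOR,
    rigid_tolerance: float = DEFAULT_RIGID_TOL,
    topology: str = "unperturbed",
    binding_pair_cutoff: float = DEFAULT_BINDING_PAIR_CUTOFF,
):
    """Single-perturbation pipeline: spec → (Δg profile, Δh profile).

    ``topology`` chooses the neighbor set for the perturbed-state ε:
    ``"unperturbed"`` (default — binding-added springs enter only through
    the modes) or ``"respective"`` (the perturbed network's own edges).
    """
    if params0 is None:
        modes0 = modes_for(model, network, rigid_tolerance)
        params0 = allosteric_potential_params(modes0, network, mode_count)
    netP = apply_perturbation(network, spec, model, binding_pair_cutoff)
    modesP = modes_for(model, netP, rigid_tolerance)
    eps_topology = network if topology == "unperturbed" else netP
    paramsP = allosteric_potential_params(modesP, eps_topology, mode_count)
    fe = free_energy_profile(
        params0, paramsP, epsilon_floor=epsilon_floor,
        description=spec.describe(model),
    )
    return fe, modulation_profile(fe, model.chain_ids, scope)


def scan_mutations(
    model: StructureModel,
    network: ContactNetwork,
    kind,
    alpha: float | None = None,
    scope: str = "chain",
    mode_count="all",
    epsilon_floor: float = DEFAULT_EPSILON_FLOOR,
    rigid_tolerance: float = DEFAULT_RIGID_TOL,
) -> AllostericSignalingMap:
    """Scan every position with an UP or DOWN mutation; row m = Δh profile.

    Rows are independent and the scan is deterministic: the unperturbed
    modes are computed once, then one eigendecomposition per position.
    """
    kind = PerturbationKind(kind)
    if kind is PerturbationKind.BINDING:
        raise ValidationError("scan kind must be 'up' or 'down'")
    if alpha is None:
        alpha = DEFAULT_ALPHA_UP if kind is PerturbationKind.UP else DEFAULT_ALPHA_DOWN
    n = model.n_residues
    modes0 = modes_for(model, network, rigid_tolerance)
    params0 = allosteric_potential_params(modes0, network, mode_count)
    values = np.empty((n, n))
    for m in range(n):
        try:
            _, mod = delta_h_for_spec(
                model, network,
                PerturbationSpec.mutation(m, kind, alpha),
                params0=params0, scope=scope, mode_count=mode_count,
                epsilon_floor=epsilon_floor, rigid_tolerance=rigid_tolerance,
            )
        except Exception as exc:
            raise type(exc)(
                f"scan failed at position {model.residues[m].label}: {exc}"
            ) from exc
        values[m] = mod.delta_h
    return AllostericSignalingMap(
        values=values,
        kind=kind.value,
        alphas={kind.value: alpha},
        labels=model.labels,
        distance_matrix=compute_distance_matrix(model),
    )


def modulation_range_map(
    up_map: AllostericSignalingMap, down_map: AllostericSignalingMap
) -> AllostericSignalingMap:
    """Elementwise UP − DOWN map: per-position allosteric leverage."""
    if up_map.values.shape != down_map.values.shape:
        raise ValidationError("UP and DOWN maps have different shapes")
    return AllostericSignalingMap(
        values=up_map.values - down_map.values,
        kind="range",
        alphas={**up_map.alphas, **down_map.alphas},
        labels=up_map.labels,
        distance_matrix=up_map.distance_matrix,
    )


def mutations_effect_on_site(
    asm: AllostericSignalingMap, site: SiteDefinition, model: StructureModel
) -> np.ndarray:
    """v[m] = mean Δh over the site's members when position m is mutated."""
    idx = site.resolve(model)
    if not idx:
        raise ValidationError(f"site {site.label!r} resolves to no residues")
    return asm.values[:, idx].mean(axis=1)


def site_to_site_signaling(
    model: StructureModel,
    network: ContactNetwork,
    sites: list,
    liganded: list,
    alpha_binding: float = DEFAULT_ALPHA_BINDING,
    binding_pair_cutoff: float = DEFAULT_BINDING_PAIR_CUTOFF,
    scope: str = "chain",
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Δh_SITE of every unliganded site under binding to the liganded subset.

    ``liganded`` lists labels of sites in ``sites`` that carry ligands; the
    BINDING perturbation is applied to each of them and the site-averaged
    modulation of every remaining site is reported.  A target site that
    shares residues with the liganded set is still reported, with a
    warning.
    """
    by_label = {s.label: s for s in sites}
    unknown = [lab for lab in liganded if lab not in by_label]
    if unknown:
        raise ValidationError(f"unknown liganded site label(s): {unknown}")
    actions = tuple(
        PerturbationSpec.binding(by_label[lab], alpha=alpha_binding).actions[0]
        for lab in liganded
    )
    spec = PerturbationSpec(actions)
    if actions:
        _, mod = delta_h_for_spec(
            model, network, spec, scope=scope,
            binding_pair_cutoff=binding_pair_cutoff, **pipeline_kwargs,
        )
        delta_h = mod.delta_h
    else:
        delta_h = np.zeros(model.n_residues)
    liganded_idx = set()
    for lab in liganded:
        liganded_idx.update(by_label[lab].resolve(model))
    rows = []
    for s in sites:
        if s.label in liganded:
            continue
        idx = s.resolve(model)
        overlap = sorted(liganded_idx.intersection(idx))
        if overlap:
            logger.warning(
                "site %s overlaps the liganded residue set at indices %s",
                s.label, overlap,
            )
        rows.append(
            {
                "site": s.label,
                "delta_h_site_kt": float(np.mean(delta_h[idx])),
                "n_members": len(idx),
                "overlaps_liganded": bool(overlap),
            }
        )
    df = pd.DataFrame(rows, columns=["site", "delta_h_site_kt", "n_members",
                                     "overlaps_liganded"])
    df.attrs["perturbation"] = spec.describe(model)
    return df


def sequential_binding_table(
    model: StructureModel,
    network: ContactNetwork,
    group_sites: list,
    target_sites: list,
    alpha_binding: float = DEFAULT_ALPHA_BINDING,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Cooperativity series: Δh_SITE of targets for 1, 2, … bound copies.

    For every combination of k liganded copies of the symmetry-related
    ``group_sites`` (k = 1..len), reports the site modulation of each
    target site — the signal to inspect for cooperativity upon sequential
    ligand binding to an oligomer's subunits.
    """
    rows = []
    for k in range(1, len(group_sites) + 1):
        for spec in enumerate_site_combinations(group_sites, k, alpha=alpha_binding):
            combo_site = spec.actions[0].targets
            _, mod = delta_h_for_spec(
                model, network, spec, **pipeline_kwargs,
            )
            for t in target_sites:
                sm = site_modulation(mod, t, model)
                rows.append(
                    {
                        "n_bound": k,
                        "combination": combo_site.label,
                        "site": t.label,
                        "delta_h_site_kt": sm.delta_h_site,
                    }
                )
    return pd.DataFrame(rows, columns=["n_bound", "combination", "site",
                                       "delta_h_site_kt"])
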