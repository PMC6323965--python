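"""Perturbations of the spring network: ligand binding, UP/DOWN mutations.

Ligand binding is mimicked by introducing strong springs among the residues
of the binding site; a stabilizing (UP) mutation scales up, and a
destabilizing Ala/Gly-like (DOWN) mutation scales down, every spring in the
mutated residue's contact network.  Perturbations compose multiplicatively
on shared edges and never remove edges.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .enm import ContactNetwork
from .errors import ValidationError
from .structure import StructureModel

DEFAULT_ALPHA_BINDING = 10.0
DEFAULT_ALPHA_UP = 2.0
DEFAULT_ALPHA_DOWN = 0.1
DEFAULT_BINDING_PAIR_CUTOFF = 15.0  # Å; max span of binding-induced springs


class PerturbationKind(str, Enum):
    BINDING = "binding"
    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class SiteDefinition:
    """A named set of residues (e.g. a ligand-binding site).

    ``symmetry_group`` ties together symmetry-related copies of the same
    site across oligomer subunits (e.g. the four "ADPa" sites of a
    tetramer).
    """

    label: str
    members: tuple
    symmetry_group: str | None = None

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"site {self.label!r} has no members")
        object.__setattr__(self, "members", tuple(self.members))

    def resolve(self, model: StructureModel) -> list[int]:
        """Member residues as internal indices (order preserved, deduplicated)."""
        seen: dict[int, None] = {}
        for m in self.members:
            seen.setdefault(model.index_of(m), None)
        return list(seen)


def parse_site_string(label: str, text: str, symmetry_group: str | None = None) -> SiteDefinition:
    """Build a site from a CLI string like ``"A:12,A:45,B:12"``."""
    members = [tok for tok in (t.strip() for t in text.split(",")) if tok]
    return SiteDefinition(label=label, members=tuple(members), symmetry_group=symmetry_group)


def load_sites_json(text: str) -> list[SiteDefinition]:
    """Load site definitions from JSON.

    Accepts ``{"sites": [...]}`` or a bare list; each entry carries
    ``label``, ``members`` (residue strings or ``{chain, resnum, icode}``
    objects) and an optional ``symmetry_group``.
    """
    data = json.loads(text)
    entries = data["sites"] if isinstance(data, dict) else data
    sites = []
    for e in entries:
        members = []
        for m in e["members"]:
            if isinstance(m, str):
                members.append(m)
            else:
                members.append((m["chain"], int(m["resnum"]), m.get("icode", "")))
        sites.append(
            SiteDefinition(
                label=e["label"],
                members=tuple(members),
                symmetry_group=e.get("symmetry_group"),
            )
        )
    return sites


@dataclass(frozen=True)
class PerturbationAction:
    kind: PerturbationKind
    targets: object  # SiteDefinition (BINDING) or single residue identifier (UP/DOWN)
    alpha: float

    def __post_init__(self):
        kind = PerturbationKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.alpha <= 0:
            raise ValidationError(f"alpha must be positive, got {self.alpha}")
        if kind in (PerturbationKind.BINDING, PerturbationKind.UP) and self.alpha <= 1:
            raise ValidationError(f"{kind.value} requires alpha > 1, got {self.alpha}")
        if kind is PerturbationKind.DOWN and not self.alpha < 1:
            raise ValidationError(f"down requires 0 < alpha < 1, got {self.alpha}")
        if kind is PerturbationKind.BINDING and not isinstance(self.targets, SiteDefinition):
            raise ValidationError("binding action requires a SiteDefinition target")


@dataclass(frozen=True)
class PerturbationSpec:
    """A composite perturbation: any mix of binding and mutation actions."""

    actions: tuple

    def __post_init__(self):
        object.__setattr__(self, "actions", tuple(self.actions))

    def validate(self, model: StructureModel) -> None:
        mutated: set[int] = set()
        for a in self.actions:
            if a.kind is PerturbationKind.BINDING:
                a.targets.resolve(model)
            else:
                idx = model.index_of(a.targets)
                if idx in mutated:
                    raise ValidationError(
                        f"residue {model.residues[idx].label} appears in more "
                        "than one mutation action"
                    )
                mutated.add(idx)

    def describe(self, model: StructureModel | None = None) -> str:
        parts = []
        for a in self.actions:
            if a.kind is PerturbationKind.BINDING:
                parts.append(f"binding[{a.targets.label}]x{a.alpha:g}")
            else:
                lab = a.targets
                if model is not None:
                    lab = model.residues[model.index_of(a.targets)].label
                parts.append(f"{a.kind.value}[{lab}]x{a.alpha:g}")
        return " + ".join(parts) if parts else "none"

    @staticmethod
    def binding(site: SiteDefinition, alpha: float = DEFAULT_ALPHA_BINDING) -> "PerturbationSpec":
        return PerturbationSpec(
            (PerturbationAction(PerturbationKind.BINDING, site, alpha),)
        )

    @staticmethod
    def mutation(residue, kind, alpha: float | None = None) -> "PerturbationSpec":
        kind = PerturbationKind(kind)
        if alpha is None:
            alpha = DEFAULT_ALPHA_UP if kind is PerturbationKind.UP else DEFAULT_ALPHA_DOWN
        return PerturbationSpec((PerturbationAction(kind, residue, alpha),))

    @staticmethod
    def empty() -> "PerturbationSpec":
        return PerturbationSpec(())


def apply_perturbation(
    network: ContactNetwork,
    spec: PerturbationSpec,
    model: StructureModel,
    binding_pair_cutoff: float = DEFAULT_BINDING_PAIR_CUTOFF,
) -> ContactNetwork:
    """Return a new spring network with the perturbation applied.

    BINDING stiffens (creating if absent, up to ``binding_pair_cutoff`` Å)
    every pairwise spring among site members; UP/DOWN rescale every existing
    spring incident to the mutated residue.  The input network is never
    modified.
    """
    spec.validate(model)
    out = network.copy()
    for action in spec.actions:
        if action.kind is PerturbationKind.BINDING:
            members = action.targets.resolve(model)
            for i, j in itertools.combinations(members, 2):
                d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
                if d > binding_pair_cutoff:
                    continue
                if out.has_edge(i, j):
                    out.set_edge(i, j, out.spring_constant(i, j) * action.alpha,
                                 out.rest_length(i, j))
                else:
                    out.set_edge(i, j, network.base_k * action.alpha, d)
        else:
            m = model.index_of(action.targets)
            for j in out.neighbors(m):
                out.set_edge(m, j, out.spring_constant(m, j) * action.alpha,
                             out.rest_length(m, j))
    return out


def enumerate_site_combinations(
    sites: list[SiteDefinition],
    choose: int,
    alpha: float = DEFAULT_ALPHA_BINDING,
) -> list[PerturbationSpec]:
    """All ways of ligating ``choose`` of the symmetry-related ``sites``.

    Each combination becomes one BINDING spec over the union of the chosen
    sites, labeled like ``"ADPa.1 & ADPa.2"``; ordering is lexicographic by
    site label (e.g. 2 of 4 sites → the six pair combinations).
    """
    if not 1 <= choose <= len(sites):
        raise ValidationError(
            f"choose={choose} out of range 1..{len(sites)}"
        )
    groups = {s.symmetry_group for s in sites}
    if len(groups) > 1:
        raise ValidationError(f"sites span multiple symmetry groups: {sorted(map(str, groups))}")
    ordered = sorted(sites, key=lambda s: s.label)
    specs = []
    for combo in itertools.combinations(ordered, choose):
        label = " & ".join(s.label for s in combo)
        members = []
        for s in combo:
            members.extend(s.members)
        merged = SiteDefinition(label=label, members=tuple(members),
                                symmetry_group=next(iter(groups)))
        specs.append(PerturbationSpec.binding(merged, alpha=alpha))
    return specs
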