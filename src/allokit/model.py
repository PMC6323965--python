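"""High-level modelling interface.

`AllostericModel` wraps a parsed Cα structure together with the elastic
network built on it; `fit` evaluates the free-energy response to a
perturbation and returns an `AllostericResults` object carrying the Δg/Δh
profiles, diagnostics and exporters, while `scan` runs the exhaustive
per-position mutation scan and returns `SignalingMapResults`.

    >>> model = AllostericModel.from_pdb(pdb_text)
    >>> res = model.fit_mutation("A:15", "up")
    >>> print(res.summary())
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .allostery import (
    DEFAULT_EPSILON_FLOOR,
    DEFAULT_TEMPERATURE_K,
    allosteric_potential_params,
    flag_extreme_residues,
    free_energy_profile,
    kt_to_kcal_per_mol,
    modulation_profile,
    modulation_range_profile,
    site_modulation,
)
from .asm import (
    AllostericSignalingMap,
    delta_h_for_spec,
    modulation_range_map,
    mutations_effect_on_site,
    scan_mutations,
    sequential_binding_table,
    site_to_site_signaling,
)
from .enm import (
    DEFAULT_BASE_K,
    DEFAULT_CUTOFF,
    DEFAULT_RIGID_TOL,
    build_contact_network,
    modes_for,
)
from .errors import ValidationError
from .perturbation import (
    DEFAULT_ALPHA_BINDING,
    DEFAULT_ALPHA_DOWN,
    DEFAULT_ALPHA_UP,
    DEFAULT_BINDING_PAIR_CUTOFF,
    PerturbationKind,
    PerturbationSpec,
    SiteDefinition,
)
from .structure import (
    StructureModel,
    compute_distance_matrix,
    parse_structure,
    write_profile_pdb,
    write_profile_table,
)


@dataclass
class RunConfig:
    """Tunable parameters of the elastic network and the free-energy rules."""

    cutoff: float = DEFAULT_CUTOFF
    base_k: float = DEFAULT_BASE_K
    alpha_binding: float = DEFAULT_ALPHA_BINDING
    alpha_up: float = DEFAULT_ALPHA_UP
    alpha_down: float = DEFAULT_ALPHA_DOWN
    binding_pair_cutoff: float = DEFAULT_BINDING_PAIR_CUTOFF
    temperature_k: float = DEFAULT_TEMPERATURE_K
    epsilon_floor: float = DEFAULT_EPSILON_FLOOR
    rigid_tolerance: float = DEFAULT_RIGID_TOL
    mode_count: object = "all"       # "all" or an int (lowest non-rigid modes)
    scope: str = "chain"             # Δh baseline: "chain" | "global"
    topology: str = "unperturbed"    # ε neighbor set in the perturbed state

    def __post_init__(self):
        for name in ("cutoff", "base_k", "binding_pair_cutoff", "temperature_k"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not self.alpha_binding > 1:
            raise ValidationError("alpha_binding must be > 1")
        if not self.alpha_up > 1:
            raise ValidationError("alpha_up must be > 1")
        if not 0 < self.alpha_down < 1:
            raise ValidationError("alpha_down must be in (0, 1)")
        if self.scope not in ("chain", "global"):
            raise ValidationError("scope must be 'chain' or 'global'")
        if self.topology not in ("unperturbed", "respective"):
            raise ValidationError("topology must be 'unperturbed' or 'respective'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["package_version"] = _pkg_version
        return d


class AllostericModel:
    """Elastic-network allostery model for one structure.

    The contact network, Hessian modes and unperturbed allosteric-potential
    parameters ε⁽⁰⁾ are computed lazily and cached; every `fit`/`scan` call
    reuses them.
    """

    def __init__(self, structure: StructureModel, config: RunConfig | None = None,
                 **config_overrides):
        if config is None:
            config = RunConfig(**config_overrides)
        elif config_overrides:
            config = RunConfig(**{**config.to_dict(), **config_overrides})
        self.structure = structure
        self.config = config
        self.network = build_contact_network(structure, config.cutoff, config.base_k)
        self._modes0 = None
        self._params0 = None

    @classmethod
    def from_pdb(cls, pdb_text: str, chains=None, config: RunConfig | None = None,
                 **config_overrides) -> "AllostericModel":
        """Build a model straight from PDB text (optionally chain-filtered)."""
        return cls(parse_structure(pdb_text, chain_filter=chains),
                   config=config, **config_overrides)

    # -- cached unperturbed state -------------------------------------------

    @property
    def modes(self):
        if self._modes0 is None:
            self._modes0 = modes_for(self.structure, self.network,
                                     self.config.rigid_tolerance)
        return self._modes0

    @property
    def params0(self):
        if self._params0 is None:
            self._params0 = allosteric_potential_params(
                self.modes, self.network, self.config.mode_count
            )
        return self._params0

    @property
    def distance_matrix(self) -> np.ndarray:
        return compute_distance_matrix(self.structure)

    # -- fitting -------------------------------------------------------------

    def fit(self, spec: PerturbationSpec) -> "AllostericResults":
        """Evaluate the response to an arbitrary perturbation spec."""
        cfg = self.config
        fe, mod = delta_h_for_spec(
            self.structure, self.network, spec,
            params0=self.params0, scope=cfg.scope, mode_count=cfg.mode_count,
            epsilon_floor=cfg.epsilon_floor, rigid_tolerance=cfg.rigid_tolerance,
            topology=cfg.topology, binding_pair_cutoff=cfg.binding_pair_cutoff,
        )
        return AllostericResults(self, spec, fe, mod)

    def fit_binding(self, site: SiteDefinition, alpha: float | None = None):
        alpha = self.config.alpha_binding if alpha is None else alpha
        return self.fit(PerturbationSpec.binding(site, alpha))

    def fit_mutation(self, residue, kind, alpha: float | None = None):
        kind = PerturbationKind(kind)
        if alpha is None:
            alpha = (self.config.alpha_up if kind is PerturbationKind.UP
                     else self.config.alpha_down)
        return self.fit(PerturbationSpec.mutation(residue, kind, alpha))

    # -- scanning --------------------------------------------------------------

    def scan(self, kind, alpha: float | None = None) -> "SignalingMapResults":
        """Exhaustive per-position mutation scan (kind 'up' or 'down')."""
        cfg = self.config
        kind = PerturbationKind(kind)
        if alpha is None:
            alpha = (cfg.alpha_up if kind is PerturbationKind.UP
                     else cfg.alpha_down)
        asm = scan_mutations(
            self.structure, self.network, kind, alpha,
            scope=cfg.scope, mode_count=cfg.mode_count,
            epsilon_floor=cfg.epsilon_floor, rigid_tolerance=cfg.rigid_tolerance,
        )
        return SignalingMapResults(self, asm)

    def scan_range(self, alpha_up: float | None = None,
                   alpha_down: float | None = None) -> "SignalingMapResults":
        """UP scan, DOWN scan, and their difference as a RANGE map."""
        up = self.scan("up", alpha_up)
        down = self.scan("down", alpha_down)
        return SignalingMapResults(self, modulation_range_map(up.map, down.map),
                                   up_map=up.map, down_map=down.map)

    def site_signaling(self, sites, liganded, **kwargs) -> pd.DataFrame:
        cfg = self.config
        return site_to_site_signaling(
            self.structure, self.network, sites, liganded,
            alpha_binding=kwargs.pop("alpha_binding", cfg.alpha_binding),
            binding_pair_cutoff=cfg.binding_pair_cutoff,
            scope=cfg.scope, mode_count=cfg.mode_count,
            epsilon_floor=cfg.epsilon_floor,
            rigid_tolerance=cfg.rigid_tolerance, topology=cfg.topology,
            **kwargs,
        )

    def binding_series(self, group_sites, target_sites, **kwargs) -> pd.DataFrame:
        cfg = self.config
        return sequential_binding_table(
            self.structure, self.network, group_sites, target_sites,
            alpha_binding=kwargs.pop("alpha_binding", cfg.alpha_binding),
            scope=cfg.scope, mode_count=cfg.mode_count,
            epsilon_floor=cfg.epsilon_floor,
            rigid_tolerance=cfg.rigid_tolerance, topology=cfg.topology,
            binding_pair_cutoff=cfg.binding_pair_cutoff,
            **kwargs,
        )


class AllostericResults:
    """Δg/Δh profiles for one perturbation, with exporters and a summary."""

    def __init__(self, model: AllostericModel, spec, fe, mod):
        self.model = model
        self.spec = spec
        self.free_energy = fe
        self.modulation = mod

    @property
    def delta_g(self) -> np.ndarray:
        """Per-residue allosteric free energy, k_B T units."""
        return self.free_energy.delta_g

    @property
    def delta_h(self) -> np.ndarray:
        """Per-residue allosteric modulation, k_B T units."""
        return self.modulation.delta_h

    @property
    def df(self) -> pd.DataFrame:
        s = self.model.structure
        t = self.model.config.temperature_k
        return pd.DataFrame(
            {
                "chain": [r.chain_id for r in s.residues],
                "resnum": [r.seq_number for r in s.residues],
                "icode": [r.insertion_code for r in s.residues],
                "resname": [r.residue_name for r in s.residues],
                "delta_g_kt": self.delta_g,
                "delta_h_kt": self.delta_h,
                "delta_g_kcal_mol": kt_to_kcal_per_mol(self.delta_g, t),
                "delta_h_kcal_mol": kt_to_kcal_per_mol(self.delta_h, t),
            }
        )

    def site_modulation(self, site: SiteDefinition):
        return site_modulation(self.modulation, site, self.model.structure)

    def flag_extremes(self, threshold=None, rule="std"):
        """(high, low) residue labels under strong ± modulation."""
        high, low = flag_extreme_residues(self.modulation, threshold, rule)
        labels = self.model.structure.labels
        return [labels[i] for i in high], [labels[i] for i in low]

    def delta_g_csv(self) -> str:
        return write_profile_table(self.model.structure, self.delta_g)

    def delta_h_csv(self) -> str:
        return write_profile_table(self.model.structure, self.delta_h)

    def to_bfactor_pdb(self, pdb_text: str, which: str = "delta_h") -> str:
        values = self.delta_h if which == "delta_h" else self.delta_g
        return write_profile_pdb(self.model.structure, values, pdb_text)

    def summary(self) -> str:
        s = self.model.structure
        h = self.delta_h
        g = self.delta_g
        high, low = self.flag_extremes()
        lines = [
            "Allosteric response summary",
            "===========================",
            f"perturbation:        {self.spec.describe(s)}",
            f"residues:            {s.n_residues} in chains {','.join(s.chains)}",
            f"contact edges:       {self.model.network.n_edges} "
            f"(cutoff {self.model.config.cutoff:g} A)",
            f"non-rigid modes:     {self.model.modes.eigenvalues.size - self.model.modes.n_rigid}",
            f"delta_g [kT]:        min {g.min():+.4f}  mean {g.mean():+.4f}  "
            f"max {g.max():+.4f}",
            f"delta_h [kT]:        min {h.min():+.4f}  max {h.max():+.4f}  "
            f"(per-chain mean 0 by construction)",
            f"high-modulation (>+1 sd): {', '.join(high) if high else 'none'}",
            f"low-modulation  (<-1 sd): {', '.join(low) if low else 'none'}",
        ]
        skipped = self.free_energy.skipped_modes
        if skipped is not None and skipped.sum():
            lines.append(f"mode terms skipped by epsilon floor: {int(skipped.sum())}")
        return "\n".join(lines)


class SignalingMapResults:
    """An allosteric signaling map plus its paired distance matrix."""

    def __init__(self, model: AllostericModel, asm: AllostericSignalingMap,
                 up_map=None, down_map=None):
        self.model = model
        self.map = asm
        self.up_map = up_map
        self.down_map = down_map

    @property
    def values(self) -> np.ndarray:
        return self.map.values

    @property
    def kind(self) -> str:
        return self.map.kind

    def effect_on_site(self, site: SiteDefinition) -> np.ndarray:
        return mutations_effect_on_site(self.map, site, self.model.structure)

    def to_csv(self) -> str:
        return self.map.to_csv()

    def to_json(self) -> str:
        return self.map.to_json()

    def distance_matrix_csv(self) -> str:
        df = pd.DataFrame(self.map.distance_matrix, index=self.map.labels,
                          columns=self.map.labels)
        df.index.name = "residue"
        buf = io.StringIO()
        df.to_csv(buf, float_format="%.4f", lineterminator="\n")
        return buf.getvalue()

    def plot(self, path, cmap: str = "RdBu_r"):
        """Write a static heat-map image (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        lim = float(np.abs(self.values).max()) or 1.0
        im = ax.imshow(self.values, cmap=cmap, vmin=-lim, vmax=lim)
        ax.set_xlabel("responding residue i")
        ax.set_ylabel("mutated position m")
        ax.set_title(f"Allosteric signaling map ({self.kind})")
        fig.colorbar(im, ax=ax, label=r"$\Delta h$ [$k_B T$]")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)

    def summary(self) -> str:
        v = self.values
        return "\n".join(
            [
                "Allosteric signaling map",
                "========================",
                f"kind:     {self.kind} (alphas {self.map.alphas})",
                f"shape:    {v.shape[0]} mutated positions x {v.shape[1]} residues",
                f"delta_h [kT]: min {v.min():+.4f}  max {v.max():+.4f}",
                "convention: rows = mutated position m, columns = responding residue i",
            ]
        )
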