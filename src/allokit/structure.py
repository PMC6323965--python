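"""Cα structure representation and PDB/CSV/JSON input-output.

The model operates on an ordered list of Cα records extracted from a PDB
file.  Residues keep their author identity (chain, sequence number,
insertion code) for user-facing references; internally everything is a
contiguous 0-based index in file order.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .errors import StructureError, ValidationError

logger = logging.getLogger(__name__)

#: (chain_id, seq_number, insertion_code) — the external residue identity.
ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class ResidueRecord:
    """A single residue, reduced to its Cα atom.

    ``insertion_code`` is ``""`` when absent.  ``ca_position`` is in Å.
    """

    chain_id: str
    seq_number: int
    insertion_code: str
    residue_name: str
    ca_position: np.ndarray

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        """Human-readable identifier, e.g. ``A:41`` or ``A:41B``."""
        return f"{self.chain_id}:{self.seq_number}{self.insertion_code}"


class StructureModel:
    """Ordered Cα residues with an index from author identity to 0-based position."""

    def __init__(self, residues: list[ResidueRecord]):
        if len(residues) < 2:
            raise StructureError(
                f"need at least 2 residues with CA atoms, got {len(residues)}"
            )
        self.residues = list(residues)
        self._index: dict[ResidueKey, int] = {}
        for i, r in enumerate(self.residues):
            if r.key in self._index:
                raise StructureError(f"duplicate residue identity {r.label}")
            if not np.all(np.isfinite(r.ca_position)):
                raise StructureError(f"non-finite CA coordinates at {r.label}")
            self._index[r.key] = i
        self.coords = np.array([r.ca_position for r in self.residues], dtype=float)
        self.chain_ids = np.array([r.chain_id for r in self.residues])

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return self.n_residues

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.residues]

    @property
    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def index_of(self, identifier) -> int:
        """Resolve a residue identifier to its internal index.

        Accepts an int (passed through, bounds-checked), a ``(chain, resnum)``
        or ``(chain, resnum, icode)`` tuple, or a string ``"A:41"`` / ``"A:41B"``.
        """
        if isinstance(identifier, (int, np.integer)):
            i = int(identifier)
            if not 0 <= i < self.n_residues:
                raise ValidationError(f"residue index {i} out of range 0..{self.n_residues - 1}")
            return i
        if isinstance(identifier, str):
            identifier = _parse_residue_string(identifier)
        if isinstance(identifier, tuple):
            if len(identifier) == 2:
                identifier = (identifier[0], identifier[1], "")
            key = (str(identifier[0]), int(identifier[1]), str(identifier[2]))
            try:
                return self._index[key]
            except KeyError:
                raise ValidationError(
                    f"unknown residue {key[0]}:{key[1]}{key[2]} (not in structure)"
                ) from None
        raise ValidationError(f"cannot interpret residue identifier {identifier!r}")


def _parse_residue_string(text: str) -> ResidueKey:
    """``"A:41"`` or ``"A:41B"`` → ``("A", 41, "B")``."""
    chain, _, rest = text.strip().partition(":")
    if not rest:
        raise ValidationError(f"bad residue identifier {text!r}, expected 'CHAIN:RESNUM[ICODE]'")
    icode = ""
    if rest and rest[-1].isalpha():
        icode = rest[-1]
        rest = rest[:-1]
    try:
        num = int(rest)
    except ValueError:
        raise ValidationError(f"bad residue number in {text!r}") from None
    return (chain, num, icode)


def parse_structure(pdb_text: str, chain_filter=None) -> StructureModel:
    """Extract the Cα representation from PDB text.

    Only the first MODEL is read; for alternate locations the first-listed
    altLoc is kept; HETATM records and residues lacking a Cα are skipped
    (the latter with a warning).
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise StructureError("no ATOM records found in PDB input")
    model = st[0]
    records: list[ResidueRecord] = []
    n_skipped = 0
    for chain in model:
        if chain_filter is not None and chain.name not in set(chain_filter):
            continue
        for res in chain:
            if res.het_flag == "H":
                continue
            ca = None
            for atom in res:  # file order → first-listed altLoc wins
                if atom.name == "CA":
                    ca = atom
                    break
            if ca is None:
                n_skipped += 1
                logger.warning(
                    "residue %s %s%d%s has no CA atom; skipped",
                    res.name, chain.name, res.seqid.num, res.seqid.icode.strip(),
                )
                continue
            records.append(
                ResidueRecord(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=res.seqid.icode.strip(),
                    residue_name=res.name,
                    ca_position=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                )
            )
    if not records:
        raise StructureError("no CA atoms found (after chain filtering)")
    if len(records) < 2:
        raise StructureError(f"fewer than 2 residues with CA atoms ({len(records)})")
    return StructureModel(records)


def compute_distance_matrix(model: StructureModel) -> np.ndarray:
    """N×N symmetric matrix of Cα–Cα Euclidean distances in Å."""
    d = cdist(model.coords, model.coords)
    np.fill_diagonal(d, 0.0)
    return d


def _format_bfactor(value: float) -> str:
    """Format for PDB columns 61–66 (width 6, 2 decimals), clamping to fit."""
    s = f"{value:6.2f}"
    if len(s) > 6:
        s = f"{max(-99.99, min(999.99, value)):6.2f}"
    return s


def write_profile_pdb(model: StructureModel, per_residue_values, pdb_text: str) -> str:
    """Return ``pdb_text`` with B-factor columns of the model's residues replaced.

    Every atom of residue i gets ``per_residue_values[i]`` (2 decimals, clamped
    to the fixed-width column).  Atoms of residues outside the model are left
    untouched.
    """
    values = np.asarray(per_residue_values, dtype=float)
    if values.shape != (model.n_residues,):
        raise ValidationError(
            f"profile length {values.shape} does not match N={model.n_residues}"
        )
    if not np.all(np.isfinite(values)):
        raise ValidationError("profile contains non-finite values")
    keys = {r.key: i for i, r in enumerate(model.residues)}
    out_lines = []
    for line in pdb_text.splitlines():
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 27:
            chain = line[21].strip()
            try:
                resnum = int(line[22:26])
            except ValueError:
                out_lines.append(line)
                continue
            icode = line[26].strip()
            idx = keys.get((chain, resnum, icode))
            if idx is not None:
                padded = line.ljust(66)
                line = padded[:60] + _format_bfactor(values[idx]) + padded[66:]
        out_lines.append(line)
    return "\n".join(out_lines) + "\n"


def write_profile_table(model: StructureModel, per_residue_values) -> str:
    """CSV profile: header ``chain,resnum,icode,resname,value``, one row per residue."""
    values = np.asarray(per_residue_values, dtype=float)
    if values.shape != (model.n_residues,):
        raise ValidationError(
            f"profile length {values.shape} does not match N={model.n_residues}"
        )
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["chain", "resnum", "icode", "resname", "value"])
    for r, v in zip(model.residues, values):
        writer.writerow([r.chain_id, r.seq_number, r.insertion_code, r.residue_name,
                         f"{v:.8g}"])
    return buf.getvalue()


def matrix_to_json(labels, values, **metadata) -> str:
    """Row-major JSON serialization of a labeled square matrix."""
    values = np.asarray(values, dtype=float)
    obj = dict(metadata)
    obj["labels"] = list(labels)
    obj["values"] = values.tolist()
    return json.dumps(obj)
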