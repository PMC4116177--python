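"""Reading, writing and geometric primitives for protein–ligand complexes.

PDB-format coordinate files are parsed (via :mod:`gemmi`) into a small
internal model that keeps author residue numbering, insertion codes and
HETATM/ATOM provenance — everything downstream pocket extraction needs and
nothing more.  Only the first MODEL of a multi-model file is read; altloc
duplicates are collapsed to the highest-occupancy conformer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AtomRecord",
    "ResidueKey",
    "StructureModel",
    "LigandSelection",
    "PDBParseError",
    "EmptyStructureError",
    "NoLigandError",
    "WATER_CODES",
    "EXCLUDED_HET_CODES",
    "read_pdb",
    "load_pdb",
    "write_pdb",
    "select_ligand",
    "min_distance",
]

#: Residue names treated as water.
WATER_CODES = frozenset({"HOH", "WAT", "DOD"})

#: Small ions and common cryo/buffer additives never auto-selected as ligand.
ION_AND_BUFFER_CODES = frozenset(
    {"NA", "CL", "MG", "ZN", "CA", "K", "SO4", "PO4", "GOL", "EDO"}
)

#: Everything excluded from ligand auto-selection.
EXCLUDED_HET_CODES = WATER_CODES | ION_AND_BUFFER_CODES


class PDBParseError(ValueError):
    """A coordinate record could not be parsed (message names the line)."""


class EmptyStructureError(ValueError):
    """The stream contained no ATOM/HETATM records."""


class NoLigandError(LookupError):
    """No hetero group qualified as the ligand."""


@dataclass(frozen=True, eq=False)
class AtomRecord:
    """One atom of a coordinate file.

    Coordinates are in Å.  ``is_hetero`` distinguishes HETATM from ATOM
    records; ``is_hydrogen`` is derived from the element and lets distance
    computations skip hydrogens uniformly.
    """

    serial: int
    name: str
    element: str
    alt_loc: str
    occupancy: float
    coords: np.ndarray
    is_hetero: bool

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


class ResidueKey(NamedTuple):
    """Identity of a residue: chain, author number, insertion code, 3-letter name."""

    chain: str
    number: int
    insertion_code: str
    name: str

    def __str__(self) -> str:  # e.g. A:MET421
        icode = self.insertion_code.strip()
        return f"{self.chain}:{self.name}{self.number}{icode}"


@dataclass
class StructureModel:
    """Parsed coordinates of one model of one structure.

    ``residues`` preserves file order and maps each :class:`ResidueKey` to
    its atoms (altlocs already collapsed).
    """

    id: str
    residues: dict[ResidueKey, list[AtomRecord]]
    source_model_index: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyStructureError(f"structure {self.id!r} has no residues")

    def atoms(self) -> Iterable[AtomRecord]:
        for atoms in self.residues.values():
            yield from atoms

    def n_atoms(self) -> int:
        return sum(len(a) for a in self.residues.values())

    def protein_residues(self) -> dict[ResidueKey, list[AtomRecord]]:
        """Residues consisting of ATOM (non-hetero) records."""
        return {
            k: v for k, v in self.residues.items() if not any(a.is_hetero for a in v)
        }

    def hetero_residues(self) -> dict[ResidueKey, list[AtomRecord]]:
        return {k: v for k, v in self.residues.items() if any(a.is_hetero for a in v)}

    def find(self, chain: str, number: int, insertion_code: str = "") -> ResidueKey:
        for key in self.residues:
            if (
                key.chain == chain
                and key.number == number
                and key.insertion_code.strip() == insertion_code.strip()
            ):
                return key
        raise KeyError(f"no residue {chain}/{number}{insertion_code} in {self.id!r}")


@dataclass
class LigandSelection:
    """The hetero group used as the distance reference for pocket extraction."""

    structure_id: str
    het_code: str
    chain: str
    residue_key: ResidueKey
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("ligand selection is empty")
        if not all(a.is_hetero for a in self.atoms):
            raise ValueError("ligand selection contains non-HETATM atoms")
        if self.het_code in EXCLUDED_HET_CODES:
            raise ValueError(f"{self.het_code} is a water/ion code, not a ligand")


# --- parsing ---------------------------------------------------------------

_COORD_SLICES = ((30, 38), (38, 46), (46, 54))


def _validate_records(text: str) -> int:
    """Check coordinate fields of every ATOM/HETATM line; return record count.

    gemmi tolerates malformed coordinate columns silently, so this pass
    exists to fail loudly with the offending line number.
    """
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        n += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        for lo, hi in _COORD_SLICES:
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed coordinate field {line[lo:hi]!r}"
                ) from None
        occ = line[54:60].strip()
        if occ:
            try:
                float(occ)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed occupancy field {occ!r}"
                ) from None
    return n


def _collapse_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, tie → lowest altloc."""
    by_name: dict[str, list[AtomRecord]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.alt_loc or "~"))
        out.append(best)
    return out


def read_pdb(text: str, structure_id: str | None = None) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only MODEL 1 is read.  Altloc duplicates are collapsed (highest
    occupancy wins; ties go to the lexicographically smallest altloc
    character).  Residues are keyed by (chain, author number, insertion
    code, name).
    """
    if _validate_records(text) == 0:
        raise EmptyStructureError("no ATOM/HETATM records in input")
    structure = gemmi.read_pdb_string(text)
    model = structure[0]
    residues: dict[ResidueKey, list[AtomRecord]] = {}
    serial = 0
    for chain in model:
        for res in chain:
            key = ResidueKey(
                chain=chain.name,
                number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                name=res.name,
            )
            is_het = res.het_flag == "H"
            records = []
            for atom in res:
                serial += 1
                occ = min(max(float(atom.occ), 0.0), 1.0)
                records.append(
                    AtomRecord(
                        serial=atom.serial or serial,
                        name=atom.name,
                        element=atom.element.name or "X",
                        alt_loc=(atom.altloc or "").strip("\x00").strip(),
                        occupancy=occ,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        is_hetero=is_het,
                    )
                )
            collapsed = _collapse_altlocs(records)
            residues.setdefault(key, []).extend(collapsed)
    label = structure_id or structure.name or "structure"
    return StructureModel(id=label, residues=residues, source_model_index=1)


def load_pdb(path: str | os.PathLike, structure_id: str | None = None) -> StructureModel:
    with open(path) as fh:
        text = fh.read()
    sid = structure_id or os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return read_pdb(text, structure_id=sid)


def write_pdb(model: StructureModel) -> str:
    """Serialize a model as minimal valid PDB text (fixtures and mutant output)."""
    lines = []
    serial = 0
    for key, atoms in model.residues.items():
        for a in atoms:
            serial += 1
            rec = "HETATM" if a.is_hetero else "ATOM  "
            name = a.name if len(a.name) >= 4 else f" {a.name:<3}"
            x, y, z = a.coords
            lines.append(
                f"{rec}{serial:>5} {name}{(a.alt_loc or ' ')[:1]}{key.name:<3} "
                f"{key.chain[:1]}{key.number:>4}{(key.insertion_code or ' ')[:1]}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


# --- ligand selection ------------------------------------------------------


def select_ligand(model: StructureModel, het_code: str | None = None) -> LigandSelection:
    """Pick the ligand hetero group of a complex.

    With ``het_code`` given, that group is returned (waters/ions are
    rejected).  Otherwise the largest hetero group by heavy-atom count is
    auto-selected after discarding waters, the fixed small-ion/buffer list
    and single-atom groups.
    """
    het = model.hetero_residues()
    if het_code is not None:
        code = het_code.upper()
        if code in EXCLUDED_HET_CODES:
            raise ValueError(f"het code {code} is excluded (water/ion/buffer)")
        matches = [(k, v) for k, v in het.items() if k.name.upper() == code]
        if not matches:
            raise NoLigandError(f"no hetero group {code} in {model.id!r}")
        key, atoms = max(matches, key=lambda kv: len(kv[1]))
        return LigandSelection(model.id, code, key.chain, key, list(atoms))
    candidates = [
        (k, v)
        for k, v in het.items()
        if k.name.upper() not in EXCLUDED_HET_CODES and len(v) > 1
    ]
    if not candidates:
        raise NoLigandError(f"no qualifying hetero group in {model.id!r}")
    key, atoms = max(candidates, key=lambda kv: len(kv[1]))
    return LigandSelection(model.id, key.name, key.chain, key, list(atoms))


# --- geometry --------------------------------------------------------------


def _coord_array(atoms: Sequence[AtomRecord], include_hydrogens: bool) -> np.ndarray:
    pts = [a.coords for a in atoms if include_hydrogens or not a.is_hydrogen]
    return np.array(pts, dtype=float).reshape(-1, 3)


def min_distance(
    residue_atoms: Sequence[AtomRecord],
    ligand_atoms: Sequence[AtomRecord],
    include_hydrogens: bool = False,
) -> float:
    """Minimum center-to-center distance (Å) over all atom pairs.

    Hydrogens are excluded by default so the cutoff semantics do not depend
    on whether a structure was deposited with or without them.
    """
    a = _coord_array(residue_atoms, include_hydrogens)
    b = _coord_array(ligand_atoms, include_hydrogens)
    if a.size == 0 or b.size == 0:
        raise ValueError("min_distance requires non-empty atom sets")
    return float(cdist(a, b).min())
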