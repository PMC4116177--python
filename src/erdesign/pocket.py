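"""Distance-cutoff extraction of ligand-binding pockets.

A residue belongs to the pocket of a complex when any of its heavy atoms
lies within the cutoff (default 6.0 Å, closed interval) of any ligand heavy
atom.  Pockets from several complexes of the same receptor are expressed in
a common reference numbering (human ERα by default downstream) and unioned,
so the definition is conservative: a position qualifies if it contacts the
ligand in *any* source structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from .structure_io import LigandSelection, ResidueKey, StructureModel, min_distance

__all__ = [
    "PocketDefinition",
    "NumberingMap",
    "extract_pocket",
    "residue_min_distances",
    "map_to_reference",
    "union_pockets",
    "pocket_table",
]

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class UnmappableStructureError(ValueError):
    """Structure could not be mapped onto the reference numbering."""


@dataclass
class NumberingMap:
    """Mapping between a structure's residues and reference positions.

    One-to-one on mapped pairs and monotone in sequence order.
    """

    pairs: dict[ResidueKey, int]
    method: str
    identity: float

    def position_of(self, key: ResidueKey) -> int | None:
        return self.pairs.get(key)


@dataclass
class PocketDefinition:
    """A cutoff-defined pocket in reference numbering with per-source provenance."""

    cutoff: float
    positions: dict[int, str]  # reference position -> reference residue name
    provenance: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for pos in self.positions:
            if not self.provenance.get(pos):
                raise ValueError(f"position {pos} lacks provenance")
        self.positions = dict(sorted(self.positions.items()))

    def __len__(self) -> int:
        return len(self.positions)

    def to_json(self) -> str:
        return json.dumps(
            {
                "cutoff_angstrom": self.cutoff,
                "positions": [
                    {
                        "position": p,
                        "residue": self.positions[p],
                        "sources": self.provenance[p],
                    }
                    for p in self.positions
                ],
            },
            indent=2,
        )


def residue_min_distances(
    model: StructureModel, ligand: LigandSelection
) -> dict[ResidueKey, float]:
    """Minimum heavy-atom distance from each protein residue to the ligand."""
    if ligand.residue_key not in model.residues:
        raise ValueError(f"ligand {ligand.residue_key} does not belong to {model.id!r}")
    out: dict[ResidueKey, float] = {}
    for key, atoms in model.protein_residues().items():
        heavy = [a for a in atoms if not a.is_hydrogen]
        if not heavy:
            continue
        out[key] = min_distance(heavy, ligand.atoms)
    return out


def extract_pocket(
    model: StructureModel, ligand: LigandSelection, cutoff: float = 6.0
) -> set[ResidueKey]:
    """Protein residues with any heavy atom within ``cutoff`` Å of the ligand.

    The interval is closed (distance ≤ cutoff qualifies); the ligand's own
    residue is never included.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dists = residue_min_distances(model, ligand)
    return {key for key, d in dists.items() if d <= cutoff}


def _chain_sequence(model: StructureModel, chain: str) -> list[tuple[ResidueKey, str]]:
    seq = []
    for key in model.protein_residues():
        if key.chain == chain and key.name in _AA3TO1:
            seq.append((key, _AA3TO1[key.name]))
    return seq


def map_to_reference(
    model: StructureModel,
    reference_sequence: str,
    reference_start: int,
    chain: str | None = None,
    min_identity: float = 0.30,
) -> NumberingMap:
    """Map a structure's residues onto reference numbering.

    If author numbering already agrees with the reference register (≥95%
    identity at shared numbers) the identity map is returned; otherwise a
    global pairwise alignment (match +1, mismatch −1, gap open −2, extend
    −1) supplies the column correspondence.  An overall mapping identity
    below ``min_identity`` raises :class:`UnmappableStructureError`.
    """
    chains = sorted({k.chain for k in model.protein_residues()})
    if not chains:
        raise UnmappableStructureError(f"{model.id!r} has no protein residues")
    use_chain = chain or chains[0]
    seq = _chain_sequence(model, use_chain)
    if not seq:
        raise UnmappableStructureError(f"chain {use_chain!r} has no standard residues")

    ref_positions = range(reference_start, reference_start + len(reference_sequence))
    ref_by_number = dict(zip(ref_positions, reference_sequence))

    shared = [(k, aa) for k, aa in seq if k.number in ref_by_number and not k.insertion_code]
    if shared:
        same = sum(1 for k, aa in shared if ref_by_number[k.number] == aa)
        identity = same / len(shared)
        if identity >= 0.95:
            return NumberingMap(
                pairs={k: k.number for k, _ in shared},
                method="author-numbering",
                identity=identity,
            )

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    struct_seq = "".join(aa for _, aa in seq)
    aln = aligner.align(reference_sequence, struct_seq)[0]
    pairs: dict[ResidueKey, int] = {}
    same = 0
    for (r0, r1), (s0, s1) in zip(*aln.aligned):
        for roff, soff in zip(range(r0, r1), range(s0, s1)):
            key, aa = seq[soff]
            pairs[key] = reference_start + roff
            if reference_sequence[roff] == aa:
                same += 1
    if not pairs or same / len(pairs) < min_identity:
        raise UnmappableStructureError(
            f"{model.id!r}: mapping identity {same / max(len(pairs), 1):.2f} "
            f"below {min_identity:.2f}"
        )
    return NumberingMap(pairs=pairs, method="global-alignment", identity=same / len(pairs))


def identity_numbering(model: StructureModel, chain: str | None = None) -> NumberingMap:
    """Trust author numbering as reference numbering (no reference sequence)."""
    res = [k for k in model.protein_residues() if chain is None or k.chain == chain]
    if not res:
        raise UnmappableStructureError(f"{model.id!r} has no protein residues")
    return NumberingMap(pairs={k: k.number for k in res}, method="author-numbering", identity=1.0)


def union_pockets(
    pockets: Sequence[tuple[Mapping[int, str], str, float]],
    cutoff: float | None = None,
) -> PocketDefinition:
    """Union pockets from several sources into one :class:`PocketDefinition`.

    Each entry is ``(positions → residue name, source label, cutoff)``.  All
    cutoffs must agree — a union across different cutoffs is undefined.
    """
    if not pockets:
        raise ValueError("no pockets to union")
    cutoffs = {round(c, 6) for _, _, c in pockets}
    if cutoff is not None:
        cutoffs.add(round(cutoff, 6))
    if len(cutoffs) != 1:
        raise ValueError(f"mixed cutoffs in union: {sorted(cutoffs)}")
    the_cutoff = cutoffs.pop()
    positions: dict[int, str] = {}
    provenance: dict[int, list[str]] = {}
    for mapping, label, _ in pockets:
        for pos, name in mapping.items():
            positions.setdefault(pos, name)
            provenance.setdefault(pos, []).append(label)
    return PocketDefinition(cutoff=the_cutoff, positions=positions, provenance=provenance)


def pocket_table(
    pocket: PocketDefinition,
    per_structure_distances: Mapping[str, Mapping[int, float]] | None = None,
) -> pd.DataFrame:
    """Tabular pocket report: position, residue, sources, optional distances."""
    rows = []
    for pos, name in pocket.positions.items():
        row: dict[str, object] = {
            "position": pos,
            "residue": name,
            "sources": ",".join(pocket.provenance[pos]),
        }
        if per_structure_distances:
            for label, dists in per_structure_distances.items():
                d = dists.get(pos)
                row[f"min_dist_{label}"] = round(d, 3) if d is not None else None
        rows.append(row)
    return pd.DataFrame(rows)
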