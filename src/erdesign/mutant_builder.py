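"""Rotamer-library point-mutation modelling and steric-clash scoring.

A mutation is modelled by stripping the original side chain beyond CB and
rebuilding the target residue's side chain from ideal internal geometry
(bond lengths, angles and fixed torsions) onto the rigid existing backbone,
once per rotamer of an embedded backbone-independent chi library.  Each
placement is scored for van-der-Waals overlap against the rest of the
protein — and, for the bound state, against the ligand — with a soft-sphere
tolerance; the placement with the least total overlap is kept.

The aromatic-proximity metric (ring-centroid distance between a placed
F/Y/W side chain and a ligand ring) quantifies the stacking opportunity
that motivates aromatic substitutions in a hydrophobic pocket.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .structure_io import (
    AtomRecord,
    LigandSelection,
    ResidueKey,
    StructureModel,
)

__all__ = [
    "RotamerPlacement",
    "ClashParameters",
    "ClashReport",
    "ProximityReport",
    "RotamerLibrary",
    "load_rotamer_library",
    "mutate_residue",
    "clash_score",
    "best_placement",
    "apply_placement",
    "aromatic_proximity",
    "CHI_COUNT",
    "SIDECHAIN_TEMPLATES",
]

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
_STANDARD = set(_ONE_TO_THREE.values())

#: Number of chi dihedrals per templated residue type.
CHI_COUNT = {"GLY": 0, "ALA": 0, "VAL": 1, "LEU": 2, "ILE": 2, "PHE": 2, "TYR": 2, "MET": 3}

# Side-chain templates as internal coordinates.  Each atom is placed by the
# natural-extension (NeRF) construction from three previously placed atoms:
# (name, element, (ref_a, ref_b, ref_c), bond length Å, bond angle deg at
# ref_c, torsion).  The torsion is ("chi", k, offset_deg) — the k-th chi
# dihedral plus a branch offset — or ("fixed", deg) for rigid groups.
# CB geometry (N-CA-CB 110.5°, improper C-N-CA-CB −123°) gives the
# L-configuration on a standard backbone.
_CB = ("CB", "C", ("C", "N", "CA"), 1.53, 110.5, ("fixed", -123.0))
SIDECHAIN_TEMPLATES: dict[str, tuple] = {
    "GLY": (),
    "ALA": (_CB,),
    "VAL": (
        _CB,
        ("CG1", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -122.3)),
    ),
    "LEU": (
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 122.6)),
    ),
    "ILE": (
        _CB,
        ("CG1", "C", ("N", "CA", "CB"), 1.53, 110.4, ("chi", 1, 0.0)),
        ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -122.3)),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.52, 113.8, ("chi", 2, 0.0)),
    ),
    "MET": (
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("SD", "S", ("CA", "CB", "CG"), 1.80, 112.7, ("chi", 2, 0.0)),
        ("CE", "C", ("CB", "CG", "SD"), 1.79, 100.8, ("chi", 3, 0.0)),
    ),
    "PHE": (
        _CB,
        ("CG", "C", ("N", "CA", "CB"), 1.51, 113.8, ("chi", 1, 0.0)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 2, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.0, ("fixed", 180.0)),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.0, ("fixed", 180.0)),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, ("fixed", 0.0)),
    ),
}
SIDECHAIN_TEMPLATES["TYR"] = SIDECHAIN_TEMPLATES["PHE"] + (
    ("OH", "O", ("CD1", "CE1", "CZ"), 1.38, 120.0, ("fixed", 180.0)),
)

#: Bond count of each template atom from CA (for bonded-pair exclusion).
_DEPTH = {
    "CB": 1, "CG": 2, "CG1": 2, "CG2": 2, "SD": 3, "CD1": 3, "CD2": 3,
    "CE": 4, "CE1": 4, "CE2": 4, "CZ": 5, "OH": 6,
}

_RING_ATOMS = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ),
}

_DEFAULT_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.10}


@dataclass
class RotamerPlacement:
    """One rebuilt side chain: chi angles plus rebuilt heavy-atom coordinates."""

    position: ResidueKey
    target_residue: str
    chi_angles: tuple[float, ...]
    atoms: list[AtomRecord]
    clash_score: float = math.nan

    def __post_init__(self) -> None:
        want = len(SIDECHAIN_TEMPLATES[self.target_residue])
        if len(self.atoms) != want:
            raise ValueError(
                f"{self.target_residue} side chain needs {want} heavy atoms, "
                f"got {len(self.atoms)}"
            )
        if len(self.chi_angles) != CHI_COUNT[self.target_residue]:
            raise ValueError(
                f"{self.target_residue} has {CHI_COUNT[self.target_residue]} chi "
                f"angles, got {len(self.chi_angles)}"
            )


@dataclass
class ClashParameters:
    """Soft-sphere overlap parameters.

    ``tolerance`` is subtracted from the radius sum before an overlap is
    counted; atom pairs within ``bonded_exclusion`` bonds of each other are
    never scored.
    """

    vdw_radii: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_VDW))
    tolerance: float = 0.4
    bonded_exclusion: int = 3
    default_radius: float = 1.70

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.vdw_radii.values()):
            raise ValueError("vdW radii must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be ≥ 0")

    def radius(self, element: str) -> float:
        return self.vdw_radii.get(element.upper(), self.default_radius)


@dataclass
class ClashReport:
    """Positive vdW overlaps of one placement against its surroundings."""

    pairs: list[tuple[AtomRecord, AtomRecord, float]]
    total: float
    max_overlap: float

    @property
    def clashing(self) -> bool:
        return self.total > 0


@dataclass
class ProximityReport:
    """Centroid-to-centroid distance between two aromatic rings."""

    ring_a_centroid: np.ndarray
    ring_b_centroid: np.ndarray
    centroid_distance: float
    ring_atoms_used: tuple[tuple[str, ...], tuple[str, ...]]


@dataclass
class RotamerLibrary:
    """Chi-angle combinations per residue type, in file order."""

    rotamers: dict[str, list[tuple[float, ...]]]

    def for_residue(self, residue: str) -> list[tuple[float, ...]]:
        try:
            return self.rotamers[residue]
        except KeyError:
            raise KeyError(f"no rotamers for residue {residue!r}") from None


def load_rotamer_library(path: str | None = None) -> RotamerLibrary:
    """Load the chi table shipped with the package (or a user-supplied one)."""
    if path is None:
        text = (
            resources.files("erdesign").joinpath("data/rotamers.tsv").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    rot: dict[str, list[tuple[float, ...]]] = {}
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        res = parts[0].upper()
        chis = tuple(float(x) for x in parts[1:] if x.strip())
        rot.setdefault(res, []).append(chis)
    return RotamerLibrary(rot)


# --- internal-coordinate construction --------------------------------------


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """NeRF: position D with |CD| = r, angle(B,C,D) = theta, dihedral(A,B,C,D) = phi."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(phi),
            r * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_sidechain(
    anchors: dict[str, np.ndarray],
    target: str,
    chis: tuple[float, ...],
) -> list[tuple[str, str, np.ndarray]]:
    """Rebuild the target side chain (name, element, coords) from anchors + chis."""
    coords = dict(anchors)
    out = []
    for name, element, refs, r, theta, torsion in SIDECHAIN_TEMPLATES[target]:
        kind = torsion[0]
        if kind == "chi":
            _, k, offset = torsion
            phi = chis[k - 1] + offset
        else:
            phi = torsion[1]
        a, b, c = (coords[ref] for ref in refs)
        pos = _place_atom(a, b, c, r, theta, phi)
        coords[name] = pos
        out.append((name, element, pos))
    return out


def mutate_residue(
    model: StructureModel,
    residue: ResidueKey,
    target_residue: str,
    library: RotamerLibrary | None = None,
) -> list[RotamerPlacement]:
    """Model a point mutation: one placement per library rotamer of the target.

    The backbone (N, CA, C and, when present, CB) stays rigid; all other
    side-chain atoms of the original residue are discarded and the target
    side chain rebuilt from ideal internal geometry.
    """
    target = _ONE_TO_THREE.get(target_residue.upper(), target_residue.upper())
    if target not in _STANDARD:
        raise ValueError(f"{target!r} is not a standard residue")
    if target not in SIDECHAIN_TEMPLATES:
        raise NotImplementedError(
            f"no side-chain template for {target}; shipped templates: "
            f"{sorted(SIDECHAIN_TEMPLATES)}"
        )
    atoms = model.residues.get(residue)
    if atoms is None:
        raise KeyError(f"no residue {residue} in {model.id!r}")
    by_name = {a.name: a for a in atoms}
    missing = [n for n in ("N", "CA", "C") if n not in by_name]
    if missing:
        raise ValueError(f"{residue}: missing backbone atoms {missing}")
    anchors = {n: by_name[n].coords.copy() for n in ("N", "CA", "C")}
    lib = library or load_rotamer_library()

    placements = []
    for chis in lib.for_residue(target):
        # an existing CB is authoritative; otherwise an ideal one is built
        if "CB" in by_name and target != "GLY":
            built = _rebuild_with_native_cb(anchors, by_name["CB"].coords, target, chis)
        else:
            built = _build_sidechain(dict(anchors), target, chis)
        records = [
            AtomRecord(
                serial=0,
                name=n,
                element=e,
                alt_loc="",
                occupancy=1.0,
                coords=c,
                is_hetero=False,
            )
            for n, e, c in built
        ]
        placements.append(
            RotamerPlacement(
                position=residue,
                target_residue=target,
                chi_angles=chis,
                atoms=records,
            )
        )
    return placements


def _rebuild_with_native_cb(
    anchors: dict[str, np.ndarray],
    cb: np.ndarray,
    target: str,
    chis: tuple[float, ...],
) -> list[tuple[str, str, np.ndarray]]:
    coords = dict(anchors)
    coords["CB"] = cb.copy()
    out = []
    for name, element, refs, r, theta, torsion in SIDECHAIN_TEMPLATES[target]:
        if name == "CB":
            out.append(("CB", "C", cb.copy()))
            continue
        kind = torsion[0]
        if kind == "chi":
            _, k, offset = torsion
            phi = chis[k - 1] + offset
        else:
            phi = torsion[1]
        a, b, c = (coords[ref] for ref in refs)
        pos = _place_atom(a, b, c, r, theta, phi)
        coords[name] = pos
        out.append((name, element, pos))
    return out


# --- clash scoring ----------------------------------------------------------

_BACKBONE_EXTRA = {"CA": 0, "N": 1, "C": 1, "O": 2, "OXT": 2}
_PREV_EXTRA = {"C": 2, "O": 3, "CA": 3}
_NEXT_EXTRA = {"N": 2, "CA": 3}


def _bond_separation(
    placement_atom: AtomRecord,
    mutated: ResidueKey,
    other_key: ResidueKey,
    other_atom: AtomRecord,
) -> float:
    depth = _DEPTH.get(placement_atom.name)
    if depth is None:
        return math.inf
    if other_key == mutated:
        extra = _BACKBONE_EXTRA.get(other_atom.name)
    elif other_key.chain == mutated.chain and other_key.number == mutated.number - 1:
        extra = _PREV_EXTRA.get(other_atom.name)
    elif other_key.chain == mutated.chain and other_key.number == mutated.number + 1:
        extra = _NEXT_EXTRA.get(other_atom.name)
    else:
        return math.inf
    return math.inf if extra is None else depth + extra


def clash_score(
    model: StructureModel,
    placement: RotamerPlacement,
    params: ClashParameters | None = None,
    include_ligand: bool = True,
) -> ClashReport:
    """Soft-sphere overlap of a placement against the model.

    ``overlap = rA + rB − d − tolerance`` when positive.  Atoms of the
    mutated residue's old side chain, hydrogens, waters, and pairs within
    the bonded-exclusion distance are never counted.  With
    ``include_ligand=False`` the unbound receptor is assessed: all hetero
    atoms are ignored.
    """
    params = params or ClashParameters()
    sidechain_names = {a.name for a in placement.atoms}
    pairs = []
    for other_key, atoms in model.residues.items():
        is_het = any(a.is_hetero for a in atoms)
        if is_het and (not include_ligand or other_key.name in ("HOH", "WAT", "DOD")):
            continue
        for other in atoms:
            if other.is_hydrogen:
                continue
            if other_key == placement.position and (
                other.name in sidechain_names or _DEPTH.get(other.name) is not None
            ):
                continue  # old side chain: replaced by the placement
            for mine in placement.atoms:
                if (
                    _bond_separation(mine, placement.position, other_key, other)
                    <= params.bonded_exclusion
                ):
                    continue
                d = float(np.linalg.norm(mine.coords - other.coords))
                overlap = (
                    params.radius(mine.element)
                    + params.radius(other.element)
                    - d
                    - params.tolerance
                )
                if overlap > 0:
                    pairs.append((mine, other, overlap))
    total = sum(o for _, _, o in pairs)
    return ClashReport(
        pairs=pairs,
        total=total,
        max_overlap=max((o for _, _, o in pairs), default=0.0),
    )


def score_placements(
    model: StructureModel,
    placements: Sequence[RotamerPlacement],
    params: ClashParameters | None = None,
    include_ligand: bool = True,
) -> list[ClashReport]:
    reports = []
    for p in placements:
        rep = clash_score(model, p, params, include_ligand)
        p.clash_score = rep.total
        reports.append(rep)
    return reports


def best_placement(
    placements: Sequence[RotamerPlacement],
    reports: Sequence[ClashReport],
) -> RotamerPlacement:
    """Least-clashing rotamer: min total overlap, then min max-overlap, then file order."""
    if not placements:
        raise ValueError("no placements to choose from")
    if len(placements) != len(reports):
        raise ValueError("placements and reports differ in length")
    order = range(len(placements))
    best = min(order, key=lambda i: (reports[i].total, reports[i].max_overlap, i))
    return placements[best]


def apply_placement(model: StructureModel, placement: RotamerPlacement) -> StructureModel:
    """Return a new model with the mutated residue's side chain replaced."""
    key = placement.position
    if key not in model.residues:
        raise KeyError(f"no residue {key} in {model.id!r}")
    new_key = ResidueKey(key.chain, key.number, key.insertion_code, placement.target_residue)
    residues: dict[ResidueKey, list[AtomRecord]] = {}
    for k, atoms in model.residues.items():
        if k != key:
            residues[k] = list(atoms)
            continue
        backbone = [a for a in atoms if a.name in ("N", "CA", "C", "O", "OXT", "H")]
        residues[new_key] = backbone + list(placement.atoms)
    return StructureModel(id=f"{model.id}_{placement.target_residue}{key.number}",
                          residues=residues, source_model_index=model.source_model_index)


# --- aromatic proximity -----------------------------------------------------


def _centroid(points: Sequence[np.ndarray]) -> np.ndarray:
    return np.mean(np.array(points), axis=0)


def _ligand_rings(ligand: LigandSelection, bond_cutoff: float = 1.85) -> list[tuple[str, ...]]:
    """Detect 5/6-membered rings in the ligand from a distance-based bond graph."""
    import networkx as nx

    heavy = [a for a in ligand.atoms if not a.is_hydrogen]
    g = nx.Graph()
    g.add_nodes_from(range(len(heavy)))
    for i in range(len(heavy)):
        for j in range(i + 1, len(heavy)):
            if np.linalg.norm(heavy[i].coords - heavy[j].coords) <= bond_cutoff:
                g.add_edge(i, j)
    rings = []
    for cycle in nx.cycle_basis(g):
        if 5 <= len(cycle) <= 6:
            rings.append(tuple(heavy[i].name for i in cycle))
    return rings


def aromatic_proximity(
    placement: RotamerPlacement,
    ligand: LigandSelection,
    ligand_ring_atoms: Sequence[str] | str = "auto",
) -> ProximityReport:
    """Ring-centroid distance between an aromatic placement and a ligand ring.

    With ``ligand_ring_atoms="auto"``, all 5/6-membered ligand rings are
    detected and the closest one is reported.
    """
    rings = _RING_ATOMS.get(placement.target_residue)
    if rings is None:
        raise ValueError(
            f"{placement.target_residue} is not aromatic (expected PHE/TYR/TRP)"
        )
    mine = {a.name: a.coords for a in placement.atoms}
    residue_rings = []
    for names in rings:
        if all(n in mine for n in names):
            residue_rings.append((names, _centroid([mine[n] for n in names])))
    if not residue_rings:
        raise ValueError("placement is missing ring atoms")

    lig_by_name = {a.name: a.coords for a in ligand.atoms if not a.is_hydrogen}
    if ligand_ring_atoms == "auto":
        candidates = _ligand_rings(ligand)
        if not candidates:
            raise ValueError(f"no 5/6-membered ring detected in ligand {ligand.het_code}")
    else:
        unresolved = [n for n in ligand_ring_atoms if n not in lig_by_name]
        if unresolved:
            raise ValueError(f"ligand ring atoms not found: {unresolved}")
        candidates = [tuple(ligand_ring_atoms)]

    best = None
    for res_names, res_c in residue_rings:
        for lig_names in candidates:
            lig_c = _centroid([lig_by_name[n] for n in lig_names])
            d = float(np.linalg.norm(res_c - lig_c))
            if best is None or d < best[0]:
                best = (d, res_c, lig_c, res_names, lig_names)
    d, res_c, lig_c, res_names, lig_names = best
    return ProximityReport(
        ring_a_centroid=res_c,
        ring_b_centroid=lig_c,
        centroid_distance=d,
        ring_atoms_used=(res_names, lig_names),
    )
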