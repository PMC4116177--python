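"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its spec (seed included), so a spec
identifies its output byte-for-byte.  The geometry and noise structure
mirror what the analysis stages assume — a hetero ligand group with protein
pseudo-residues planted at controlled minimum distances, alignment columns
with prescribed residue counts, logistic competition curves and Boltzmann
melt curves with Gaussian noise — without attempting physically realistic
protein architecture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .conservation import Alignment
from .assay_models import CompetitionCurve, MeltCurve, competition_model, melt_model
from .structure_io import AtomRecord, ResidueKey, StructureModel, write_pdb

__all__ = [
    "ComplexSpec",
    "AssaySpec",
    "MeltSpec",
    "make_complex",
    "make_alignment",
    "make_competition_curve",
    "make_melt_curve",
]

_RESNAMES = ("ALA", "VAL", "LEU", "ILE", "MET", "PHE", "SER", "THR", "GLY", "TYR")


@dataclass(frozen=True)
class ComplexSpec:
    """Blueprint of a synthetic protein–ligand complex.

    ``pocket_distances`` are the planted minimum heavy-atom distances (Å)
    from each pocket pseudo-residue to the ligand; ``n_far_residues``
    residues are placed beyond ``cutoff + 2`` Å.
    """

    pocket_distances: tuple[float, ...] = (3.5, 4.0, 4.5, 5.0, 5.5)
    n_far_residues: int = 10
    ligand_atoms: int = 12
    cutoff: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.pocket_distances):
            raise ValueError("planted distances must be positive")
        if self.n_far_residues < 0 or self.ligand_atoms < 1:
            raise ValueError("counts out of range")


@dataclass(frozen=True)
class AssaySpec:
    """Blueprint of one-site competition curves.

    Defaults follow the assay design the analytics expect: 12 log-spaced
    competitor concentrations spanning 10 pM – 10 µM, polarization falling
    from ``max`` to ``min`` with unit hill slope, Gaussian noise expressed
    as a fraction of the dynamic range.
    """

    true_ic50: float = 1e-8  # mol/L
    min: float = 50.0
    max: float = 300.0
    hill: float = 1.0
    concentrations: tuple[float, ...] = tuple(np.logspace(-11, -5, 12))
    noise_sd: float = 0.0  # fraction of (max - min)
    n_replicates: int = 1
    seed: int = 0
    ligand: str = "ligand"
    receptor: str = "receptor"

    def __post_init__(self) -> None:
        if self.true_ic50 <= 0:
            raise ValueError("true_ic50 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")


@dataclass(frozen=True)
class MeltSpec:
    """Blueprint of a thermal-melt curve: 25–90 °C at 1 °C steps by default."""

    true_tm: float = 59.5
    slope_width: float = 2.0
    folded_baseline: float = -20.0
    unfolded_baseline: float = -4.0
    t_start: float = 25.0
    t_stop: float = 90.0
    t_step: float = 1.0
    noise_sd: float = 0.0  # fraction of |folded - unfolded|
    seed: int = 0
    receptor: str = "receptor"

    def __post_init__(self) -> None:
        if self.slope_width <= 0:
            raise ValueError("slope_width must be positive")
        if self.t_step <= 0 or self.t_stop <= self.t_start:
            raise ValueError("bad temperature grid")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.t_stop - self.t_start) / self.t_step)) + 1
        return self.t_start + self.t_step * np.arange(n)


# --- structures -------------------------------------------------------------


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (golden-spiral points on the sphere)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _distance_to_ligand(point: np.ndarray, ligand: np.ndarray) -> float:
    return float(np.min(np.linalg.norm(ligand - point, axis=1)))


def _solve_radius(direction: np.ndarray, ligand: np.ndarray, target: float) -> np.ndarray:
    """Point along ``direction`` whose min distance to the ligand equals target."""
    lo, hi = 0.0, float(np.max(np.linalg.norm(ligand, axis=1))) + target + 5.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if _distance_to_ligand(direction * mid, ligand) < target:
            lo = mid
        else:
            hi = mid
    return direction * ((lo + hi) / 2.0)


def make_complex(spec: ComplexSpec) -> tuple[str, set[ResidueKey]]:
    """Generate a synthetic complex as PDB text plus its ground-truth pocket.

    The ligand (het code LIG, chain L) sits near the origin; every pocket
    pseudo-residue's nearest atom is placed at its planted distance, far
    residues beyond ``cutoff + 2`` Å.  Ground truth is recomputed from the
    coordinates as they round-trip through the PDB writer, so the returned
    keys agree exactly with what a reader sees.
    """
    rng = np.random.default_rng(spec.seed)
    lig_pts = rng.uniform(-1.5, 1.5, size=(spec.ligand_atoms, 3))

    n_res = len(spec.pocket_distances) + spec.n_far_residues
    if n_res > 200:
        raise ValueError("spec asks for more residues than can be placed cleanly")
    dirs = _fibonacci_directions(max(n_res, 1))
    rng.shuffle(dirs)

    residues: dict[ResidueKey, list[AtomRecord]] = {}
    serial = 0
    placed_points: list[np.ndarray] = []

    def add_residue(number: int, anchor: np.ndarray, direction: np.ndarray, n_atoms: int):
        nonlocal serial
        name = _RESNAMES[number % len(_RESNAMES)]
        key = ResidueKey(chain="A", number=number, insertion_code="", name=name)
        atoms = []
        for j in range(n_atoms):
            serial += 1
            # extra atoms march away from the ligand so the anchor stays nearest
            coords = anchor + direction * (1.4 * j)
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=f"C{j + 1}",
                    element="C",
                    alt_loc="",
                    occupancy=1.0,
                    coords=coords,
                    is_hetero=False,
                )
            )
        residues[key] = atoms
        placed_points.append(anchor)

    for i, d in enumerate(spec.pocket_distances):
        anchor = _solve_radius(dirs[i], lig_pts, float(d))
        if abs(_distance_to_ligand(anchor, lig_pts) - d) > 0.05:
            raise ValueError(
                f"unsatisfiable spec: cannot plant residue {i + 1} at {d} Å"
            )
        if placed_points and min(
            np.linalg.norm(p - anchor) for p in placed_points
        ) < 1.0:
            raise ValueError(
                f"unsatisfiable spec: residue {i + 1} lands within 1 Å of another"
            )
        add_residue(i + 1, anchor, dirs[i], int(rng.integers(1, 6)))

    for i in range(spec.n_far_residues):
        idx = len(spec.pocket_distances) + i
        d = spec.cutoff + 2.0 + float(rng.uniform(0.5, 10.0))
        anchor = _solve_radius(dirs[idx], lig_pts, d)
        add_residue(idx + 1, anchor, dirs[idx], int(rng.integers(1, 6)))

    lig_key = ResidueKey(chain="L", number=1, insertion_code="", name="LIG")
    residues[lig_key] = [
        AtomRecord(
            serial=serial + 1 + j,
            name=f"C{j + 1}",
            element="C",
            alt_loc="",
            occupancy=1.0,
            coords=lig_pts[j],
            is_hetero=True,
        )
        for j in range(spec.ligand_atoms)
    ]

    model = StructureModel(id=f"synthetic-{spec.seed}", residues=residues)
    text = write_pdb(model)

    # ground truth from the serialized (3-decimal) coordinates
    from .structure_io import read_pdb, select_ligand
    from .pocket import extract_pocket

    rt = read_pdb(text, structure_id=model.id)
    truth = extract_pocket(rt, select_ligand(rt, "LIG"), cutoff=spec.cutoff)
    return text, truth


# --- alignments -------------------------------------------------------------


def make_alignment(
    n_sequences: int,
    column_specs: Mapping[int, Mapping[str, int]] | None = None,
    seed: int = 0,
    reference_name: str = "reference",
    reference_start: int = 303,
    length: int = 245,
    reference_overrides: Mapping[int, str] | None = None,
) -> Alignment:
    """Alignment with exact per-column residue counts at chosen positions.

    Unspecified columns are filled with the reference residue (100%
    conserved).  At a specified column the counts must sum to
    ``n_sequences``; rows receive residues in a seed-shuffled order.  The
    reference row carries the modal residue unless overridden.
    """
    column_specs = dict(column_specs or {})
    overrides = dict(reference_overrides or {})
    rng = np.random.default_rng(seed)

    base = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length)
    names = [reference_name] + [f"seq{i:04d}" for i in range(1, n_sequences)]
    rows = [list("".join(base)) for _ in range(n_sequences)]

    for pos, counts in column_specs.items():
        col = pos - reference_start
        if not 0 <= col < length:
            raise ValueError(f"position {pos} outside the alignment")
        total = sum(counts.values())
        if total != n_sequences:
            raise ValueError(
                f"column {pos}: counts sum to {total}, expected {n_sequences}"
            )
        ref_res = overrides.get(pos) or max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
        if counts.get(ref_res, 0) < 1:
            raise ValueError(f"column {pos}: reference residue {ref_res} has no count")
        pool = []
        for res, cnt in sorted(counts.items()):
            pool.extend([res] * cnt)
        pool.remove(ref_res)  # the reference row consumes one copy
        pool = list(rng.permutation(pool))
        rows[0][col] = ref_res
        for row, res in zip(rows[1:], pool):
            row[col] = res

    return Alignment(
        names=names,
        rows=["".join(r) for r in rows],
        reference_name=reference_name,
        reference_start=reference_start,
    )


# --- assay curves -----------------------------------------------------------


def make_competition_curve(spec: AssaySpec) -> list[CompetitionCurve]:
    """Logistic competition curves with seeded Gaussian noise (one per replicate)."""
    rng = np.random.default_rng(spec.seed)
    x = np.asarray(spec.concentrations, dtype=float)
    log_ic50 = math.log10(spec.true_ic50)
    clean = competition_model(np.log10(x), spec.min, spec.max, log_ic50, spec.hill)
    out = []
    for _ in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd * (spec.max - spec.min), size=x.shape)
        out.append(
            CompetitionCurve(
                concentrations=x.copy(),
                polarizations=clean + noise,
                ligand=spec.ligand,
                receptor=spec.receptor,
            )
        )
    return out


def make_melt_curve(spec: MeltSpec) -> MeltCurve:
    """Boltzmann melt curve with seeded Gaussian noise on the temperature grid.

    A midpoint outside the grid is generated anyway but flagged in
    ``warnings`` — a fit on such a curve is expected to fail honestly.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.grid
    clean = melt_model(t, spec.true_tm, spec.slope_width,
                       spec.folded_baseline, spec.unfolded_baseline)
    amp = abs(spec.folded_baseline - spec.unfolded_baseline)
    noise = rng.normal(0.0, spec.noise_sd * amp, size=t.shape)
    warnings = ()
    if not (t[0] <= spec.true_tm <= t[-1]):
        warnings = (f"true_tm {spec.true_tm} outside grid [{t[0]}, {t[-1]}]",)
    return MeltCurve(
        temperatures=t,
        signals=clean + noise,
        receptor=spec.receptor,
        warnings=warnings,
    )
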