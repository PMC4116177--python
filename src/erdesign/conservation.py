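"""Conservation profiling of pocket positions across an ortholog alignment.

The conservation metric is the modal-residue fraction: the share of counted
sequences carrying the most common residue at a column (1.0 = invariant).
Gaps are absence of evidence and ambiguous letters (X/B/Z) carry none, so
both are excluded from the counts and from the effective depth.

Candidate mutations are the natural variants: non-wild-type residues seen
in at least ``min_support`` sequences at a pocket position.  The wild type
is the *reference* sequence's residue, not the modal one — an ortholog set
can out-vote the reference (human ERα carries L349 where most species have
M), and the design question is always "what can we change the reference
to".
"""

from __future__ import annotations

import io
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO

from .pocket import PocketDefinition

__all__ = [
    "Alignment",
    "AlignmentColumnProfile",
    "CandidateMutation",
    "read_alignment",
    "clean_alignment",
    "column_profile",
    "pocket_conservation",
    "candidate_mutations",
    "conservation_table",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_AMBIGUOUS = set("XBZ")
_GAPS = set("-.")
_ALPHABET = _AA | _AMBIGUOUS | _GAPS


class AlignmentFormatError(ValueError):
    pass


@dataclass
class Alignment:
    """A named multiple sequence alignment with a designated reference row.

    ``reference_start`` is the residue number of the first non-gap reference
    character, so alignment columns can be addressed by reference position.
    """

    names: list[str]
    rows: list[str]
    reference_name: str
    reference_start: int = 1

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentFormatError("names and rows differ in length")
        if len(self.rows) < 2:
            raise AlignmentFormatError("alignment needs at least 2 sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if self.reference_name not in self.names:
            raise AlignmentFormatError(f"reference {self.reference_name!r} not in alignment")
        for name, row in zip(self.names, self.rows):
            bad = set(row.upper()) - _ALPHABET
            if bad:
                raise AlignmentFormatError(f"{name}: illegal symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def reference_row(self) -> str:
        return self.rows[self.names.index(self.reference_name)]

    def column(self, index: int) -> list[str]:
        return [row[index] for row in self.rows]

    def column_of_position(self, reference_position: int) -> int:
        """Alignment column index carrying the given reference position."""
        pos = self.reference_start - 1
        for i, ch in enumerate(self.reference_row):
            if ch in _GAPS:
                continue
            pos += 1
            if pos == reference_position:
                return i
        raise KeyError(
            f"reference position {reference_position} outside reference "
            f"({self.reference_start}–{pos})"
        )


@dataclass
class AlignmentColumnProfile:
    """Residue counts and conservation at one reference position."""

    reference_position: int
    reference_residue: str
    counts: dict[str, int]
    n_effective: int
    modal_residue: str
    conservation: float

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_effective:
            raise ValueError("counts do not sum to n_effective")
        if not 0.0 < self.conservation <= 1.0:
            raise ValueError("conservation outside (0, 1]")


@dataclass(frozen=True)
class CandidateMutation:
    """A natural-variant point mutation licensed by the ortholog alignment."""

    reference_position: int
    wild_type: str
    variant: str
    support: int
    variant_fraction: float

    def __post_init__(self) -> None:
        if self.variant == self.wild_type:
            raise ValueError("variant equals wild type")
        if self.support < 1:
            raise ValueError("support must be ≥ 1")

    def __str__(self) -> str:  # e.g. M421F
        return f"{self.wild_type}{self.reference_position}{self.variant}"


def read_alignment(
    source: str | io.TextIOBase,
    reference_name: str,
    fmt: str = "fasta",
    reference_start: int = 1,
) -> Alignment:
    """Read a FASTA or Clustal alignment; the reference row is required."""
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    handle = io.StringIO(source) if isinstance(source, str) else source
    try:
        msa = AlignIO.read(handle, fmt)
    except ValueError as e:
        raise AlignmentFormatError(str(e)) from e
    return Alignment(
        names=[rec.id for rec in msa],
        rows=[str(rec.seq).upper() for rec in msa],
        reference_name=reference_name,
        reference_start=reference_start,
    )


def clean_alignment(a: Alignment, min_coverage: float = 0.8) -> Alignment:
    """Drop duplicate rows and rows that barely cover the reference.

    Exact duplicate sequence strings keep the first name in name order; rows
    whose non-gap coverage of reference (non-gap) columns falls below
    ``min_coverage`` are removed.  The reference itself is never removed.
    """
    ref_row = a.reference_row
    ref_cols = [i for i, ch in enumerate(ref_row) if ch not in _GAPS]

    keep: dict[str, str] = {}
    seen: dict[str, str] = {}  # sequence string -> kept name
    for name in sorted(a.names):
        row = a.rows[a.names.index(name)]
        if name == a.reference_name:
            continue
        if row in seen:
            continue
        seen[row] = name
        covered = sum(1 for i in ref_cols if row[i] not in _GAPS)
        if covered / len(ref_cols) < min_coverage:
            continue
        keep[name] = row
    if ref_row in seen:  # a duplicate of the reference: drop the copy
        keep.pop(seen[ref_row], None)

    names = [n for n in a.names if n == a.reference_name or n in keep]
    rows = [a.rows[a.names.index(n)] for n in names]
    if len(names) < 2:
        raise AlignmentFormatError("cleaning left fewer than 2 sequences")
    return Alignment(names, rows, a.reference_name, a.reference_start)


def column_profile(a: Alignment, reference_position: int) -> AlignmentColumnProfile:
    """Residue frequency profile of the column at one reference position."""
    col_index = a.column_of_position(reference_position)
    counts = Counter(
        ch for ch in a.column(col_index) if ch in _AA
    )
    if not counts:
        raise ValueError(f"column at {reference_position} has no counted residues")
    n_eff = sum(counts.values())
    modal, modal_count = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    return AlignmentColumnProfile(
        reference_position=reference_position,
        reference_residue=a.reference_row[col_index],
        counts=dict(counts),
        n_effective=n_eff,
        modal_residue=modal,
        conservation=modal_count / n_eff,
    )


def pocket_conservation(
    a: Alignment, pocket: PocketDefinition | Iterable[int]
) -> tuple[list[AlignmentColumnProfile], list[int]]:
    """Profile every pocket position; unmappable positions are reported, not lost.

    Returns ``(profiles ordered by position, skipped positions)``.
    """
    positions = (
        sorted(pocket.positions) if isinstance(pocket, PocketDefinition) else sorted(pocket)
    )
    profiles, skipped = [], []
    for pos in positions:
        try:
            profiles.append(column_profile(a, pos))
        except (KeyError, ValueError):
            skipped.append(pos)
    return profiles, skipped


def candidate_mutations(
    profiles: Sequence[AlignmentColumnProfile], min_support: int = 2
) -> list[CandidateMutation]:
    """Natural-variant candidates: one per non-wild-type residue with enough support.

    Ranked by variant fraction (descending), then position, then residue
    letter, so the ordering is invariant under alignment row permutation.
    """
    out = []
    for p in profiles:
        for residue, count in p.counts.items():
            if residue == p.reference_residue or count < min_support:
                continue
            out.append(
                CandidateMutation(
                    reference_position=p.reference_position,
                    wild_type=p.reference_residue,
                    variant=residue,
                    support=count,
                    variant_fraction=count / p.n_effective,
                )
            )
    return sorted(
        out, key=lambda c: (-c.variant_fraction, c.reference_position, c.variant)
    )


def conservation_table(
    profiles: Sequence[AlignmentColumnProfile],
    candidates: Sequence[CandidateMutation] = (),
) -> pd.DataFrame:
    """Per-position report: modal residue, conservation, variants with support."""
    by_pos: dict[int, list[str]] = {}
    for c in candidates:
        by_pos.setdefault(c.reference_position, []).append(f"{c.variant}:{c.support}")
    return pd.DataFrame(
        [
            {
                "position": p.reference_position,
                "reference": p.reference_residue,
                "modal": p.modal_residue,
                "conservation": round(p.conservation, 4),
                "n_sequences": p.n_effective,
                "variants": ",".join(by_pos.get(p.reference_position, [])),
            }
            for p in profiles
        ]
    )
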