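"""Sequence set I/O, annotation-based grouping, and reference projection.

Alignments are analysed with respect to a chosen reference sequence: every
column where the reference holds a gap is discarded, and the surviving
columns are numbered by the reference's own 1-based residue numbering.  This
makes per-site results directly interpretable on the reference protein (and
on its crystal structure, which shares the numbering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: canonical one-letter codes counted as observed residues
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: ambiguity/rare letters retained in sequences but treated as missing data
AMBIGUOUS = "BZXUO"
GAP = "-"


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed into a valid record set."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein sequence with its accession and annotation line."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residues")


@dataclass
class SequenceGroup:
    """A named subfamily: a label plus the member record ids."""

    label: str
    members: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GroupingResult:
    """Outcome of annotation-based grouping: groups, dropped and unmatched ids."""

    groups: list[SequenceGroup]
    dropped: list[str]
    unmatched: list[str]

    def group(self, label: str) -> SequenceGroup:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)


@dataclass
class ProjectedAlignment:
    """An MSA restricted to columns that are non-gap in the reference row.

    Columns are indexed by ``site_numbers``: consecutive 1-based positions
    along the ungapped reference sequence.  ``columns`` is a rectangular
    ``(n_rows, n_sites)`` array of single characters; rows keep whatever
    character (residue or gap) they held in the retained columns.

    ``reference_id`` names the sequence that defined the projection; for
    synthetic alignments it may not correspond to any row.
    """

    reference_id: str
    ids: list[str]
    site_numbers: list[int]
    columns: np.ndarray
    row_groups: list[str | None] | None = None

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype="<U1")
        if self.columns.ndim != 2:
            raise ValueError("columns must be a 2-D character matrix")
        if self.columns.shape[0] != len(self.ids):
            raise ValueError("row count does not match ids")
        if self.columns.shape[1] != len(self.site_numbers):
            raise ValueError("column count does not match site_numbers")
        if any(b <= a for a, b in zip(self.site_numbers, self.site_numbers[1:])):
            raise ValueError("site_numbers must be strictly increasing")
        if self.row_groups is not None and len(self.row_groups) != len(self.ids):
            raise ValueError("row_groups length does not match ids")

    @property
    def n_rows(self) -> int:
        return self.columns.shape[0]

    @property
    def n_sites(self) -> int:
        return self.columns.shape[1]

    def row_index(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"sequence {seq_id!r} not in alignment") from None

    def site_index(self, site_number: int) -> int:
        try:
            return self.site_numbers.index(site_number)
        except ValueError:
            raise KeyError(f"site {site_number} not in projection") from None

    def column(self, site_number: int, rows: Sequence[int] | None = None) -> np.ndarray:
        """Characters of one site, optionally restricted to a row subset."""
        col = self.columns[:, self.site_index(site_number)]
        return col if rows is None else col[np.asarray(rows)]

    def rows_of_group(self, label: str) -> list[int]:
        if self.row_groups is None:
            raise ValueError("alignment carries no row group labels")
        return [i for i, g in enumerate(self.row_groups) if g == label]

    def row_string(self, seq_id: str) -> str:
        return "".join(self.columns[self.row_index(seq_id)])


def _normalize(seq: str) -> str:
    """Upper-case and map '.' gaps (some aligners' dialect) to '-'."""
    return seq.upper().replace(".", GAP)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of records, order preserved.

    Residues are upper-cased and '.' gap characters normalized to '-'.
    Duplicate ids and empty files are rejected.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FastaParseError(f"cannot parse {path}: {exc}") from exc
    if not parsed:
        raise FastaParseError(f"{path} contains no FASTA records")
    for rec in parsed:
        if rec.id in seen:
            raise FastaParseError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _normalize(str(rec.seq))
        if not seq:
            raise FastaParseError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, description=rec.description, residues=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else f"{rec.id} {rec.description}".strip()
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def alignment_to_records(projection: ProjectedAlignment) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=i, description=i, residues="".join(row))
        for i, row in zip(projection.ids, projection.columns)
    ]


def assign_groups(
    records: Sequence[SequenceRecord],
    rules: Sequence[tuple[str, Sequence[str]]],
    drop_patterns: Sequence[str] = (),
) -> GroupingResult:
    """Assign records to subfamilies by annotation substrings.

    ``rules`` is an ordered list of ``(label, patterns)``; each surviving
    record joins the first rule whose pattern occurs (case-insensitively) in
    its description.  Records matching a ``drop_patterns`` entry (e.g.
    "hypothetical", "putative") are removed before matching.  Unmatched
    records are reported, never silently discarded.
    """
    if not rules:
        raise ValueError("at least one grouping rule is required")
    labels = [label for label, _ in rules]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate group labels: {dupes}")

    drop_lc = [p.lower() for p in drop_patterns]
    groups = [SequenceGroup(label=label) for label in labels]
    dropped: list[str] = []
    unmatched: list[str] = []
    for rec in records:
        desc = rec.description.lower()
        if any(p in desc for p in drop_lc):
            dropped.append(rec.id)
            continue
        for group, (_, patterns) in zip(groups, rules):
            if any(p.lower() in desc for p in patterns):
                group.members.append(rec.id)
                break
        else:
            unmatched.append(rec.id)
    for g in groups:
        if not g.members:
            logger.warning("group %r matched no sequences", g.label)
    logger.info(
        "grouping: %s; dropped %d; unmatched %d",
        {g.label: len(g) for g in groups}, len(dropped), len(unmatched),
    )
    return GroupingResult(groups=groups, dropped=dropped, unmatched=unmatched)


def project_to_reference(
    records: Sequence[SequenceRecord],
    reference_id: str,
    row_groups: list[str | None] | None = None,
) -> ProjectedAlignment:
    """Project an aligned record set onto its reference sequence.

    Columns where the reference holds a gap are removed from every row;
    kept columns are numbered 1..L along the ungapped reference.
    """
    ids = [r.id for r in records]
    if reference_id not in ids:
        raise KeyError(f"reference {reference_id!r} not among alignment rows")
    lengths = {len(r.residues) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    matrix = np.array([list(_normalize(r.residues)) for r in records], dtype="<U1")
    ref_row = matrix[ids.index(reference_id)]
    keep = ref_row != GAP
    if not keep.any():
        raise ValueError(f"reference {reference_id!r} is entirely gaps; no sites to project")
    projected = matrix[:, keep]
    site_numbers = list(range(1, int(keep.sum()) + 1))
    return ProjectedAlignment(
        reference_id=reference_id,
        ids=list(ids),
        site_numbers=site_numbers,
        columns=projected,
        row_groups=list(row_groups) if row_groups is not None else None,
    )


def projection_column_map(records: Sequence[SequenceRecord], reference_id: str) -> list[tuple[int, int]]:
    """Map projected site numbers to 0-based source-alignment column indices."""
    ids = [r.id for r in records]
    if reference_id not in ids:
        raise KeyError(f"reference {reference_id!r} not among alignment rows")
    ref = _normalize(records[ids.index(reference_id)].residues)
    out: list[tuple[int, int]] = []
    site = 0
    for col, ch in enumerate(ref):
        if ch != GAP:
            site += 1
            out.append((site, col))
    return out
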