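"""Representative-set reduction and merging for phylogeny input.

Phylogenetic inference on thousands of near-identical database hits is both
slow and redundant.  The reduction here thins a set to k representatives by
repeatedly locating the closest remaining pair in the pairwise distance
matrix and discarding one of its members, which yields the most even
possible spread of the survivors.  Reduced sets from several searches are
then merged with duplicate removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from famcons.sequence_io import GAP, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] (1 - fractional identity)."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")
        if (self.d < 0).any() or (self.d > 1 + 1e-12).any():
            raise ValueError("distances must lie in [0, 1]")

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in keep]
        return DistanceMatrix(ids=list(keep), d=self.d[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        """Cache as TSV: id header line, then lower-triangle rows."""
        with Path(path).open("w") as fh:
            fh.write("\t".join(self.ids) + "\n")
            for i in range(len(self.ids)):
                fh.write("\t".join(f"{self.d[i, j]:.6f}" for j in range(i + 1)) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        lines = Path(path).read_text().splitlines()
        ids = lines[0].split("\t")
        n = len(ids)
        d = np.zeros((n, n))
        for i, line in enumerate(lines[1 : n + 1]):
            vals = [float(x) for x in line.split("\t")]
            d[i, : i + 1] = vals
            d[: i + 1, i] = vals
        return cls(ids=ids, d=d)


def pairwise_identity_matrix(records: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Distance = 1 - identity over mutually non-gap columns of an alignment.

    Pairs with no comparable (both non-gap) positions get distance 1.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(r.residues) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    ids = [r.id for r in records]
    mat = np.array([list(r.residues.upper()) for r in records], dtype="<U1")
    nongap = mat != GAP
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            comparable = int(both.sum())
            if comparable == 0:
                dist = 1.0
            else:
                matches = int((mat[i][both] == mat[j][both]).sum())
                dist = 1.0 - matches / comparable
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=ids, d=d)


def select_representatives(matrix: DistanceMatrix, k: int) -> list[str]:
    """Thin a set to k ids with maximal evenness of spread.

    Iteratively finds the globally closest remaining pair and removes one
    member until k survive.  The removed member is the one whose
    next-nearest remaining neighbour (excluding its pair partner) is
    closer — the member sitting in the denser region — so isolated
    sequences are kept.  Ties are broken lexicographically by id (the
    later id is removed), making the procedure fully deterministic.
    Returned ids preserve the input order.
    """
    n = len(matrix.ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    d = matrix.d.copy()
    np.fill_diagonal(d, np.inf)
    alive = np.ones(n, dtype=bool)
    ids = matrix.ids

    def nearest_excluding(i: int, skip: int) -> float:
        row = d[i].copy()
        row[~alive] = np.inf
        row[skip] = np.inf
        return float(row.min())

    n_alive = n
    while n_alive > k:
        sub = d.copy()
        sub[~alive, :] = np.inf
        sub[:, ~alive] = np.inf
        flat = np.argmin(sub)
        i, j = np.unravel_index(flat, sub.shape)
        best = sub[i, j]
        # resolve distance ties lexicographically for determinism
        ti, tj = np.where(np.isclose(sub, best))
        pairs = sorted(
            {(min(ids[a], ids[b]), max(ids[a], ids[b])) for a, b in zip(ti, tj)}
        )
        id_a, id_b = pairs[0]
        a, b = ids.index(id_a), ids.index(id_b)
        na, nb = nearest_excluding(a, b), nearest_excluding(b, a)
        if na < nb:
            remove = a
        elif nb < na:
            remove = b
        else:
            remove = max(a, b, key=lambda x: ids[x])
        alive[remove] = False
        n_alive -= 1
    return [ids[i] for i in range(n) if alive[i]]


def merge_dedupe(*sets: Sequence[SequenceRecord]) -> tuple[list[SequenceRecord], int]:
    """Union of record sets preserving first occurrence.

    A record is a duplicate if its id or its exact residue string was seen
    before.  Returns the merged list and the number of duplicates removed.
    """
    merged: list[SequenceRecord] = []
    seen_ids: set[str] = set()
    seen_seqs: set[str] = set()
    removed = 0
    for records in sets:
        for rec in records:
            if rec.id in seen_ids or rec.residues in seen_seqs:
                removed += 1
                logger.debug("duplicate removed: %s", rec.id)
                continue
            seen_ids.add(rec.id)
            seen_seqs.add(rec.residues)
            merged.append(rec)
    logger.info("merged %d sets -> %d records (%d duplicates removed)",
                len(sets), len(merged), removed)
    return merged, removed


def min_retained_distance(matrix: DistanceMatrix, retained: Sequence[str]) -> float:
    """Minimum pairwise distance among a retained id subset (inf if < 2 ids)."""
    idx = [matrix.ids.index(i) for i in retained]
    if len(idx) < 2:
        return float("inf")
    sub = matrix.d[np.ix_(idx, idx)]
    return float(min(sub[i, j] for i, j in combinations(range(len(idx)), 2)))
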