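"""Compensatory base change (CBC) and nucleotide-variation counting.

A CBC is a substitution at *both* nucleotides of a base pair that is
maintained in two structures (e.g. G-C in one record, A-U in the other); a
hemi-CBC changes exactly one side while both pairings remain valid
(canonical or G-U wobble).  CBCs between two ITS2 structures are the
delimitation marker: their presence indicates distinct species.  Hemi-CBCs
are reported but do not drive delimitation.

Counting runs over a :class:`~its2morph.alignment.StructuralAlignment`:
only column pairs paired in *both* records are examined, columns where the
records disagree on pairedness contribute to neither count (a structural,
not substitutional, difference), and non-canonical "pairs" never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import GAP, StructuralAlignment

__all__ = ["CBCMatrix", "VariationSummary", "count_cbc", "cbc_matrix", "count_variation"]

VALID_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}
_TRANSITIONS = {frozenset(("A", "G")), frozenset(("C", "U"))}


@dataclass
class CBCMatrix:
    """Symmetric pairwise CBC / hemi-CBC counts with a zero diagonal."""

    ids: list[str]
    cbc: np.ndarray
    hemi: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for mat in (self.cbc, self.hemi):
            if mat.shape != (n, n):
                raise ValueError("matrix shape does not match ids")
            if not np.array_equal(mat, mat.T):
                raise ValueError("CBC matrix must be symmetric")
            if (mat < 0).any() or np.diag(mat).any():
                raise ValueError("counts must be non-negative with zero diagonal")

    def get(self, x: str, y: str) -> tuple[int, int]:
        i, j = self.ids.index(x), self.ids.index(y)
        return int(self.cbc[i, j]), int(self.hemi[i, j])

    def to_frame(self, which: str = "cbc") -> pd.DataFrame:
        mat = self.cbc if which == "cbc" else self.hemi
        return pd.DataFrame(mat, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, cbc_df: pd.DataFrame, hemi_df: pd.DataFrame | None = None) -> "CBCMatrix":
        ids = list(cbc_df.index)
        cbc = cbc_df.to_numpy(dtype=int)
        hemi = hemi_df.to_numpy(dtype=int) if hemi_df is not None else np.zeros_like(cbc)
        return cls(ids, cbc, hemi)


@dataclass(frozen=True)
class VariationSummary:
    """Substitution and INDEL bookkeeping for one record pair."""

    transitions: int
    transversions: int
    indel_events: int  # maximal runs of gap-vs-residue columns
    indel_columns: int

    @property
    def substitutions(self) -> int:
        return self.transitions + self.transversions


def count_cbc(alignment: StructuralAlignment, x: str, y: str) -> tuple[int, int]:
    """CBC and hemi-CBC counts between records ``x`` and ``y``.

    Examines every alignment-column pair (i, j) paired in both records;
    a gap in either record at i or j cannot occur there (gaps never encode
    structure).
    """
    shared = alignment.pair_set(x) & alignment.pair_set(y)
    cbc = hemi = 0
    for i, j in shared:
        xi, xj = alignment.residue(x, i), alignment.residue(x, j)
        yi, yj = alignment.residue(y, i), alignment.residue(y, j)
        if GAP in (xi, xj, yi, yj):  # defensive; pair_set excludes gaps
            continue
        if xi + xj not in VALID_PAIRS or yi + yj not in VALID_PAIRS:
            continue
        diff = (xi != yi) + (xj != yj)
        if diff == 2:
            cbc += 1
        elif diff == 1:
            hemi += 1
    return cbc, hemi


def cbc_matrix(alignment: StructuralAlignment) -> CBCMatrix:
    """All pairwise CBC / hemi-CBC counts from one multiple alignment."""
    ids = alignment.ids
    if len(ids) < 2:
        raise ValueError("need >= 2 records")
    n = len(ids)
    cbc = np.zeros((n, n), dtype=int)
    hemi = np.zeros((n, n), dtype=int)
    pair_sets = {rid: alignment.pair_set(rid) for rid in ids}
    residues = {
        rid: [alignment.residue(rid, c) for c in range(alignment.n_columns)] for rid in ids
    }
    for a in range(n):
        for b in range(a + 1, n):
            ra, rb = residues[ids[a]], residues[ids[b]]
            c = h = 0
            for i, j in pair_sets[ids[a]] & pair_sets[ids[b]]:
                xi, xj, yi, yj = ra[i], ra[j], rb[i], rb[j]
                if xi + xj not in VALID_PAIRS or yi + yj not in VALID_PAIRS:
                    continue
                diff = (xi != yi) + (xj != yj)
                if diff == 2:
                    c += 1
                elif diff == 1:
                    h += 1
            cbc[a, b] = cbc[b, a] = c
            hemi[a, b] = hemi[b, a] = h
    return CBCMatrix(list(ids), cbc, hemi)


def count_variation(alignment: StructuralAlignment, x: str, y: str) -> VariationSummary:
    """Transitions (A<->G, C<->U), transversions, and INDELs between two rows.

    INDEL events are maximal runs of gap-vs-residue columns; columns gapped
    in both records are invisible to the pair and are dropped first.
    """
    row_x = [alignment.residue(x, c) for c in range(alignment.n_columns)]
    row_y = [alignment.residue(y, c) for c in range(alignment.n_columns)]
    ts = tv = events = cols = 0
    gap_side = None  # which record is gapped in the current run
    for rx, ry in zip(row_x, row_y):
        if rx == GAP and ry == GAP:
            continue
        if (rx == GAP) != (ry == GAP):
            side = "x" if rx == GAP else "y"
            cols += 1
            if side != gap_side:
                events += 1
                gap_side = side
            continue
        gap_side = None
        if rx != ry:
            if frozenset((rx, ry)) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    return VariationSummary(ts, tv, events, cols)
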