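"""Joint sequence-structure alignment in a 12-letter combined alphabet.

Each position of a folded ITS2 is encoded as one of 12 letters, the cross
product of the residue {A,C,G,U} and its pairing state {unpaired, opening,
closing}:

====== ========= ======== ========
residue unpaired  opening  closing
====== ========= ======== ========
A      a         A        B
C      c         C        D
G      g         G        H
U      u         U        V
====== ========= ======== ========

The encoding is bijective per position, so an encoded string decodes back to
the (sequence, dot-bracket) it came from.  Pairwise alignment is global with
affine gaps (a gap of length L costs ``gap_open + L * gap_extend``); the
default scoring rewards joint residue+state matches (+3) over state-only
(+1) and residue-only (-1) matches, with -2 when neither agrees — the
qualitative structure-over-sequence ordering the method assumes.  The matrix
is a loadable table so a published ITS2-specific matrix can be dropped in.

Multiple alignment is progressive: a UPGMA guide tree on score-derived
distances, then profile-profile alignment along the tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .folding import SecondaryStructure, to_rna
from .io_formats import check_balanced, dotbracket_to_pairs

__all__ = [
    "LETTERS",
    "GAP",
    "EncodedSequence",
    "ScoringMatrix",
    "StructuralAlignment",
    "encode",
    "decode",
    "align_pair",
    "align_progressive",
]

RESIDUES = "ACGU"
STATES = ".()"
#: encoded alphabet, indexed residue-major then state
LETTERS = "acguACGUBDHV"
GAP = "-"

_ENCODE = {}
_DECODE = {}
for _ri, _res in enumerate(RESIDUES):
    for _si, _st in enumerate(STATES):
        _letter = LETTERS[_si * 4 + _ri]
        _ENCODE[(_res, _st)] = _letter
        _DECODE[_letter] = (_res, _st)

_LETTER_INDEX = {ch: k for k, ch in enumerate(LETTERS)}


@dataclass(frozen=True)
class EncodedSequence:
    """A sequence-structure string over the 12-letter alphabet."""

    id: str
    letters: str

    def __len__(self) -> int:
        return len(self.letters)


def encode(sequence: str, structure: "SecondaryStructure | str", record_id: Optional[str] = None) -> EncodedSequence:
    """Encode (sequence, structure) into the 12-letter alphabet, losslessly."""
    dotbracket = structure.dotbracket if isinstance(structure, SecondaryStructure) else structure
    rid = record_id or (structure.record_id if isinstance(structure, SecondaryStructure) else "seq")
    seq = to_rna(sequence)
    if len(seq) != len(dotbracket):
        raise ValueError(
            f"{rid}: sequence length {len(seq)} != structure length {len(dotbracket)}"
        )
    check_balanced(dotbracket, rid)
    try:
        letters = "".join(_ENCODE[(r, s)] for r, s in zip(seq, dotbracket))
    except KeyError as exc:
        raise ValueError(f"{rid}: cannot encode position with residue/state {exc}") from None
    return EncodedSequence(rid, letters)


def decode(encoded: EncodedSequence) -> tuple[str, str]:
    """Invert :func:`encode`; gaps are not allowed in an EncodedSequence."""
    seq = []
    dot = []
    for ch in encoded.letters:
        r, s = _DECODE[ch]
        seq.append(r)
        dot.append(s)
    return "".join(seq), "".join(dot)


class ScoringMatrix:
    """12x12 substitution scores plus affine gap penalties."""

    def __init__(self, scores: np.ndarray, gap_open: float = -5.0, gap_extend: float = -1.0):
        scores = np.asarray(scores, dtype=np.float64)
        if scores.shape != (12, 12):
            raise ValueError("scoring table must cover all 12x12 code pairs")
        self.scores = scores
        self.gap_open = float(gap_open)
        self.gap_extend = float(gap_extend)

    @classmethod
    def default(cls, gap_open: float = -5.0, gap_extend: float = -1.0) -> "ScoringMatrix":
        s = np.empty((12, 12))
        for a, la in enumerate(LETTERS):
            ra, sa = _DECODE[la]
            for b, lb in enumerate(LETTERS):
                rb, sb = _DECODE[lb]
                if ra == rb and sa == sb:
                    s[a, b] = 3.0
                elif sa == sb:
                    s[a, b] = 1.0
                elif ra == rb:
                    s[a, b] = -1.0
                else:
                    s[a, b] = -2.0
        return cls(s, gap_open, gap_extend)

    @classmethod
    def from_tsv(cls, path, gap_open: float = -5.0, gap_extend: float = -1.0) -> "ScoringMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.loc[list(LETTERS), list(LETTERS)]
        return cls(df.to_numpy(), gap_open, gap_extend)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.scores, index=list(LETTERS), columns=list(LETTERS)).to_csv(
            path, sep="\t"
        )


# ---------------------------------------------------------------------------
# affine-gap global alignment (Gotoh), numba-accelerated
# ---------------------------------------------------------------------------

_NEG = -1e30


def _gotoh_fill_py(S, go, ge):
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in second sequence (consume first)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in first sequence (consume second)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + ge * i
    for j in range(1, m + 1):
        Y[0, j] = go + ge * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best_prev:
                best_prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best_prev:
                best_prev = Y[i - 1, j - 1]
            M[i, j] = best_prev + S[i - 1, j - 1]
            open_x = M[i - 1, j] if M[i - 1, j] > Y[i - 1, j] else Y[i - 1, j]
            X[i, j] = max(X[i - 1, j] + ge, open_x + go + ge)
            open_y = M[i, j - 1] if M[i, j - 1] > X[i, j - 1] else X[i, j - 1]
            Y[i, j] = max(Y[i, j - 1] + ge, open_y + go + ge)
    return M, X, Y


try:  # pragma: no cover
    from numba import njit

    _gotoh_fill = njit(cache=True)(_gotoh_fill_py)
except Exception:  # pragma: no cover
    _gotoh_fill = _gotoh_fill_py


def _gotoh(S: np.ndarray, go: float, ge: float):
    """Optimal global alignment on a precomputed column-score matrix.

    Returns (score, path) where path is a list of (i, j) with -1 marking a
    gap.  Tie-break: match/mismatch over gap, then gap in the first row.
    """
    n, m = S.shape
    M, X, Y = _gotoh_fill(S, go, ge)
    eps = 1e-9

    def argpref(i, j):  # tie-break: match/mismatch, then gap in first row
        best = max(M[i, j], Y[i, j], X[i, j])
        if M[i, j] >= best - eps:
            return "M"
        return "Y" if Y[i, j] >= best - eps else "X"

    score = max(M[n, m], Y[n, m], X[n, m])
    path = []
    i, j = n, m
    state = argpref(i, j)
    while i > 0 or j > 0:
        if state == "M":
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            if i > 0 or j > 0:
                state = argpref(i, j)
        elif state == "Y":  # gap in first row, consume second
            path.append((-1, j - 1))
            if abs(Y[i, j] - (Y[i, j - 1] + ge)) <= eps:
                state = "Y"
            else:
                state = "M" if M[i, j - 1] >= X[i, j - 1] - eps else "X"
            j -= 1
        else:  # X: gap in second row, consume first
            path.append((i - 1, -1))
            if abs(X[i, j] - (X[i - 1, j] + ge)) <= eps:
                state = "X"
            else:
                state = "M" if M[i - 1, j] >= Y[i - 1, j] - eps else "Y"
            i -= 1
    path.reverse()
    return float(score), path


class StructuralAlignment:
    """Aligned encoded sequences; gaps (``-``) never encode structure.

    Per-record pairing maps are lifted to alignment columns on demand.
    """

    def __init__(self, rows: Sequence[tuple[str, str]]):
        if not rows:
            raise ValueError("alignment needs at least one row")
        lengths = {len(r[1]) for r in rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")
        ids = [r[0] for r in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")
        self.ids = ids
        self._rows = dict(rows)
        self.n_columns = lengths.pop()
        for rid, letters in self._rows.items():
            stripped = letters.replace(GAP, "")
            bad = set(stripped) - set(LETTERS)
            if bad:
                raise ValueError(f"{rid}: invalid alignment characters {sorted(bad)}")
            check_balanced("".join(_DECODE[ch][1] for ch in stripped), rid)

    @property
    def rows(self) -> list[tuple[str, str]]:
        return [(rid, self._rows[rid]) for rid in self.ids]

    def row(self, rid: str) -> str:
        return self._rows[rid]

    def residue(self, rid: str, col: int) -> str:
        ch = self._rows[rid][col]
        return GAP if ch == GAP else _DECODE[ch][0]

    def state(self, rid: str, col: int) -> str:
        ch = self._rows[rid][col]
        return GAP if ch == GAP else _DECODE[ch][1]

    def ungapped(self, rid: str) -> EncodedSequence:
        return EncodedSequence(rid, self._rows[rid].replace(GAP, ""))

    def pair_set(self, rid: str) -> set[tuple[int, int]]:
        """This record's base pairs as alignment-column index pairs (i < j)."""
        letters = self._rows[rid]
        cols = [c for c, ch in enumerate(letters) if ch != GAP]
        dot = "".join(_DECODE[letters[c]][1] for c in cols)
        return {(cols[i], cols[j]) for i, j in dotbracket_to_pairs(dot)}

    def column_pairs(self, rid: str) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pair_set(rid):
            out[i] = j
            out[j] = i
        return out

    def select(self, ids: Iterable[str]) -> "StructuralAlignment":
        return StructuralAlignment([(rid, self._rows[rid]) for rid in ids])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, letters in self.rows:
                fh.write(f">{rid}\n{letters}\n")

    @classmethod
    def read_fasta(cls, path) -> "StructuralAlignment":
        rows = []
        rid = None
        buf: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if rid is not None:
                        rows.append((rid, "".join(buf)))
                    rid = line[1:].split()[0]
                    buf = []
                else:
                    buf.append(line)
        if rid is not None:
            rows.append((rid, "".join(buf)))
        return cls(rows)


def _score_matrix_for(a_idx: np.ndarray, b_idx: np.ndarray, matrix: ScoringMatrix) -> np.ndarray:
    return matrix.scores[np.ix_(a_idx, b_idx)]


def _indices(enc: EncodedSequence) -> np.ndarray:
    return np.fromiter((_LETTER_INDEX[ch] for ch in enc.letters), dtype=np.int64, count=len(enc))


def align_pair(
    a: EncodedSequence,
    b: EncodedSequence,
    matrix: Optional[ScoringMatrix] = None,
    return_score: bool = False,
):
    """Optimal global alignment of two encoded sequences under affine gaps."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align empty sequences")
    matrix = matrix or ScoringMatrix.default()
    S = _score_matrix_for(_indices(a), _indices(b), matrix)
    score, path = _gotoh(S, matrix.gap_open, matrix.gap_extend)
    row_a = "".join(a.letters[i] if i >= 0 else GAP for i, _ in path)
    row_b = "".join(b.letters[j] if j >= 0 else GAP for _, j in path)
    aln = StructuralAlignment([(a.id, row_a), (b.id, row_b)])
    return (aln, score) if return_score else aln


def pairwise_score(a: EncodedSequence, b: EncodedSequence, matrix: Optional[ScoringMatrix] = None) -> float:
    matrix = matrix or ScoringMatrix.default()
    S = _score_matrix_for(_indices(a), _indices(b), matrix)
    M, X, Y = _gotoh_fill(S, matrix.gap_open, matrix.gap_extend)
    n, m = S.shape
    return float(max(M[n, m], X[n, m], Y[n, m]))


def _profile(rows: list[np.ndarray]) -> np.ndarray:
    """(L, 12) letter-frequency profile; gaps (index -1) contribute nothing."""
    L = rows[0].shape[0]
    P = np.zeros((L, 12))
    for r in rows:
        valid = r >= 0
        P[np.nonzero(valid)[0], r[valid]] += 1.0
    return P / len(rows)


def align_progressive(
    encoded: Sequence[EncodedSequence], matrix: Optional[ScoringMatrix] = None
) -> StructuralAlignment:
    """Progressive multiple alignment: UPGMA guide tree on score-derived
    distances, then profile-profile alignment along the tree."""
    if len(encoded) < 2:
        raise ValueError("progressive alignment needs >= 2 records")
    matrix = matrix or ScoringMatrix.default()
    n = len(encoded)
    idx = [_indices(e) for e in encoded]
    self_scores = np.array(
        [float(np.sum(matrix.scores[ix, ix])) for ix in idx]
    )
    # pairwise alignment scores -> distances for the guide tree
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = pairwise_score(encoded[i], encoded[j], matrix)
            d = max(0.0, (self_scores[i] + self_scores[j]) / 2.0 - s)
            dist[i, j] = dist[j, i] = d
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(dist, checks=False), method="average")

    # cluster state: list of (record index, gapped index array; -1 = gap)
    clusters: dict[int, list[tuple[int, np.ndarray]]] = {
        k: [(k, idx[k].copy())] for k in range(n)
    }
    for step, (ia, ib, _, _) in enumerate(Z):
        a_rows = clusters.pop(int(ia))
        b_rows = clusters.pop(int(ib))
        Pa = _profile([r for _, r in a_rows])
        Pb = _profile([r for _, r in b_rows])
        S = Pa @ matrix.scores @ Pb.T
        _, path = _gotoh(S, matrix.gap_open, matrix.gap_extend)
        new_rows: list[tuple[int, np.ndarray]] = []
        a_cols = np.array([p[0] for p in path])
        b_cols = np.array([p[1] for p in path])
        for rec, r in a_rows:
            out = np.where(a_cols >= 0, r[np.clip(a_cols, 0, None)], -1)
            new_rows.append((rec, out.astype(np.int64)))
        for rec, r in b_rows:
            out = np.where(b_cols >= 0, r[np.clip(b_cols, 0, None)], -1)
            new_rows.append((rec, out.astype(np.int64)))
        clusters[n + step] = new_rows
    (final_rows,) = clusters.values()
    by_rec = dict(final_rows)
    rows = []
    for k, e in enumerate(encoded):
        arr = by_rec[k]
        rows.append((e.id, "".join(LETTERS[v] if v >= 0 else GAP for v in arr)))
    return StructuralAlignment(rows)
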