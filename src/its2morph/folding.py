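"""Minimum-free-energy RNA secondary structure prediction.

The predictor is a dynamic program over nested (pseudoknot-free) structures
with a deliberately simplified thermodynamic model: one stacking energy per
stacked pair combination, size-dependent hairpin and interior/bulge loop
penalties (interior/bulge loops capped at 30 nt), and an affine multiloop
cost.  It reproduces the topology-level behaviour ITS2 morphometrics needs
(helix counts, suboptimal band, deterministic selection); it makes no claim
of matching full nearest-neighbour parameter sets, and externally predicted
structures can be supplied in Vienna format to bypass folding entirely.

Two energy models are available:

``stacking``
    the simplified nearest-neighbour model described above (default);
``pair-count``
    every pair contributes -1.0 kcal/mol and loops are free (a Nussinov-style
    maximum-pairing objective, useful for oracle tests).

All energies are handled internally as integer tenths of kcal/mol so that
optima are exact and reproducible.

Suboptimal structures within a percentage band of the MFE are enumerated
with a best-first Wuchty-style expansion of the dynamic-programming cases;
the case analysis is disjoint, so every structure is generated exactly once
and in order of increasing energy.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .io_formats import dotbracket_to_pairs, pairs_to_dotbracket

__all__ = [
    "FoldingParams",
    "SecondaryStructure",
    "fold_mfe",
    "fold_suboptimal",
    "select_structure",
    "structure_energy",
    "to_rna",
]

INF = 1 << 40

#: base encoding used by the dynamic program
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

#: canonical + wobble pair types, indexed for the stacking table
PAIR_TYPES = ("AU", "UA", "GC", "CG", "GU", "UG")
_PAIR_INDEX = -np.ones((5, 5), dtype=np.int64)
for _k, _pt in enumerate(PAIR_TYPES):
    _PAIR_INDEX[_CODE[_pt[0]], _CODE[_pt[1]]] = _k

#: per-pair-type stacking strength (tenths of kcal/mol); a stack of two
#: pairs contributes -(strength[p] + strength[q])
_STACK_STRENGTH = np.array([11, 11, 17, 17, 7, 7], dtype=np.int64)

# loop penalties, tenths of kcal/mol
_HAIRPIN_BASE, _HAIRPIN_PER_NT = 30, 3
_INTERNAL_BASE, _INTERNAL_PER_NT = 20, 3
_ML_CLOSE, _ML_BRANCH, _ML_UNPAIRED = 34, 4, 1


def to_rna(sequence: str) -> str:
    """Uppercase and convert T to U; folding is modelled on RNA rules."""
    return sequence.upper().replace("T", "U")


def _encode_bases(sequence: str) -> np.ndarray:
    codes = np.empty(len(sequence), dtype=np.int64)
    for i, ch in enumerate(sequence):
        if ch in _CODE:
            codes[i] = _CODE[ch]
        elif ch == "N":
            codes[i] = 4  # unpairable
        else:
            raise ValueError(f"non-IUPAC character in sequence: {ch!r}")
    return codes


@dataclass
class FoldingParams:
    """Folding settings: 5% suboptimality band, at most 50 structures,
    interior/bulge loops capped at 30 nt, minimum hairpin loop 3 nt."""

    min_loop: int = 3
    subopt_percent: float = 5.0
    max_structures: int = 50
    max_internal_loop: int = 30
    energy_model: str = "stacking"  # or "pair-count"
    temperature: str = "37C"  # label only; the model is not T-dependent

    def __post_init__(self) -> None:
        if not (0 < self.subopt_percent <= 100):
            raise ValueError("suboptimality percent must be in (0, 100]")
        if self.max_structures < 1:
            raise ValueError("max structures must be >= 1")
        if self.energy_model not in ("stacking", "pair-count"):
            raise ValueError(f"unknown energy model {self.energy_model!r}")

    @property
    def _pair_bonus(self) -> int:
        return -10 if self.energy_model == "pair-count" else 0

    @property
    def _stack_table(self) -> np.ndarray:
        if self.energy_model == "pair-count":
            return np.zeros((6, 6), dtype=np.int64)
        return -(_STACK_STRENGTH[:, None] + _STACK_STRENGTH[None, :])

    @property
    def _loop_consts(self) -> tuple[int, int, int, int, int, int, int]:
        if self.energy_model == "pair-count":
            return (0, 0, 0, 0, 0, 0, 0)
        return (
            _HAIRPIN_BASE,
            _HAIRPIN_PER_NT,
            _INTERNAL_BASE,
            _INTERNAL_PER_NT,
            _ML_CLOSE,
            _ML_BRANCH,
            _ML_UNPAIRED,
        )


@dataclass
class SecondaryStructure:
    """A nested secondary structure with its model free energy.

    Pairs are stored 0-based (i < j); reports use 1-based coordinates.
    """

    record_id: str
    dotbracket: str
    pairs: tuple[tuple[int, int], ...]
    energy: float
    rank: int = 0
    flags: tuple[str, ...] = ()

    @classmethod
    def from_dotbracket(
        cls, record_id: str, dotbracket: str, energy: float = 0.0, rank: int = 0
    ) -> "SecondaryStructure":
        return cls(record_id, dotbracket, tuple(dotbracket_to_pairs(dotbracket)), energy, rank)

    @property
    def pairs_1based(self) -> tuple[tuple[int, int], ...]:
        return tuple((i + 1, j + 1) for i, j in self.pairs)

    def __len__(self) -> int:
        return len(self.dotbracket)

    def validate(self, sequence: str, params: Optional[FoldingParams] = None) -> None:
        """Check nestedness, pair validity and minimum loop size."""
        params = params or FoldingParams()
        seq = to_rna(sequence)
        if len(seq) != len(self.dotbracket):
            raise ValueError("sequence/structure length mismatch")
        if pairs_to_dotbracket(self.pairs, len(seq)) != self.dotbracket:
            raise ValueError("dot-bracket inconsistent with pair set")
        dotbracket_to_pairs(self.dotbracket)  # raises on crossing/unbalance
        for i, j in self.pairs:
            if j - i - 1 < params.min_loop:
                raise ValueError(f"pair ({i + 1},{j + 1}) violates min loop size")
            if seq[i] + seq[j] not in PAIR_TYPES:
                raise ValueError(f"invalid pair {seq[i]}-{seq[j]} at ({i + 1},{j + 1})")


# ---------------------------------------------------------------------------
# dynamic-programming fill (numba-accelerated when available)
# ---------------------------------------------------------------------------


def _fill_matrices_py(codes, pair_idx, minloop, max_int, pb, stack, h0, h1, i0, i1, ma, mb, mc):
    n = codes.shape[0]
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    WM1 = np.full((n, n), INF, dtype=np.int64)
    W = np.zeros(n, dtype=np.int64)
    for d in range(0, n):
        for i in range(0, n - d):
            j = i + d
            # --- V(i, j): i paired with j -------------------------------
            pt = pair_idx[codes[i], codes[j]] if codes[i] < 4 and codes[j] < 4 else -1
            if pt >= 0 and d - 1 >= minloop:
                best = h0 + h1 * (d - 1)  # hairpin
                # stack
                if i + 1 < j - 1 and codes[i + 1] < 4 and codes[j - 1] < 4:
                    pt2 = pair_idx[codes[i + 1], codes[j - 1]]
                    if pt2 >= 0 and V[i + 1, j - 1] < INF:
                        cand = V[i + 1, j - 1] + stack[pt, pt2]
                        if cand < best:
                            best = cand
                # interior / bulge loops, total unpaired 1..max_int
                pmax = min(i + max_int + 1, j - 1)
                for p in range(i + 1, pmax + 1):
                    left = p - i - 1
                    qlo = max(p + 1, j - 1 - (max_int - left))
                    for q in range(qlo, j):
                        u = left + (j - q - 1)
                        if u < 1 or u > max_int:
                            continue
                        if V[p, q] < INF:
                            cand = V[p, q] + i0 + i1 * u
                            if cand < best:
                                best = cand
                # multiloop: last branch starts at k
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k - 1] < INF and WM1[k, j - 1] < INF:
                        cand = ma + mb + WM[i + 1, k - 1] + WM1[k, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = pb + best
            # --- WM1(i, j): one branch, starting exactly at i -----------
            b1 = INF
            if j > i and WM1[i, j - 1] < INF:
                b1 = WM1[i, j - 1] + mc
            if V[i, j] < INF and V[i, j] + mb < b1:
                b1 = V[i, j] + mb
            WM1[i, j] = b1
            # --- WM(i, j): >= 1 branch in a multiloop context -----------
            bm = INF
            if i + 1 <= j and WM[i + 1, j] < INF:
                bm = WM[i + 1, j] + mc
            for l in range(i + minloop + 1, j + 1):
                if V[i, l] < INF:
                    tail = mc * (j - l)
                    rest = WM[l + 1, j] if l + 1 <= j else INF
                    t = tail if tail < rest else rest
                    cand = V[i, l] + mb + t
                    if cand < bm:
                        bm = cand
            WM[i, j] = bm
    # --- exterior ----------------------------------------------------------
    for j in range(n):
        best = W[j - 1] if j > 0 else 0
        for i in range(0, j):
            if V[i, j] < INF:
                left = W[i - 1] if i > 0 else 0
                cand = left + V[i, j]
                if cand < best:
                    best = cand
        W[j] = best
    return V, WM, WM1, W


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _fill_matrices = njit(cache=True)(_fill_matrices_py)
except Exception:  # pragma: no cover
    _fill_matrices = _fill_matrices_py


class _Engine:
    """Filled DP matrices plus the disjoint case expansion used by both the
    greedy traceback and the Wuchty suboptimal enumeration."""

    def __init__(self, sequence: str, params: FoldingParams):
        self.seq = to_rna(sequence)
        self.params = params
        if len(self.seq) < params.min_loop + 2:
            raise ValueError(
                f"sequence too short to fold (need >= {params.min_loop + 2} nt)"
            )
        self.codes = _encode_bases(self.seq)
        h0, h1, i0, i1, ma, mb, mc = params._loop_consts
        self.consts = (h0, h1, i0, i1, ma, mb, mc)
        self.pb = params._pair_bonus
        self.stack = params._stack_table
        self.V, self.WM, self.WM1, self.W = _fill_matrices(
            self.codes,
            _PAIR_INDEX,
            params.min_loop,
            params.max_internal_loop,
            self.pb,
            self.stack,
            h0, h1, i0, i1, ma, mb, mc,
        )
        self.n = len(self.seq)

    # -- matrix lookup ------------------------------------------------------
    def value(self, item) -> int:
        kind = item[0]
        if kind == "W":
            j = item[1]
            return 0 if j < 0 else int(self.W[j])
        _, i, j = item
        if i > j:
            return INF
        if kind == "V":
            return int(self.V[i, j])
        if kind == "M":
            return int(self.WM[i, j])
        return int(self.WM1[i, j])

    def _pt(self, i, j):
        ci, cj = self.codes[i], self.codes[j]
        if ci > 3 or cj > 3:
            return -1
        return int(_PAIR_INDEX[ci, cj])

    def cases(self, item):
        """Yield (cost, new_items, new_pairs) for every disjoint DP case.

        Ordering implements the traceback tie-break: prefer the pairing that
        starts 5'-most, then the one extending the current helix.
        """
        h0, h1, i0, i1, ma, mb, mc = self.consts
        kind = item[0]
        minloop = self.params.min_loop
        if kind == "W":
            j = item[1]
            if j < 0:
                return
            for i in range(0, j - minloop):
                if self._pt(i, j) >= 0 and self.V[i, j] < INF:
                    yield 0, (("W", i - 1), ("V", i, j)), ((i, j),)
            yield 0, (("W", j - 1),), ()
            return
        _, i, j = item
        if kind == "V":
            pb = self.pb
            # stack
            if i + 1 < j - 1 and self._pt(i + 1, j - 1) >= 0 and self.V[i + 1, j - 1] < INF:
                pt, pt2 = self._pt(i, j), self._pt(i + 1, j - 1)
                yield pb + int(self.stack[pt, pt2]), (("V", i + 1, j - 1),), ((i + 1, j - 1),)
            # interior / bulge
            max_int = self.params.max_internal_loop
            pmax = min(i + max_int + 1, j - 1)
            for p in range(i + 1, pmax + 1):
                left = p - i - 1
                qlo = max(p + 1, j - 1 - (max_int - left))
                for q in range(j - 1, qlo - 1, -1):
                    u = left + (j - q - 1)
                    if u < 1 or u > max_int:
                        continue
                    if self.V[p, q] < INF:
                        yield pb + i0 + i1 * u, (("V", p, q),), ((p, q),)
            # multiloop
            for k in range(i + 2, j - 1):
                if self.WM[i + 1, k - 1] < INF and self.WM1[k, j - 1] < INF:
                    yield pb + ma + mb, (("M", i + 1, k - 1), ("M1", k, j - 1)), ()
            # hairpin
            yield pb + h0 + h1 * (j - i - 1), (), ()
            return
        if kind == "M":
            for l in range(i + minloop + 1, j + 1):
                if self._pt(i, l) >= 0 and self.V[i, l] < INF:
                    if l + 1 <= j and self.WM[l + 1, j] < INF:
                        yield mb, (("V", i, l), ("M", l + 1, j)), ((i, l),)
                    yield mb + mc * (j - l), (("V", i, l),), ((i, l),)
            if i + 1 <= j:
                yield mc, (("M", i + 1, j),), ()
            return
        # M1: single branch starting exactly at i
        if self._pt(i, j) >= 0 and self.V[i, j] < INF:
            yield mb, (("V", i, j),), ((i, j),)
        if j - 1 >= i:
            yield mc, (("M1", i, j - 1),), ()

    # -- greedy traceback of one optimal structure --------------------------
    def traceback(self) -> tuple[tuple[int, int], ...]:
        pairs: list[tuple[int, int]] = []
        stack = [("W", self.n - 1)]
        while stack:
            item = stack.pop()
            target = self.value(item)
            if item[0] == "W" and item[1] < 0:
                continue
            # pairs are recorded when the V item holding them is created,
            # so each case only contributes its new_pairs
            for cost, items, new_pairs in self.cases(item):
                if cost + sum(self.value(it) for it in items) == target:
                    pairs.extend(new_pairs)
                    stack.extend(items)
                    break
            else:  # pragma: no cover - would indicate a fill/expand mismatch
                raise RuntimeError(f"traceback failed at {item}")
        return tuple(sorted(set(pairs)))


def _structure_from_pairs(record_id, seq_len, pairs, deci_energy, rank=0, flags=()):
    return SecondaryStructure(
        record_id=record_id,
        dotbracket=pairs_to_dotbracket(pairs, seq_len),
        pairs=tuple(sorted(pairs)),
        energy=deci_energy / 10.0,
        rank=rank,
        flags=tuple(flags),
    )


def fold_mfe(
    sequence: str, params: Optional[FoldingParams] = None, record_id: str = "seq"
) -> SecondaryStructure:
    """Predict the minimum-free-energy structure of one sequence.

    Deterministic: ties in the traceback are broken toward the pairing that
    starts 5'-most, then toward extending the current helix.
    """
    params = params or FoldingParams()
    eng = _Engine(sequence, params)
    pairs = eng.traceback()
    mfe = int(eng.W[eng.n - 1])
    return _structure_from_pairs(record_id, eng.n, pairs, mfe)


def fold_suboptimal(
    sequence: str, params: Optional[FoldingParams] = None, record_id: str = "seq"
) -> list[SecondaryStructure]:
    """Enumerate all structures within ``subopt_percent`` of the MFE energy,
    sorted by energy, at most ``max_structures``, mutually distinct."""
    params = params or FoldingParams()
    eng = _Engine(sequence, params)
    mfe = int(eng.W[eng.n - 1])
    band = int(abs(mfe) * params.subopt_percent / 100.0 + 1e-9)
    limit = mfe + band

    counter = 0
    # heap entries: (bound, tiebreak, fixed_cost, pending_items, pairs)
    heap = [(mfe, 0, 0, (("W", eng.n - 1),), ())]
    out: list[SecondaryStructure] = []
    seen: set[frozenset] = set()
    while heap and len(out) < params.max_structures:
        bound, _, fixed, items, pairs = heapq.heappop(heap)
        if bound > limit:
            break
        if not items:
            key = frozenset(pairs)
            if key not in seen:
                seen.add(key)
                out.append(
                    _structure_from_pairs(record_id, eng.n, pairs, fixed, rank=len(out))
                )
            continue
        head, rest = items[0], items[1:]
        if head[0] == "W" and head[1] < 0:
            rest_bound = fixed + sum(eng.value(it) for it in rest)
            counter += 1
            heapq.heappush(heap, (rest_bound, counter, fixed, rest, pairs))
            continue
        for cost, new_items, new_pairs in eng.cases(head):
            nfixed = fixed + cost
            nitems = new_items + rest
            nbound = nfixed + sum(eng.value(it) for it in nitems)
            if nbound <= limit:
                counter += 1
                heapq.heappush(heap, (nbound, counter, nfixed, nitems, pairs + new_pairs))
    return out


def select_structure(
    candidates: list[SecondaryStructure], helix_counts: Iterable[int] = (3, 4)
) -> SecondaryStructure:
    """Apply the structure-selection rule: the lowest-energy candidate whose
    topology has 3-4 principal helices radiating from the central loop wins;
    if none qualifies the MFE structure is returned flagged
    ``non-canonical topology``."""
    from .annotation import build_helix_tree  # deferred: annotation imports us

    if not candidates:
        raise ValueError("empty candidate list")
    ordered = sorted(candidates, key=lambda s: (s.energy, s.rank))
    wanted = set(helix_counts)
    for cand in ordered:
        tree = build_helix_tree(cand)
        if len(tree.principal_helices) in wanted:
            return cand
    best = ordered[0]
    return SecondaryStructure(
        best.record_id,
        best.dotbracket,
        best.pairs,
        best.energy,
        best.rank,
        best.flags + ("non-canonical topology",),
    )


# ---------------------------------------------------------------------------
# independent energy evaluation (loop decomposition of a finished structure)
# ---------------------------------------------------------------------------


def structure_energy(
    sequence: str,
    structure: "SecondaryStructure | str | Iterable[tuple[int, int]]",
    params: Optional[FoldingParams] = None,
) -> float:
    """Evaluate the model energy of a given structure by loop decomposition.

    Accepts a :class:`SecondaryStructure`, a dot-bracket string or an
    iterable of 0-based pairs.  Raises ``ValueError`` for structures the
    model cannot score (invalid pair, loop-size violation).
    """
    params = params or FoldingParams()
    seq = to_rna(sequence)
    if isinstance(structure, SecondaryStructure):
        pairs = list(structure.pairs)
    elif isinstance(structure, str):
        pairs = dotbracket_to_pairs(structure)
    else:
        pairs = sorted(structure)
    h0, h1, i0, i1, ma, mb, mc = params._loop_consts
    pb = params._pair_bonus
    stack = params._stack_table
    ptype: dict[tuple[int, int], int] = {}
    for i, j in pairs:
        duo = seq[i] + seq[j]
        if duo not in PAIR_TYPES:
            raise ValueError(f"invalid pair {duo} at ({i + 1},{j + 1})")
        if j - i - 1 < params.min_loop:
            raise ValueError(f"hairpin loop below minimum at ({i + 1},{j + 1})")
        ptype[(i, j)] = PAIR_TYPES.index(duo)
    # direct children of each pair (nesting), via an interval sweep
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    stack_pairs: list[tuple[int, int]] = []
    events = sorted(pairs)
    paired_pos = {i for p in pairs for i in p}
    for p in events:
        while stack_pairs and not (stack_pairs[-1][0] < p[0] and p[1] < stack_pairs[-1][1]):
            stack_pairs.pop()
        if stack_pairs:
            children[stack_pairs[-1]].append(p)
        stack_pairs.append(p)
    total = pb * len(pairs)
    for (i, j), kids in children.items():
        if not kids:
            total += h0 + h1 * (j - i - 1)
        elif len(kids) == 1:
            (p, q) = kids[0]
            u = (p - i - 1) + (j - q - 1)
            if u == 0:
                total += int(stack[ptype[(i, j)], ptype[(p, q)]])
            elif u <= params.max_internal_loop:
                total += i0 + i1 * u
            else:
                raise ValueError(
                    f"interior/bulge loop of size {u} exceeds cap at ({i + 1},{j + 1})"
                )
        else:
            unpaired = (j - i - 1) - sum(q - p + 1 for p, q in kids)
            total += ma + mb * (1 + len(kids)) + mc * unpaired
    return total / 10.0
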