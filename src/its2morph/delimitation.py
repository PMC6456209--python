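"""CBC-based species delimitation.

Decision rules:

* a CBC between two records always indicates distinct species, so the
  *minimal species count* of a dataset is the minimum number of groups such
  that no within-group pair shows a CBC — the chromatic number of the
  CBC-incompatibility graph (exact by branch-and-bound up to 16 records,
  greedy largest-first with an exactness flag beyond that);
* a query is given a reference species name only on *absolute identity*
  with that reference's ITS2 sequence-structure (strict mode: gap-free
  alignment, zero substitutions, identical pairing) and zero CBCs against it;
* queries without a named reference are delimited to genus level only and
  grouped into CBC-compatible blocks labelled ``<Genus> sp. type-NN``;
* a query with a CBC against every reference and query of its genus is
  flagged a putative new species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

from .alignment import EncodedSequence, ScoringMatrix, align_pair
from .cbc import CBCMatrix

__all__ = [
    "SpeciesPartition",
    "minimal_species_count",
    "assign_species",
    "absolute_identity",
]


class DelimitationError(ValueError):
    pass


@dataclass
class SpeciesPartition:
    """Blocks of records compatible under the zero-CBC-within rule."""

    blocks: list[set[str]]
    labels: dict[str, str] = field(default_factory=dict)
    flags: dict[str, list[str]] = field(default_factory=dict)
    exact: bool = True

    @property
    def n_species(self) -> int:
        return len(self.blocks)

    def block_of(self, rid: str) -> int:
        for k, blk in enumerate(self.blocks):
            if rid in blk:
                return k
        raise KeyError(rid)


def _incompatibility_graph(cbc: CBCMatrix) -> dict[int, set[int]]:
    n = len(cbc.ids)
    adj: dict[int, set[int]] = {v: set() for v in range(n)}
    for a in range(n):
        for b in range(a + 1, n):
            if cbc.cbc[a, b] >= 1:
                adj[a].add(b)
                adj[b].add(a)
    return adj


def _exact_coloring(adj: dict[int, set[int]]) -> list[int]:
    """Minimum graph coloring by iterative-deepening backtracking.

    Deterministic: vertices ordered by (degree desc, index); feasible for the
    <= 16-vertex instances it is used on.
    """
    n = len(adj)
    if n == 0:
        return []
    order = sorted(adj, key=lambda v: (-len(adj[v]), v))
    best: list[int] = []

    def try_k(k: int) -> Optional[list[int]]:
        colors: dict[int, int] = {}

        def bt(pos: int) -> bool:
            if pos == n:
                return True
            v = order[pos]
            used = {colors[u] for u in adj[v] if u in colors}
            max_new = min(k, (max(colors.values()) + 2) if colors else 1)
            for c in range(max_new):
                if c not in used:
                    colors[v] = c
                    if bt(pos + 1):
                        return True
                    del colors[v]
            return False

        if bt(0):
            return [colors[v] for v in range(n)]
        return None

    lower = 1
    for k in range(lower, n + 1):
        res = try_k(k)
        if res is not None:
            best = res
            break
    return best


def _greedy_coloring(adj: dict[int, set[int]]) -> list[int]:
    order = sorted(adj, key=lambda v: (-len(adj[v]), v))
    colors: dict[int, int] = {}
    for v in order:
        used = {colors[u] for u in adj[v] if u in colors}
        c = 0
        while c in used:
            c += 1
        colors[v] = c
    return [colors[v] for v in range(len(adj))]


def minimal_species_count(
    cbc: CBCMatrix, exact_limit: int = 16
) -> tuple[int, SpeciesPartition]:
    """Minimum number of species groups compatible with the CBC evidence.

    Exact for up to ``exact_limit`` records; larger sets fall back to a
    deterministic greedy (largest-degree-first) coloring, flagged
    ``exact=False``.
    """
    adj = _incompatibility_graph(cbc)
    exact = len(adj) <= exact_limit
    coloring = _exact_coloring(adj) if exact else _greedy_coloring(adj)
    n_blocks = (max(coloring) + 1) if coloring else 0
    blocks: list[set[str]] = [set() for _ in range(n_blocks)]
    for v, c in enumerate(coloring):
        blocks[c].add(cbc.ids[v])
    # renumber blocks by first appearance in input order
    seen: list[set[str]] = []
    for rid in cbc.ids:
        for blk in blocks:
            if rid in blk and blk not in seen:
                seen.append(blk)
    part = SpeciesPartition(seen, exact=exact)
    for k, blk in enumerate(seen):
        for rid in blk:
            part.labels[rid] = f"block-{k + 1:02d}"
    return len(seen), part


def absolute_identity(
    x: EncodedSequence,
    y: EncodedSequence,
    mode: str = "strict",
    matrix: Optional[ScoringMatrix] = None,
) -> bool:
    """Absolute identity of two folded records.

    ``strict`` (default): gap-free alignment, zero substitutions and
    identical pairing — i.e. identical encoded strings.  ``structure-only``:
    identical pairing states column-by-column after alignment, regardless of
    the residues.
    """
    if mode == "strict":
        return x.letters == y.letters
    if mode == "structure-only":
        if len(x) != len(y):
            aln = align_pair(x, y, matrix)
            states_x = [aln.state(x.id, c) for c in range(aln.n_columns)]
            states_y = [aln.state(y.id, c) for c in range(aln.n_columns)]
            return states_x == states_y
        from .alignment import _DECODE  # state projection without alignment

        return all(_DECODE[a][1] == _DECODE[b][1] for a, b in zip(x.letters, y.letters))
    raise ValueError(f"unknown identity mode {mode!r}")


def assign_species(
    queries: Sequence[str],
    references: Sequence[tuple[str, str]],
    cbc: CBCMatrix,
    identity: "Mapping[tuple[str, str], bool] | Callable[[str, str], bool]",
    genus: Mapping[str, str],
) -> SpeciesPartition:
    """Assign each query a species name or a genus-level ``type-NN`` label.

    ``references`` are (record id, species name) pairs; ``identity`` gives
    the absolute-identity predicate for (query, reference) pairs; ``genus``
    maps every query to its genus.  A query identical to a reference takes
    that species name (conflicting names or identity alongside a CBC raise
    :class:`DelimitationError`); remaining queries are grouped per genus into
    CBC-compatible blocks numbered by input order; a query with CBCs against
    all references and queries of its genus is flagged a putative new species.
    """
    ident = identity if callable(identity) else (lambda q, r: identity.get((q, r), False))
    ref_ids = [r for r, _ in references]
    ref_name = dict(references)
    missing = [q for q in queries if q not in genus]
    if missing:
        raise DelimitationError(f"queries without genus label: {missing}")

    labels: dict[str, str] = {}
    flags: dict[str, list[str]] = {q: [] for q in queries}
    named_blocks: dict[str, set[str]] = {}
    unnamed: list[str] = []
    for q in queries:
        hits = [r for r in ref_ids if ident(q, r)]
        names = {ref_name[r] for r in hits}
        if len(names) > 1:
            raise DelimitationError(
                f"query {q!r} absolutely identical to references with conflicting "
                f"names: {sorted(names)}"
            )
        if hits:
            for r in hits:
                c, _ = cbc.get(q, r) if r in cbc.ids else (0, 0)
                if c >= 1:
                    raise DelimitationError(
                        f"inconsistency: {q!r} identical to {r!r} but CBC >= 1 "
                        "(upstream alignment fault?)"
                    )
            name = names.pop()
            labels[q] = name
            named_blocks.setdefault(name, set()).add(q)
        else:
            unnamed.append(q)

    # genus-level grouping of unnamed queries into zero-CBC blocks
    blocks: list[set[str]] = list(named_blocks.values())
    by_genus: dict[str, list[str]] = {}
    for q in unnamed:
        by_genus.setdefault(genus[q], []).append(q)
    for gname in sorted(by_genus):
        members = by_genus[gname]
        sub_ids = [rid for rid in cbc.ids if rid in members]
        if len(sub_ids) == 1:
            sub_blocks = [set(sub_ids)]
        else:
            import numpy as np

            idx = [cbc.ids.index(r) for r in sub_ids]
            sub = CBCMatrix(
                sub_ids,
                cbc.cbc[np.ix_(idx, idx)],
                cbc.hemi[np.ix_(idx, idx)],
            )
            _, sub_part = minimal_species_count(sub)
            sub_blocks = sub_part.blocks
        # number blocks by first member's input order
        sub_blocks.sort(key=lambda blk: min(members.index(m) for m in blk))
        for k, blk in enumerate(sub_blocks):
            label = f"{gname} sp. type-{k + 1:02d}"
            for q in blk:
                labels[q] = label
            blocks.append(blk)

    # putative-new-species flag
    for q in queries:
        others = [
            r
            for r in cbc.ids
            if r != q and (r in ref_ids or (r in genus and genus.get(r) == genus[q]))
        ]
        if others and all(cbc.get(q, r)[0] >= 1 for r in others):
            flags[q].append("putative new species")

    return SpeciesPartition(blocks, labels, flags, exact=True)
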