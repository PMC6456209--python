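"""Helix-level annotation of ITS2 secondary structures.

A eukaryotic ITS2 folds into a central loop (the exterior multiloop of the
dot-bracket) with 3-4 helices radiating from it, numbered I-IV in 5'->3'
order; helix III is typically the longest and carries a UGGC motif (CGGC in
some lineages) at the base of its 5' strand.  Some structures instead place
two or three helices on an "extended subdomain": a short stem (here <= 3
pairs, configurable) that opens into a second-level multiloop.  A small 2-3
bp helix with an apical loop between helices II and III is designated IIa
and excluded from the principal-helix count.

Five topology classes are distinguished:

1. three helices, all radiating from the central loop;
2. helix I central, helices II and III on an extended subdomain;
3. as type 2 plus the small helix IIa between II and III;
4. four helices, all central;
5. helices I and II on an extended subdomain, III and IV central.

Anything else is reported as type 0 (unclassified) and propagates as a flag
rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .folding import SecondaryStructure, to_rna
from .io_formats import get_logger, pairs_to_dotbracket

__all__ = [
    "Helix",
    "HelixTree",
    "TopologyType",
    "ConsensusStructure",
    "build_helix_tree",
    "classify_topology",
    "detect_basal_motif",
    "build_consensus",
]

log = get_logger(__name__)

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


@dataclass
class Helix:
    """One arm of the structure: a stem (possibly interrupted by interior
    loops/bulges) walked from its outermost closing pair to a hairpin loop
    or a multiloop."""

    closing_pair: tuple[int, int]  # outermost pair, 0-based
    stem_pairs: int  # total pairs along the arm
    segments: list[list[tuple[int, int]]]  # runs of contiguously stacked pairs
    apical: bool  # ends in a hairpin loop
    origin: str = "central"  # or "subdomain"
    label: str = ""

    @property
    def start(self) -> int:
        return self.closing_pair[0]


@dataclass
class HelixTree:
    central_loop: list[int]  # unpaired exterior positions, 0-based
    helices: list[Helix] = field(default_factory=list)  # 5'->3', labelled
    subdomain_present: bool = False
    subdomain_stem: int = 0  # pairs in the stem enclosing the subdomain

    @property
    def principal_helices(self) -> list[Helix]:
        return [h for h in self.helices if h.label != "IIa"]

    @property
    def iia_present(self) -> bool:
        return any(h.label == "IIa" for h in self.helices)


@dataclass(frozen=True)
class TopologyType:
    type_code: int  # 1..5, or 0 = unclassified
    n_central: int
    subdomain_present: bool
    iia_present: bool


def _children_map(pairs: Sequence[tuple[int, int]]):
    """Direct-nesting children for each pair plus the top level (exterior)."""
    top: list[tuple[int, int]] = []
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    stack: list[tuple[int, int]] = []
    for p in sorted(pairs):
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        (children[stack[-1]] if stack else top).append(p)
        stack.append(p)
    return top, children


def _walk_arm(outer, children):
    """Follow an arm from its outermost pair while it has exactly one child;
    return (Helix-without-origin/label, terminal_pair)."""
    segments: list[list[tuple[int, int]]] = [[outer]]
    cur = outer
    n = 1
    while len(children[cur]) == 1:
        (nxt,) = children[cur]
        if nxt[0] == cur[0] + 1 and nxt[1] == cur[1] - 1:
            segments[-1].append(nxt)
        else:
            segments.append([nxt])
        cur = nxt
        n += 1
    apical = len(children[cur]) == 0
    return Helix(outer, n, segments, apical), cur


def build_helix_tree(
    structure: SecondaryStructure, subdomain_max_stem: int = 3
) -> HelixTree:
    """Annotate the helices radiating from the central loop.

    The central loop is the exterior multiloop.  An arm whose stem has at
    most ``subdomain_max_stem`` pairs and opens into a multiloop is treated
    as an extended subdomain of the central loop: its branches join the
    radiating-helix list with ``origin="subdomain"``.  A structure without
    pairs yields a tree with zero helices.
    """
    pairs = list(structure.pairs)
    n = len(structure.dotbracket)
    paired = {i for p in pairs for i in p}
    central = [i for i in range(n) if i not in paired]
    tree = HelixTree(central_loop=central)
    if not pairs:
        return tree
    top, children = _children_map(pairs)
    helices: list[Helix] = []
    for outer in top:
        helix, terminal = _walk_arm(outer, children)
        kids = children[terminal]
        if len(kids) >= 2 and helix.stem_pairs <= subdomain_max_stem:
            tree.subdomain_present = True
            tree.subdomain_stem = helix.stem_pairs
            for sub_outer in kids:
                sub_helix, _ = _walk_arm(sub_outer, children)
                sub_helix.origin = "subdomain"
                helices.append(sub_helix)
        else:
            helix.origin = "central"
            helices.append(helix)
    helices.sort(key=lambda h: h.start)
    _assign_labels(helices)
    tree.helices = helices
    return tree


def _assign_labels(helices: list[Helix]) -> None:
    """Label helices I.. in 5'->3' order; a small (2-3 bp) apical helix with
    at least two principal helices before it and one after is IIa."""
    iia_idx: Optional[int] = None
    if len(helices) >= 4:
        for k in range(2, len(helices) - 1):
            h = helices[k]
            if (
                h.apical
                and 2 <= h.stem_pairs <= 3
                and helices[k - 1].stem_pairs > 3
                and helices[k + 1].stem_pairs > 3
            ):
                iia_idx = k
                break
    counter = 0
    for k, h in enumerate(helices):
        if k == iia_idx:
            h.label = "IIa"
        else:
            h.label = ROMAN[counter] if counter < len(ROMAN) else str(counter + 1)
            counter += 1


def classify_topology(tree: HelixTree) -> TopologyType:
    """Map a helix tree onto the five ITS2 topology classes (0 = none)."""
    principal = tree.principal_helices
    origins = tuple(h.origin for h in principal)
    n = len(principal)
    n_central = origins.count("central")
    iia = tree.iia_present
    code = 0
    if n == 3 and origins == ("central",) * 3 and not iia:
        code = 1
    elif n == 3 and origins == ("central", "subdomain", "subdomain"):
        code = 3 if iia else 2
    elif n == 4 and origins == ("central",) * 4 and not iia:
        code = 4
    elif n == 4 and origins == ("subdomain", "subdomain", "central", "central") and not iia:
        code = 5
    return TopologyType(code, n_central, tree.subdomain_present, iia)


def detect_basal_motif(
    tree: HelixTree, sequence: str, window: int = 6
) -> tuple[str, str]:
    """Scan the base of helix III for the UGGC motif or its CGGC variant.

    Helix III is taken positionally (third principal helix, 5'->3'); if a
    different helix is the longest a warning is logged.  The first ``window``
    nucleotides of the helix's 5' strand are searched for UGGC, then CGGC.
    Returns ``(matched_motif, variant)`` with variant one of ``"UGGC"``,
    ``"CGGC"``, ``"absent"``.
    """
    principal = tree.principal_helices
    if len(principal) < 3:
        log.warning("fewer than 3 principal helices; no helix III to scan")
        return ("", "absent")
    h3 = principal[2]
    longest = max(principal, key=lambda h: h.stem_pairs)
    if longest is not h3 and longest.stem_pairs > h3.stem_pairs:
        log.warning(
            "longest helix (%s, %d bp) is not positional helix III (%d bp)",
            longest.label, longest.stem_pairs, h3.stem_pairs,
        )
    seq = to_rna(sequence)
    start = h3.closing_pair[0]
    segment = seq[start : start + window]
    for motif in ("UGGC", "CGGC"):
        if motif in segment:
            return (motif, motif)
    return ("", "absent")


@dataclass
class ConsensusStructure:
    """Column-wise consensus of a structural alignment.

    ``conservation`` is the majority-residue frequency among non-gap rows;
    columns are flagged conserved above the 0.51 threshold.  Consensus pairs
    are the column pairs maintained by more than half of the records, so a
    helix absent from most records (e.g. a variable helix IV) drops out of
    the consensus.
    """

    residues: str
    conservation: list[float]
    dotbracket: str
    conserved: list[bool]
    threshold: float = 0.51


def build_consensus(alignment, threshold: float = 0.51) -> ConsensusStructure:
    """Majority-rule consensus over a :class:`~its2morph.alignment.StructuralAlignment`."""
    rows = alignment.rows
    if len(rows) < 2:
        raise ValueError("consensus needs at least 2 aligned records")
    ncol = alignment.n_columns
    nrec = len(rows)
    residues = []
    conservation = []
    conserved = []
    for c in range(ncol):
        counts: dict[str, int] = {}
        for rid in alignment.ids:
            base = alignment.residue(rid, c)
            if base != "-":
                counts[base] = counts.get(base, 0) + 1
        if not counts:
            residues.append("-")
            conservation.append(0.0)
            conserved.append(False)
            continue
        base, cnt = max(sorted(counts.items()), key=lambda kv: kv[1])
        frac = cnt / sum(counts.values())
        residues.append(base)
        conservation.append(frac)
        conserved.append(frac > threshold)
    # pair-wise majority vote; >50% of all records must maintain the pair
    pair_counts: dict[tuple[int, int], int] = {}
    for rid in alignment.ids:
        for i, j in alignment.column_pairs(rid).items():
            if i < j:
                pair_counts[(i, j)] = pair_counts.get((i, j), 0) + 1
    kept: list[tuple[int, int]] = []
    used: set[int] = set()
    for (i, j), cnt in sorted(pair_counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if cnt * 2 > nrec and i not in used and j not in used:
            kept.append((i, j))
            used.update((i, j))
    kept = _drop_crossing(sorted(kept))
    dot = pairs_to_dotbracket(kept, ncol)
    return ConsensusStructure("".join(residues), conservation, dot, conserved, threshold)


def _drop_crossing(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Greedily keep a nested subset (5'-most first); crossing pairs from a
    mixed majority vote are rare but must not corrupt the dot-bracket."""
    kept: list[tuple[int, int]] = []
    for p in pairs:
        if all(q[1] < p[0] or p[1] < q[0] or (q[0] < p[0] and p[1] < q[1]) or (p[0] < q[0] and q[1] < p[1]) for q in kept):
            kept.append(p)
    return kept
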