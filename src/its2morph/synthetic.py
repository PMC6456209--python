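"""Synthetic ITS2-like data with planted, fully-known ground truth.

The generator emulates the two kinds of data the pipeline consumes:

* **Sequence sets** built from a structural template — a central loop with
  3-4 helices radiating from it, 5.8S/28S-proxy flanks, and a UGGC motif at
  the base of the longest (third) helix.  Species are differentiated by
  *planted* compensatory base changes (CBCs) at dedicated stem positions
  (so every between-species pair carries a known number of CBCs and every
  within-species pair carries none, the delimitation premise), plus
  hemi-CBCs and unpaired substitutions within species and optional
  insertion/deletion events in unpaired regions.  The true dot-bracket of
  every record is known by construction.

* **Community tables** with the statistical shape of a leaf-segment survey:
  hosts x sampling events x leaf regions (midrib/lamina), per-segment
  infection as a Bernoulli draw, and species abundances from Fisher's
  log-series, whose natural parameter alpha the diversity module estimates.

A single integer seed drives all randomness; no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .diversity import CommunityTable
from .io_formats import FastaRecord, SequenceSet

__all__ = [
    "StructureTemplate",
    "PlantedTruth",
    "generate_species_set",
    "generate_community",
    "FLANK_5P",
    "FLANK_3P",
]

#: conserved fungal rDNA proxies: 3' end of 5.8S and 5' start of 28S
FLANK_5P = "GCATCGATGAAGAACGCAGC"
FLANK_3P = "GCATATCAATAAGCGGAGGA"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: full compensatory change per Watson-Crick pair (both sides change, pair kept)
_CBC_ALT = {("G", "C"): ("A", "T"), ("A", "T"): ("G", "C"),
            ("C", "G"): ("T", "A"), ("T", "A"): ("C", "G")}
#: one-sided change to a wobble pair (hemi-CBC)
_HEMI_ALT = {("G", "C"): ("G", "T"), ("A", "T"): ("G", "T"),
             ("C", "G"): ("T", "G"), ("T", "A"): ("T", "G")}


@dataclass
class StructureTemplate:
    """Blueprint of an ITS2-like fold: ordered helices (stem bp, loop nt),
    unpaired spacers between them, and conserved flanking motifs."""

    helices: list[tuple[int, int]] = field(
        default_factory=lambda: [(14, 8), (16, 9), (22, 7)]
    )
    spacers: list[int] = field(default_factory=lambda: [6, 6, 6, 6])
    flank_5p: str = FLANK_5P
    flank_3p: str = FLANK_3P
    length_range: tuple[int, int] = (145, 181)

    def __post_init__(self) -> None:
        if len(self.spacers) != len(self.helices) + 1:
            raise ValueError("need one spacer per gap: len(spacers) == len(helices)+1")
        for stem, loop in self.helices:
            if stem < 2:
                raise ValueError("stem length must be >= 2 bp")
            if loop < 3:
                raise ValueError("loop length must be >= 3 nt")
        lo, hi = self.length_range
        if not (lo <= self.its2_length <= hi):
            raise ValueError(
                f"template ITS2 length {self.its2_length} outside range {self.length_range}"
            )

    @property
    def its2_length(self) -> int:
        return sum(2 * s + l for s, l in self.helices) + sum(self.spacers)

    @classmethod
    def four_helix(cls) -> "StructureTemplate":
        return cls(helices=[(12, 6), (14, 7), (20, 5), (10, 5)], spacers=[5, 5, 5, 5, 5])


@dataclass
class PlantedTruth:
    """Everything the generator knows: species labels, true structures and
    the planted per-pair mutation counts."""

    species: dict[str, str]
    dotbrackets: dict[str, str]  # true structure of the ITS2 region, per record
    its2_span: dict[str, tuple[int, int]]  # 1-based inclusive, on the full record
    cbc: dict[frozenset, int]
    hemi: dict[frozenset, int]

    def cbc_between(self, x: str, y: str) -> int:
        return 0 if x == y else self.cbc[frozenset((x, y))]

    def partition(self) -> list[set[str]]:
        blocks: dict[str, set[str]] = {}
        for rid, sp in self.species.items():
            blocks.setdefault(sp, set()).add(rid)
        return [blocks[k] for k in sorted(blocks)]


def _build_ancestor(template: StructureTemplate, rng: np.random.Generator):
    """Random ancestor ITS2 honouring the template; returns (chars, dotbracket,
    helix pair coordinate lists)."""
    bases = np.array(list("ACGT"))
    # loops and spacers are A/C-biased so they cannot nucleate stems that
    # compete with the planted helices when records are re-folded
    loop_bases = np.array(list("ACCA"))
    chars: list[str] = []
    dots: list[str] = []
    helix_pairs: list[list[tuple[int, int]]] = []
    longest = max(range(len(template.helices)), key=lambda k: template.helices[k][0])

    def emit_unpaired(n: int) -> None:
        chars.extend(rng.choice(loop_bases, size=n))
        dots.extend("." * n)

    emit_unpaired(template.spacers[0])
    for h, (stem, loop) in enumerate(template.helices):
        five = list(rng.choice(bases, size=stem))
        if h == longest:
            five[:4] = list("TGGC")  # UGGC motif at the helix base (RNA view)
        start5 = len(chars)
        chars.extend(five)
        dots.extend("(" * stem)
        emit_unpaired(loop)
        start3 = len(chars)
        chars.extend(_COMPLEMENT[b] for b in reversed(five))
        dots.extend(")" * stem)
        helix_pairs.append(
            [(start5 + k, start3 + stem - 1 - k) for k in range(stem)]
        )
        emit_unpaired(template.spacers[h + 1])
    return chars, dots, helix_pairs


def generate_species_set(
    template: Optional[StructureTemplate] = None,
    n_species: int = 3,
    n_per_species: int = 3,
    cbc_between: int = 2,
    hemicbc_within: int = 1,
    indel_rate: float = 0.0,
    seed: int = 0,
    sub_between: int = 4,
    sub_within: int = 1,
    include_flanks: bool = True,
) -> tuple[SequenceSet, PlantedTruth]:
    """Generate ``n_species x n_per_species`` ITS2-like records.

    Every between-species pair carries at least ``cbc_between`` planted CBCs
    in homologous stem positions (in fact one set per species, so
    ``2 x cbc_between``); within-species pairs carry none.  ``sub_between``
    unpaired substitutions per species provide phylogenetic signal outside
    the stems; ``hemicbc_within`` and ``sub_within`` vary individuals inside
    a species; ``indel_rate`` is a per-unpaired-site insertion/deletion
    probability per individual.  Deterministic under ``seed``.
    """
    template = template or StructureTemplate()
    if n_species < 1:
        raise ValueError("need at least one species")
    if n_species > 1 and cbc_between < 1:
        raise ValueError("cbc_between must be >= 1 when n_species > 1")
    rng = np.random.default_rng(seed)
    chars, dots, helix_pairs = _build_ancestor(template, rng)

    # stem positions eligible for planting: >= 2 bp from either helix end
    eligible = [p for pairs in helix_pairs for p in pairs[2:-2]]
    # keep the motif pairs untouched
    longest = max(range(len(template.helices)), key=lambda k: template.helices[k][0])
    motif_cols = {c for (i, j) in helix_pairs[longest][:4] for c in (i, j)}
    eligible = [p for p in eligible if p[0] not in motif_cols]
    rng.shuffle(eligible)

    need = n_species * cbc_between + n_species * n_per_species * hemicbc_within
    if len(eligible) < need:
        raise ValueError(
            f"template stems too short to host {need} planted events "
            f"({len(eligible)} eligible stem positions)"
        )
    cursor = 0
    cbc_sites: dict[int, list[tuple[int, int]]] = {}
    for s in range(n_species):
        cbc_sites[s] = eligible[cursor : cursor + cbc_between] if n_species > 1 else []
        if n_species > 1:
            cursor += cbc_between

    unpaired_cols = [k for k, d in enumerate(dots) if d == "."]
    sub_cols = rng.permutation(unpaired_cols).tolist()
    sp_subs: dict[int, list[int]] = {}
    for s in range(n_species):
        sp_subs[s] = sub_cols[s * sub_between : (s + 1) * sub_between]

    species_seqs: dict[int, list[str]] = {}
    for s in range(n_species):
        seq = list(chars)
        for i, j in cbc_sites[s]:
            seq[i], seq[j] = _CBC_ALT[(seq[i], seq[j])]
        for c in sp_subs[s]:
            seq[c] = str(rng.choice([b for b in "ACGT" if b != seq[c]]))
        species_seqs[s] = seq

    records: list[FastaRecord] = []
    truth = PlantedTruth({}, {}, {}, {}, {})
    hemi_sites: dict[str, int] = {}
    for s in range(n_species):
        sp_label = f"sp{s + 1:02d}"
        for r in range(n_per_species):
            rid = f"{sp_label}-r{r + 1}"
            seq = list(species_seqs[s])
            dot = list(dots)
            n_hemi = 0
            for _ in range(hemicbc_within):
                if cursor >= len(eligible):
                    raise ValueError("template stems too short for hemi-CBC planting")
                i, j = eligible[cursor]
                cursor += 1
                seq[i], seq[j] = _HEMI_ALT[(chars[i], chars[j])]
                n_hemi += 1
            for _ in range(sub_within):
                c = int(rng.choice(unpaired_cols))
                seq[c] = str(rng.choice([b for b in "ACGT" if b != seq[c]]))
            if indel_rate > 0:
                seq, dot = _apply_indels(seq, dot, indel_rate, rng)
            hemi_sites[rid] = n_hemi
            its2 = "".join(seq)
            if include_flanks:
                full = template.flank_5p + its2 + template.flank_3p
                span = (len(template.flank_5p) + 1, len(template.flank_5p) + len(its2))
            else:
                full, span = its2, (1, len(its2))
            records.append(FastaRecord(rid, f"species={sp_label}", full))
            truth.species[rid] = sp_label
            truth.dotbrackets[rid] = "".join(dot)
            truth.its2_span[rid] = span

    ids = [rec.id for rec in records]
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            x, y = ids[a], ids[b]
            key = frozenset((x, y))
            sx = int(truth.species[x][2:]) - 1
            sy = int(truth.species[y][2:]) - 1
            if sx == sy:
                truth.cbc[key] = 0
            else:
                truth.cbc[key] = len(cbc_sites[sx]) + len(cbc_sites[sy])
            truth.hemi[key] = hemi_sites[x] + hemi_sites[y]
    return SequenceSet(records), truth


def _apply_indels(seq: list[str], dot: list[str], rate: float, rng: np.random.Generator):
    """Insert or delete single bases at unpaired positions; stems untouched."""
    out_seq: list[str] = []
    out_dot: list[str] = []
    for ch, d in zip(seq, dot):
        if d == "." and rng.random() < rate:
            if rng.random() < 0.5:
                continue  # deletion
            out_seq.append(ch)
            out_dot.append(".")
            out_seq.append(str(rng.choice(list("ACGT"))))
            out_dot.append(".")
        else:
            out_seq.append(ch)
            out_dot.append(d)
    return out_seq, out_dot


def generate_community(
    n_hosts: int = 3,
    segments_per_host: int = 300,
    infection_prob: float = 0.4,
    alpha: float = 8.0,
    species_pool: int = 60,
    seed: int = 0,
    events: int = 2,
    extra_isolate_prob: float = 0.05,
) -> CommunityTable:
    """Community sampling with the shape of a leaf-segment survey.

    Each host is screened in ``events`` sampling events x two leaf regions
    (midrib, lamina); each segment is infected with probability
    ``infection_prob`` and yields one isolate (occasionally two, at
    ``extra_isolate_prob``); species are drawn from a log-series abundance
    model with parameter ``alpha``, identities taken from a global pool so
    hosts share species.
    """
    if not (0 <= infection_prob <= 1):
        raise ValueError("infection_prob must be in [0, 1]")
    if species_pool == 0 and infection_prob > 0:
        raise ValueError("species_pool must be positive when infections occur")
    from scipy.stats import logser

    rng = np.random.default_rng(seed)
    pool = [f"sp{k + 1:03d}" for k in range(species_pool)]
    per_cell = segments_per_host // (events * 2)
    rows = []
    iso_counter = 0
    for h in range(n_hosts):
        host = f"host{h + 1}"
        # infected segments
        cells = []
        for ev in range(events):
            for region in ("midrib", "lamina"):
                infected = np.nonzero(rng.random(per_cell) < infection_prob)[0]
                for seg in infected:
                    cells.append((f"E{ev + 1}", region, int(seg) + 1))
                    if rng.random() < extra_isolate_prob:
                        cells.append((f"E{ev + 1}", region, int(seg) + 1))
        N = len(cells)
        if N == 0:
            continue
        x = N / (N + alpha)
        counts: list[int] = []
        total = 0
        while total < N:
            k = int(logser.rvs(x, random_state=rng))
            counts.append(min(k, N - total))
            total += counts[-1]
        if len(counts) > species_pool:
            raise ValueError(
                f"log-series draw needs {len(counts)} species; pool has {species_pool}"
            )
        identity = rng.permutation(species_pool)[: len(counts)]
        labels = np.repeat([pool[i] for i in identity], counts)
        rng.shuffle(labels)
        for (ev, region, seg), sp in zip(cells, labels):
            iso_counter += 1
            rows.append(
                {
                    "isolate": f"iso{iso_counter:05d}",
                    "species": sp,
                    "host": host,
                    "region": region,
                    "event": ev,
                    "segment": seg,
                }
            )
    df = pd.DataFrame(
        rows, columns=["isolate", "species", "host", "region", "event", "segment"]
    )
    segments = {f"host{h + 1}": per_cell * events * 2 for h in range(n_hosts)}
    return CommunityTable(df, segments)
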