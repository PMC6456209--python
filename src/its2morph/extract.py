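"""ITS2 excision from full ITS sequences by conserved-flank motif search.

The ITS2 spacer sits between the 3' end of the 5.8S and the 5' start of the
28S rRNA genes.  Both gene ends are strongly conserved across fungi, so the
spacer is located by scanning for degenerate flanking motifs (IUPAC
alphabet, bounded mismatches) rather than by a profile HMM: the best match
is the one with fewest mismatches, ties broken toward the leftmost 5.8S /
rightmost 28S hit, and the ITS2 is everything strictly between the two
motifs.  Before folding, up to 20 bases of the flanking genes are padded
back onto each end, mirroring how proximal 5.8S/28S stems stabilize the
ITS2 fold; padding never invents bases beyond the source sequence
(truncation is logged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io_formats import FastaRecord, SequenceSet, get_logger
from .synthetic import FLANK_3P, FLANK_5P

__all__ = ["ITS2Record", "FlankNotFoundError", "extract_its2", "pad_flanks", "sequence_stats"]

log = get_logger(__name__)

#: IUPAC degenerate nucleotide codes
IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("TU"), "U": set("TU"),
    "R": set("AG"), "Y": set("CTU"), "S": set("GC"), "W": set("ATU"),
    "K": set("GTU"), "M": set("AC"), "B": set("CGTU"), "D": set("AGTU"),
    "H": set("ACTU"), "V": set("ACG"), "N": set("ACGTU"),
}

DEFAULT_MOTIF_5P = FLANK_5P  # 3' end of 5.8S (conserved fungal consensus)
DEFAULT_MOTIF_3P = FLANK_3P  # 5' start of 28S


class FlankNotFoundError(ValueError):
    pass


@dataclass
class ITS2Record:
    """An extracted ITS2 with provenance and 1-based source coordinates."""

    id: str
    host: str
    its2: str
    padded: str
    its2_span: tuple[int, int]  # 1-based inclusive on the source
    padded_span: tuple[int, int]
    source: str = ""


def _scan(sequence: str, motif: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (start, mismatches) of motif occurrences within the budget."""
    hits = []
    m = len(motif)
    for start in range(len(sequence) - m + 1):
        mm = 0
        for k in range(m):
            if sequence[start + k] not in IUPAC[motif[k]]:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append((start, mm))
    return hits


def extract_its2(
    record: FastaRecord,
    motif_5p: str = DEFAULT_MOTIF_5P,
    motif_3p: str = DEFAULT_MOTIF_3P,
    max_mismatch: int = 2,
    host: str = "",
) -> ITS2Record:
    """Excise the ITS2 strictly between the two flank motifs.

    Raises :class:`FlankNotFoundError` (naming the best partial match) when
    either motif is absent within ``max_mismatch``.
    """
    seq = record.sequence.upper()
    for motif, name in ((motif_5p, "5'"), (motif_3p, "3'")):
        bad = set(motif.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{name} motif has non-IUPAC characters: {sorted(bad)}")

    hits5 = _scan(seq, motif_5p.upper(), max_mismatch)
    if not hits5:
        best = min(
            ((start, _mismatches(seq, motif_5p.upper(), start)) for start in range(max(1, len(seq) - len(motif_5p) + 1))),
            key=lambda t: t[1],
            default=(0, len(motif_5p)),
        )
        raise FlankNotFoundError(
            f"{record.id}: 5' flank not found within {max_mismatch} mismatches "
            f"(best partial match: {best[1]} mismatches at position {best[0] + 1})"
        )
    # fewest mismatches, then leftmost
    best5 = min(hits5, key=lambda t: (t[1], t[0]))
    its2_start = best5[0] + len(motif_5p)  # 0-based

    hits3 = [(s, mm) for s, mm in _scan(seq, motif_3p.upper(), max_mismatch) if s >= its2_start]
    if not hits3:
        best = min(
            ((start, _mismatches(seq, motif_3p.upper(), start)) for start in range(its2_start, max(its2_start + 1, len(seq) - len(motif_3p) + 1))),
            key=lambda t: t[1],
            default=(its2_start, len(motif_3p)),
        )
        raise FlankNotFoundError(
            f"{record.id}: 3' flank not found within {max_mismatch} mismatches "
            f"(best partial match: {best[1]} mismatches at position {best[0] + 1})"
        )
    # fewest mismatches, then rightmost
    best3 = min(hits3, key=lambda t: (t[1], -t[0]))
    its2_end = best3[0]  # 0-based, exclusive

    its2 = seq[its2_start:its2_end]
    if not its2:
        raise FlankNotFoundError(f"{record.id}: flank motifs are adjacent; empty ITS2")
    rec = ITS2Record(
        id=record.id,
        host=host,
        its2=its2,
        padded=its2,
        its2_span=(its2_start + 1, its2_end),
        padded_span=(its2_start + 1, its2_end),
        source=seq,
    )
    return rec


def _mismatches(seq: str, motif: str, start: int) -> int:
    mm = 0
    for k in range(len(motif)):
        if start + k >= len(seq) or seq[start + k] not in IUPAC.get(motif[k], set()):
            mm += 1
    return mm


def passthrough(record: FastaRecord, host: str = "") -> ITS2Record:
    """Treat an already-bare ITS2 record as extracted (no padding possible)."""
    seq = record.sequence.upper()
    return ITS2Record(record.id, host, seq, seq, (1, len(seq)), (1, len(seq)), seq)


def pad_flanks(rec: ITS2Record, n: int = 20) -> ITS2Record:
    """Add up to ``n`` source bases of 5.8S/28S to each end of the ITS2.

    Padding is truncated (and logged) where the source runs out; with
    ``n=0`` the padded sequence equals the bare ITS2.
    """
    start, end = rec.its2_span  # 1-based inclusive
    pad_start = max(1, start - n)
    pad_end = min(len(rec.source), end + n)
    if n > 0 and (start - pad_start < n or pad_end - end < n):
        log.warning(
            "%s: padding truncated to %d/%d bases (5'/3')",
            rec.id, start - pad_start, pad_end - end,
        )
    padded = rec.source[pad_start - 1 : pad_end]
    return ITS2Record(
        rec.id, rec.host, rec.its2, padded, rec.its2_span, (pad_start, pad_end), rec.source
    )


def sequence_stats(records: Sequence[ITS2Record], padded: bool = False) -> pd.DataFrame:
    """Length and GC content (%) per record; N bases are excluded from both
    the numerator and the denominator of the GC fraction."""
    if not records:
        raise ValueError("empty record set")
    rows = []
    for rec in records:
        seq = rec.padded if padded else rec.its2
        gc = sum(seq.count(b) for b in "GC")
        acgt = sum(seq.count(b) for b in "ACGTU")
        rows.append(
            {
                "id": rec.id,
                "length": len(seq),
                "GC": round(100.0 * gc / acgt, 2) if acgt else float("nan"),
            }
        )
    return pd.DataFrame(rows)
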