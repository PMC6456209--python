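"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA carries DNA/RNA sequences, Vienna triplets carry a sequence with its
dot-bracket secondary structure (and an optional free energy in kcal/mol),
Newick carries trees with bootstrap supports as internal node labels, and
flat-key YAML carries run configuration.  All readers validate their input
against the type invariants and raise :class:`ParseError` instead of
silently repairing records.
"""

from __future__ import annotations

import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

__all__ = [
    "ParseError",
    "FastaRecord",
    "SequenceSet",
    "ViennaRecord",
    "read_fasta",
    "write_fasta",
    "read_vienna",
    "write_vienna",
    "write_newick",
    "read_tsv",
    "write_tsv",
    "load_config",
    "get_logger",
]

#: nucleotide alphabet accepted on input (stored uppercase)
VALID_ALPHABET = set("ACGTUN")

_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class FastaRecord:
    id: str
    description: str
    sequence: str


@dataclass
class SequenceSet:
    """An ordered collection of uniquely-identified nucleotide sequences."""

    records: list[FastaRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ParseError(f"duplicate sequence id: {rec.id!r}")
            seen.add(rec.id)
            if not rec.sequence:
                raise ParseError(f"empty sequence for record {rec.id!r}")
            bad = set(rec.sequence) - VALID_ALPHABET
            if bad:
                raise ParseError(
                    f"record {rec.id!r} contains invalid characters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key: str) -> FastaRecord:
        for rec in self.records:
            if rec.id == key:
                return rec
        raise KeyError(key)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass
class ViennaRecord:
    """Sequence plus dot-bracket structure; energy is optional (kcal/mol)."""

    id: str
    sequence: str
    dotbracket: str
    energy: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ParseError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.dotbracket)}"
            )
        check_balanced(self.dotbracket, self.id)


def check_balanced(dotbracket: str, record_id: str = "?") -> None:
    depth = 0
    for ch in dotbracket:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(f"record {record_id!r}: unbalanced brackets")
        elif ch != ".":
            raise ParseError(
                f"record {record_id!r}: invalid structure character {ch!r}"
            )
    if depth != 0:
        raise ParseError(f"record {record_id!r}: unbalanced brackets")


def read_fasta(path) -> SequenceSet:
    """Parse a multi-record FASTA file.

    Both T and U are accepted; whitespace inside sequence lines is stripped.
    Malformed headers, empty sequences and duplicate ids raise
    :class:`ParseError` naming the offending line.
    """
    records: list[FastaRecord] = []
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"line {header_line}: record {header!r} has empty sequence")
        parts = header.split(None, 1)
        rid, desc = parts[0], (parts[1] if len(parts) > 1 else "")
        records.append(FastaRecord(rid, desc, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise ParseError(f"line {lineno}: empty FASTA header")
            else:
                if header is None:
                    raise ParseError(f"line {lineno}: sequence data before first header")
                chunks.append("".join(line.split()))
    flush()
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    try:
        return SequenceSet(records)
    except ParseError as exc:  # attach file context
        raise ParseError(f"{path}: {exc}") from None


def write_fasta(seqset: SequenceSet | Iterable[FastaRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in seqset:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_vienna(path) -> list[ViennaRecord]:
    """Parse header/sequence/structure triplets, with optional trailing energy.

    The structure line may end with an energy token such as ``(-12.30)``;
    absent energies are stored as ``None``, never as 0.
    """
    out: list[ViennaRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 3 != 0:
        raise ParseError(f"{path}: expected header/sequence/structure triplets")
    for k in range(0, len(lines), 3):
        head, seq, struct = lines[k], lines[k + 1], lines[k + 2]
        if not head.startswith(">"):
            raise ParseError(f"{path}: record {k // 3 + 1}: missing '>' header")
        rid = head[1:].split(None, 1)[0]
        energy = None
        m = _ENERGY_RE.search(struct)
        if m:
            energy = float(m.group(1))
            struct = struct[: m.start()].strip()
        out.append(ViennaRecord(rid, seq.strip().upper(), struct, energy))
    return out


def write_vienna(records: Iterable[ViennaRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n{rec.dotbracket}")
            if rec.energy is not None:
                fh.write(f" ({rec.energy:.2f})")
            fh.write("\n")


def write_newick(tree, path) -> None:
    """Write a tree in Newick, branch lengths and integer supports included.

    Every leaf must be labelled; ``ParseError`` is raised otherwise.
    """
    from .phylogeny import Tree  # local import to avoid a module cycle

    if not isinstance(tree, Tree):
        raise TypeError("write_newick expects a phylogeny.Tree")
    newick = tree.to_newick()
    with open(path, "w") as fh:
        fh.write(newick + "\n")


def read_tsv(path, **kwargs):
    import pandas as pd

    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df, path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=kwargs.pop("index", False), **kwargs)


def load_config(path) -> dict:
    """Load a flat-key YAML configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def get_logger(name: str = "its2morph") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def dotbracket_to_pairs(dotbracket: str) -> list[tuple[int, int]]:
    """0-based (i, j) pairs, i < j, from a balanced dot-bracket string."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ParseError("unbalanced brackets")
            pairs.append((stack.pop(), i))
    if stack:
        raise ParseError("unbalanced brackets")
    return sorted(pairs)


def pairs_to_dotbracket(pairs: Iterable[tuple[int, int]], length: int) -> str:
    s = ["."] * length
    for i, j in pairs:
        s[i], s[j] = "(", ")"
    return "".join(s)
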