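"""FASTA and pattern-TSV input/output, batch validation, reverse complement.

Sequence batches come in two roles: equal-length nucleosomal sequences
aligned by the experimental (MNase cleavage) end, from which patterns are
derived, and arbitrary sequences in which nucleosomes are mapped.  Records
containing characters outside {A, C, G, T} (N or other IUPAC ambiguity
codes) are handled only by whole-record drop or error — mirroring how
masked sequences are excluded from curated nucleosome databases — never by
per-position masking.

Pattern tables are plain TSV: ``#``-prefixed ``key=value`` metadata lines,
a ``position<TAB>value`` header, then one row per (1-based, contiguous)
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceBatch",
    "PatternTable",
    "FilterReport",
    "read_fasta",
    "write_fasta",
    "filter_batch",
    "reverse_complement",
    "read_pattern",
    "write_pattern",
]

_VALID = frozenset("ACGT")


@dataclass
class SequenceBatch:
    """A list of (id, sequence) records, optionally aligned and equal-length.

    ``alignment`` is ``"experimental_end"`` for MNase-style batches aligned
    by the cleavage end (the batch role required for pattern derivation) or
    ``"none"`` for arbitrary mapping targets.
    """

    records: list[tuple[str, str]]
    alignment: str = "none"

    def __post_init__(self):
        if self.alignment not in ("experimental_end", "none"):
            raise ValueError(f"unknown alignment: {self.alignment!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def seqs(self) -> list[str]:
        return [r[1] for r in self.records]

    @property
    def length(self) -> int:
        """Common sequence length; raises if lengths differ or batch empty."""
        lengths = {len(s) for s in self.seqs}
        if not lengths:
            raise ValueError("empty batch has no length")
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        return lengths.pop()


@dataclass
class FilterReport:
    kept: int
    dropped: int
    dropped_ids: list[str] = field(default_factory=list)


@dataclass
class PatternTable:
    """Positions (1-based, contiguous) with real values plus free metadata."""

    positions: np.ndarray
    values: np.ndarray
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise ValueError("positions and values must be 1-D and equal-length")
        if len(self.positions) == 0:
            raise ValueError("empty pattern table")
        diffs = np.diff(self.positions)
        if len(diffs) and not np.all(diffs == 1):
            raise ValueError("positions must be strictly increasing and contiguous")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pattern values must be finite")


def read_fasta(path, alignment: str = "none") -> SequenceBatch:
    """Read a multi-record FASTA file into a batch, upper-casing sequences.

    No filtering is applied: ambiguity codes survive (use
    :func:`filter_batch` to drop them).  Empty files and records without
    sequence lines are errors.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has no sequence")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceBatch(records, alignment=alignment)


def write_fasta(batch: SequenceBatch, path, width: int = 70) -> None:
    """Write a batch as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in batch.records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def filter_batch(
    batch: SequenceBatch,
    n_policy: str = "drop",
    require_equal_length: bool = False,
) -> tuple[SequenceBatch, FilterReport]:
    """Remove (or reject) records with characters outside {A, C, G, T}.

    Parameters
    ----------
    n_policy
        ``"drop"`` removes offending records and counts them;
        ``"error"`` raises on the first offending record.
    require_equal_length
        If set, surviving records must share one length.

    Returns the filtered batch plus a report with kept/dropped counts.
    """
    if n_policy not in ("drop", "error"):
        raise ValueError(f"unknown n_policy: {n_policy!r}")
    if len(batch) == 0:
        raise ValueError("empty batch")
    kept, dropped_ids = [], []
    for name, seq in batch.records:
        if set(seq) <= _VALID:
            kept.append((name, seq))
        elif n_policy == "error":
            bad = sorted(set(seq) - _VALID)
            raise ValueError(f"record {name!r} contains non-ACGT characters: {bad}")
        else:
            dropped_ids.append(name)
    if not kept:
        raise ValueError("all records dropped by filter")
    out = SequenceBatch(kept, alignment=batch.alignment)
    if require_equal_length:
        out.length  # raises on unequal lengths
    return out, FilterReport(kept=len(kept), dropped=len(dropped_ids), dropped_ids=dropped_ids)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a strict-ACGT string."""
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    return str(Seq(seq).reverse_complement())


def write_pattern(table: PatternTable, path) -> None:
    """Write a pattern table as TSV with '#' metadata header lines."""
    with open(path, "w") as fh:
        for key, val in table.metadata.items():
            fh.write(f"#{key}={val}\n")
        fh.write("position\tvalue\n")
        for pos, val in zip(table.positions, table.values):
            fh.write(f"{pos}\t{float(val)!r}\n")


def read_pattern(path) -> PatternTable:
    """Read a pattern TSV written by :func:`write_pattern` (lossless round-trip)."""
    metadata: dict[str, str] = {}
    positions, values = [], []
    with open(path) as fh:
        header_seen = False
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                metadata[key] = val
                continue
            if not header_seen:
                if line.split("\t")[:2] != ["position", "value"]:
                    raise ValueError(f"{path}: expected 'position\\tvalue' header, got {line!r}")
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated fields")
            positions.append(int(fields[0]))
            values.append(float(fields[1]))
    if not positions:
        raise ValueError(f"{path}: no pattern rows")
    return PatternTable(np.array(positions), np.array(values), metadata)
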