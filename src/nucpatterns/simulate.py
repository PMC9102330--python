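"""Synthetic nucleosomal-sequence batches with known ground truth.

The generator emulates the statistical structure of an MNase-derived batch
of nucleosomal sequences aligned by the experimental (cleavage) end:

* i.i.d. background bases (uniform A/C/G/T by default);
* a fixed dinucleotide at position 1 of every sequence, reproducing the
  cleavage-site sequence bias that shows up as a narrow large peak at the
  start of frequency profiles;
* a dyad-symmetric nucleosome core: within a core of ``core_len`` bases
  starting at ``start``, the planted dinucleotide (AA by default) is
  written with probability ``signal`` at every ``period``-th position of
  the left half, and its reverse complement (TT) at the mirror-image
  positions of the right half, enforcing the pseudo-two-fold dyad symmetry
  of real nucleosomal DNA and the ~10-bp helical repeat.

Each scheduled left-half site and its mirror share one Bernoulli draw, so
planted sequences are individually dyad-symmetric at the planted sites.
Ground truth (common start, dyad position, per-sequence planted sites) is
returned alongside the batch and can be written as a sidecar TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dinuc import rc_class
from .seqio import SequenceBatch

__all__ = ["SimulationParams", "SimulationTruth", "simulate_batch", "write_truth"]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationParams:
    """Generator settings; defaults give a 500 x 400 bp AA/TT 10-bp batch."""

    n_seqs: int = 500
    seq_len: int = 400
    start: int = 30            # 1-based common nucleosome start
    core_len: int = 147
    period: int = 10           # helical repeat of planted sites, bp
    signal: float = 0.8        # planting probability per scheduled site
    planted_class: str = "AA"  # literal dinucleotide planted in the left half
    cleavage_bias: bool = True
    cleavage_dinuc: str = "CG"  # fixed dinucleotide at position 1
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 1

    def validate(self) -> None:
        if self.n_seqs < 1:
            raise ValueError("n_seqs must be >= 1")
        if self.start < 1 or self.start + self.core_len - 1 > self.seq_len:
            raise ValueError("nucleosome core must fit inside the sequence")
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("signal probability must be in [0, 1]")
        if self.period < 2:
            raise ValueError("period must be >= 2")
        if len(self.planted_class) != 2 or set(self.planted_class) - set("ACGT"):
            raise ValueError("planted_class must be a literal dinucleotide")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")


@dataclass
class SimulationTruth:
    start: int                      # 1-based common nucleosome start
    dyad: int                       # 1-based dyad = start + core_len // 2
    planted: list[list[int]] = field(default_factory=list)  # per-seq 1-based dinuc starts


def _scheduled_sites(params: SimulationParams) -> list[tuple[int, int]]:
    """(left_start, mirror_start) pairs of 0-based planted dinucleotide starts."""
    s0 = params.start - 1
    C = params.core_len
    d0 = s0 + C // 2  # 0-based dyad index
    pairs = []
    b = s0
    while b + 1 < d0:  # dinucleotide fully in the left half
        mirror = s0 + (C - 1) - (b - s0) - 1  # start of the mirrored dinucleotide
        if mirror + 1 <= s0 + C - 1:
            pairs.append((b, mirror))
        b += params.period
    return pairs


def simulate_batch(params: SimulationParams) -> tuple[SequenceBatch, SimulationTruth]:
    """Generate an end-aligned synthetic batch plus its ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    sites = _scheduled_sites(params)
    fw = params.planted_class.upper()
    rc = rc_class(fw)
    truth = SimulationTruth(
        start=params.start, dyad=params.start + params.core_len // 2
    )
    records = []
    for i in range(params.n_seqs):
        arr = rng.choice(_BASES, size=params.seq_len, p=params.background)
        planted_here: list[int] = []
        for left, mirror in sites:
            if rng.random() < params.signal:
                arr[left], arr[left + 1] = fw[0], fw[1]
                arr[mirror], arr[mirror + 1] = rc[0], rc[1]
                planted_here.extend([left + 1, mirror + 1])
        if params.cleavage_bias:
            arr[0], arr[1] = params.cleavage_dinuc[0], params.cleavage_dinuc[1]
        records.append((f"sim_{i:05d}", "".join(arr)))
        truth.planted.append(sorted(planted_here))
    return SequenceBatch(records, alignment="experimental_end"), truth


def write_truth(truth: SimulationTruth, batch: SequenceBatch, path) -> None:
    """Sidecar TSV: one row per sequence with the common start/dyad and sites."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tdyad\tplanted_positions\n")
        for (name, _), sites in zip(batch.records, truth.planted):
            fh.write(f"{name}\t{truth.start}\t{truth.dyad}\t{','.join(map(str, sites))}\n")
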