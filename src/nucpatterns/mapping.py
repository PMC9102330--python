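"""Map nucleosome dyads in sequences by sliding Pearson correlation.

For each placement of a pattern along a sequence, the sequence segment
under the pattern is converted to the binary occurrence indicator of the
pattern's dinucleotide class and the Pearson correlation between pattern
values and indicator is computed.  The CC is reported at the sequence
position of the pattern's dyad (placement offset + half the pattern
length); the maximum positive CC marks the most likely dyad.  With several
patterns, per-position CC values are averaged before taking the argmax.

A single unique most likely dyad is only meaningful for sequences up to
about two nucleosome lengths (< 294 bp); longer inputs trigger a
non-uniqueness warning rather than an error, since batch scans over longer
fragments are still useful for track inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dinuc import encode_occurrences
from .pattern import NucleosomePattern

__all__ = [
    "MappingTrack",
    "MappingResult",
    "cc_track",
    "predict_dyad",
    "map_sequence",
    "evaluate_accuracy",
    "NONUNIQUE_LENGTH",
]

#: Two nucleosome lengths; beyond this a unique dyad call is not guaranteed.
NONUNIQUE_LENGTH = 294


@dataclass
class MappingTrack:
    """Pearson CC per candidate dyad position (1-based sequence coordinate).

    ``cc`` spans the full sequence length; positions where the pattern
    window does not fit, or where the indicator has zero variance, are NaN.
    """

    cc: np.ndarray
    pattern_id: str
    class_code: str

    def __post_init__(self):
        self.cc = np.asarray(self.cc, dtype=float)

    def argmax_positive(self) -> tuple[int, float] | None:
        """(position, cc) of the maximum positive CC, or None if no positive CC."""
        if np.all(np.isnan(self.cc)):
            return None
        k = int(np.nanargmax(self.cc))
        v = float(self.cc[k])
        if v <= 0:
            return None
        return k + 1, v


@dataclass
class MappingResult:
    seq_id: str
    predicted_dyad: int | None
    max_cc: float | None
    tracks: list[MappingTrack] = field(default_factory=list)
    aggregation: str = "single"
    no_call: bool = False


def cc_track(seq: str, pattern: NucleosomePattern, pattern_id: str | None = None) -> MappingTrack:
    """Sliding-window Pearson CC between a pattern and a sequence.

    At placement offset ``t`` (0-based), the indicator of the pattern's
    class over ``seq[t : t + m + 1]`` (length-m binary vector, m = pattern
    length) is correlated with the pattern values; the CC is stored at the
    dyad coordinate ``t + m // 2`` (1-based: ``t + m // 2 + 1``).
    """
    m = len(pattern)
    if len(seq) < m + 1:
        raise ValueError(f"sequence length {len(seq)} < pattern window {m + 1}")
    ind = encode_occurrences(seq, pattern.class_code).astype(float)  # length L-1
    # all length-m windows of the indicator, one per placement offset
    w = np.lib.stride_tricks.sliding_window_view(ind, m)
    p = pattern.values - pattern.values.mean()
    sp = np.sqrt(p @ p)
    dw = w - w.mean(axis=1, keepdims=True)
    sw = np.sqrt(np.einsum("ij,ij->i", dw, dw))
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = (dw @ p) / (sw * sp)
    cc[sw == 0] = np.nan
    if sp == 0:
        cc[:] = np.nan
    track = np.full(len(seq), np.nan)
    offsets = np.arange(len(w))  # 0-based placement offsets
    track[offsets + m // 2] = cc
    pid = pattern_id or f"{pattern.class_code}"
    return MappingTrack(track, pid, pattern.class_code)


def predict_dyad(tracks: list[MappingTrack], aggregation: str = "mean") -> MappingResult:
    """Aggregate tracks (mean over non-missing) and call the dyad.

    The argmax positive aggregated CC wins, ties toward the smaller
    position; if no position has positive CC the result is flagged
    ``no_call`` rather than raising, so batch runs complete.
    """
    if not tracks:
        raise ValueError("need at least one mapping track")
    if aggregation != "mean":
        raise ValueError(f"unsupported aggregation: {aggregation!r}")
    stacked = np.vstack([t.cc for t in tracks])
    if stacked.shape[0] > 1 and len({t.cc.shape for t in tracks}) != 1:
        raise ValueError("tracks span different sequence lengths")
    seq_len = stacked.shape[1]
    if seq_len > NONUNIQUE_LENGTH:
        warnings.warn(
            f"sequence length {seq_len} exceeds two nucleosome lengths "
            f"({NONUNIQUE_LENGTH} bp); the maximum-CC dyad may not be unique",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        agg = np.nanmean(stacked, axis=0)
    mode = "mean" if len(tracks) > 1 else "single"
    if np.all(np.isnan(agg)) or np.nanmax(agg) <= 0:
        return MappingResult("", None, None, list(tracks), mode, no_call=True)
    k = int(np.nanargmax(agg))
    return MappingResult("", k + 1, float(agg[k]), list(tracks), mode)


def map_sequence(
    seq_id: str,
    seq: str,
    patterns: dict[str, NucleosomePattern],
    aggregation: str = "mean",
) -> MappingResult:
    """Convenience: per-pattern tracks + aggregated dyad call for one sequence."""
    tracks = [cc_track(seq, p, pattern_id=pid) for pid, p in sorted(patterns.items())]
    res = predict_dyad(tracks, aggregation=aggregation)
    res.seq_id = seq_id
    return res


def evaluate_accuracy(
    results: dict[str, MappingResult],
    truth: dict[str, int],
    tolerance: int = 4,
) -> tuple[pd.DataFrame, float]:
    """Per-sequence mapping accuracy against known dyads.

    For each sequence, every pattern's own track is called individually;
    the best pattern is the one with minimal |predicted - true| (ties ->
    lexicographically smallest pattern id).  A hit is a best distance
    <= ``tolerance`` (the experimental accuracy of curated dyad
    positions).  Returns the per-sequence table and the overall hit rate.
    """
    rows = []
    for seq_id, res in results.items():
        if seq_id not in truth:
            raise KeyError(f"no true dyad for sequence {seq_id!r}")
        true_dyad = truth[seq_id]
        best = None
        for t in sorted(res.tracks, key=lambda t: t.pattern_id):
            called = t.argmax_positive()
            if called is None:
                continue
            dist = abs(called[0] - true_dyad)
            if best is None or dist < best[1]:
                best = (t.pattern_id, dist, called[0])
        if best is None:
            rows.append(
                {"seq_id": seq_id, "best_pattern": None, "predicted": None,
                 "distance": np.nan, "hit": False}
            )
        else:
            rows.append(
                {"seq_id": seq_id, "best_pattern": best[0], "predicted": best[2],
                 "distance": best[1], "hit": best[1] <= tolerance}
            )
    table = pd.DataFrame(rows)
    hit_rate = float(table["hit"].mean()) if len(table) else float("nan")
    return table, hit_rate
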