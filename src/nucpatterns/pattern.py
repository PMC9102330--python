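"""Build nucleosome positioning patterns from frequency profiles.

A pattern is the nucleosome-core window of a class's frequency profile,
processed in three steps:

1. *Symmetrization* — average the forward profile with the mirrored
   profile of the reverse-complement class, so both strands contribute
   equally:  out[j] = (P_code[start+j] + P_rc[start+W-1-j]) / 2.
2. *Trimming* — drop a few positions from each end (default 4) to avoid
   the cleavage-boundary effect.
3. *Smoothing* — centered moving average (default window 3), valid
   positions only.

Trimming precedes smoothing so boundary positions never leak into the
averages; the final length is W - 2*trim - (smoothing_window - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dinuc import rc_class
from .profiles import FrequencyProfile
from .seqio import PatternTable

__all__ = [
    "NucleosomePattern",
    "extract_window",
    "symmetrize",
    "smooth_moving_average",
    "trim_ends",
    "build_pattern",
    "pattern_to_table",
    "pattern_from_table",
]


@dataclass
class NucleosomePattern:
    values: np.ndarray
    class_code: str
    start: int
    window: int
    smoothing_window: int = 3
    trim: int = 4
    symmetrized: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def extract_window(profile: FrequencyProfile, start: int, window: int) -> np.ndarray:
    """Contiguous profile slice [start, start + window - 1], 1-based."""
    if start < 1 or start + window - 1 > len(profile.values):
        raise ValueError(
            f"window [{start}, {start + window - 1}] out of range for profile of "
            f"length {len(profile.values)}"
        )
    return profile.values[start - 1 : start - 1 + window].copy()


def symmetrize(
    profiles: dict[str, FrequencyProfile], code: str, start: int, window: int
) -> np.ndarray:
    """Average the forward window with the mirrored reverse-complement window."""
    code = code.upper()
    fw = extract_window(profiles[code], start, window)
    rc = extract_window(profiles[rc_class(code)], start, window)
    return (fw + rc[::-1]) / 2.0


def smooth_moving_average(x: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average, valid positions only (no padding)."""
    x = np.asarray(x, dtype=float)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window > len(x):
        raise ValueError("smoothing window exceeds vector length")
    if window == 1:
        return x.copy()
    return np.convolve(x, np.full(window, 1.0 / window), mode="valid")


def trim_ends(x: np.ndarray, n: int = 4) -> np.ndarray:
    """Drop ``n`` positions from each end."""
    x = np.asarray(x, dtype=float)
    if n < 0:
        raise ValueError("trim must be >= 0")
    if len(x) <= 2 * n:
        raise ValueError(f"cannot trim {n} from each end of length-{len(x)} vector")
    return x[n : len(x) - n].copy()


def build_pattern(
    profiles: dict[str, FrequencyProfile],
    code: str,
    start: int,
    window: int = 146,
    smoothing_window: int = 3,
    trim: int = 4,
) -> NucleosomePattern:
    """Symmetrize, trim, and smooth a profile window into a pattern."""
    sym = symmetrize(profiles, code, start, window)
    trimmed = trim_ends(sym, trim)
    smoothed = smooth_moving_average(trimmed, smoothing_window)
    return NucleosomePattern(
        values=smoothed,
        class_code=code.upper(),
        start=start,
        window=window,
        smoothing_window=smoothing_window,
        trim=trim,
        symmetrized=True,
    )


def pattern_to_table(p: NucleosomePattern) -> PatternTable:
    """Serialize a pattern with its provenance metadata (1-based positions)."""
    meta = {
        "class_code": p.class_code,
        "start": str(p.start),
        "window": str(p.window),
        "smoothing_window": str(p.smoothing_window),
        "trim": str(p.trim),
        "symmetrized": str(p.symmetrized),
    }
    return PatternTable(np.arange(1, len(p) + 1), p.values, meta)


def pattern_from_table(t: PatternTable) -> NucleosomePattern:
    m = t.metadata
    return NucleosomePattern(
        values=t.values,
        class_code=m.get("class_code", "WW"),
        start=int(m.get("start", 1)),
        window=int(m.get("window", len(t.values))),
        smoothing_window=int(m.get("smoothing_window", 1)),
        trim=int(m.get("trim", 0)),
        symmetrized=m.get("symmetrized", "True") == "True",
    )
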