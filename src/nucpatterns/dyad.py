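"""Nucleosome start detection from dyad symmetry of frequency profiles.

Nucleosomal DNA is pseudo-two-fold symmetric about its dyad: within the
core window, the forward frequency profile of a dinucleotide class mirrors
the profile of its reverse-complement class read backwards.  Sliding a
window of the nucleosome size (default 146 profile positions) along the
profiles and correlating the forward profile with the mirrored
complementary profile therefore yields a maximum positive Pearson
correlation at the common nucleosome start of an end-aligned batch.

The pairing used at candidate start ``s`` (1-based) is

    u[j] = P_code[s + j]                      j = 0 .. W-1
    v[j] = P_rc_class(code)[s + (W-1) - j]

so that exact dyad symmetry of the window makes ``CC(s) = 1``.  For
palindromic classes (AT, TA, CG, GC, WW, SS) this compares a window of a
profile against its own reversal.

Start inference cannot be fully automated — the best class differs between
organisms (AA/TT in mouse, AT/GC in human) — so :func:`infer_start` returns
a per-class diagnostic table alongside the argmax of the mean track.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dinuc import rc_class
from .profiles import FrequencyProfile, cleavage_site

__all__ = [
    "NUCLEOSOME_WINDOW",
    "CorrelationTrack",
    "fw_rc_correlation_track",
    "infer_start",
    "search_range_after_cleavage",
    "pearson",
]

#: Default dyad-symmetry window, in profile positions (nucleosome core size).
NUCLEOSOME_WINDOW = 146


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation; NaN when either argument has zero variance."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    du = u - u.mean()
    dv = v - v.mean()
    su = math.sqrt(du @ du)
    sv = math.sqrt(dv @ dv)
    if su == 0.0 or sv == 0.0:
        return float("nan")
    return float((du @ dv) / (su * sv))


@dataclass
class CorrelationTrack:
    """Forward/reverse-complement window correlation per candidate start.

    ``values[k]`` is the CC at 1-based candidate start ``k + 1``; NaN marks
    zero-variance windows.  Support is 1 <= s <= L_profile - W + 1.
    """

    values: np.ndarray
    class_code: str
    window: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, len(self.values) + 1)


def _sliding_pearson(a: np.ndarray, b: np.ndarray, W: int) -> np.ndarray:
    """CC between a[s:s+W] and reversed b[s:s+W] for every valid offset s.

    Vectorized two-pass computation over all windows; zero-variance
    windows yield NaN.
    """
    wa = np.lib.stride_tricks.sliding_window_view(a, W)
    wb = np.lib.stride_tricks.sliding_window_view(b, W)[:, ::-1]
    da = wa - wa.mean(axis=1, keepdims=True)
    db = wb - wb.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", da, db)
    sa = np.sqrt(np.einsum("ij,ij->i", da, da))
    sb = np.sqrt(np.einsum("ij,ij->i", db, db))
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = num / (sa * sb)
    cc[(sa == 0) | (sb == 0)] = np.nan
    return cc


def fw_rc_correlation_track(
    profiles: dict[str, FrequencyProfile],
    code: str,
    window: int = NUCLEOSOME_WINDOW,
) -> CorrelationTrack:
    """Track of Pearson CC between forward and mirrored-complement profiles.

    Parameters
    ----------
    profiles
        A profile set holding both ``code`` and its reverse-complement
        class (as produced by :func:`nucpatterns.profiles.profile_set`).
    code
        Dinucleotide class whose forward profile is correlated.
    window
        Dyad-symmetry window in profile positions (W >= 4).
    """
    code = code.upper()
    if window < 4:
        raise ValueError("window must be >= 4")
    fw = profiles[code].values
    rc = profiles[rc_class(code)].values
    if window > len(fw):
        raise ValueError(f"window {window} exceeds profile length {len(fw)}")
    return CorrelationTrack(_sliding_pearson(fw, rc, window), code, window)


def search_range_after_cleavage(
    profiles: dict[str, FrequencyProfile], window: int = NUCLEOSOME_WINDOW
) -> tuple[int, int]:
    """Default start-search interval: downstream of the cleavage-site peak.

    Returns 1-based (lo, hi) from one position past the global profile
    maximum to the last candidate start where the window still fits.
    """
    lo = cleavage_site(profiles) + 1
    hi = len(next(iter(profiles.values()))) - window + 1
    if lo > hi:
        raise ValueError("no candidate start downstream of the cleavage peak")
    return lo, hi


def infer_start(
    tracks: list[CorrelationTrack],
    search_range: tuple[int, int] | None = None,
) -> tuple[int, pd.DataFrame]:
    """Common nucleosome start of the batch from one or more CC tracks.

    Returns the 1-based argmax of the mean of the supplied tracks within
    ``search_range`` (ties broken toward the smaller position) together
    with a per-class diagnostic table (argmax and max per track) so a user
    can override the automatic choice.
    """
    if not tracks:
        raise ValueError("need at least one correlation track")
    stacked = np.vstack([t.values for t in tracks])
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_track = np.nanmean(stacked, axis=0)
    n = stacked.shape[1]
    lo, hi = search_range if search_range is not None else (1, n)
    if not (1 <= lo <= hi <= n):
        raise ValueError(f"search range ({lo}, {hi}) outside track support (1, {n})")
    segment = mean_track[lo - 1 : hi]
    if np.all(np.isnan(segment)):
        raise ValueError("all correlations missing in the search range")
    start = lo + int(np.nanargmax(segment))

    rows = []
    for t in tracks:
        seg = t.values[lo - 1 : hi]
        if np.all(np.isnan(seg)):
            rows.append({"class": t.class_code, "argmax": np.nan, "max_cc": np.nan})
        else:
            k = int(np.nanargmax(seg))
            rows.append({"class": t.class_code, "argmax": lo + k, "max_cc": float(seg[k])})
    return start, pd.DataFrame(rows)
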