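"""Dinucleotide-class algebra and binary occurrence encoding.

A *dinucleotide class* is either one of the 16 literal dinucleotides
(``AA`` ... ``TT``) or one of the four composite classes used in
nucleosome-positioning analysis:

``WW``
    weak-weak, W = A or T: {AA, AT, TA, TT}
``SS``
    strong-strong, S = C or G: {CC, CG, GC, GG}
``RR``
    purine-purine, R = A or G: {AA, AG, GA, GG}
``YY``
    pyrimidine-pyrimidine, Y = C or T: {CC, CT, TC, TT}

A sequence of length L is encoded, for a given class, as a binary vector of
length L-1 whose entry *i* (counting starts of dinucleotides) is 1 iff the
dinucleotide starting at base *i* belongs to the class.  These occurrence
vectors are the raw material for positional frequency profiles and for
pattern-based mapping.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "LITERAL_CLASSES",
    "COMPOSITE_CLASSES",
    "ALL_CLASSES",
    "class_members",
    "rc_class",
    "encode_occurrences",
    "occurrence_matrix",
    "dinucleotide_counts",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 16 literal dinucleotides, AA, AC, ..., TT.
LITERAL_CLASSES: tuple[str, ...] = tuple(
    a + b for a, b in product("ACGT", repeat=2)
)

#: Composite class membership.
COMPOSITE_CLASSES: dict[str, frozenset[str]] = {
    "WW": frozenset({"AA", "AT", "TA", "TT"}),
    "SS": frozenset({"CC", "CG", "GC", "GG"}),
    "RR": frozenset({"AA", "AG", "GA", "GG"}),
    "YY": frozenset({"CC", "CT", "TC", "TT"}),
}

ALL_CLASSES: tuple[str, ...] = LITERAL_CLASSES + tuple(COMPOSITE_CLASSES)


def class_members(code: str) -> frozenset[str]:
    """Set of literal dinucleotides belonging to class ``code``."""
    code = code.upper()
    if code in COMPOSITE_CLASSES:
        return COMPOSITE_CLASSES[code]
    if code in LITERAL_CLASSES:
        return frozenset({code})
    raise ValueError(f"unknown dinucleotide class: {code!r}")


def rc_class(code: str) -> str:
    """Reverse-complement class of ``code``.

    For a literal dinucleotide XY this is the Watson-Crick reverse
    complement (AA <-> TT, CA <-> TG, ...); the palindromes AT, TA, CG, GC
    map to themselves.  For composites, WW and SS are closed under reverse
    complement while RR and YY swap.
    """
    code = code.upper()
    if code in LITERAL_CLASSES:
        return _COMPLEMENT[code[1]] + _COMPLEMENT[code[0]]
    if code in ("WW", "SS"):
        return code
    if code == "RR":
        return "YY"
    if code == "YY":
        return "RR"
    raise ValueError(f"unknown dinucleotide class: {code!r}")


# base -> 0..3 lookup over ASCII codes; 255 flags anything outside ACGT
_BASE_LUT = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i

#: literal dinucleotide -> integer code 0..15 (4 * first + second)
_DINUC_INDEX = {d: 4 * "ACGT".index(d[0]) + "ACGT".index(d[1]) for d in LITERAL_CLASSES}


def _base_codes(seq: str) -> np.ndarray:
    codes = _BASE_LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = sorted(set(seq.upper()) - set("ACGT"))
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    return codes


def _dinuc_codes(seq: str) -> np.ndarray:
    """Integer code (0..15) of the dinucleotide starting at each position."""
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2 to contain a dinucleotide")
    c = _base_codes(seq)
    return (4 * c[:-1] + c[1:]).astype(np.uint8)


def encode_occurrences(seq: str, code: str) -> np.ndarray:
    """Binary occurrence vector of class ``code`` along ``seq``.

    Entry ``i`` (0-based) is 1 iff the dinucleotide ``seq[i:i+2]`` is a
    member of the class; the vector has length ``len(seq) - 1``.

    Parameters
    ----------
    seq
        DNA string over {A, C, G, T}, length >= 2.
    code
        Literal or composite dinucleotide class.
    """
    members = np.array(sorted(_DINUC_INDEX[m] for m in class_members(code)))
    return np.isin(_dinuc_codes(seq), members).astype(np.uint8)


def occurrence_matrix(seqs, code: str) -> np.ndarray:
    """Stack per-sequence occurrence vectors into an (n, L-1) binary matrix.

    All sequences must share one length.
    """
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    return np.vstack([encode_occurrences(s, code) for s in seqs])


def dinucleotide_counts(seq: str) -> np.ndarray:
    """Counts of all 16 literal dinucleotides along ``seq`` (AA, AC, ..., TT order)."""
    return np.bincount(_dinuc_codes(seq), minlength=16)
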