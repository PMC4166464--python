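"""Shared nucleotide state alphabet.

Valid states are the four bases, the IUPAC ambiguity codes (kept as
composite states), ``-`` for an alignment gap and ``?``/``N`` for missing
data.  ``U`` is folded into ``T`` on input and everything is stored
uppercase.

Internally every character maps to a 5-bit mask: bits 1-4 encode the set
of compatible bases, bit 5 marks a gap, and missing data maps to 0.  Two
resolved states *match* when their masks intersect, which makes
ambiguity-overlap comparisons (R vs A) and gap-as-fifth-state
comparisons (``-`` vs ``-`` match, ``-`` vs base mismatch) a single
bitwise AND.
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 1, 2, 4, 8
GAP_BIT = 16

IUPAC_MASKS: dict[str, int] = {
    "A": A, "C": C, "G": G, "T": T,
    "R": A | G, "Y": C | T, "S": C | G, "W": A | T,
    "K": G | T, "M": A | C,
    "B": C | G | T, "D": A | G | T, "H": A | C | T, "V": A | C | G,
}

CHAR_TO_MASK: dict[str, int] = dict(IUPAC_MASKS)
CHAR_TO_MASK["-"] = GAP_BIT
CHAR_TO_MASK["?"] = 0
CHAR_TO_MASK["N"] = 0

VALID_CHARS = frozenset(CHAR_TO_MASK)
AMBIGUITY_CHARS = frozenset("RYSWKMBDHV")
MISSING_CHARS = frozenset("?N")
GAP_CHAR = "-"
BASES = "ACGT"

_LUT = np.zeros(128, dtype=np.uint8)
for _ch, _m in CHAR_TO_MASK.items():
    _LUT[ord(_ch)] = _m


def normalize(seq: str) -> str:
    """Uppercase a raw sequence, fold U->T, and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    bad = sorted(set(s) - VALID_CHARS)
    if bad:
        raise ValueError(f"invalid sequence characters: {bad!r}")
    return s


def char_matrix(rows: list[str]) -> np.ndarray:
    """Stack equal-length sequence strings into an (n, L) '<U1' array."""
    return np.array([list(r) for r in rows], dtype="<U1")


def masks(chars: np.ndarray) -> np.ndarray:
    """Bit-mask encoding of a character array (any shape)."""
    codes = chars.astype("<U1").view(np.uint32).reshape(chars.shape)
    return _LUT[codes]
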