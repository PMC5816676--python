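"""Genotype integer codes shared across the package.

Genotypes are stored as ``int8``: parent-A homozygote 0, heterozygote 1,
parent-B homozygote 2, missing -1.  The additive numeric coding used in the
QTL regression (A = +1, H = 0, B = -1) is derived from these, never stored.
"""

from __future__ import annotations

import numpy as np

MISSING: int = -1
AA: int = 0
AB: int = 1
BB: int = 2

CODE_TO_CHAR = {AA: "A", AB: "H", BB: "B", MISSING: "-"}
CHAR_TO_CODE = {v: k for k, v in CODE_TO_CHAR.items()}

# lookup table indexed by code+1 -> additive dosage of the A allele (-1..+1)
_ADDITIVE = np.array([np.nan, 1.0, 0.0, -1.0])


def to_additive(codes: np.ndarray) -> np.ndarray:
    """Map genotype codes to the +1/0/-1 additive scale (missing -> NaN)."""
    codes = np.asarray(codes)
    if codes.size and (codes.min() < MISSING or codes.max() > BB):
        bad = codes[(codes < MISSING) | (codes > BB)][0]
        raise ValueError(f"invalid genotype code {bad}; valid codes are -1, 0, 1, 2")
    return _ADDITIVE[codes.astype(np.int64) + 1]


def to_chars(codes: np.ndarray) -> np.ndarray:
    """Genotype codes -> single-character labels A/H/B/-."""
    out = np.empty(np.shape(codes), dtype="U1")
    for code, char in CODE_TO_CHAR.items():
        out[np.asarray(codes) == code] = char
    return out


def from_chars(chars: np.ndarray) -> np.ndarray:
    """Single-character labels -> genotype codes; unknown labels raise."""
    arr = np.asarray(chars, dtype="U1")
    out = np.full(arr.shape, -9, dtype=np.int8)
    for char, code in CHAR_TO_CODE.items():
        out[arr == char] = code
    if (out == -9).any():
        bad = arr[out == -9]
        raise ValueError(
            f"unknown genotype code {bad.flat[0]!r}; valid codes are "
            + ", ".join(repr(c) for c in CHAR_TO_CODE)
        )
    return out
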