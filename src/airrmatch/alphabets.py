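"""Sequence alphabets.

Matching operates over a fixed alphabet: the 20 standard amino acids for
junction_aa input, or the 4 DNA nucleotides for junction input.  Ambiguity
codes, stop codons (``*``) and ``X`` are rejected on read so that the
variant-enumeration machinery works over a closed symbol set.
"""
from __future__ import annotations

import numpy as np

from .errors import ParameterError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

MODES = {
    "amino_acid": AMINO_ACIDS,
    "nucleotide": NUCLEOTIDES,
}

#: marker for "symbol not in alphabet" in the 256-entry encode tables
INVALID = np.uint8(255)

_LOOKUPS: dict[str, np.ndarray] = {}
_INDEXES: dict[str, dict[str, int]] = {}


def alphabet_for(mode: str) -> str:
    """Return the symbol string for an alphabet mode."""
    try:
        return MODES[mode]
    except KeyError:
        raise ParameterError(
            f"unknown alphabet mode {mode!r}; expected one of {sorted(MODES)}"
        ) from None


def symbol_set(mode: str) -> frozenset[str]:
    return frozenset(alphabet_for(mode))


def symbol_index(mode: str) -> dict[str, int]:
    """Symbol -> integer code, cached per mode."""
    if mode not in _INDEXES:
        _INDEXES[mode] = {c: i for i, c in enumerate(alphabet_for(mode))}
    return _INDEXES[mode]


def encode_lookup(mode: str) -> np.ndarray:
    """256-entry uint8 table mapping ASCII byte -> symbol code (255 = invalid)."""
    if mode not in _LOOKUPS:
        table = np.full(256, INVALID, dtype=np.uint8)
        for i, c in enumerate(alphabet_for(mode)):
            table[ord(c)] = i
        _LOOKUPS[mode] = table
    return _LOOKUPS[mode]
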