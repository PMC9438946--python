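"""Zobrist (tabulation) hashing of sequences and variant-hash enumeration.

A sequence hashes to the XOR over positions ``i`` of a fixed random 64-bit
value ``T[i, symbol]``.  Because XOR is its own inverse, the hash of any
single-symbol edit is two XORs away from the original hash, which makes it
cheap to enumerate the hashes of *all* strings within 1-2 substitutions or
one insertion/deletion of a query without materialising the strings
themselves.  Indels are handled with prefix/suffix XOR accumulators over
the shifted positions, so each indel variant costs O(1) after an O(L)
precomputation.

Two equivalent enumeration paths are provided:

* :func:`enumerate_variants` — a generator yielding ``(hash, descriptor)``
  pairs, where the descriptor can reconstruct the variant string (used for
  verification and property testing);
* :func:`variant_hash_array` — a vectorised NumPy twin returning just the
  hash values, used on the hot matching path.  It may emit duplicate hashes
  (e.g. the identity hash reappears where a "substitution" re-inserts the
  original symbol); downstream verification dedupes, so only the *set* of
  hashes matters.

Indels are supported only at d = 1; d = 2 enumerates substitution pairs.
Larger d is served by the all-versus-all engine in ``index_match``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .alphabets import INVALID, alphabet_for, encode_lookup, symbol_index
from .errors import ParameterError

#: default seed for the Zobrist table; fixed so runs are reproducible by
#: default and overridable from the CLI.
DEFAULT_TABLE_SEED = 20177


class ZobristTable:
    """Per-(position, symbol) random 64-bit values for tabulation hashing.

    The table is drawn from a seeded PCG64 stream row by row (position
    major), so extending the capacity with :meth:`ensure_capacity` re-draws
    a longer prefix of the *same* stream and leaves all existing entries —
    and therefore all previously computed hashes — unchanged.
    """

    def __init__(
        self,
        alphabet_mode: str = "amino_acid",
        capacity: int = 64,
        seed: int = DEFAULT_TABLE_SEED,
    ):
        self.alphabet_mode = alphabet_mode
        self.alphabet = alphabet_for(alphabet_mode)
        self.seed = int(seed)
        self.capacity = max(int(capacity), 1)
        self._sym_index = symbol_index(alphabet_mode)
        self._lookup = encode_lookup(alphabet_mode)
        self.values = self._draw(self.capacity)
        self._int_rows: list[list[int]] | None = None

    def _draw(self, capacity: int) -> np.ndarray:
        rng = np.random.Generator(np.random.PCG64(self.seed))
        return rng.integers(
            0, 2**64, size=(capacity, len(self.alphabet)), dtype=np.uint64
        )

    def ensure_capacity(self, n: int) -> None:
        """Grow the table so positions 0..n-1 exist; earlier rows unchanged."""
        if n > self.capacity:
            self.capacity = max(n, 2 * self.capacity)
            self.values = self._draw(self.capacity)
            self._int_rows = None

    @property
    def int_rows(self) -> list[list[int]]:
        """Table values as plain Python ints, for scalar hot loops."""
        if self._int_rows is None:
            self._int_rows = self.values.tolist()
        return self._int_rows

    def encode(self, seq: str) -> np.ndarray:
        """Sequence -> uint8 symbol codes; raises on out-of-alphabet symbols."""
        try:
            raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        except UnicodeEncodeError:
            raise ParameterError(
                f"sequence contains non-ASCII symbols: {seq!r}"
            ) from None
        codes = self._lookup[raw]
        if (codes == INVALID).any():
            bad = seq[int(np.argmax(codes == INVALID))]
            raise ParameterError(
                f"symbol {bad!r} not in the {self.alphabet_mode} alphabet"
            )
        return codes

    def hash(self, seq: str) -> int:
        """Scalar Zobrist hash; the empty sequence hashes to 0."""
        self.ensure_capacity(len(seq))
        rows = self.int_rows
        idx = self._sym_index
        h = 0
        try:
            for i, c in enumerate(seq):
                h ^= rows[i][idx[c]]
        except KeyError:
            raise ParameterError(
                f"symbol {c!r} not in the {self.alphabet_mode} alphabet"
            ) from None
        return h


def hash_sequence(table: ZobristTable, seq: str) -> int:
    """XOR over positions i of table[(i, seq[i])]; '' hashes to 0."""
    return table.hash(seq)


def substitute_hash(table: ZobristTable, h: int, pos: int, old: str, new: str) -> int:
    """Incrementally update h for the substitution old -> new at pos.

    Requires that h is the hash of a sequence whose symbol at ``pos`` is
    ``old`` (caller's contract).  ``new == old`` returns h unchanged.
    """
    table.ensure_capacity(pos + 1)
    row = table.int_rows[pos]
    idx = table._sym_index
    return h ^ row[idx[old]] ^ row[idx[new]]


def bulk_hashes(table: ZobristTable, seqs: list[str]) -> np.ndarray:
    """Vectorised hashes of many non-empty sequences (uint64 array)."""
    if not seqs:
        return np.empty(0, dtype=np.uint64)
    joined = "".join(seqs)
    codes = table._lookup[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    if (codes == INVALID).any():
        raise ParameterError("sequence contains out-of-alphabet symbols")
    lengths = np.fromiter(map(len, seqs), dtype=np.int64, count=len(seqs))
    if (lengths == 0).any():
        raise ParameterError("bulk hashing requires non-empty sequences")
    table.ensure_capacity(int(lengths.max()))
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    pos = np.arange(offsets[-1], dtype=np.int64) - np.repeat(offsets[:-1], lengths)
    vals = table.values[pos, codes]
    return np.bitwise_xor.reduceat(vals, offsets[:-1])


@dataclass(frozen=True, slots=True)
class VariantDescriptor:
    """Recipe for one variant of a query sequence.

    ``kind`` is one of identity / substitution / deletion / insertion /
    double_substitution; ``pos`` holds the affected position(s) and ``new``
    the replacement/inserted symbol(s).
    """

    kind: str
    pos: tuple[int, ...] = ()
    new: tuple[str, ...] = ()

    def apply(self, seq: str) -> str:
        """Reconstruct the variant string from the query sequence."""
        if self.kind == "identity":
            return seq
        if self.kind == "substitution":
            p = self.pos[0]
            return seq[:p] + self.new[0] + seq[p + 1 :]
        if self.kind == "deletion":
            p = self.pos[0]
            return seq[:p] + seq[p + 1 :]
        if self.kind == "insertion":
            p = self.pos[0]
            return seq[:p] + self.new[0] + seq[p:]
        if self.kind == "double_substitution":
            p, q = self.pos
            a, b = self.new
            return seq[:p] + a + seq[p + 1 : q] + b + seq[q + 1 :]
        raise ParameterError(f"unknown variant kind {self.kind!r}")


def enumerate_variants(
    table: ZobristTable, seq: str, d: int, allow_indels: bool = False
) -> Iterator[tuple[int, VariantDescriptor]]:
    """Yield (hash, descriptor) for every variant of ``seq`` within distance d.

    Emission order is fixed for reproducibility: identity, substitutions by
    (position, symbol), then (indel mode) deletions by position and
    insertions by (position, symbol), then (d = 2) substitution pairs by
    lexicographic position pairs.  Completeness: every string at Hamming
    distance <= d (or Levenshtein distance <= 1 with indels) from ``seq``
    has its hash emitted at least once.
    """
    if d not in (1, 2):
        raise ParameterError(
            f"variant enumeration supports d in {{1, 2}}, got {d}; "
            "use the all-versus-all engine for larger d"
        )
    if allow_indels and d != 1:
        raise ParameterError("indels are only supported with d = 1")
    L = len(seq)
    if L < 1:
        raise ParameterError("cannot enumerate variants of an empty sequence")
    table.ensure_capacity(L + 1)
    rows = table.int_rows
    alphabet = table.alphabet
    idx = table._sym_index
    codes = [idx[c] for c in seq]

    h0 = 0
    for i in range(L):
        h0 ^= rows[i][codes[i]]
    yield h0, VariantDescriptor("identity")

    for p in range(L):
        row = rows[p]
        base = h0 ^ row[codes[p]]
        for a, sym in enumerate(alphabet):
            if a == codes[p]:
                continue
            yield base ^ row[a], VariantDescriptor("substitution", (p,), (sym,))

    if allow_indels:
        # pre[p] = hash of seq[:p]; sdel[j] = XOR of rows[i-1][codes[i]] for
        # i >= j (suffix re-indexed one position left after a deletion);
        # sins[j] = XOR of rows[i+1][codes[i]] for i >= j (one right).
        pre = [0] * (L + 1)
        for i in range(L):
            pre[i + 1] = pre[i] ^ rows[i][codes[i]]
        sdel = [0] * (L + 1)
        for j in range(L - 1, 0, -1):
            sdel[j] = sdel[j + 1] ^ rows[j - 1][codes[j]]
        for p in range(L):
            yield pre[p] ^ sdel[p + 1], VariantDescriptor("deletion", (p,))
        sins = [0] * (L + 1)
        for j in range(L - 1, -1, -1):
            sins[j] = sins[j + 1] ^ rows[j + 1][codes[j]]
        for p in range(L + 1):
            row = rows[p]
            base = pre[p] ^ sins[p]
            for a, sym in enumerate(alphabet):
                yield base ^ row[a], VariantDescriptor("insertion", (p,), (sym,))

    if d == 2:
        for p in range(L):
            rowp = rows[p]
            basep = h0 ^ rowp[codes[p]]
            for q in range(p + 1, L):
                rowq = rows[q]
                base = basep ^ rowq[codes[q]]
                for a, syma in enumerate(alphabet):
                    if a == codes[p]:
                        continue
                    ba = base ^ rowp[a]
                    for b, symb in enumerate(alphabet):
                        if b == codes[q]:
                            continue
                        yield ba ^ rowq[b], VariantDescriptor(
                            "double_substitution", (p, q), (syma, symb)
                        )


def variant_hash_array(
    table: ZobristTable, seq: str, d: int, allow_indels: bool = False
) -> np.ndarray:
    """Vectorised variant hashes (uint64, duplicates permitted).

    Covers the same neighbourhood as :func:`enumerate_variants` plus the
    identity; ``d = 0`` returns just the query's own hash.  The set of
    distinct values equals the hash image of all strings within the
    configured distance.
    """
    if d not in (0, 1, 2):
        raise ParameterError(f"d must be in {{0, 1, 2}}, got {d}")
    if allow_indels and d != 1:
        raise ParameterError("indels are only supported with d = 1")
    L = len(seq)
    if L < 1:
        raise ParameterError("cannot enumerate variants of an empty sequence")
    table.ensure_capacity(L + 1)
    codes = table.encode(seq)
    T = table.values
    positions = np.arange(L)
    vals = T[positions, codes]
    h0 = np.bitwise_xor.reduce(vals)
    parts = [np.array([h0], dtype=np.uint64)]
    if d >= 1:
        delta = vals[:, None] ^ T[:L, :]  # (L, A); zero column at own symbol
        parts.append((h0 ^ delta).ravel())
    if allow_indels:
        pre = np.zeros(L + 1, dtype=np.uint64)
        pre[1:] = np.bitwise_xor.accumulate(vals)
        # deletions: pre[p] ^ XOR_{i>p} T[i-1, codes[i]]
        sdel = np.zeros(L + 1, dtype=np.uint64)
        if L > 1:
            w = T[np.arange(L - 1), codes[1:]]
            sdel[1:L] = np.bitwise_xor.accumulate(w[::-1])[::-1]
        parts.append(pre[:L] ^ sdel[1:])
        # insertions at p of symbol a: pre[p] ^ T[p, a] ^ XOR_{i>=p} T[i+1, codes[i]]
        u = T[np.arange(1, L + 1), codes]
        sins = np.zeros(L + 1, dtype=np.uint64)
        sins[:L] = np.bitwise_xor.accumulate(u[::-1])[::-1]
        parts.append(((pre ^ sins)[:, None] ^ T[: L + 1, :]).ravel())
    if d == 2 and L >= 2:
        delta = vals[:, None] ^ T[:L, :]
        ii, jj = np.triu_indices(L, k=1)
        dbl = h0 ^ (delta[ii][:, :, None] ^ delta[jj][:, None, :])
        parts.append(dbl.ravel())
    return np.concatenate(parts)
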