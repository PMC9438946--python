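"""Bloom-filter-screened hash index and exact/approximate sequence matching.

Target sequences are indexed once under their Zobrist hash; each query then
enumerates the hashes of every sequence within the configured distance and
probes the index.  A Bloom filter sits in front of the hash table purely to
skip lookups that cannot hit — it never affects results, because every
bucket hit is *verified* by computing the actual Hamming (or, with indels,
Levenshtein) distance between the two sequences.  Hash equality is never
trusted as sequence equality, so hash collisions cannot create false
positives, and enumeration completeness guarantees no false negatives.

For distances beyond the variant-enumeration range (d >= 3, substitutions
only) a simple all-versus-all engine compares every query against every
equal-length target.
"""
from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .airr_io import RepertoireSet, SequenceRecord
from .errors import OptionError, ParameterError
from .hashing import (
    DEFAULT_TABLE_SEED,
    ZobristTable,
    bulk_hashes,
    variant_hash_array,
)


class MatchPair(NamedTuple):
    """A verified (query, target) match with its sequence distance."""

    query_rep: int
    query_rec: int
    target_rep: int
    target_rec: int
    n_diff: int


@dataclass(frozen=True)
class MatchOptions:
    """Matching configuration shared by all engines."""

    d: int = 0
    allow_indels: bool = False
    use_genes: bool = True
    use_bloom: bool = True
    hash_seed: int = DEFAULT_TABLE_SEED

    def __post_init__(self):
        if self.d < 0:
            raise OptionError(f"d must be >= 0, got {self.d}")
        if self.allow_indels and self.d != 1:
            raise OptionError("indels are only supported with d = 1")


class BloomFilter:
    """Bit-array prefilter over 64-bit hashes; no false negatives.

    Sized to the smallest power of two >= 16 x (expected items), with two
    probe positions taken from the high and low 32 bits of the hash.  The
    bit array is stored one byte per bit (NumPy bool) — memory is traded
    for simple vectorised probing.
    """

    def __init__(self, n_items: int):
        m = 1 << max(6, (16 * max(n_items, 1) - 1).bit_length())
        self.m = m
        self._mask = m - 1
        self.bits = np.zeros(m, dtype=bool)

    def insert(self, h: int) -> None:
        self.bits[(h >> 32) & self._mask] = True
        self.bits[h & self._mask] = True

    def insert_many(self, hashes: np.ndarray) -> None:
        mask = np.uint64(self._mask)
        self.bits[(hashes >> np.uint64(32)) & mask] = True
        self.bits[hashes & mask] = True

    def contains(self, h: int) -> bool:
        return bool(
            self.bits[(h >> 32) & self._mask] and self.bits[h & self._mask]
        )

    def contains_many(self, hashes: np.ndarray) -> np.ndarray:
        mask = np.uint64(self._mask)
        return self.bits[(hashes >> np.uint64(32)) & mask] & self.bits[hashes & mask]


class HashIndex:
    """Map from 64-bit hash to the list of (repertoire, record) positions."""

    def __init__(self):
        self.buckets: dict[int, list[tuple[int, int]]] = {}

    def add(self, h: int, pos: tuple[int, int]) -> None:
        self.buckets.setdefault(h, []).append(pos)

    def get(self, h: int):
        return self.buckets.get(h, ())

    def __len__(self) -> int:
        return len(self.buckets)


@dataclass
class MatchIndex:
    """Bundle of Bloom filter + hash index over one target set."""

    targets: RepertoireSet
    table: ZobristTable
    bloom: BloomFilter = field(init=False)
    hash_index: HashIndex = field(init=False)

    def __post_init__(self):
        positions = []
        seqs = []
        for ri, si, rec in self.targets.iter_records():
            positions.append((ri, si))
            seqs.append(rec.seq)
        self.bloom = BloomFilter(len(positions))
        self.hash_index = HashIndex()
        if positions:
            hashes = bulk_hashes(self.table, seqs)
            self.bloom.insert_many(hashes)
            add = self.hash_index.add
            for h, pos in zip(hashes.tolist(), positions):
                add(h, pos)


def build_index(targets: RepertoireSet, table: ZobristTable) -> MatchIndex:
    """Index every (assumed deduplicated) target record under its hash."""
    table.ensure_capacity(targets.max_length() + 1)
    return MatchIndex(targets, table)


def verify(a: str, b: str, d: int, allow_indels: bool = False):
    """Distance test between two sequences: (matched, n_diff).

    Substitutions-only: equal lengths and Hamming distance <= d.
    Indels (d = 1): Levenshtein distance <= 1.  Returns ``(False, None)``
    when the sequences do not match.
    """
    if not allow_indels:
        if len(a) != len(b):
            return False, None
        diff = 0
        for x, y in zip(a, b):
            if x != y:
                diff += 1
                if diff > d:
                    return False, None
        return True, diff
    la, lb = len(a), len(b)
    if la == lb:
        diff = 0
        for x, y in zip(a, b):
            if x != y:
                diff += 1
                if diff > 1:
                    return False, None
        return True, diff
    if abs(la - lb) != 1:
        return False, None
    if la < lb:
        a, b = b, a
        la, lb = lb, la
    # a is one longer: match iff deleting one symbol of a yields b
    i = 0
    while i < lb and a[i] == b[i]:
        i += 1
    return (True, 1) if a[i + 1 :] == b[i:] else (False, None)


def _genes_compatible(q: SequenceRecord, t: SequenceRecord) -> bool:
    """Exact string equality of both calls; a missing call on either side fails."""
    return (
        q.v_call is not None
        and q.j_call is not None
        and q.v_call == t.v_call
        and q.j_call == t.j_call
    )


def _collect_bucket_matches(
    seq, query, qpos, cand_hashes, index, d, allow_indels, use_genes
):
    best: dict[tuple[int, int], int] = {}
    reps = index.targets.repertoires
    get = index.hash_index.get
    for h in cand_hashes:
        for tpos in get(h):
            prev = best.get(tpos)
            trec = reps[tpos[0]].records[tpos[1]]
            ok, nd = verify(seq, trec.seq, d, allow_indels)
            if not ok:
                continue
            if use_genes and not _genes_compatible(query, trec):
                continue
            if prev is None or nd < prev:
                best[tpos] = nd
    return [
        MatchPair(qpos[0], qpos[1], t[0], t[1], nd)
        for t, nd in sorted(best.items())
    ]


def find_matches(
    query: SequenceRecord,
    query_pos: tuple[int, int],
    index: MatchIndex,
    d: int,
    allow_indels: bool = False,
    use_genes: bool = True,
    use_bloom: bool = True,
) -> list[MatchPair]:
    """All verified matches of one query against the indexed targets.

    Each (query, target) pair appears at most once, with the minimal
    verified distance; results are sorted by target position.
    """
    if d not in (0, 1, 2):
        raise ParameterError(
            f"indexed matching supports d in {{0, 1, 2}}, got {d}"
        )
    seq = query.seq
    table = index.table
    if d == 0:
        h = table.hash(seq)
        cands = [h] if (not use_bloom or index.bloom.contains(h)) else []
    else:
        arr = variant_hash_array(table, seq, d, allow_indels)
        if use_bloom:
            arr = arr[index.bloom.contains_many(arr)]
        cands = np.unique(arr).tolist()
    return _collect_bucket_matches(
        seq, query, query_pos, cands, index, d, allow_indels, use_genes
    )


def all_vs_all_matches(
    queries: RepertoireSet,
    targets: RepertoireSet,
    d: int,
    use_genes: bool = True,
    allow_indels: bool = False,
) -> list[MatchPair]:
    """Hamming matching by direct comparison of every equal-length pair.

    Serves arbitrary substitution counts (the fallback for d >= 3); indels
    are not supported on this path.
    """
    if allow_indels:
        raise OptionError("the all-versus-all engine does not support indels")
    if d < 0:
        raise ParameterError(f"d must be >= 0, got {d}")
    # group targets by length into byte matrices for vectorised comparison
    grouped: dict[int, list[tuple[int, int, SequenceRecord]]] = {}
    for ri, si, rec in targets.iter_records():
        grouped.setdefault(len(rec.seq), []).append((ri, si, rec))
    mats = {}
    for L, items in grouped.items():
        mat = np.frombuffer(
            "".join(rec.seq for _, _, rec in items).encode("ascii"), dtype=np.uint8
        ).reshape(len(items), L)
        mats[L] = (items, mat)

    out: list[MatchPair] = []
    for ri, si, rec in queries.iter_records():
        entry = mats.get(len(rec.seq))
        if entry is None:
            continue
        items, mat = entry
        q = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8)
        diffs = (mat != q).sum(axis=1)
        for k in np.nonzero(diffs <= d)[0]:
            tri, tsi, trec = items[k]
            if use_genes and not _genes_compatible(rec, trec):
                continue
            out.append(MatchPair(ri, si, tri, tsi, int(diffs[k])))
    return out


def _match_chunk(chunk, index, options: MatchOptions) -> list[MatchPair]:
    out: list[MatchPair] = []
    if options.d == 0:
        # hot path: bulk-hash the whole chunk, probe with scalar lookups
        hashes = bulk_hashes(index.table, [rec.seq for _, _, rec in chunk]).tolist()
        bloom = index.bloom
        for (ri, si, rec), h in zip(chunk, hashes):
            if options.use_bloom and not bloom.contains(h):
                continue
            out.extend(
                _collect_bucket_matches(
                    rec.seq, rec, (ri, si), (h,), index, 0, False, options.use_genes
                )
            )
    else:
        for ri, si, rec in chunk:
            out.extend(
                find_matches(
                    rec,
                    (ri, si),
                    index,
                    options.d,
                    options.allow_indels,
                    options.use_genes,
                    options.use_bloom,
                )
            )
    return out


def match_all(
    queries: RepertoireSet,
    targets: RepertoireSet,
    options: MatchOptions = MatchOptions(),
    n_workers: int = 1,
    table: ZobristTable | None = None,
) -> list[MatchPair]:
    """All verified matches between two repertoire sets.

    Pairs come out in canonical order — sorted by (query repertoire, query
    record, target repertoire, target record) — and the result is
    identical for every ``n_workers >= 1``: queries are split into
    contiguous chunks whose results are concatenated in order.
    """
    if queries.alphabet_mode != targets.alphabet_mode:
        raise OptionError("query and target sets use different alphabets")
    if n_workers < 1:
        raise ParameterError("n_workers must be >= 1")
    if options.d >= 3:
        return all_vs_all_matches(queries, targets, options.d, options.use_genes)
    if table is None:
        table = ZobristTable(
            queries.alphabet_mode,
            capacity=max(queries.max_length(), targets.max_length()) + 1,
            seed=options.hash_seed,
        )
    index = build_index(targets, table)
    items = list(queries.iter_records())
    if not items:
        return []
    if n_workers == 1:
        return _match_chunk(items, index, options)
    bounds = np.linspace(0, len(items), n_workers + 1).astype(int)
    chunks = [items[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
    with ThreadPoolExecutor(max_workers=n_workers) as pool:
        results = list(pool.map(lambda c: _match_chunk(c, index, options), chunks))
    out: list[MatchPair] = []
    for r in results:
        out.extend(r)
    return out
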