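"""Independent brute-force oracles used across the test suite.

Everything here is deliberately implemented without touching the package's
hashing/index machinery: neighbourhoods are enumerated as literal strings,
distances come from direct position comparison (Hamming) or the edlib
C library (Levenshtein), and connected components come from
scipy.sparse.csgraph.
"""
from __future__ import annotations

import itertools

import edlib
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


def hamming(a: str, b: str) -> int | None:
    if len(a) != len(b):
        return None
    return sum(x != y for x, y in zip(a, b))


def levenshtein(a: str, b: str) -> int:
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def brute_neighbors(seq: str, d: int, allow_indels: bool, alphabet: str) -> set[str]:
    """All strings within the configured distance of seq, including seq."""
    out = {seq}
    subs = set()
    for p in range(len(seq)):
        for c in alphabet:
            if c != seq[p]:
                subs.add(seq[:p] + c + seq[p + 1 :])
    out |= subs
    if d >= 2:
        for s in subs:
            for p in range(len(s)):
                for c in alphabet:
                    if c != s[p]:
                        out.add(s[:p] + c + s[p + 1 :])
    if allow_indels:
        for p in range(len(seq)):
            out.add(seq[:p] + seq[p + 1 :])
        for p in range(len(seq) + 1):
            for c in alphabet:
                out.add(seq[:p] + c + seq[p:])
    return out


def _distance(a: str, b: str, d: int, allow_indels: bool) -> int | None:
    """Verified distance if the pair matches under the mode, else None."""
    if allow_indels:
        dist = levenshtein(a, b)
        return dist if dist <= 1 else None
    h = hamming(a, b)
    return h if h is not None and h <= d else None


def _genes_ok(q, t, use_genes: bool) -> bool:
    if not use_genes:
        return True
    return (
        q.v_call is not None
        and q.j_call is not None
        and q.v_call == t.v_call
        and q.j_call == t.j_call
    )


def brute_match_pairs(qset, tset, d: int, allow_indels: bool, use_genes: bool):
    """O(N^2) oracle match set: {(qrep, qrec, trep, trec, n_diff)}.

    Hamming comparisons are vectorised per equal-length group; Levenshtein
    pairs (length difference exactly 1) go through edlib.
    """
    q_items = list(qset.iter_records())
    t_items = list(tset.iter_records())
    t_by_len: dict[int, list] = {}
    for ri, si, rec in t_items:
        t_by_len.setdefault(len(rec.seq), []).append((ri, si, rec))
    mats = {
        L: np.frombuffer(
            "".join(r.seq for _, _, r in items).encode(), dtype=np.uint8
        ).reshape(len(items), L)
        for L, items in t_by_len.items()
    }
    out = set()
    for ri, si, rec in q_items:
        L = len(rec.seq)
        if L in t_by_len:
            q = np.frombuffer(rec.seq.encode(), dtype=np.uint8)
            diffs = (mats[L] != q).sum(axis=1)
            limit = 1 if allow_indels else d
            for k in np.nonzero(diffs <= limit)[0]:
                tri, tsi, trec = t_by_len[L][k]
                if _genes_ok(rec, trec, use_genes):
                    out.add((ri, si, tri, tsi, int(diffs[k])))
        if allow_indels:
            for dL in (L - 1, L + 1):
                for tri, tsi, trec in t_by_len.get(dL, ()):
                    if levenshtein(rec.seq, trec.seq) <= 1 and _genes_ok(
                        rec, trec, use_genes
                    ):
                        out.add((ri, si, tri, tsi, 1))
    return out


def pairs_as_set(pairs):
    return {tuple(p) for p in pairs}


def brute_partition(rep, d: int, allow_indels: bool, use_genes: bool):
    """Connected components of the distance-<=d graph, as a set of frozensets."""
    n = len(rep.records)
    rows, cols = [], []
    for i, j in itertools.combinations(range(n), 2):
        a, b = rep.records[i], rep.records[j]
        if _distance(a.seq, b.seq, d, allow_indels) is None:
            continue
        if not _genes_ok(a, b, use_genes):
            continue
        rows.append(i)
        cols.append(j)
    adj = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, set[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def partition_from_labels(labels):
    groups: dict[int, set[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return {frozenset(g) for g in groups.values()}
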