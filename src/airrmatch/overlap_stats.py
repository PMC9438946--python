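"""Aggregation of verified match pairs into the output products.

Three products are supported:

* an n x n repertoire overlap matrix whose cell (s, t) is the sum over all
  matched sequence pairs (x in s, y in t) of a summary statistic of the two
  duplicate counts — product, min, max, mean or ratio (row/query count in
  the numerator);
* Morisita-Horn or Jaccard similarity matrices, defined for exact matching
  only (their behaviour under approximate matching is deliberately left
  undefined rather than invented);
* an n x m presence table marking (or count-summing) matches of each of m
  reference sequences in each of n query repertoires.

Counts default to raw post-deduplication duplicate counts; ``relative=True``
converts them to within-repertoire frequencies before aggregation, and
``ignore_counts=True`` replaces every count by 1 (so the product matrix
cell becomes the number of matching pairs).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .airr_io import Repertoire, RepertoireSet
from .errors import OptionError, ParameterError
from .index_match import MatchPair

PAIR_STATISTICS = ("product", "min", "max", "mean", "ratio")
SIMILARITY_STATISTICS = ("MH", "Jaccard")


@dataclass
class OverlapMatrix:
    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    statistic: str
    d: int = 0
    allow_indels: bool = False


@dataclass
class PresenceTable:
    repertoire_ids: list[str]
    reference_ids: list[str]
    values: np.ndarray


def _count_vectors(rset: RepertoireSet, ignore_counts: bool, relative: bool):
    out = []
    for rep in rset.repertoires:
        if ignore_counts:
            out.append([1.0] * len(rep.records))
        elif relative:
            total = float(rep.total_count)
            out.append([rec.count / total for rec in rep.records])
        else:
            out.append([float(rec.count) for rec in rep.records])
    return out


def pairwise_matrix(
    query_set: RepertoireSet,
    pairs: Iterable[MatchPair],
    statistic: str = "product",
    ignore_counts: bool = False,
    relative: bool = False,
    target_set: RepertoireSet | None = None,
    d: int = 0,
    allow_indels: bool = False,
) -> OverlapMatrix:
    """Aggregate deduplicated match pairs into the overlap matrix.

    ``pairs`` must each appear once per (query, target) sequence pair;
    the matrix rows are the query repertoires and the columns the target
    repertoires (the same set when ``target_set`` is omitted).
    """
    if statistic not in PAIR_STATISTICS:
        raise OptionError(
            f"statistic must be one of {PAIR_STATISTICS}, got {statistic!r}"
        )
    tset = target_set if target_set is not None else query_set
    qc = _count_vectors(query_set, ignore_counts, relative)
    tc = qc if tset is query_set else _count_vectors(tset, ignore_counts, relative)
    nq, nt = len(query_set), len(tset)
    rows = [[0.0] * nt for _ in range(nq)]
    stat = statistic
    for qr, qs, tr, ts, _ in pairs:
        cx = qc[qr][qs]
        cy = tc[tr][ts]
        if stat == "product":
            g = cx * cy
        elif stat == "min":
            g = cx if cx < cy else cy
        elif stat == "max":
            g = cx if cx > cy else cy
        elif stat == "mean":
            g = (cx + cy) / 2.0
        else:  # ratio, query side in the numerator
            g = cx / cy
        rows[qr][tr] += g
    return OverlapMatrix(
        query_set.ids, tset.ids, np.array(rows, dtype=float), stat, d, allow_indels
    )


def _count_map(rep: Repertoire, use_genes: bool) -> dict:
    out: dict = {}
    for rec in rep.records:
        key = (rec.seq, rec.v_call, rec.j_call) if use_genes else rec.seq
        out[key] = out.get(key, 0) + rec.count
    return out


def morisita_horn(a: Repertoire, b: Repertoire, use_genes: bool = True) -> float:
    """Morisita-Horn similarity of two repertoires' count distributions.

    With x_i, y_i the counts of unique receptor i in a and b, X = sum x_i,
    Y = sum y_i:

        C_H = 2 * sum(x_i y_i) / ((sum(x_i^2)/X^2 + sum(y_i^2)/Y^2) * X * Y)

    Defined under exact matching only; 1 for identical distributions, 0 for
    disjoint repertoires.
    """
    if not a.records or not b.records:
        raise ParameterError("Morisita-Horn is undefined for an empty repertoire")
    xa = _count_map(a, use_genes)
    xb = _count_map(b, use_genes)
    X = sum(xa.values())
    Y = sum(xb.values())
    sxy = sum(x * xb[k] for k, x in xa.items() if k in xb)
    sx2 = sum(x * x for x in xa.values())
    sy2 = sum(y * y for y in xb.values())
    return 2.0 * sxy / ((sx2 / X**2 + sy2 / Y**2) * X * Y)


def jaccard(a: Repertoire, b: Repertoire, use_genes: bool = True) -> float:
    """Jaccard index |A ∩ B| / |A ∪ B| over unique receptor keys (counts ignored)."""
    if not a.records and not b.records:
        raise ParameterError("Jaccard is undefined for two empty repertoires")
    ka = set(_count_map(a, use_genes))
    kb = set(_count_map(b, use_genes))
    return len(ka & kb) / len(ka | kb)


def similarity_matrix(
    set_a: RepertoireSet,
    set_b: RepertoireSet | None = None,
    statistic: str = "MH",
    use_genes: bool = True,
    d: int = 0,
) -> OverlapMatrix:
    """Pairwise Morisita-Horn or Jaccard matrix between repertoire sets."""
    if statistic not in SIMILARITY_STATISTICS:
        raise OptionError(
            f"statistic must be one of {SIMILARITY_STATISTICS}, got {statistic!r}"
        )
    if d != 0:
        raise OptionError(f"{statistic} is only defined for exact matching (d = 0)")
    sb = set_b if set_b is not None else set_a
    fn = morisita_horn if statistic == "MH" else jaccard
    vals = np.zeros((len(set_a), len(sb)))
    symmetric = sb is set_a
    for i, ra in enumerate(set_a.repertoires):
        for j, rb in enumerate(sb.repertoires):
            if symmetric and j < i:
                vals[i, j] = vals[j, i]
            else:
                vals[i, j] = fn(ra, rb, use_genes)
    return OverlapMatrix(set_a.ids, sb.ids, vals, statistic, 0, False)


def existence_table(
    queries: RepertoireSet,
    reference: Repertoire,
    pairs: Iterable[MatchPair],
    ignore_counts: bool = False,
) -> PresenceTable:
    """n x m presence table of reference receptors across query repertoires.

    ``pairs`` must have been computed with ``reference`` (wrapped as a
    single-repertoire target set) as the target; the target record index is
    the reference column.  Cells sum the matching query records' duplicate
    counts, or hold 1/0 presence flags with ``ignore_counts``.
    """
    m = len(reference.records)
    rows = [[0.0] * m for _ in range(len(queries))]
    if ignore_counts:
        for qr, _, _, ts, _ in pairs:
            rows[qr][ts] = 1.0
    else:
        qc = _count_vectors(queries, False, False)
        for qr, qs, _, ts, _ in pairs:
            rows[qr][ts] += qc[qr][qs]
    return PresenceTable(
        queries.ids,
        [rec.sequence_id for rec in reference.records],
        np.array(rows, dtype=float),
    )
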