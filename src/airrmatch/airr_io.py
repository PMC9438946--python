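"""AIRR Rearrangement TSV input/output and synthetic repertoire generation.

The input dialect is a tab-separated file with a header row, following the
AIRR Rearrangement column names: ``repertoire_id``, ``sequence_id``,
``junction_aa`` (amino-acid mode) or ``junction`` (nucleotide mode),
``v_call``, ``j_call`` and ``duplicate_count``.  ``repertoire_id`` and the
sequence column are mandatory; a missing ``duplicate_count`` column means
every record has count 1.  Files are UTF-8, LF-terminated, unquoted.

Records are grouped into :class:`Repertoire` objects in order of first
appearance of each repertoire id.  Deduplication (merging records with the
same sequence and, optionally, the same V/J calls) is a separate explicit
step so that duplicate counts are well defined per unique receptor.

:func:`generate_synthetic_set` builds CDR3-like random repertoires with a
planted shared pool (exact cross-repertoire overlap) and planted one-edit
variants of pool sequences (approximate overlap), used throughout the test
suite in place of experimental data.
"""
from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd

from .alphabets import alphabet_for, symbol_set
from .errors import FormatError, ParameterError, RecordError


@dataclass(slots=True)
class SequenceRecord:
    """One adaptive immune receptor: a junction sequence with annotations."""

    sequence_id: str
    repertoire_id: str
    seq: str
    v_call: str | None = None
    j_call: str | None = None
    count: int = 1


@dataclass(slots=True)
class Repertoire:
    """Ordered collection of receptors from one individual/sample."""

    id: str
    records: list[SequenceRecord] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(slots=True)
class RepertoireSet:
    """Ordered collection of repertoires sharing one alphabet."""

    repertoires: list[Repertoire] = field(default_factory=list)
    alphabet_mode: str = "amino_acid"

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.repertoires]

    def __len__(self) -> int:
        return len(self.repertoires)

    def __iter__(self) -> Iterator[Repertoire]:
        return iter(self.repertoires)

    def n_records(self) -> int:
        return sum(len(r) for r in self.repertoires)

    def iter_records(self) -> Iterator[tuple[int, int, SequenceRecord]]:
        """Yield (repertoire index, record index, record) in document order."""
        for ri, rep in enumerate(self.repertoires):
            for si, rec in enumerate(rep.records):
                yield ri, si, rec

    def max_length(self) -> int:
        out = 0
        for _, _, rec in self.iter_records():
            if len(rec.seq) > out:
                out = len(rec.seq)
        return out


# ---------------------------------------------------------------------------
# reading


def _seq_column(alphabet_mode: str) -> str:
    return "junction_aa" if alphabet_mode == "amino_acid" else "junction"


def read_airr_tsv(
    source: str | IO[str],
    alphabet_mode: str = "amino_acid",
    require_genes: bool = False,
    skip_invalid: bool = False,
) -> RepertoireSet:
    """Parse an AIRR-style TSV into a :class:`RepertoireSet`.

    Parameters
    ----------
    source:
        Path or open text stream.
    alphabet_mode:
        ``"amino_acid"`` reads the ``junction_aa`` column, ``"nucleotide"``
        reads ``junction``.
    require_genes:
        Demand that ``v_call`` and ``j_call`` columns be present.
    skip_invalid:
        Downgrade record-level errors (bad symbol, bad count) to warnings
        and drop the offending rows instead of raising.
    """
    seq_col = _seq_column(alphabet_mode)
    allowed = symbol_set(alphabet_mode)
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)

    for col in ("repertoire_id", seq_col):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    if require_genes:
        for col in ("v_call", "j_call"):
            if col not in df.columns:
                raise FormatError(f"missing mandatory column {col!r}")

    cols = {c: df[c].tolist() for c in df.columns}
    has_id = "sequence_id" in cols
    has_v = "v_call" in cols
    has_j = "j_call" in cols
    has_count = "duplicate_count" in cols

    reps: dict[str, Repertoire] = {}
    order: list[str] = []

    for i in range(len(df)):
        line = i + 2  # header is line 1
        seq = cols[seq_col][i].strip().upper()
        try:
            if not seq:
                raise RecordError(line, f"empty {seq_col}")
            bad = set(seq) - allowed
            if bad:
                raise RecordError(
                    line,
                    f"symbol {sorted(bad)[0]!r} not in the {alphabet_mode} alphabet",
                )
            if has_count:
                raw = cols["duplicate_count"][i].strip()
                try:
                    count = int(raw)
                except ValueError:
                    raise RecordError(
                        line, f"duplicate_count {raw!r} is not an integer"
                    ) from None
                if count <= 0:
                    raise RecordError(line, f"duplicate_count {count} must be >= 1")
            else:
                count = 1
        except RecordError as err:
            if skip_invalid:
                warnings.warn(f"skipping record: {err}", stacklevel=2)
                continue
            raise

        rid = cols["repertoire_id"][i].strip()
        rec = SequenceRecord(
            sequence_id=cols["sequence_id"][i].strip() if has_id else f"seq{line}",
            repertoire_id=rid,
            seq=seq,
            v_call=(cols["v_call"][i].strip() or None) if has_v else None,
            j_call=(cols["j_call"][i].strip() or None) if has_j else None,
            count=count,
        )
        if rid not in reps:
            reps[rid] = Repertoire(rid)
            order.append(rid)
        reps[rid].records.append(rec)

    return RepertoireSet([reps[r] for r in order], alphabet_mode)


def deduplicate(rep: Repertoire, use_genes: bool = True) -> Repertoire:
    """Merge records sharing the same (seq[, v_call, j_call]) key.

    Counts are summed; the first-seen sequence_id (and, when genes are
    ignored, the first-seen gene calls) is retained.  Total count is
    conserved exactly.
    """
    merged: dict[object, SequenceRecord] = {}
    for rec in rep.records:
        key = (rec.seq, rec.v_call, rec.j_call) if use_genes else rec.seq
        prev = merged.get(key)
        if prev is None:
            merged[key] = replace(rec)
        else:
            prev.count += rec.count
    return Repertoire(rep.id, list(merged.values()))


# ---------------------------------------------------------------------------
# writing


def _open_sink(sink):
    if isinstance(sink, str):
        if sink == "-":
            return sys.stdout, False
        return open(sink, "w", encoding="utf-8", newline="\n"), True
    return sink, False


def _fmt_cell(x) -> str:
    """Integral values print without a decimal point; reals with 6 sig. digits."""
    xf = float(x)
    if xf.is_integer() and abs(xf) < 1e15:
        return str(int(xf))
    return format(xf, ".6g")


def write_airr_tsv(rset: RepertoireSet, sink) -> None:
    """Serialize a repertoire set back to the input TSV dialect."""
    out, close = _open_sink(sink)
    seq_col = _seq_column(rset.alphabet_mode)
    try:
        out.write(
            "\t".join(
                [
                    "repertoire_id",
                    "sequence_id",
                    seq_col,
                    "v_call",
                    "j_call",
                    "duplicate_count",
                ]
            )
            + "\n"
        )
        for _, _, rec in rset.iter_records():
            out.write(
                "\t".join(
                    [
                        rec.repertoire_id,
                        rec.sequence_id,
                        rec.seq,
                        rec.v_call or "",
                        rec.j_call or "",
                        str(rec.count),
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            out.close()


def write_matrix(mat, sink) -> None:
    """Write an overlap/similarity matrix as TSV with a ``#`` header cell."""
    out, close = _open_sink(sink)
    try:
        out.write("#\t" + "\t".join(mat.col_ids) + "\n")
        for rid, row in zip(mat.row_ids, mat.values):
            out.write(rid + "\t" + "\t".join(_fmt_cell(v) for v in row) + "\n")
    finally:
        if close:
            out.close()


def write_presence_table(tab, sink) -> None:
    """Write an n-repertoires x m-reference-sequences presence table as TSV."""
    out, close = _open_sink(sink)
    try:
        out.write("#\t" + "\t".join(tab.reference_ids) + "\n")
        for rid, row in zip(tab.repertoire_ids, tab.values):
            out.write(rid + "\t" + "\t".join(_fmt_cell(v) for v in row) + "\n")
    finally:
        if close:
            out.close()


def write_pairs(
    pairs: Iterable,
    query_set: RepertoireSet,
    target_set: RepertoireSet,
    sink,
) -> None:
    """Write matched pairs as a flat AIRR-style TSV.

    Every record column is emitted twice, suffixed ``_1`` (query side) and
    ``_2`` (target side); a final ``distance`` column holds the verified
    number of differences.
    """
    out, close = _open_sink(sink)
    seq_col = _seq_column(query_set.alphabet_mode)
    base = ["repertoire_id", "sequence_id", seq_col, "v_call", "j_call", "duplicate_count"]
    try:
        header = [c + "_1" for c in base] + [c + "_2" for c in base] + ["distance"]
        out.write("\t".join(header) + "\n")
        for p in pairs:
            q = query_set.repertoires[p.query_rep].records[p.query_rec]
            t = target_set.repertoires[p.target_rep].records[p.target_rec]
            row = [
                q.repertoire_id, q.sequence_id, q.seq, q.v_call or "", q.j_call or "",
                str(q.count),
                t.repertoire_id, t.sequence_id, t.seq, t.v_call or "", t.j_call or "",
                str(t.count),
                str(p.n_diff),
            ]
            out.write("\t".join(row) + "\n")
    finally:
        if close:
            out.close()


def write_clusters(rset: RepertoireSet, assignments, sink) -> None:
    """Write the input echoed with an appended ``cluster_id`` column.

    ``assignments`` is one ClusterAssignment per repertoire; cluster ids are
    offset so they are unique across the whole file.  Rows are grouped by
    cluster and sorted by descending duplicate count within each cluster.
    """
    out, close = _open_sink(sink)
    seq_col = _seq_column(rset.alphabet_mode)
    try:
        out.write(
            "\t".join(
                [
                    "repertoire_id",
                    "sequence_id",
                    seq_col,
                    "v_call",
                    "j_call",
                    "duplicate_count",
                    "cluster_id",
                ]
            )
            + "\n"
        )
        offset = 0
        for rep, asg in zip(rset.repertoires, assignments):
            rows = sorted(
                range(len(rep.records)),
                key=lambda i: (asg.labels[i], -rep.records[i].count, i),
            )
            for i in rows:
                rec = rep.records[i]
                out.write(
                    "\t".join(
                        [
                            rec.repertoire_id,
                            rec.sequence_id,
                            rec.seq,
                            rec.v_call or "",
                            rec.j_call or "",
                            str(rec.count),
                            str(asg.labels[i] + offset),
                        ]
                    )
                    + "\n"
                )
            offset += asg.n_clusters
    finally:
        if close:
            out.close()


# ---------------------------------------------------------------------------
# synthetic repertoires

_V_GENES = tuple(f"TRBV{i}" for i in range(1, 31))
_J_GENES = tuple(f"TRBJ1-{i}" for i in range(1, 7)) + tuple(
    f"TRBJ2-{i}" for i in range(1, 8)
)


def _random_unique_seqs(rng, k, length_range, alphabet, forbidden):
    """Generate k distinct random strings, avoiding the forbidden set."""
    lo, hi = length_range
    alph = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)
    seen = set(forbidden)
    out: list[str] = []
    while len(out) < k:
        need = k - len(out)
        batch = need + max(16, need // 8)
        lengths = rng.integers(lo, hi + 1, size=batch)
        flat = alph[rng.integers(0, len(alph), size=int(lengths.sum()))]
        offsets = np.concatenate(([0], np.cumsum(lengths)))
        for a, b in zip(offsets[:-1], offsets[1:]):
            s = flat[a:b].tobytes().decode("ascii")
            if s in seen:
                continue
            seen.add(s)
            out.append(s)
            if len(out) == k:
                break
    return out


def _mutate_once(rng, seq: str, alphabet: str) -> str:
    """Substitute one position with a different symbol."""
    p = int(rng.integers(len(seq)))
    choices = [c for c in alphabet if c != seq[p]]
    c = choices[int(rng.integers(len(choices)))]
    return seq[:p] + c + seq[p + 1 :]


def generate_synthetic_set(
    n_reps: int,
    n_seqs: int,
    length_range: tuple[int, int] = (8, 16),
    alphabet_mode: str = "amino_acid",
    shared_fraction: float = 0.1,
    mutant_fraction: float = 0.0,
    seed: int = 0,
) -> RepertoireSet:
    """Generate random CDR3-like repertoires with planted overlap.

    Every repertoire contains the same pool of ``floor(shared_fraction *
    n_seqs)`` sequences (planted exact overlap, with identical V/J calls
    across repertoires), ``floor(mutant_fraction * n_seqs)`` single-
    substitution variants of pool sequences (planted approximate overlap,
    inheriting the pool V/J calls), and enough private random sequences to
    reach ``n_seqs`` unique sequences per repertoire.  Duplicate counts are
    geometric with mean 2, mimicking a skewed clone-size distribution.
    Deterministic for a given seed.
    """
    if n_reps < 1 or n_seqs < 1:
        raise ParameterError("n_reps and n_seqs must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ParameterError(f"invalid length range {length_range!r}")
    alphabet = alphabet_for(alphabet_mode)

    n_shared = int(shared_fraction * n_seqs)
    n_mut = int(mutant_fraction * n_seqs)
    if not 0.0 <= shared_fraction <= 1.0 or not 0.0 <= mutant_fraction <= 1.0:
        raise ParameterError("shared_fraction and mutant_fraction must be in [0, 1]")
    if n_shared + n_mut > n_seqs:
        raise ParameterError("shared_fraction + mutant_fraction exceeds capacity")
    if n_mut > 0 and n_shared == 0:
        raise ParameterError("mutant_fraction > 0 requires a non-empty shared pool")

    # feasibility: demand slack so rejection sampling of unique strings halts
    space = 0
    for length in range(lo, hi + 1):
        space += len(alphabet) ** length
        if space > 8 * (n_seqs + n_shared):
            break
    if space < 4 * (n_seqs + n_shared):
        raise ParameterError(
            "alphabet^length space too small for the requested number of "
            "unique sequences"
        )

    rng = np.random.default_rng(seed)
    pool = _random_unique_seqs(rng, n_shared, length_range, alphabet, set())
    pool_v = [_V_GENES[i] for i in rng.integers(0, len(_V_GENES), size=n_shared)]
    pool_j = [_J_GENES[i] for i in rng.integers(0, len(_J_GENES), size=n_shared)]

    reps: list[Repertoire] = []
    for r in range(n_reps):
        rid = f"R{r + 1}"
        records: list[SequenceRecord] = []
        seen = set(pool)
        for k, s in enumerate(pool):
            records.append(
                SequenceRecord(f"{rid}-p{k + 1}", rid, s, pool_v[k], pool_j[k])
            )
        for k in range(n_mut):
            src = int(rng.integers(n_shared))
            m = _mutate_once(rng, pool[src], alphabet)
            while m in seen:
                m = _mutate_once(rng, pool[src], alphabet)
            seen.add(m)
            records.append(
                SequenceRecord(f"{rid}-m{k + 1}", rid, m, pool_v[src], pool_j[src])
            )
        n_rand = n_seqs - n_shared - n_mut
        randoms = _random_unique_seqs(rng, n_rand, length_range, alphabet, seen)
        rv = rng.integers(0, len(_V_GENES), size=n_rand)
        rj = rng.integers(0, len(_J_GENES), size=n_rand)
        for k, s in enumerate(randoms):
            records.append(
                SequenceRecord(
                    f"{rid}-s{k + 1}", rid, s, _V_GENES[rv[k]], _J_GENES[rj[k]]
                )
            )
        counts = rng.geometric(0.5, size=n_seqs)
        for rec, c in zip(records, counts):
            rec.count = int(c)
        reps.append(Repertoire(rid, records))

    return RepertoireSet(reps, alphabet_mode)
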