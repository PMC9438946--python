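import io
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from airrmatch import Repertoire, RepertoireSet, SequenceRecord, deduplicate


TOY_TSV = (
    "repertoire_id\tsequence_id\tjunction_aa\tduplicate_count\n"
    "R1\ts1\tCASSF\t2\n"
    "R1\ts2\tCARF\t1\n"
    "R2\ts3\tCASSF\t3\n"
)


@pytest.fixture
def toy_tsv_text():
    return TOY_TSV


@pytest.fixture
def toy_tsv_stream():
    return io.StringIO(TOY_TSV)


@pytest.fixture
def toy_tsv_path(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text(TOY_TSV)
    return str(p)


def make_repertoire(rid, seqs_counts, alphabet_mode="amino_acid", v=None, j=None):
    """Build a repertoire from (seq, count) pairs; genes optional."""
    recs = [
        SequenceRecord(f"{rid}-{k}", rid, s, v, j, c)
        for k, (s, c) in enumerate(seqs_counts)
    ]
    return Repertoire(rid, recs)


def make_set(reps, alphabet_mode="amino_acid"):
    return RepertoireSet(list(reps), alphabet_mode)


def dedup_set(rset, use_genes=True):
    rset.repertoires = [deduplicate(r, use_genes) for r in rset.repertoires]
    return rset
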