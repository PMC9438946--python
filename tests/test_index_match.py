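"""Index building, verification, and the exact/approximate match engines."""
import pytest

from airrmatch import (
    MatchOptions,
    OptionError,
    Repertoire,
    RepertoireSet,
    SequenceRecord,
    ZobristTable,
    all_vs_all_matches,
    build_index,
    deduplicate,
    find_matches,
    generate_synthetic_set,
    match_all,
    verify,
)

from conftest import dedup_set, make_repertoire, make_set
from helpers import brute_match_pairs, pairs_as_set


def fixture_set(seed, n_seqs=60, alphabet="amino_acid", lengths=(6, 14)):
    rset = generate_synthetic_set(
        2, n_seqs, lengths, alphabet, shared_fraction=0.15, mutant_fraction=0.1,
        seed=seed,
    )
    return dedup_set(rset)


class TestVerify:
    @pytest.mark.parametrize(
        "a,b,d,indels,expected",
        [
            ("CASSF", "CASSF", 0, False, (True, 0)),
            ("CARF", "CGRF", 1, False, (True, 1)),
            ("CARF", "CGRF", 0, False, (False, None)),
            ("CAR", "CARS", 1, False, (False, None)),
            ("CAR", "CARS", 1, True, (True, 1)),
            ("CARS", "CAR", 1, True, (True, 1)),
            ("CAR", "CARSS", 1, True, (False, None)),
            ("AAAAA", "TTTAA", 3, False, (True, 3)),
            ("AAAAA", "TTTTA", 3, False, (False, None)),
            ("CASSF", "CASSF", 1, True, (True, 0)),
            ("AB", "BA", 1, True, (False, None)),  # two substitutions
        ],
    )
    def test_distance_semantics(self, a, b, d, indels, expected):
        assert verify(a, b, d, indels) == expected


class TestBuildIndex:
    def test_empty_targets(self):
        table = ZobristTable("amino_acid", seed=1)
        idx = build_index(make_set([]), table)
        assert len(idx.hash_index) == 0
        q = SequenceRecord("q", "Q", "CASSF")
        assert find_matches(q, (0, 0), idx, 0) == []

    def test_identical_sequences_share_a_bucket(self):
        table = ZobristTable("amino_acid", seed=1)
        rset = make_set(
            [
                make_repertoire("A", [("CASSF", 1)]),
                make_repertoire("B", [("CASSF", 1)]),
            ]
        )
        idx = build_index(rset, table)
        assert len(idx.hash_index) == 1
        (bucket,) = idx.hash_index.buckets.values()
        assert bucket == [(0, 0), (1, 0)]

    def test_every_record_findable_by_own_hash(self):
        rset = generate_synthetic_set(1, 10_000, (8, 16), "amino_acid", 0.0, 0.0, seed=2)
        table = ZobristTable("amino_acid", seed=1)
        idx = build_index(rset, table)
        for ri, si, rec in rset.iter_records():
            matches = find_matches(rec, (ri, si), idx, 0, use_genes=False)
            assert (ri, si, ri, si, 0) in pairs_as_set(matches)

    def test_bloom_has_no_false_negatives(self):
        rset = generate_synthetic_set(1, 2000, (8, 16), "amino_acid", 0.0, 0.0, seed=4)
        table = ZobristTable("amino_acid", seed=1)
        idx = build_index(rset, table)
        for h in idx.hash_index.buckets:
            assert idx.bloom.contains(h)


class TestFindMatches:
    def test_exact_match_found(self):
        rset = make_set([make_repertoire("A", [("CASSF", 2)])])
        table = ZobristTable("amino_acid", seed=1)
        idx = build_index(rset, table)
        q = SequenceRecord("q", "Q", "CASSF")
        assert find_matches(q, (0, 0), idx, 0, use_genes=False) == [(0, 0, 0, 0, 0)]

    def test_distance_bound_respected(self):
        rset = make_set([make_repertoire("A", [("CASSF", 1)])])
        table = ZobristTable("amino_acid", seed=1)
        idx = build_index(rset, table)
        q = SequenceRecord("q", "Q", "CGSSW")  # Hamming distance 2
        assert find_matches(q, (0, 0), idx, 1, use_genes=False) == []
        assert find_matches(q, (0, 0), idx, 2, use_genes=False) == [(0, 0, 0, 0, 2)]

    def test_gene_restriction(self):
        rep = Repertoire(
            "A",
            [
                SequenceRecord("t1", "A", "CASSF", "V1", "J1", 1),
                SequenceRecord("t2", "A", "CASSF", "V2", "J1", 1),
                SequenceRecord("t3", "A", "CASSF", None, "J1", 1),
            ],
        )
        table = ZobristTable("amino_acid", seed=1)
        idx = build_index(make_set([rep]), table)
        q = SequenceRecord("q", "Q", "CASSF", "V1", "J1")
        got = find_matches(q, (0, 0), idx, 0, use_genes=True)
        assert got == [(0, 0, 0, 0, 0)]  # only the V1/J1 target
        # a query with a missing call matches nothing under restriction
        q2 = SequenceRecord("q", "Q", "CASSF", None, "J1")
        assert find_matches(q2, (0, 0), idx, 0, use_genes=True) == []

    @pytest.mark.parametrize(
        "d,indels", [(0, False), (1, False), (1, True), (2, False)]
    )
    @pytest.mark.parametrize("alphabet", ["amino_acid", "nucleotide"])
    def test_equals_brute_force_oracle(self, d, indels, alphabet):
        rset = fixture_set(seed=17, alphabet=alphabet)
        opts = MatchOptions(d=d, allow_indels=indels, use_genes=False)
        got = pairs_as_set(match_all(rset, rset, opts))
        assert got == brute_match_pairs(rset, rset, d, indels, use_genes=False)

    def test_oracle_equality_with_gene_restriction(self):
        rset = fixture_set(seed=23)
        opts = MatchOptions(d=1, use_genes=True)
        got = pairs_as_set(match_all(rset, rset, opts))
        assert got == brute_match_pairs(rset, rset, 1, False, use_genes=True)


class TestAllVsAll:
    def test_hamming_three_matched(self):
        a = make_set([make_repertoire("A", [("AAAAA", 1)])], "amino_acid")
        b = make_set(
            [make_repertoire("B", [("TTTAA", 1), ("TTTTA", 1)])], "amino_acid"
        )
        got = all_vs_all_matches(a, b, 3, use_genes=False)
        assert got == [(0, 0, 0, 0, 3)]

    def test_indels_unsupported(self):
        a = make_set([make_repertoire("A", [("AAAAA", 1)])])
        with pytest.raises(OptionError):
            all_vs_all_matches(a, a, 3, allow_indels=True)

    def test_agreement_with_indexed_engine_at_d2(self):
        rset = fixture_set(seed=31)
        via_index = pairs_as_set(
            match_all(rset, rset, MatchOptions(d=2, use_genes=False))
        )
        via_avs = pairs_as_set(all_vs_all_matches(rset, rset, 2, use_genes=False))
        assert via_index == via_avs

    def test_d3_equals_brute_force(self):
        rset = fixture_set(seed=37, n_seqs=40)
        got = pairs_as_set(match_all(rset, rset, MatchOptions(d=3, use_genes=False)))
        assert got == brute_match_pairs(rset, rset, 3, False, use_genes=False)


class TestMatchAll:
    def test_worker_count_invariance(self):
        rset = fixture_set(seed=41, n_seqs=150)
        opts = MatchOptions(d=1, use_genes=False)
        p1 = match_all(rset, rset, opts, n_workers=1)
        p4 = match_all(rset, rset, opts, n_workers=4)
        assert p1 == p4

    def test_canonical_order(self):
        rset = fixture_set(seed=43)
        pairs = match_all(rset, rset, MatchOptions(d=1, use_genes=False))
        assert pairs == sorted(pairs)

    def test_every_record_self_matches_at_d0(self):
        rset = fixture_set(seed=47)
        pairs = pairs_as_set(match_all(rset, rset, MatchOptions(d=0)))
        for ri, si, _ in rset.iter_records():
            assert (ri, si, ri, si, 0) in pairs

    def test_planted_overlap_recovered(self):
        rset = generate_synthetic_set(2, 100, (8, 16), "amino_acid", 0.1, 0.0, seed=7)
        dedup_set(rset)
        pairs = pairs_as_set(match_all(rset, rset, MatchOptions(d=0)))
        pool = {r.seq for r in rset.repertoires[0].records[:10]}
        idx0 = {r.seq: i for i, r in enumerate(rset.repertoires[0].records)}
        idx1 = {r.seq: i for i, r in enumerate(rset.repertoires[1].records)}
        for s in pool:
            assert (0, idx0[s], 1, idx1[s], 0) in pairs

    def test_symmetry_on_self_comparison(self):
        rset = fixture_set(seed=53)
        pairs = pairs_as_set(match_all(rset, rset, MatchOptions(d=1, allow_indels=True, use_genes=False)))
        for qr, qs, tr, ts, nd in pairs:
            assert (tr, ts, qr, qs, nd) in pairs

    def test_bloom_filter_is_pure_optimization(self):
        rset = fixture_set(seed=59)
        for d, indels in [(0, False), (1, True), (2, False)]:
            with_bloom = match_all(
                rset, rset, MatchOptions(d=d, allow_indels=indels, use_genes=False)
            )
            without = match_all(
                rset,
                rset,
                MatchOptions(d=d, allow_indels=indels, use_genes=False, use_bloom=False),
            )
            assert with_bloom == without

    def test_pair_reported_once_with_minimal_distance(self):
        # query at distance 1 reachable via many variant hashes
        a = make_set([make_repertoire("A", [("CASSF", 1)])])
        b = make_set([make_repertoire("B", [("CASSW", 1)])])
        pairs = match_all(a, b, MatchOptions(d=2, use_genes=False))
        assert pairs == [(0, 0, 0, 0, 1)]

    def test_alphabet_mismatch_rejected(self):
        a = make_set([make_repertoire("A", [("CASSF", 1)])], "amino_acid")
        b = make_set([make_repertoire("B", [("ACGT", 1)])], "nucleotide")
        with pytest.raises(OptionError):
            match_all(a, b, MatchOptions(d=0))


class TestMatchOptions:
    def test_indels_require_d1(self):
        with pytest.raises(OptionError):
            MatchOptions(d=2, allow_indels=True)
        with pytest.raises(OptionError):
            MatchOptions(d=0, allow_indels=True)
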