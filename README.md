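# airrmatch

Fast exact and approximate overlap analysis for adaptive immune receptor
repertoires (AIRRs).

Adaptive immune receptors (T- and B-cell receptors) record past immune
encounters, and shared immune states give rise to identical or near-identical
receptor sequences — usually compared by their CDR3/junction region — across
individuals. Counting matching receptors across repertoires is therefore a
foundational step in repertoire analysis, but a naive implementation compares
every sequence of every repertoire against every sequence of every other, which
does not scale to cohorts of thousands of repertoires with 10⁵–10⁶ sequences
each.

`airrmatch` avoids the all-pairs comparison with tabulation (Zobrist) hashing:
a sequence hashes to the XOR over positions *i* of a fixed random 64-bit value
*T*[*i*, *s*ᵢ]. Because XOR is an involution, the hash of any single-symbol
edit is two XOR operations away, so the hashes of **all** sequences within 1–2
substitutions (or one insertion/deletion) of a query can be enumerated without
materialising the variant strings. Target sequences are indexed once in a hash
table behind a Bloom-filter prefilter; each query probes the index with its
variant hashes, and every bucket hit is verified by computing the actual
Hamming or Levenshtein distance. Hash equality is never trusted as sequence
equality, so the result is *exactly* the brute-force match set — the hashing
only changes the speed. Distances of 3 or more substitutions are served by a
simple all-versus-all engine.

From the verified match pairs the package builds:

- an *n* × *n* repertoire **overlap matrix**, each cell summing a statistic of
  the two matched duplicate counts (`product`, `min`, `max`, `mean`, `ratio`),
  or the **Morisita-Horn** / **Jaccard** similarity index (exact matching
  only);
- an *n* × *m* **presence table** of *m* reference sequences across *n* query
  repertoires;
- a **single-linkage clustering** of one repertoire (connected components of
  the distance-≤ *d* graph);
- optionally, the list of matching pairs as a flat AIRR-style TSV.

Matches can be restricted to pairs with identical V and J gene calls, and
input/output follows the AIRR Rearrangement TSV column conventions
(`repertoire_id`, `sequence_id`, `junction_aa`/`junction`, `v_call`, `j_call`,
`duplicate_count`).

## Worked example

Given `toy.tsv`:

```
repertoire_id	sequence_id	junction_aa	duplicate_count
R1	s1	CASSF	2
R1	s2	CARF	1
R2	s3	CASSF	3
```

```sh
$ airrmatch -m -d 0 -s product toy.tsv
#	R1	R2
R1	5	6
R2	6	9
```

The off-diagonal cell is the sum over exactly matching sequence pairs of the
product of their duplicate counts: `CASSF` appears in both repertoires with
counts 2 and 3, so cell (R1, R2) = 2 × 3 = 6. Diagonal cells include
self-pairs: cell (R1, R1) = 2² + 1² = 5, cell (R2, R2) = 3² = 9. With `-d 1`
the sum would also include sequence pairs one substitution apart, with
`-d 1 -i` pairs one substitution **or** one indel apart. The log (stderr)
reports records read, unique sequences after deduplication, and matched pairs.

Other modes: `-x queries.tsv reference.tsv` writes the presence table of the
reference sequences in each query repertoire; `-c -d 1 reps.tsv` appends a
`cluster_id` column from single-linkage clustering. `-s MH` or `-s Jaccard`
selects the similarity indices, `-g` ignores gene calls, `-f` ignores
duplicate counts, `-t N` uses N worker threads (output is identical for any
N), and `--seed` fixes the hash-table seed.

The same pipeline is available as a library:

```python
from airrmatch import MatchOptions, generate_synthetic_set, deduplicate, \
    match_all, pairwise_matrix

rset = generate_synthetic_set(10, 1000, (8, 16), "amino_acid",
                              shared_fraction=0.05, seed=1)
rset.repertoires = [deduplicate(r) for r in rset.repertoires]
pairs = match_all(rset, rset, MatchOptions(d=1))
mat = pairwise_matrix(rset, pairs, "product")
```

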