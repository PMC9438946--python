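# Methods

## Matching model

Two receptors match when their junction sequences are within a configured
distance and, when gene restriction is active, their V and J gene calls are
identical strings. The distance is Hamming distance at equal length
(substitutions-only matching, any *d* ≥ 0), or Levenshtein distance when
indels are tolerated. Indel tolerance is offered only at *d* = 1: the
neighbourhood "one substitution or one insertion or one deletion" is
well-defined and cheap to enumerate, whereas mixed substitution/indel
neighbourhoods at *d* = 2 multiply the variant count without a clear use
case, so *d* = 2 enumerates substitution pairs only and *d* ≥ 3 is
substitutions-only via the all-versus-all engine.

Sequences are compared over a closed alphabet (20 amino acids or 4
nucleotides). Stop codons (`*`), `X` and other ambiguity codes are rejected
on read (or skipped with `--skip-invalid`): a match semantics over wildcard
symbols would be ill-defined, and the variant enumeration requires a fixed
symbol set.

Every repertoire is deduplicated before matching, merging records with equal
(sequence, V, J) keys — equal sequence alone when genes are ignored — and
summing duplicate counts. This makes "the count of a matching receptor"
well-defined. Gene calls are compared verbatim, so allele-level calls
(`TRBV7-2*01`) only match identical allele strings; inputs annotated at
different resolutions should be normalised upstream or compared with `-g`.
When an input file carries no V/J columns at all, the command-line tool
disables gene restriction for the run (with a log note) instead of silently
producing an empty result, since the strict per-record rule — a missing call
on either side fails the restriction — would otherwise reject every pair.

## Hashing and variant enumeration

A sequence hashes to the XOR over positions *i* of a fixed random 64-bit
table entry *T*[*i*, *s*ᵢ] (Zobrist/tabulation hashing); the empty string
hashes to 0. The table is drawn position-major from a seeded PCG64 stream,
so growing the table for longer sequences re-draws a longer prefix of the
same stream and leaves existing entries — and all previously computed
hashes — unchanged. The default table seed is fixed (`20177`) so runs are
reproducible by default; `--seed` overrides it.

Hashes of all single substitutions are obtained with two XORs each. For
indel variants, prefix- and suffix-XOR accumulators are precomputed over the
shifted positions (the suffix of a deletion re-indexed one position left,
of an insertion one right), so each of the O(L·A) variants costs O(1) after
O(L) preparation. Double substitutions combine two single-substitution
deltas over all position pairs. Two implementations share these recurrences:
a reference generator that yields (hash, descriptor) pairs, where the
descriptor reconstructs the variant string — used for verification and
property tests — and a vectorised NumPy twin used on the hot path, which may
emit duplicate hash values (e.g. re-inserting the original symbol reproduces
the identity); only the set of distinct hashes matters downstream.

## Index, Bloom filter, verification

Targets are indexed once in a dict keyed by their own hash. A Bloom filter
(smallest power of two ≥ 16 bits per indexed record, two probes from the
high and low 32 bits of the hash) sits in front to skip lookups that cannot
hit. The filter stores one byte per bit (a NumPy bool array), trading ~8×
the minimal memory for simple vectorised probing; it is a pure optimisation,
and the test suite asserts that removing it changes nothing but speed.

Every bucket hit is verified by computing the true Hamming or Levenshtein
distance between the two sequences, so hash collisions (64-bit, ≈ 2⁻⁶⁴ per
pair) cannot produce false positives, and enumeration completeness —
property-tested against brute-force neighbourhood enumeration — rules out
false negatives. A pair reachable through several variants is reported once
with the minimal verified distance.

Self-pairs (a record matched to itself when query and target sets coincide)
are kept: the matrix diagonal is then the within-repertoire overlap
(Σcᵢ² for the exact product statistic), documented so users can ignore it.

## Output statistics

Matrix cell (*s*, *t*) sums g(c_x, c_y) over matched pairs (x ∈ s, y ∈ t)
with g ∈ {product, min, max, mean, ratio}; `ratio` puts the row (query-side)
count in the numerator, the one orientation that had to be picked. Counts
are raw post-deduplication duplicate counts by default; `--relative`
converts to within-repertoire frequencies first, `-f` replaces every count
by 1 (product cells then count matching pairs). Morisita-Horn
(C_H = 2Σxᵢyᵢ / ((Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y)) and Jaccard (|A∩B|/|A∪B| over
unique keys) are defined for exact matching only; requesting them with
*d* > 0 is an error rather than a silent generalisation, since their meaning
under approximate matching is not established. Real-valued cells print with
6 significant digits, integral values without a decimal point, keeping
golden files stable.

Single-linkage clusters are the connected components of the verified match
graph (self-edges ignored), computed by union-find with path halving over
the streamed pairs; the result is independent of pair order. Cluster ids
1..K are assigned by decreasing per-cluster total count, ties broken by the
lowest member record index. Note the standard single-linkage caveat:
within-cluster *chain* distances are ≤ d, pairwise distances need not be.

## Determinism and threading

All outputs are byte-identical across runs with the same inputs, options
and seed, and across worker counts: queries are split into contiguous
chunks whose per-query results (sorted by target) are concatenated in query
order, which equals the canonical (query, target) sort. Workers are threads
sharing the read-only index; under the CPython GIL this bounds rather than
multiplies throughput, and the thread option exists chiefly to honour the
determinism contract of a parallel mode.

## Synthetic data

`generate_synthetic_set` emulates CDR3-like repertoires: uniform random
strings (default lengths 8–16, amino-acid alphabet), geometric duplicate
counts with mean 2 as a stand-in for skewed clone sizes, and uniform V/J
calls from 30 TRBV / 13 TRBJ names. Planted structure: a pool of
⌊shared_fraction·n⌋ sequences present in every repertoire with identical
V/J calls (exact overlap ground truth) and ⌊mutant_fraction·n⌋
single-substitution variants of pool sequences per repertoire (approximate
overlap ground truth; mutants therefore require a non-empty pool). What it
does **not** emulate: the positional composition biases of real VDJ
recombination, length-dependent amino-acid usage, power-law clone sizes, or
correlated gene usage. Passing tests demonstrate algorithmic exactness and
scaling on data with realistic sizes and planted truth, not biological
fidelity of any similarity value.

## Problem sizes and numerical choices

The oracle-equality tests run 20 random instances of two 200-sequence
repertoires (lengths 5–25, both alphabets, all five matching modes) against
an O(N²) oracle built on edlib and vectorised Hamming counts; variant
soundness/completeness runs 1000 random length-5–12 sequences (the
substitution-pair mode on a 300-sequence subsample, which keeps the check
thorough while the d = 1 modes cover all 1000). The scaling check times the
exact-matrix pipeline at 10 and 100 repertoires of 10⁴ sequences
(shared_fraction 0.05) and requires growth in repertoire count with fitted
exponent < 1.8 — meaningfully sub-quadratic — plus completion within a
15-minute single-CPU budget; matching is near-linear in total sequences,
while the planted-pool pair list itself grows quadratically in the
repertoire count and keeps the exponent above 1.

Degenerate inputs: empty repertoires are rejected by the similarity indices
(undefined) and yield empty clusterings; a deletion from a length-1
sequence hashes to the empty string's hash 0; counts must be positive
integers. Ratio cells cannot divide by zero because counts are ≥ 1.

## Known limitations

No banded alignment or substitution-matrix (BLOSUM) similarity; no indels
at d ≥ 2; no paired-chain merging of presence tables; no rarefaction or
size normalisation of repertoires; allele-level gene comparison is verbatim
string equality.
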