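"""Single-linkage clustering of the receptors of one repertoire.

Clusters are the connected components of the graph whose edges join
sequences within the configured distance (and with identical V/J calls
when gene restriction is active).  Components are found with union-find
over the streamed match pairs from the same index/variant machinery used
for cross-repertoire matching, so the edge set is exactly the verified
match set.  Note the usual single-linkage caveat: members of one cluster
are connected by a *chain* of within-distance pairs, but their pairwise
distance may exceed d.
"""
from __future__ import annotations

from dataclasses import dataclass

from .airr_io import Repertoire, RepertoireSet
from .hashing import DEFAULT_TABLE_SEED
from .index_match import MatchOptions, match_all


@dataclass
class ClusterAssignment:
    """Cluster label per record plus per-cluster duplicate-count totals.

    Labels are 1..K, assigned in decreasing order of per-cluster total
    count; ties broken by the lowest member record index.
    """

    labels: list[int]
    cluster_counts: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_counts)


def single_linkage_cluster(
    rep: Repertoire,
    d: int = 1,
    allow_indels: bool = False,
    use_genes: bool = True,
    alphabet_mode: str = "amino_acid",
    hash_seed: int = DEFAULT_TABLE_SEED,
) -> ClusterAssignment:
    """Cluster a (deduplicated) repertoire by single linkage at distance d.

    With d = 0 every unique receptor is its own cluster.  An empty
    repertoire yields an empty assignment.
    """
    n = len(rep.records)
    if n == 0:
        return ClusterAssignment([], {})

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]  # path halving
            x = parent[x]
        return x

    if d > 0:
        rset = RepertoireSet([rep], alphabet_mode)
        options = MatchOptions(
            d=d, allow_indels=allow_indels, use_genes=use_genes, hash_seed=hash_seed
        )
        for _, qs, _, ts, _ in match_all(rset, rset, options):
            if qs == ts:
                continue  # self-match edges carry no linkage information
            ra, rb = find(qs), find(ts)
            if ra != rb:
                parent[rb] = ra

    roots = [find(i) for i in range(n)]
    totals: dict[int, int] = {}
    first: dict[int, int] = {}
    for i, r in enumerate(roots):
        totals[r] = totals.get(r, 0) + rep.records[i].count
        if r not in first:
            first[r] = i
    ordered = sorted(totals, key=lambda r: (-totals[r], first[r]))
    relabel = {r: k + 1 for k, r in enumerate(ordered)}
    labels = [relabel[r] for r in roots]
    return ClusterAssignment(labels, {relabel[r]: totals[r] for r in ordered})
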