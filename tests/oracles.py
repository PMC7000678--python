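"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and shares no code with the package
internals: position-by-position scans, all-pairs double loops, and a
Steiner-tree dynamic program over the *entire* site hypercube.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree


def naive_overlap_count(seq: str, motif: str) -> int:
    """Position-by-position scan; windows containing N never match."""
    k = len(motif)
    return sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] == motif)


def naive_hd(counts: list[int]) -> float:
    """Haplotype diversity by explicit pair counting: the probability that
    two draws without replacement come from different haplotypes."""
    n = sum(counts)
    same = sum(c * (c - 1) for c in counts)
    return 1.0 - same / (n * (n - 1))


def naive_k(seqs: list[str]) -> float:
    """Mean pairwise difference by an explicit double loop."""
    pairs = list(itertools.combinations(seqs, 2))
    total = sum(sum(a != b for a, b in zip(x, y)) for x, y in pairs)
    return total / len(pairs)


def hypercube_steiner_length(vectors_bits: list[int], n_sites: int) -> int:
    """Exact Steiner minimal tree length for binary haplotypes.

    Dynamic program over the full hypercube {0,1}^n_sites: every unobserved
    state vector is available as a potential median node.
    """
    V = 1 << n_sites
    popcount = np.array([bin(x).count("1") for x in range(V)])
    dist = np.array([[popcount[a ^ b] for b in range(V)] for a in range(V)])
    terms = list(vectors_bits)
    if len(terms) <= 1:
        return 0
    t0 = terms[-1]
    rest = terms[:-1]
    k = len(rest)
    S = {1 << i: dist[t].copy() for i, t in enumerate(rest)}
    for size in range(2, k + 1):
        for combo in itertools.combinations(range(k), size):
            mask = sum(1 << i for i in combo)
            best = np.full(V, 10**9)
            sub = (mask - 1) & mask
            while sub:
                other = mask ^ sub
                if sub <= other:
                    best = np.minimum(best, S[sub] + S[other])
                sub = (sub - 1) & mask
            # relax through an intermediate vertex
            S[mask] = (dist + best[None, :]).min(axis=1)
    return int(S[(1 << k) - 1][t0])


def exhaustive_steiner_length(vectors_bits: list[int], n_sites: int, max_extra: int = 3) -> int:
    """Steiner length by literally enumerating subsets of unobserved state
    vectors as extra nodes and taking the best spanning-tree length.
    Only feasible for very small hypercubes; validates the DP oracle."""
    V = 1 << n_sites
    popcount = [bin(x).count("1") for x in range(V)]

    def mst_len(nodes: list[int]) -> int:
        m = len(nodes)
        d = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                d[i, j] = popcount[nodes[i] ^ nodes[j]]
        return int(round(minimum_spanning_tree(d + d.T).sum()))

    terms = list(vectors_bits)
    extras = [v for v in range(V) if v not in set(terms)]
    best = mst_len(terms)
    for k in range(1, max_extra + 1):
        for combo in itertools.combinations(extras, k):
            best = min(best, mst_len(terms + list(combo)))
    return best


def ground_truth_k(truth, clade: str) -> float:
    """Mean pairwise difference recomputed from the mutation lists alone:
    reconstruct each tip's deviations from the ancestor and count per-site
    mismatches pair by pair (collisions between lineages included)."""
    muts = truth.mutations[clade]
    tips = sorted(muts)
    anc = truth.clade_ancestors[clade]
    total, pairs = 0, 0
    for a, b in itertools.combinations(tips, 2):
        da = {site: new for site, _, new in muts[a]}
        db = {site: new for site, _, new in muts[b]}
        diff = 0
        for site in set(da) | set(db):
            if da.get(site, anc[site]) != db.get(site, anc[site]):
                diff += 1
        total += diff
        pairs += 1
    return total / pairs
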