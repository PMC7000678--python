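"""Median-joining haplotype network construction.

Builds the networks used to visualize within-clade haplotype structure:
an epsilon-relaxed minimum spanning network (MSN) over the haplotypes,
augmented with median (consensus) vectors that act as Steiner points and
shorten the network.

The MSN keeps an edge (u, v) exactly when

    d(u, v) <= sigma(u, v) + epsilon

where ``sigma(u, v)`` is the connection cost: the smallest distance class
at which u and v fall into one component when edges are admitted in
increasing distance order (equivalently the minimax path distance).  With
epsilon = 0 this is the union of all minimum spanning trees; with epsilon
at least the maximal distance it is the complete graph.

Median vectors are per-site majority consensi of node triplets.  At a
site where all three states differ no majority exists; the candidate
inherits the state of the lexicographically first member of the triplet.
Two construction paths share this median operation:

* small tables (few observed haplotypes): the full median closure of the
  observed haplotypes is generated, and an exact Steiner-tree dynamic
  program over that closure picks the median nodes that minimize total
  network length.  For binary characters the median closure provably
  contains every most-parsimonious tree, so the resulting length is the
  Steiner optimum.
* larger tables: iterative greedy augmentation — medians of linked
  triplets are added one per round when they strictly reduce the total
  spanning length, with degree-<3 unobserved nodes purged between
  rounds.  Total length is strictly decreasing, so the loop terminates.

Either way the final network is the MSN over the surviving node set with
observed frequencies attached; median nodes have frequency 0.

Internally vectors live as uint8 arrays over the segregating sites only
(constant sites cannot influence distances or medians); the public
surface speaks full-length residue strings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree as _scipy_mst

from .errors import NonConvergenceError
from .popgen_stats import HaplotypeTable


def hamming(a: str, b: str) -> int:
    """Count of positions at which two equal-length vectors differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        return 0
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return int((x != y).sum())


@dataclass
class HaplotypeNetwork:
    """Attributed haplotype graph with observed and inferred median nodes."""

    graph: nx.Graph
    epsilon: int = 0

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "median"]

    def total_length(self) -> int:
        """Sum of edge weights of a minimum spanning tree over the node set.

        The network itself may hold parallel minimal connections (union of
        MSTs), so length is measured on a spanning tree, which is what
        median addition shortens.
        """
        if self.graph.number_of_nodes() <= 1:
            return 0
        mst = nx.minimum_spanning_tree(self.graph, weight="weight")
        return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))

    def frequencies(self) -> dict[str, int]:
        return {n: d["frequency"] for n, d in self.graph.nodes(data=True)}


# ---------------------------------------------------------------- internals


def _encode(vectors: list[str]) -> np.ndarray:
    if not vectors:
        return np.zeros((0, 0), dtype=np.uint8)
    return np.frombuffer("".join(vectors).encode(), dtype=np.uint8).reshape(
        len(vectors), -1
    )


def _pairwise(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[0]
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        d[i] = (arr != arr[i]).sum(axis=1)
    return d


def _connection_costs(d: np.ndarray) -> np.ndarray:
    """sigma(i, j): distance class at which i and j first share a component."""
    n = d.shape[0]
    parent = np.arange(n)

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    sigma = np.zeros((n, n), dtype=int)
    done = np.eye(n, dtype=bool)
    for dist in np.unique(d[np.triu_indices(n, k=1)]):
        ii, jj = np.nonzero(np.triu(d == dist, k=1))
        for i, j in zip(ii, jj):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        roots = np.array([find(i) for i in range(n)])
        same = roots[:, None] == roots[None, :]
        newly = same & ~done
        sigma[newly] = dist
        done |= newly
        if done.all():
            break
    return sigma


def _msn_adj(d: np.ndarray, epsilon: int) -> np.ndarray:
    """Boolean adjacency of the epsilon-relaxed minimum spanning network."""
    n = d.shape[0]
    if n <= 1:
        return np.zeros((n, n), dtype=bool)
    adj = d <= _connection_costs(d) + epsilon
    np.fill_diagonal(adj, False)
    return adj


def _mst_length(d: np.ndarray) -> int:
    if d.shape[0] <= 1:
        return 0
    return int(round(_scipy_mst(d.astype(float)).sum()))


def _median_rows(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    first = min((u, v, w), key=lambda r: r.tobytes())
    return np.where((u == v) | (u == w), u, np.where(v == w, v, first))


def _purge(arr: np.ndarray, is_obs: np.ndarray, epsilon: int):
    """Drop median rows of MSN degree < 3, recomputing until stable."""
    while arr.shape[0] > 1:
        adj = _msn_adj(_pairwise(arr), epsilon)
        doomed = ~is_obs & (adj.sum(axis=0) < 3)
        if not doomed.any():
            break
        arr, is_obs = arr[~doomed], is_obs[~doomed]
    return arr, is_obs


def _sorted_rows(arr: np.ndarray, is_obs: np.ndarray):
    if arr.shape[0] <= 1 or arr.shape[1] == 0:
        return arr, is_obs
    order = np.lexsort(arr.T[::-1])
    return arr[order], is_obs[order]


def _median_closure(arr: np.ndarray, cap: int) -> np.ndarray | None:
    """All vectors reachable by iterated triplet medians; None above cap."""
    rows = {arr[i].tobytes(): arr[i] for i in range(arr.shape[0])}
    grew = True
    while grew:
        grew = False
        cur = list(rows.values())
        for i, j, k in itertools.combinations(range(len(cur)), 3):
            m = _median_rows(cur[i], cur[j], cur[k])
            key = m.tobytes()
            if key not in rows:
                rows[key] = m
                grew = True
                if len(rows) > cap:
                    return None
    keys = sorted(rows)
    return np.array([np.frombuffer(k, dtype=arr.dtype) for k in keys])


def _steiner_dw(verts: np.ndarray, term_idx: list[int]) -> tuple[int, set[int]]:
    """Exact minimal Steiner tree over a fixed vertex pool (Hamming metric)
    by the Dreyfus-Wagner dynamic program; returns (length, used vertices)."""
    d = _pairwise(verts).astype(np.int64)
    if len(term_idx) <= 1:
        return 0, set(term_idx)
    root, rest = term_idx[-1], term_idx[:-1]
    kk = len(rest)
    V = verts.shape[0]
    S: dict[int, np.ndarray] = {1 << i: d[rest[i]].copy() for i in range(kk)}
    M: dict[int, np.ndarray] = {}
    for size in range(2, kk + 1):
        for combo in itertools.combinations(range(kk), size):
            mask = sum(1 << i for i in combo)
            best = np.full(V, np.iinfo(np.int64).max // 4, dtype=np.int64)
            sub = (mask - 1) & mask
            while sub:
                other = mask ^ sub
                if sub <= other:
                    best = np.minimum(best, S[sub] + S[other])
                sub = (sub - 1) & mask
            M[mask] = best
            S[mask] = (d + best[None, :]).min(axis=1)
    full = (1 << kk) - 1
    length = int(S[full][root])

    used: set[int] = set(term_idx)

    def trace(mask: int, v: int) -> None:
        if mask.bit_count() == 1:
            used.add(rest[mask.bit_length() - 1])
            return
        u = int(np.argmin(d[v] + M[mask]))
        used.add(u)
        sub = (mask - 1) & mask
        while sub:
            other = mask ^ sub
            if sub <= other and S[sub][u] + S[other][u] == M[mask][u]:
                trace(sub, u)
                trace(other, u)
                return
            sub = (sub - 1) & mask
        raise AssertionError("Steiner traceback failed")

    trace(full, root)
    return length, used


# ------------------------------------------------------------------ public


def _build_network(
    full_vectors: list[str],
    meta: dict[str, dict],
    epsilon: int,
    seg_arr: np.ndarray | None = None,
) -> HaplotypeNetwork:
    g = nx.Graph()
    for v in full_vectors:
        attrs = dict(meta[v])
        node_id = attrs.pop("node_id")
        g.add_node(node_id, residues=v, **attrs)
    n = len(full_vectors)
    if n > 1:
        arr = seg_arr if seg_arr is not None else _encode(full_vectors)
        d = _pairwise(arr)
        adj = _msn_adj(d, epsilon)
        for i, j in zip(*np.nonzero(np.triu(adj, k=1))):
            g.add_edge(
                meta[full_vectors[i]]["node_id"],
                meta[full_vectors[j]]["node_id"],
                weight=int(d[i, j]),
            )
    return HaplotypeNetwork(g, epsilon=epsilon)


def minimum_spanning_network(table: HaplotypeTable, epsilon: int = 0) -> HaplotypeNetwork:
    """Epsilon-relaxed MSN over the observed haplotypes only."""
    meta = {
        res: {"node_id": hid, "kind": "observed", "frequency": count}
        for hid, res, _, count in table.haplotypes
    }
    return _build_network(list(meta), meta, epsilon)


def median_joining(
    table: HaplotypeTable,
    epsilon: int = 0,
    max_nodes_factor: int = 10,
    exact_max_haplotypes: int = 10,
    closure_cap: int = 512,
) -> HaplotypeNetwork:
    """Median-joining network over a haplotype table.

    Tables with at most ``exact_max_haplotypes`` observed haplotypes (and a
    median closure within ``closure_cap`` vectors) are solved exactly;
    larger tables use the greedy iterative augmentation, which raises
    :class:`NonConvergenceError` (partial network attached) if the node set
    grows past ``max_nodes_factor`` times the observed count.
    """
    observed_meta = {
        res: {"node_id": hid, "kind": "observed", "frequency": count}
        for hid, res, _, count in table.haplotypes
    }
    observed_full = sorted(observed_meta)
    n_obs = len(observed_full)

    full_arr = _encode(observed_full)
    seg = (
        np.nonzero((full_arr != full_arr[0]).any(axis=0))[0]
        if n_obs > 1
        else np.array([], dtype=int)
    )
    template = full_arr[0] if n_obs else None

    def restore(row: np.ndarray) -> str:
        full = template.copy()
        full[seg] = row
        return full.tobytes().decode()

    def finalize(arr: np.ndarray, is_obs: np.ndarray) -> HaplotypeNetwork:
        meta = dict(observed_meta)
        fulls = []
        k = 0
        for row, obs in zip(arr, is_obs):
            full = restore(row)
            fulls.append(full)
            if not obs:
                k += 1
                meta[full] = {"node_id": f"M{k}", "kind": "median", "frequency": 0}
        return _build_network(fulls, meta, epsilon, seg_arr=arr)

    arr = full_arr[:, seg]
    is_obs = np.ones(n_obs, dtype=bool)

    if n_obs <= 2 or table.analyzed_sites == 0 or seg.size == 0:
        return finalize(*_sorted_rows(arr, is_obs))

    if n_obs <= exact_max_haplotypes:
        pool = _median_closure(arr, closure_cap)
        if pool is not None:
            index = {pool[i].tobytes(): i for i in range(pool.shape[0])}
            term_idx = [index[arr[i].tobytes()] for i in range(n_obs)]
            _, used = _steiner_dw(pool, term_idx)
            node_idx = sorted(set(term_idx) | used)
            out = pool[node_idx]
            out_obs = np.array([i in set(term_idx) for i in node_idx])
            out, out_obs = _purge(out, out_obs, epsilon)
            return finalize(*_sorted_rows(out, out_obs))

    # greedy augmentation for large tables
    ceiling = max_nodes_factor * max(n_obs, 1)
    while True:
        arr, is_obs = _purge(arr, is_obs, epsilon)
        arr, is_obs = _sorted_rows(arr, is_obs)
        d = _pairwise(arr)
        adj = _msn_adj(d, epsilon)
        current = _mst_length(d)
        n = arr.shape[0]
        existing = {arr[i].tobytes() for i in range(n)}

        candidates: dict[bytes, np.ndarray] = {}
        for i, j in zip(*np.nonzero(np.triu(adj, k=1))):
            for k in range(n):
                if k == i or k == j:
                    continue
                m = _median_rows(arr[i], arr[j], arr[k])
                key = m.tobytes()
                if key not in existing and key not in candidates:
                    candidates[key] = m

        best_key, best_len = None, current
        ext = np.zeros((n + 1, n + 1), dtype=int)
        ext[:n, :n] = d
        for key in sorted(candidates):
            m = candidates[key]
            row = (arr != m).sum(axis=1)
            ext[n, :n] = row
            ext[:n, n] = row
            new_len = _mst_length(ext)
            if new_len < best_len:
                best_key, best_len = key, new_len
        if best_key is None:
            break
        arr = np.vstack([arr, candidates[best_key]])
        is_obs = np.append(is_obs, False)
        if arr.shape[0] > ceiling:
            p_arr, p_obs = _purge(arr, is_obs, epsilon)
            raise NonConvergenceError(
                f"median-joining node set exceeded {ceiling} nodes",
                partial=finalize(*_sorted_rows(p_arr, p_obs)),
            )

    arr, is_obs = _purge(arr, is_obs, epsilon)
    return finalize(*_sorted_rows(arr, is_obs))


def write_network(net: HaplotypeNetwork, path, format: str = "graphml") -> None:
    """Write the network as GraphML, GML, or a TSV edge list."""
    g = net.graph
    if format == "graphml":
        nx.write_graphml(g, str(path))
    elif format == "gml":
        nx.write_gml(g, str(path))
    elif format == "tsv-edgelist":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            for a, b, dat in g.edges(data=True):
                fh.write(f"{a}\t{b}\t{dat['weight']}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> HaplotypeNetwork:
    if format == "graphml":
        g = nx.read_graphml(str(path))
    elif format == "gml":
        g = nx.read_gml(str(path))
    else:
        raise ValueError(f"unknown network format {format!r}")
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    for _, _, dat in g.edges(data=True):
        dat["weight"] = int(dat["weight"])
    for _, dat in g.nodes(data=True):
        if "frequency" in dat:
            dat["frequency"] = int(dat["frequency"])
    return HaplotypeNetwork(g)
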