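"""Weighted protein networks: STRING-style edge lists, top-k pruning,
symmetric normalization with self-loops, and mini-batch neighborhoods.

The operative object is the normalized adjacency of graph convolution,
D̃^{-1/2} Ã D̃^{-1/2} with Ã = A + I, where A holds edge weights in (0, 1]
(STRING combined scores divided by 1000) and D̃ is the degree matrix of Ã.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)


class ProteinGraph:
    """Undirected weighted protein network with weights in (0, 1].

    Edges are stored once per unordered pair; no self-edges.
    """

    def __init__(self, nodes: Sequence[str], edges):
        self.nodes = list(nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.edges: dict[tuple, float] = {}
        for u, v, w in edges:
            if u == v:
                raise ValueError(f"self-edge on {u}")
            if not 0.0 < w <= 1.0:
                raise ValueError(f"edge weight {w} outside (0, 1]")
            if u not in self.index or v not in self.index:
                raise ValueError(f"edge endpoint not in node set: ({u}, {v})")
            key = (u, v) if u < v else (v, u)
            self.edges[key] = max(w, self.edges.get(key, 0.0))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, node: str) -> bool:
        return node in self.index

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric weighted adjacency A (zero diagonal)."""
        n = len(self.nodes)
        rows, cols, data = [], [], []
        for (u, v), w in self.edges.items():
            i, j = self.index[u], self.index[v]
            rows += [i, j]
            cols += [j, i]
            data += [w, w]
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def neighbors(self, node: str):
        """Iterate (neighbor, weight) pairs of ``node``."""
        for (u, v), w in self.edges.items():
            if u == node:
                yield v, w
            elif v == node:
                yield u, w


def load_string_edges(stream, nodes: Sequence[str] | None = None, score_scale: float = 1000.0) -> ProteinGraph:
    """Read a STRING-style TSV (protein1, protein2, combined score).

    Weights are score/score_scale clipped to (0, 1]; duplicate pairs keep the
    maximum weight; self-pairs and non-positive or non-numeric scores are
    dropped with a log message. When ``nodes`` is omitted the node set is the
    union of edge endpoints in first-appearance order.
    """
    raw = []
    seen_nodes: list[str] = []
    seen = set()
    n_dropped = 0
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.lower().startswith("protein1"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            n_dropped += 1
            continue
        u, v, score = parts[0], parts[1], parts[2]
        try:
            s = float(score)
        except ValueError:
            n_dropped += 1
            continue
        if s <= 0:
            n_dropped += 1
            continue
        if u == v:
            continue
        w = min(s / score_scale, 1.0)
        raw.append((u, v, w))
        for x in (u, v):
            if x not in seen:
                seen.add(x)
                seen_nodes.append(x)
    if n_dropped:
        logger.warning("dropped %d malformed/non-positive edge lines", n_dropped)
    return ProteinGraph(nodes if nodes is not None else seen_nodes, raw)


def top_k_prune(graph: ProteinGraph, k: int) -> ProteinGraph:
    """Keep edge (i, j) iff it is among the k heaviest edges of i OR of j.

    The union rule preserves symmetry; ties are broken by lexicographic
    neighbor identifier. Surviving edges keep their original weights.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    incident: dict[str, list] = {n: [] for n in graph.nodes}
    for (u, v), w in graph.edges.items():
        incident[u].append((w, v, (u, v)))
        incident[v].append((w, u, (u, v)))
    keep = set()
    for node, lst in incident.items():
        # heaviest first; lexicographically smaller neighbor wins ties
        lst.sort(key=lambda t: (-t[0], t[1]))
        keep.update(key for _, _, key in lst[:k])
    return ProteinGraph(graph.nodes, [(u, v, graph.edges[(u, v)]) for u, v in keep])


class NormalizedAdjacency:
    """The symmetrically normalized adjacency Â = D̃^{-1/2} (A+I) D̃^{-1/2}."""

    def __init__(self, nodes: Sequence[str], matrix: sparse.csr_matrix):
        self.nodes = list(nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.matrix = matrix.tocsr()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def normalized_adjacency(graph: ProteinGraph) -> NormalizedAdjacency:
    """Compute Â with unit self-loops: Â_ij = Ã_ij / sqrt(D̃_ii D̃_jj).

    An isolated node has D̃_ii = 1 (self-loop only), which is valid.
    """
    a = graph.adjacency().tolil()
    a.setdiag(1.0)
    a = a.tocsr()
    deg = np.asarray(a.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(deg)
    d = sparse.diags(inv_sqrt)
    return NormalizedAdjacency(graph.nodes, (d @ a @ d).tocsr())


@dataclass
class BatchSubgraph:
    """A seed set plus its M-hop neighborhood with the restricted Â.

    The local matrix is the global normalized adjacency restricted to the
    included rows/columns (no renormalization), so an M-layer forward pass on
    the subgraph reproduces the full-graph forward pass exactly on seed rows.
    """

    seeds: list
    included: list
    local_matrix: sparse.csr_matrix
    global_indices: np.ndarray  # local position -> global node index
    seed_positions: np.ndarray  # positions of seeds within `included`


def batch_neighborhood(normalized: NormalizedAdjacency, seeds: Sequence[str], hops: int) -> BatchSubgraph:
    """Seeds plus all nodes reachable within ``hops`` nonzero entries of Â."""
    for s in seeds:
        if s not in normalized.index:
            raise KeyError(f"unknown seed node {s}")
    mat = normalized.matrix
    frontier = np.array(sorted(normalized.index[s] for s in seeds), dtype=np.int64)
    included = set(frontier.tolist())
    current = frontier
    for _ in range(hops):
        if current.size == 0:
            break
        nbrs = set(mat[current].indices.tolist()) - included
        included |= nbrs
        current = np.fromiter(nbrs, dtype=np.int64) if nbrs else np.array([], dtype=np.int64)
    global_idx = np.array(sorted(included), dtype=np.int64)
    local = mat[global_idx][:, global_idx].tocsr()
    pos = {g: l for l, g in enumerate(global_idx)}
    seed_pos = np.array([pos[normalized.index[s]] for s in seeds], dtype=np.int64)
    return BatchSubgraph(
        seeds=list(seeds),
        included=[normalized.nodes[g] for g in global_idx],
        local_matrix=local,
        global_indices=global_idx,
        seed_positions=seed_pos,
    )


def write_string_edges(graph: ProteinGraph, stream, score_scale: float = 1000.0):
    stream.write("protein1\tprotein2\tcombined_score\n")
    for (u, v), w in sorted(graph.edges.items()):
        stream.write(f"{u}\t{v}\t{int(round(w * score_scale))}\n")
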