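"""Pair-node graphs: turning link prediction into node classification.

Every candidate lncRNA-disease pair becomes one node ``PN(L, D)``. Two
graphs are laid over the same node set:

* the **interconnected graph (CG)**: an edge joins two pair nodes iff they
  share the lncRNA or the disease — pure bipartite topology;
* the **association feature graph (RFG)**: each node is joined to its k
  most cosine-similar nodes in concatenated-feature space
  ``F(PN) = [emb_L || emb_D]``, union-symmetrized.

Neither construction looks at labels, so test pairs can sit in the graphs
transductively while their labels stay held out. Self-loops are not stored;
the GCN normalization adds them once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from lncgraph.types import EmbeddingMatrix

Pair = tuple[str, str]

UNLABELED = -1


@dataclass
class PairNodeSet:
    """Ordered pair nodes with optional labels (1 / 0 / -1 for unlabeled)."""

    pairs: list[Pair]
    labels: np.ndarray  # int8, UNLABELED for candidates

    def validate(self) -> "PairNodeSet":
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pair nodes")
        if len(self.labels) != len(self.pairs):
            raise ValueError("one label slot per pair required")
        return self

    @property
    def index(self) -> dict[Pair, int]:
        return {p: i for i, p in enumerate(self.pairs)}

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.labels != UNLABELED


@dataclass
class PairGraph:
    node_set: PairNodeSet
    adjacency: sp.csr_matrix  # symmetric, no self-loops
    kind: str  # "CG" | "RFG"
    k_neighbors: int | None = None

    def validate(self) -> "PairGraph":
        a = self.adjacency
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.node_set):
            raise ValueError("adjacency must be square over the node set")
        if a.diagonal().any():
            raise ValueError("self-loops must not be stored")
        if (a != a.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        return self


def make_pair_nodes(
    positives: Iterable[Pair],
    negatives: Iterable[Pair],
    candidates: Iterable[Pair] = (),
) -> PairNodeSet:
    """Assemble the pair-node universe: positives, negatives, then unlabeled
    candidates, each block in lexicographic order."""
    pos = sorted(set(positives))
    neg = sorted(set(negatives))
    overlap = set(pos) & set(neg)
    if overlap:
        raise ValueError(f"pairs appear as both positive and negative: {sorted(overlap)[:5]}")
    labeled = set(pos) | set(neg)
    cand = sorted(set(candidates) - labeled)
    pairs = pos + neg + cand
    labels = np.concatenate(
        [
            np.ones(len(pos), dtype=np.int8),
            np.zeros(len(neg), dtype=np.int8),
            np.full(len(cand), UNLABELED, dtype=np.int8),
        ]
    )
    return PairNodeSet(pairs, labels).validate()


def build_interconnected_graph(nodes: PairNodeSet) -> PairGraph:
    """CG: edge iff two distinct pair nodes share a lncRNA or a disease."""
    if len(nodes) < 1:
        raise ValueError("at least one pair node required")
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for key in (0, 1):  # group by shared lncRNA, then by shared disease
        groups: dict[str, list[int]] = {}
        for i, pair in enumerate(nodes.pairs):
            groups.setdefault(pair[key], []).append(i)
        for members in groups.values():
            if len(members) < 2:
                continue
            m = np.asarray(members)
            r, c = np.meshgrid(m, m, indexing="ij")
            keep = r != c
            rows.append(r[keep])
            cols.append(c[keep])
    n = len(nodes)
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        adj = sp.csr_matrix((np.ones(len(r)), (r, c)), shape=(n, n))
        adj.data[:] = 1.0  # pairs sharing both entities are impossible, but be safe
    else:
        adj = sp.csr_matrix((n, n))
    return PairGraph(nodes, adj, kind="CG").validate()


def pair_features(
    nodes: PairNodeSet,
    lncrna_emb: EmbeddingMatrix,
    disease_emb: EmbeddingMatrix,
) -> np.ndarray:
    """Pair-node features: ``[emb_L || emb_D]`` per pair, nodes x (dl + dd)."""
    l_index = {e: i for i, e in enumerate(lncrna_emb.entity_ids)}
    d_index = {e: i for i, e in enumerate(disease_emb.entity_ids)}
    missing_l = sorted({l for l, _ in nodes.pairs} - set(l_index))
    missing_d = sorted({d for _, d in nodes.pairs} - set(d_index))
    if missing_l or missing_d:
        raise KeyError(
            f"missing embeddings for lncRNAs {missing_l[:5]} / diseases {missing_d[:5]}"
        )
    li = np.asarray([l_index[l] for l, _ in nodes.pairs])
    di = np.asarray([d_index[d] for _, d in nodes.pairs])
    return np.concatenate([lncrna_emb.vectors[li], disease_emb.vectors[di]], axis=1)


def cosine_matrix(features: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(features, axis=1)
    if (norms == 0).any():
        bad = np.flatnonzero(norms == 0)[:5].tolist()
        raise ValueError(f"zero-norm feature vectors at node indices {bad}")
    unit = features / norms[:, None]
    return unit @ unit.T


def build_feature_graph(
    nodes: PairNodeSet, features: np.ndarray, k_neighbors: int = 5
) -> PairGraph:
    """RFG: connect each node to its k most cosine-similar other nodes.

    Ties are broken by ascending node index; the directed k-NN selection is
    union-symmetrized, so every node ends with degree >= k (non-degenerate
    feature sets).
    """
    n = len(nodes)
    if features.shape[0] != n:
        raise ValueError("one feature row per pair node required")
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors ({k_neighbors}) must be < node count ({n})")
    S = cosine_matrix(features)
    np.fill_diagonal(S, -np.inf)
    rows, cols = [], []
    order_idx = np.arange(n)
    for i in range(n):
        # sort by similarity desc, then node index asc (deterministic ties)
        order = np.lexsort((order_idx, -S[i]))
        neigh = order[:k_neighbors]
        rows.append(np.full(k_neighbors, i))
        cols.append(neigh)
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    adj = sp.csr_matrix((np.ones(len(r)), (r, c)), shape=(n, n))
    adj = adj.maximum(adj.T)  # union symmetrization
    adj.data[:] = 1.0
    return PairGraph(nodes, adj, kind="RFG", k_neighbors=k_neighbors).validate()


def normalized_adjacency(graph: PairGraph) -> sp.csr_matrix:
    """Symmetric GCN normalization with self-loops: D^-1/2 (A + I) D^-1/2."""
    n = graph.adjacency.shape[0]
    a_hat = graph.adjacency + sp.eye(n, format="csr")
    deg = np.asarray(a_hat.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return sp.csr_matrix(D @ a_hat @ D)


def edge_list_with_self_loops(graph: PairGraph) -> tuple[np.ndarray, np.ndarray]:
    """(src, dst) arrays for attention message passing; N(i) includes i."""
    coo = (graph.adjacency + sp.eye(graph.adjacency.shape[0], format="csr")).tocoo()
    order = np.lexsort((coo.col, coo.row))
    return coo.col[order], coo.row[order]  # src = neighbor j, dst = target i
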