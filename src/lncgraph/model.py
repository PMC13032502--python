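"""The neural core: hybrid GCN-GAT encoder, attention fusion, MLP head.

Both pair-node graphs are encoded by a GCN-GAT-GCN stack:

    H1 = ReLU(D^-1/2 (A+I) D^-1/2  H0 W1)          (graph convolution)
    H2 = ELU(sum_{j in N(i)} alpha_ij W2 h_j)      (graph attention)
    H3 = ReLU(D^-1/2 (A+I) D^-1/2  H2 W3)
    F  = H1 (+) H3                                 (skip concatenation, K-dim)

Attention logits follow the standard GAT form
``LeakyReLU(a_src . W h_i + a_dst . W h_j)`` softmax-normalized over the
self-inclusive neighborhood N(i). The per-view representations F_CG and
F_RFG are fused per node by a softmax attention over view scores
``w_view = q . tanh(W_f F_view^T + b)``, and an MLP with a sigmoid output
turns the fused representation into an association probability.

Ablation variants rewire this graph: ``gcn`` drops the attention layer
(GCN-GCN), ``gat`` drops the convolutions (GAT-GAT), ``noatt`` replaces the
learned fusion by an element-wise mean, ``cg``/``rfg`` encode a single view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from lncgraph import autodiff as ad
from lncgraph.autodiff import Tensor
from lncgraph.config import ModelConfig
from lncgraph.pairs import PairGraph, edge_list_with_self_loops, normalized_adjacency


@dataclass
class GraphTensor:
    """Precomputed propagation operators for one pair graph.

    ``gather_src``/``gather_dst`` (E x n) select endpoint rows per edge and
    ``scatter_dst`` (n x E) sums edge rows into destination nodes; keeping
    them as sparse matrices makes edge-wise message passing a pair of sparse
    products instead of slow fancy-indexing loops.
    """

    norm_adjacency: sp.csr_matrix        # D^-1/2 (A+I) D^-1/2
    edges: tuple[np.ndarray, np.ndarray]  # (src, dst) incl. self-loops
    node_count: int
    gather_src: sp.csr_matrix = None
    gather_dst: sp.csr_matrix = None
    scatter_dst: sp.csr_matrix = None

    @classmethod
    def from_graph(cls, graph: PairGraph) -> "GraphTensor":
        src, dst = edge_list_with_self_loops(graph)
        n = len(graph.node_set)
        n_edges = len(src)
        ones = np.ones(n_edges)
        rows = np.arange(n_edges)
        g_src = sp.csr_matrix((ones, (rows, src)), shape=(n_edges, n))
        g_dst = sp.csr_matrix((ones, (rows, dst)), shape=(n_edges, n))
        return cls(
            norm_adjacency=normalized_adjacency(graph),
            edges=(src, dst),
            node_count=n,
            gather_src=g_src,
            gather_dst=g_dst,
            scatter_dst=sp.csr_matrix(g_dst.T),
        )


def gcn_layer(
    H: Tensor, graph: GraphTensor, weights: Tensor, activation=ad.relu
) -> Tensor:
    """One graph-convolution step ``act(D^-1/2 (A+I) D^-1/2 H W)``."""
    return activation(ad.spmm(graph.norm_adjacency, H) @ weights)


def gat_layer(
    H: Tensor,
    graph: GraphTensor,
    weights: Tensor,
    attn_src: Tensor,
    attn_dst: Tensor,
    activation=ad.elu,
) -> tuple[Tensor, Tensor]:
    """One graph-attention step; returns (output, per-edge alpha).

    Attention coefficients are softmax-normalized over each node's
    self-inclusive neighborhood, so they sum to 1 per node. The softmax is
    shifted by the per-neighborhood maximum logit for numerical stability
    (an exact transformation).
    """
    src, dst = graph.edges
    n = graph.node_count
    Hw = H @ weights
    h_src = ad.spmm(graph.gather_src, Hw)
    h_dst = ad.spmm(graph.gather_dst, Hw)
    logits = ad.leaky_relu(h_src @ attn_src + h_dst @ attn_dst, alpha=0.2)
    seg_max = np.full(n, -np.inf)
    np.maximum.at(seg_max, dst, logits.value.ravel())
    shifted = logits - Tensor(seg_max[dst][:, None])
    ex = ad.exp(shifted)
    denom = ad.spmm(graph.scatter_dst, ex)
    alpha = ex / ad.spmm(graph.gather_dst, denom)
    messages = alpha * h_src
    out = ad.spmm(graph.scatter_dst, messages)
    return activation(out), alpha


def attention_scores(alpha: Tensor, dst: np.ndarray, n: int) -> np.ndarray:
    """Per-node sums of attention coefficients (should be 1 by construction)."""
    sums = np.zeros(n)
    np.add.at(sums, dst, alpha.value.ravel())
    return sums


class PairModel:
    """Learnable state of the full stack for one ablation variant."""

    SINGLE_VIEW = {"cg": "CG", "rfg": "RFG"}

    def __init__(self, in_dim: int, config: ModelConfig, variant: str = "full", seed: int = 0):
        self.config = config
        self.variant = variant
        self.in_dim = in_dim
        rng = np.random.default_rng(seed)
        h1, hg, h3 = config.gcn1_dim, config.gat_dim, config.gcn3_dim
        self.K = h1 + h3
        views = ("CG",) if variant == "cg" else ("RFG",) if variant == "rfg" else ("CG", "RFG")
        self.views = views
        self.params: dict[str, Tensor] = {}

        def add(name: str, t: Tensor) -> Tensor:
            self.params[name] = t
            return t

        for v in views:
            if variant == "gcn":
                add(f"{v}.W1", ad.glorot(rng, in_dim, h1))
                add(f"{v}.W3", ad.glorot(rng, h1, h3))
            elif variant == "gat":
                add(f"{v}.W1", ad.glorot(rng, in_dim, h1))
                add(f"{v}.a1_src", ad.glorot(rng, h1, 1, shape=(h1, 1)))
                add(f"{v}.a1_dst", ad.glorot(rng, h1, 1, shape=(h1, 1)))
                add(f"{v}.W3", ad.glorot(rng, h1, h3))
                add(f"{v}.a3_src", ad.glorot(rng, h3, 1, shape=(h3, 1)))
                add(f"{v}.a3_dst", ad.glorot(rng, h3, 1, shape=(h3, 1)))
            else:  # full / noatt / cg / rfg / rwr-features
                add(f"{v}.W1", ad.glorot(rng, in_dim, h1))
                add(f"{v}.W2", ad.glorot(rng, h1, hg))
                add(f"{v}.a_src", ad.glorot(rng, hg, 1, shape=(hg, 1)))
                add(f"{v}.a_dst", ad.glorot(rng, hg, 1, shape=(hg, 1)))
                add(f"{v}.W3", ad.glorot(rng, hg, h3))
        if len(views) == 2 and variant not in ("noatt",):
            dl = config.attention_dim
            add("fuse.W", ad.glorot(rng, dl, self.K, shape=(dl, self.K)))
            add("fuse.b", ad.zeros((dl, 1)))
            add("fuse.q", ad.glorot(rng, dl, 1, shape=(dl, 1)))
        dims = [self.K] + list(config.mlp_hidden) + [1]
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            add(f"mlp.W{i}", ad.glorot(rng, a, b))
            add(f"mlp.b{i}", ad.zeros((1, b)))
        self.n_mlp = len(dims) - 1

    # -- forward pieces --------------------------------------------------
    def _dropout(self, H: Tensor, training: bool, rng: np.random.Generator | None) -> Tensor:
        p = self.config.dropout
        if not training or p == 0 or rng is None:
            return H
        mask = (rng.random(H.shape) >= p) / (1.0 - p)
        return H * Tensor(mask)

    def encode_view(
        self,
        view: str,
        X: Tensor,
        graph: GraphTensor,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Per-view representation F = H1 (+) H_last, K-dimensional per node."""
        P = self.params
        H0 = self._dropout(X, training, rng)
        if self.variant == "gcn":
            H1 = gcn_layer(H0, graph, P[f"{view}.W1"])
            H3 = gcn_layer(self._dropout(H1, training, rng), graph, P[f"{view}.W3"])
        elif self.variant == "gat":
            H1, _ = gat_layer(H0, graph, P[f"{view}.W1"], P[f"{view}.a1_src"], P[f"{view}.a1_dst"])
            H3, _ = gat_layer(
                self._dropout(H1, training, rng),
                graph, P[f"{view}.W3"], P[f"{view}.a3_src"], P[f"{view}.a3_dst"],
            )
        else:
            H1 = gcn_layer(H0, graph, P[f"{view}.W1"])
            H2, _ = gat_layer(
                self._dropout(H1, training, rng),
                graph, P[f"{view}.W2"], P[f"{view}.a_src"], P[f"{view}.a_dst"],
            )
            H3 = gcn_layer(self._dropout(H2, training, rng), graph, P[f"{view}.W3"])
        return ad.concat([H1, H3], axis=1)

    def attention_fuse(self, H_cg: Tensor, H_rfg: Tensor) -> tuple[Tensor, np.ndarray]:
        """Softmax attention over the two views; returns (fused, alphas n x 2)."""
        P = self.params
        W, b, q = P["fuse.W"], P["fuse.b"], P["fuse.q"]

        def score(H: Tensor) -> Tensor:
            # w_i = q^T tanh(W H_i^T + b), computed for all nodes at once
            return ad.tanh(H @ _transpose_param(W) + _transpose_param(b)) @ q  # (n,1)

        w_cg, w_rfg = score(H_cg), score(H_rfg)
        shift = Tensor(np.maximum(w_cg.value, w_rfg.value))
        e_cg, e_rfg = ad.exp(w_cg - shift), ad.exp(w_rfg - shift)
        denom = e_cg + e_rfg
        a_cg, a_rfg = e_cg / denom, e_rfg / denom
        fused = H_cg * a_cg + H_rfg * a_rfg
        alphas = np.concatenate([a_cg.value, a_rfg.value], axis=1)
        return fused, alphas

    def mlp_logits(
        self, H: Tensor, training: bool = False, rng: np.random.Generator | None = None
    ) -> Tensor:
        P = self.params
        out = H
        for i in range(self.n_mlp):
            out = self._dropout(out, training, rng) if i > 0 else out
            out = out @ P[f"mlp.W{i}"] + P[f"mlp.b{i}"]
            if i < self.n_mlp - 1:
                out = ad.relu(out)
        return out

    def forward(
        self,
        features: np.ndarray,
        cg: GraphTensor | None,
        rfg: GraphTensor | None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, np.ndarray | None]:
        """Full forward pass; returns (logits (n,1), per-node view alphas).

        ``alphas`` is None for single-view and mean-fused (noatt) variants.
        """
        X = Tensor(np.asarray(features, dtype=np.float64))
        graphs = {"CG": cg, "RFG": rfg}
        reps: dict[str, Tensor] = {}
        for v in self.views:
            if graphs[v] is None:
                raise ValueError(f"variant {self.variant!r} requires the {v} graph")
            reps[v] = self.encode_view(v, X, graphs[v], training, rng)
        alphas: np.ndarray | None = None
        if len(self.views) == 1:
            fused = reps[self.views[0]]
        elif self.variant == "noatt":
            fused = (reps["CG"] + reps["RFG"]) * 0.5
        else:
            fused, alphas = self.attention_fuse(reps["CG"], reps["RFG"])
        logits = self.mlp_logits(fused, training, rng)
        return logits, alphas

    def predict(
        self,
        features: np.ndarray,
        cg: GraphTensor | None,
        rfg: GraphTensor | None,
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Inference scores in (0, 1) plus the attention report."""
        logits, alphas = self.forward(features, cg, rfg, training=False)
        return ad.sigmoid(logits).value.ravel(), alphas

    # -- state handling --------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def state_values(self) -> dict[str, np.ndarray]:
        return {k: v.value.copy() for k, v in self.params.items()}

    def load_state_values(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].value = v.copy()


def _transpose_param(t: Tensor) -> Tensor:
    """View a parameter transposed while keeping gradients flowing."""
    out = Tensor(t.value.T, parents=(t,))
    out._backward = lambda g: t._accumulate(g.T)
    return out
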