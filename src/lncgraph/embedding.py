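"""Network diffusion features and their autoencoder compression.

Each similarity network is turned into a column-stochastic transition matrix
W; random walk with restart (RWR) iterates ``r = c W r + (1 - c) e`` to a
fixed point per seed node, giving a diffusion profile that scores the
proximity of every node to the seed. Profiles are concatenated across views
(entities x n_views * n_entities) and compressed with a single-hidden-layer
denoising autoencoder (masking corruption, MSE reconstruction) whose encoder
output is the final feature vector. The c constant weights the walk term,
matching the printed recurrence; the restart weight is 1 - c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lncgraph import autodiff as ad
from lncgraph.config import DaeConfig, RwrConfig
from lncgraph.types import EmbeddingMatrix, SimilarityMatrix


@dataclass
class TransitionMatrix:
    entity_ids: list[str]
    values: np.ndarray  # column-stochastic

    def validate(self, atol: float = 1e-10) -> "TransitionMatrix":
        if (self.values < 0).any():
            raise ValueError("transition matrix must be non-negative")
        if np.abs(self.values.sum(axis=0) - 1.0).max() > atol:
            raise ValueError("transition matrix columns must sum to 1")
        return self


@dataclass
class DiffusionProfile:
    seed_id: str
    r: np.ndarray
    iterations_used: int
    residual: float


class RwrConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iterations: int):
        super().__init__(
            f"RWR did not converge within {max_iterations} iterations "
            f"(L1 residual {residual:.3e})"
        )
        self.residual = residual


def to_transition(similarity: SimilarityMatrix) -> TransitionMatrix:
    """Column-normalize a similarity matrix; zero columns become uniform."""
    values = np.asarray(similarity.values, dtype=np.float64)
    if (values < 0).any():
        raise ValueError("similarity must be non-negative")
    col_sums = values.sum(axis=0)
    n = values.shape[0]
    W = np.where(col_sums > 0, values / np.where(col_sums > 0, col_sums, 1.0), 1.0 / n)
    return TransitionMatrix(list(similarity.entity_ids), W).validate()


def rwr(W: TransitionMatrix, seed_id: str, config: RwrConfig | None = None) -> DiffusionProfile:
    """Iterate ``r = c W r + (1 - c) e`` from the seed's indicator vector."""
    config = config or RwrConfig()
    try:
        idx = W.entity_ids.index(seed_id)
    except ValueError as exc:
        raise KeyError(f"seed {seed_id!r} not in network") from exc
    e = np.zeros(len(W.entity_ids))
    e[idx] = 1.0
    r = e.copy()
    c = config.c
    for it in range(1, config.max_iterations + 1):
        r_next = c * (W.values @ r) + (1 - c) * e
        residual = float(np.abs(r_next - r).sum())
        r = r_next
        if residual <= config.tolerance:
            return DiffusionProfile(seed_id, r, it, residual)
    raise RwrConvergenceError(residual, config.max_iterations)


def rwr_solve(W: TransitionMatrix, seed_id: str, config: RwrConfig | None = None) -> np.ndarray:
    """Closed-form RWR fixed point ``(1 - c)(I - c W)^-1 e`` (oracle route)."""
    config = config or RwrConfig()
    idx = W.entity_ids.index(seed_id)
    n = len(W.entity_ids)
    e = np.zeros(n)
    e[idx] = 1.0
    return (1 - config.c) * np.linalg.solve(np.eye(n) - config.c * W.values, e)


def _rwr_all_seeds(W: TransitionMatrix, config: RwrConfig) -> np.ndarray:
    """All-seed RWR in one matrix iteration: column j is the profile of seed j."""
    n = len(W.entity_ids)
    E = np.eye(n)
    R = E.copy()
    c = config.c
    for _ in range(config.max_iterations):
        R_next = c * (W.values @ R) + (1 - c) * E
        residual = float(np.abs(R_next - R).sum(axis=0).max())
        R = R_next
        if residual <= config.tolerance:
            return R
    raise RwrConvergenceError(residual, config.max_iterations)


def diffusion_features(
    similarities: dict[str, SimilarityMatrix],
    config: RwrConfig | None = None,
) -> EmbeddingMatrix:
    """Concatenate per-view RWR profiles into raw entity features.

    Every view must share the same entity set; the feature row of entity i
    is the concatenation over views (in sorted view order) of its diffusion
    profile, giving entities x (n_views * n_entities) raw embeddings.
    """
    config = config or RwrConfig()
    if not similarities:
        raise ValueError("at least one similarity view required")
    views = sorted(similarities)
    ids = similarities[views[0]].entity_ids
    blocks = []
    for view in views:
        sim = similarities[view]
        if sim.entity_ids != ids:
            raise ValueError(f"entity set of view {view!r} differs from the others")
        R = _rwr_all_seeds(to_transition(sim), config)
        blocks.append(R.T)  # row i = profile with seed i
    return EmbeddingMatrix(list(ids), np.concatenate(blocks, axis=1), "raw-rwr").validate()


def train_dae(
    X: np.ndarray, config: DaeConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Train a denoising autoencoder; return (W1, b1) encoder and loss curve.

    Architecture: masking corruption -> linear+ReLU encoder -> linear
    decoder -> MSE against the uncorrupted input. Full-batch Adam. Fully
    deterministic given the seed.
    """
    n, d = X.shape
    if config.hidden_dim >= d:
        raise ValueError(f"hidden_dim ({config.hidden_dim}) must be < input dim ({d})")
    rng = np.random.default_rng(seed)
    h = config.hidden_dim
    W1 = ad.glorot(rng, d, h)
    b1 = ad.zeros((1, h))
    W2 = ad.glorot(rng, h, d)
    b2 = ad.zeros((1, d))
    params = [W1, b1, W2, b2]
    opt = ad.Adam(params, lr=config.learning_rate)
    losses: list[float] = []
    for _ in range(config.epochs):
        if config.corruption > 0:
            mask = rng.random(X.shape) >= config.corruption
            corrupted = X * mask
        else:
            corrupted = X
        xin = ad.Tensor(corrupted)
        hidden = ad.relu(xin @ W1 + b1)
        recon = hidden @ W2 + b2
        diff = recon - ad.Tensor(X)
        loss = ad.mean(diff * diff)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.value))
    return W1.value, b1.value, losses


def dae_compress(
    raw: EmbeddingMatrix, config: DaeConfig, seed: int = 0
) -> EmbeddingMatrix:
    """Compress raw diffusion features through a trained DAE encoder."""
    raw.validate()
    W1, b1, _ = train_dae(raw.vectors, config, seed)
    hidden = np.maximum(raw.vectors @ W1 + b1, 0.0)
    return EmbeddingMatrix(list(raw.entity_ids), hidden, "dae").validate()


def rwr_only_features(
    similarities: dict[str, SimilarityMatrix],
    rwr_config: RwrConfig | None = None,
    truncate_dim: int | None = None,
) -> EmbeddingMatrix:
    """Raw RWR features without autoencoder compression.

    When ``truncate_dim`` is given, the concatenated profiles are reduced to
    that dimension by a deterministic truncated SVD (sign fixed so each
    component's largest-magnitude loading is positive) so the downstream
    model sees the same input width as in the compressed route.
    """
    raw = diffusion_features(similarities, rwr_config)
    if truncate_dim is None or truncate_dim >= raw.vectors.shape[1]:
        return raw
    U, s, Vt = np.linalg.svd(raw.vectors, full_matrices=False)
    k = truncate_dim
    signs = np.sign(Vt[np.arange(len(s)), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    reduced = (U[:, :k] * s[:k]) * signs[:k]
    return EmbeddingMatrix(list(raw.entity_ids), reduced, "raw-rwr").validate()
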