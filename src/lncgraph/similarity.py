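"""Entity-entity similarity networks.

Three families of similarity feed the pipeline:

* the **Gaussian interaction profile (GIP) kernel** over binary association
  profiles, ``GIP(i, j) = exp(-||A_i - A_j||^2 / sigma^2)``. The bandwidth
  sigma is either fixed or, by default, profile-normalized:
  ``sigma^2 = mean_i ||A_i||^2`` (the usual GIP convention, scale-free
  across datasets of different density);
* **Jaccard similarity** over shared omic partner sets,
  ``|P_i & P_j| / |P_i | P_j|``, with the empty-vs-empty case defined as 0;
* a **semantic similarity** between diseases. Dedicated semantic measures
  that integrate functional networks are dataset products and arrive here as
  a precomputed matrix; the built-in stand-in is the ancestor-set Jaccard on
  the IS_A ontology (each term counts itself among its ancestors), which is
  1 on the diagonal and monotone in shared-ancestor depth. Min-max
  normalization of the off-diagonal is applied to the semantic matrix.
"""

from __future__ import annotations

import numpy as np

from lncgraph.config import RunConfig, SimilarityConfig
from lncgraph.types import (
    DISEASE_VIEWS,
    LNCRNA_VIEWS,
    Bundle,
    OmicLinkTable,
    OntologyTable,
    SimilarityMatrix,
)


def gip_kernel(
    profiles: np.ndarray,
    entity_ids: list[str],
    bandwidth_mode: str = "profile-normalized",
    sigma: float = 1.0,
    source_view: str = "gip",
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over binary profile rows.

    Parameters
    ----------
    profiles
        Binary matrix, one interaction profile per entity row.
    bandwidth_mode
        ``"fixed"`` uses ``sigma`` as given; ``"profile-normalized"`` sets
        ``sigma^2`` to the mean squared profile norm.
    """
    profiles = np.asarray(profiles, dtype=np.float64)
    if profiles.shape[0] != len(entity_ids):
        raise ValueError("one profile row per entity required")
    if profiles.shape[0] < 2:
        raise ValueError("GIP kernel needs at least two entities")
    if bandwidth_mode == "profile-normalized":
        sigma_sq = float((profiles**2).sum(axis=1).mean())
        if sigma_sq == 0.0:
            raise ValueError("all interaction profiles are empty; bandwidth undefined")
    elif bandwidth_mode == "fixed":
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        sigma_sq = float(sigma) ** 2
    else:
        raise ValueError(f"unknown bandwidth_mode {bandwidth_mode!r}")
    # ||x - y||^2 = ||x||^2 + ||y||^2 - 2 x.y, computed via one Gram matrix
    sq = (profiles**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (profiles @ profiles.T)
    d2 = np.maximum(d2, 0.0)
    values = np.exp(-d2 / sigma_sq)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(entity_ids), values, source_view).validate()


def jaccard_similarity(links: OmicLinkTable) -> SimilarityMatrix:
    """Jaccard similarity of partner sets; two empty sets score 0."""
    links.validate()
    m = links.links.astype(np.float64)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, np.where(sizes > 0, 1.0, 0.0))
    return SimilarityMatrix(
        list(links.left_ids), values, source_view=f"jaccard_{links.view_name}"
    ).validate()


def semantic_similarity_standin(
    ontology: OntologyTable, diseases: list[str]
) -> SimilarityMatrix:
    """Ancestor-set Jaccard on the IS_A DAG (diseases must be ontology terms).

    Each term's ancestor set includes the term itself, so the diagonal is 1
    and siblings (deep shared ancestry) score above cousins (shallow shared
    ancestry).
    """
    missing = sorted(set(diseases) - ontology.nodes)
    if missing:
        raise ValueError(f"diseases absent from ontology: {missing}")
    diseases = sorted(diseases)
    ancestor_sets = [ontology.ancestors(d) for d in diseases]
    n = len(diseases)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ancestor_sets[i], ancestor_sets[j]
            values[i, j] = values[j, i] = len(a & b) / len(a | b)
    return SimilarityMatrix(diseases, values, source_view="semantic").validate()


def minmax_normalize(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Affinely rescale off-diagonal values to [0, 1]; diagonal reset to 1.

    A constant off-diagonal (degenerate range) maps to all zeros rather than
    dividing by zero.
    """
    values = np.asarray(sim.values, dtype=np.float64).copy()
    n = values.shape[0]
    off = ~np.eye(n, dtype=bool)
    if n > 1:
        lo, hi = values[off].min(), values[off].max()
        if hi > lo:
            values[off] = (values[off] - lo) / (hi - lo)
        else:
            values[off] = 0.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(sim.entity_ids), values, sim.source_view).validate()


def build_all_similarities(
    bundle: Bundle, config: RunConfig | SimilarityConfig
) -> dict[str, SimilarityMatrix]:
    """Build every enabled similarity view for both entity sides.

    Returns a map with lncRNA views ``gip``, ``jaccard_lncrna_*`` and
    disease views ``semantic``, ``jaccard_disease_*``, honoring the per-view
    inclusion flags (the hook used by leave-one-omic-out analyses).
    """
    sim_cfg = config.similarity if isinstance(config, RunConfig) else config
    out: dict[str, SimilarityMatrix] = {}
    A = bundle.associations
    out["gip"] = gip_kernel(
        A.values, A.lncrna_ids, sim_cfg.bandwidth_mode, sim_cfg.sigma, source_view="gip"
    )
    if sim_cfg.disease_gip:
        out["gip_disease"] = gip_kernel(
            A.values.T, A.disease_ids, sim_cfg.bandwidth_mode, sim_cfg.sigma,
            source_view="gip_disease",
        )
    for view in LNCRNA_VIEWS + DISEASE_VIEWS:
        if not sim_cfg.views.get(view, True):
            continue
        if view not in bundle.links:
            raise ValueError(f"omic view {view!r} requested but no link table supplied")
        out[f"jaccard_{view}"] = jaccard_similarity(bundle.links[view])
    if bundle.semantic_similarity is not None:
        semantic = bundle.semantic_similarity.validate()
    elif bundle.ontology is not None:
        semantic = semantic_similarity_standin(bundle.ontology, A.disease_ids)
    else:
        raise ValueError("no disease semantic similarity: supply a matrix or an ontology")
    if sim_cfg.minmax_semantic:
        semantic = minmax_normalize(semantic)
    out["semantic"] = semantic
    return out


def lncrna_views(sims: dict[str, SimilarityMatrix]) -> dict[str, SimilarityMatrix]:
    keys = [k for k in sims if k == "gip" or k.startswith("jaccard_lncrna")]
    return {k: sims[k] for k in sorted(keys)}


def disease_views(sims: dict[str, SimilarityMatrix]) -> dict[str, SimilarityMatrix]:
    keys = [
        k
        for k in sims
        if k in ("semantic", "gip_disease") or k.startswith("jaccard_disease")
    ]
    return {k: sims[k] for k in sorted(keys)}
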