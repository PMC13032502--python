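"""Cross-validated evaluation: negative sampling, training, metrics, ablations.

The protocol mirrors standard practice for association prediction: unknown
cells are sampled 1:1 against the known positives, labeled pairs are split
into stratified folds, and for every fold the association-derived GIP kernel
is recomputed with the test cells zeroed so no test label leaks into any
training input. Test pairs still participate in the pair graphs as nodes
(transductive evaluation); only their labels are withheld.

Metrics: AUC (rank statistic, midrank ties), AUPR (step-wise precision-
recall integration), and thresholded precision, recall, F1 and the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from lncgraph import similarity as simmod
from lncgraph.config import ABLATION_VARIANTS, RunConfig
from lncgraph.embedding import dae_compress, diffusion_features, rwr_only_features
from lncgraph.model import GraphTensor, PairModel
from lncgraph.pairs import (
    Pair,
    PairNodeSet,
    build_feature_graph,
    build_interconnected_graph,
    make_pair_nodes,
    pair_features,
)
from lncgraph.types import AssociationMatrix, Bundle

logger = logging.getLogger("lncgraph")

METRIC_COLUMNS = ["auc", "aupr", "precision", "recall", "f1", "mcc"]


@dataclass
class MetricsReport:
    """Per-fold metric rows plus their average."""

    rows: list[dict] = field(default_factory=list)
    threshold: float = 0.5

    def add(self, fold: int, metrics: dict) -> None:
        self.rows.append({"fold": fold, **metrics})

    @property
    def average(self) -> dict:
        return {m: float(np.mean([r[m] for r in self.rows])) for m in METRIC_COLUMNS}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        avg = {"fold": "average", **self.average}
        return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def confusion_counts(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    pred = scores >= threshold
    labels = labels.astype(bool)
    return {
        "TP": int((pred & labels).sum()),
        "TN": int((~pred & ~labels).sum()),
        "FP": int((pred & ~labels).sum()),
        "FN": int((~pred & labels).sum()),
    }


def mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    num = tp * tn - fp * fn
    den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return float(num / den) if den > 0 else 0.0


def compute_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    """AUC, AUPR, precision, recall, F1 and MCC for one score/label vector."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("metrics require at least one positive and one negative label")
    c = confusion_counts(scores, labels, threshold)
    tp, tn, fp, fn = c["TP"], c["TN"], c["FP"], c["FN"]
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "mcc": mcc_from_counts(tp, tn, fp, fn),
    }


def sample_negatives(
    A: AssociationMatrix, ratio: float = 1.0, seed: int = 0
) -> list[Pair]:
    """Uniform sample (without replacement) of unlabeled cells as negatives."""
    zeros = np.argwhere(A.values == 0)
    n_needed = int(round(ratio * A.n_positive))
    if n_needed > len(zeros):
        raise ValueError(
            f"cannot sample {n_needed} negatives from {len(zeros)} zero cells"
        )
    rng = np.random.default_rng(seed)
    chosen = zeros[rng.choice(len(zeros), size=n_needed, replace=False)]
    return sorted(
        (A.lncrna_ids[i], A.disease_ids[j]) for i, j in chosen
    )


def positive_pairs(A: AssociationMatrix) -> list[Pair]:
    rows, cols = np.nonzero(A.values)
    return sorted((A.lncrna_ids[i], A.disease_ids[j]) for i, j in zip(rows, cols))


def make_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Stratified fold partition over labeled node indices (test indices per fold)."""
    labeled = np.flatnonzero(labels >= 0)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [labeled[test] for _, test in skf.split(labeled, labels[labeled])]


# -- fold-level pipeline --------------------------------------------------

def _fold_safe_associations(
    bundle: Bundle, nodes: PairNodeSet, test_idx: np.ndarray, enabled: bool
) -> AssociationMatrix:
    A = bundle.associations.copy()
    if not enabled:
        return A
    li = {e: i for i, e in enumerate(A.lncrna_ids)}
    di = {e: i for i, e in enumerate(A.disease_ids)}
    for t in test_idx:
        l, d = nodes.pairs[t]
        A.values[li[l], di[d]] = 0
    return A


def _entity_features(bundle: Bundle, A: AssociationMatrix, config: RunConfig, seed: int):
    """Similarities -> RWR diffusion -> (optionally) DAE compression, per side."""
    fold_bundle = Bundle(
        associations=A,
        links=bundle.links,
        ontology=bundle.ontology,
        semantic_similarity=bundle.semantic_similarity,
    )
    sims = simmod.build_all_similarities(fold_bundle, config)
    l_views = simmod.lncrna_views(sims)
    d_views = simmod.disease_views(sims)
    if config.variant == "rwr":
        dim = config.dae.hidden_dim
        emb_l = rwr_only_features(l_views, config.rwr, truncate_dim=dim)
        emb_d = rwr_only_features(d_views, config.rwr, truncate_dim=dim)
    else:
        emb_l = dae_compress(diffusion_features(l_views, config.rwr), config.dae, seed=seed)
        emb_d = dae_compress(diffusion_features(d_views, config.rwr), config.dae, seed=seed + 1)
    return emb_l, emb_d


def standardize(feats: np.ndarray) -> np.ndarray:
    """Column z-scoring of pair features before graph construction/encoding.

    Raw diffusion-derived features share a large common baseline that pushes
    all pairwise cosines toward 1 and shrinks gradients; centering restores
    contrast without reordering any single feature.
    """
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (feats - mu) / sd


def _build_graphs(nodes: PairNodeSet, feats: np.ndarray, config: RunConfig):
    variant = config.variant
    cg = rfg = None
    if variant != "rfg":
        cg = GraphTensor.from_graph(build_interconnected_graph(nodes))
    if variant != "cg":
        rfg = GraphTensor.from_graph(
            build_feature_graph(nodes, feats, config.pair_graph.k_neighbors)
        )
    return cg, rfg


def train_model(
    feats: np.ndarray,
    cg: GraphTensor | None,
    rfg: GraphTensor | None,
    labels: np.ndarray,
    train_idx: np.ndarray,
    config: RunConfig,
    seed: int,
) -> PairModel:
    """Train on BCE over labeled train nodes with early stopping.

    A stratified 10% slice of the training nodes is held out to monitor
    validation AUC; training stops when it has not improved for ``patience``
    epochs and the best parameters are restored.
    """
    from lncgraph import autodiff as ad

    rng = np.random.default_rng(seed)
    model = PairModel(feats.shape[1], config.model, config.variant, seed=seed)
    opt = ad.Adam(model.parameters(), lr=config.train.learning_rate)

    y = labels[train_idx].astype(np.float64)
    order = rng.permutation(len(train_idx))
    n_val = max(2, int(round(config.train.val_fraction * len(train_idx))))
    pos = [i for i in order if y[i] == 1]
    neg = [i for i in order if y[i] == 0]
    val_local = np.asarray(pos[: max(1, n_val // 2)] + neg[: max(1, n_val // 2)])
    fit_local = np.asarray([i for i in order if i not in set(val_local.tolist())])
    val_idx = train_idx[val_local]
    fit_idx = train_idx[fit_local]

    best_state = model.state_values()
    best_val = -np.inf
    stale = 0
    for epoch in range(config.train.epochs):
        logits, _ = model.forward(feats, cg, rfg, training=True, rng=rng)
        fit_logits = ad.gather(logits, fit_idx)
        loss = ad.bce_with_logits(fit_logits, labels[fit_idx].astype(np.float64)[:, None])
        opt.zero_grad()
        loss.backward()
        opt.step()
        scores, _ = model.predict(feats, cg, rfg)
        val_auc = roc_auc_score(labels[val_idx], scores[val_idx])
        if val_auc > best_val + 1e-6:
            best_val, stale = val_auc, 0
            best_state = model.state_values()
        else:
            stale += 1
            if stale >= config.train.patience:
                break
    model.load_state_values(best_state)
    return model


def run_fold(
    bundle: Bundle,
    nodes: PairNodeSet,
    test_idx: np.ndarray,
    config: RunConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Train on everything labeled outside ``test_idx``; score all nodes."""
    A_fold = _fold_safe_associations(
        bundle, nodes, test_idx[nodes.labels[test_idx] == 1], config.evaluation.fold_safe_gip
    )
    emb_l, emb_d = _entity_features(bundle, A_fold, config, seed)
    feats = standardize(pair_features(nodes, emb_l, emb_d))
    cg, rfg = _build_graphs(nodes, feats, config)
    labeled = np.flatnonzero(nodes.labels >= 0)
    train_idx = np.setdiff1d(labeled, test_idx)
    model = train_model(feats, cg, rfg, nodes.labels, train_idx, config, seed)
    return model.predict(feats, cg, rfg)


def cross_validate(
    bundle: Bundle, config: RunConfig, nodes: PairNodeSet | None = None
) -> tuple[MetricsReport, pd.DataFrame]:
    """k-fold cross-validation; returns (metrics, per-pair prediction table)."""
    seed = config.seed
    if nodes is None:
        A = bundle.associations
        negatives = sample_negatives(A, config.evaluation.negative_ratio, seed)
        nodes = make_pair_nodes(positive_pairs(A), negatives)
    folds = make_folds(nodes.labels, config.evaluation.k_folds, seed)
    report = MetricsReport(threshold=config.evaluation.threshold)
    records: list[dict] = []
    for f, test_idx in enumerate(folds):
        if nodes.labels[test_idx].max() < 1:
            raise ValueError(f"fold {f} contains no positive pairs")
        scores, alphas = run_fold(bundle, nodes, test_idx, config, seed + f)
        metrics = compute_metrics(
            scores[test_idx], nodes.labels[test_idx], config.evaluation.threshold
        )
        report.add(f + 1, metrics)
        logger.info("fold %d: %s", f + 1, {k: round(v, 4) for k, v in metrics.items()})
        for t in test_idx:
            l, d = nodes.pairs[t]
            row = {
                "lncrna_id": l,
                "disease_id": d,
                "score": float(scores[t]),
                "label": int(nodes.labels[t]),
                "fold": f + 1,
            }
            if alphas is not None:  # view-attention report for interpretability
                row["alpha_cg"] = float(alphas[t, 0])
                row["alpha_rfg"] = float(alphas[t, 1])
            records.append(row)
    predictions = pd.DataFrame.from_records(records).sort_values(
        ["fold", "lncrna_id", "disease_id"], kind="stable", ignore_index=True
    )
    return report, predictions


def run_ablation(
    bundle: Bundle, config: RunConfig, variants: list[str] | None = None
) -> pd.DataFrame:
    """One cross-validation per ablation variant on shared folds and seeds."""
    variants = list(variants) if variants is not None else list(ABLATION_VARIANTS)
    unknown = set(variants) - set(ABLATION_VARIANTS)
    if unknown:
        raise ValueError(f"unknown ablation variants: {sorted(unknown)}")
    A = bundle.associations
    negatives = sample_negatives(A, config.evaluation.negative_ratio, config.seed)
    nodes = make_pair_nodes(positive_pairs(A), negatives)
    rows = []
    for variant in variants:
        cfg = config.model_copy(deep=True)
        cfg.variant = variant
        report, _ = cross_validate(bundle, cfg, nodes=nodes)
        rows.append({"variant": variant, **report.average})
    return pd.DataFrame(rows)


def leave_one_omic_out(bundle: Bundle, config: RunConfig) -> pd.DataFrame:
    """Remove one omic view at a time, keeping every other setting identical."""
    active = [v for v, on in config.similarity.views.items() if on and v in bundle.links]
    if len(active) < 2:
        raise ValueError("leave-one-omic-out needs at least two active omic views")
    rows = []
    for excluded in [None] + active:
        cfg = config.model_copy(deep=True)
        if excluded is not None:
            cfg.similarity.views[excluded] = False
        report, _ = cross_validate(bundle, cfg)
        rows.append(
            {
                "excluded_view": excluded or "none (full data)",
                "config_hash": cfg.config_hash(),
                **report.average,
            }
        )
    return pd.DataFrame(rows)


def rank_candidates(
    bundle: Bundle, config: RunConfig, disease_id: str, top_k: int = 20
) -> pd.DataFrame:
    """Rank unlabeled lncRNAs for one disease by predicted score.

    Trains on all labeled pairs (positives plus sampled negatives) with the
    disease's unlabeled pairs present as candidate nodes, then returns the
    top ``top_k`` candidates sorted by descending score, ties by lncRNA ID.
    """
    A = bundle.associations
    if disease_id not in A.disease_ids:
        raise KeyError(f"unknown disease {disease_id!r}")
    negatives = sample_negatives(A, config.evaluation.negative_ratio, config.seed)
    positives = positive_pairs(A)
    labeled = set(positives) | set(negatives)
    j = A.disease_ids.index(disease_id)
    candidates = [
        (l, disease_id)
        for i, l in enumerate(A.lncrna_ids)
        if A.values[i, j] == 0 and (l, disease_id) not in labeled
    ]
    if not candidates:
        raise ValueError(f"disease {disease_id!r} has no candidate pairs")
    nodes = make_pair_nodes(positives, negatives, candidates)
    emb_l, emb_d = _entity_features(bundle, A, config, config.seed)
    feats = standardize(pair_features(nodes, emb_l, emb_d))
    cg, rfg = _build_graphs(nodes, feats, config)
    labeled_idx = np.flatnonzero(nodes.labels >= 0)
    model = train_model(feats, cg, rfg, nodes.labels, labeled_idx, config, config.seed)
    scores, _ = model.predict(feats, cg, rfg)
    index = nodes.index
    rows = [
        {"lncrna_id": l, "disease_id": d, "score": float(scores[index[(l, d)]])}
        for l, d in candidates
    ]
    df = pd.DataFrame(rows).sort_values(
        ["score", "lncrna_id"], ascending=[False, True], kind="stable", ignore_index=True
    )
    return df.head(top_k)
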