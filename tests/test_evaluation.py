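"""Metric correctness, fold hygiene, negative sampling, and ranking."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from lncgraph import evaluation as ev
from lncgraph.config import RunConfig
from lncgraph.synthetic import PlantedWorld, simulate_world
from lncgraph.types import AssociationMatrix


def auc_oracle(scores, labels):
    """Explicit pairwise counting over all positive-negative pairs, ties 0.5."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def aupr_oracle(scores, labels):
    """Exhaustive sweep over distinct thresholds (step-wise, no interpolation):
    AP = sum over thresholds of (recall step) * precision, ties grouped."""
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return float(ap)


class TestMetrics:
    def test_balanced_confusion_gives_zero_mcc(self):
        assert ev.mcc_from_counts(25, 25, 25, 25) == 0.0

    def test_perfect_classification(self):
        scores = np.array([0.9] * 10 + [0.1] * 10)
        labels = np.array([1] * 10 + [0] * 10)
        m = ev.compute_metrics(scores, labels)
        assert m["mcc"] == pytest.approx(1.0)
        assert m["f1"] == pytest.approx(1.0)
        assert m["auc"] == pytest.approx(1.0)

    def test_hand_evaluated_confusion(self):
        """TP=50 TN=40 FP=10 FN=5 evaluated directly from the definitions."""
        assert ev.mcc_from_counts(50, 40, 10, 5) == pytest.approx(
            1950 / np.sqrt(60 * 55 * 50 * 45)
        )
        assert ev.mcc_from_counts(50, 40, 10, 5) == pytest.approx(0.7156, abs=1e-4)
        scores = np.concatenate([np.full(50, 0.9), np.full(5, 0.1),
                                 np.full(40, 0.1), np.full(10, 0.9)])
        labels = np.concatenate([np.ones(55), np.zeros(50)])
        m = ev.compute_metrics(scores, labels)
        assert m["precision"] == pytest.approx(50 / 60, abs=1e-12)
        assert m["recall"] == pytest.approx(50 / 55, abs=1e-12)
        assert m["f1"] == pytest.approx(0.8696, abs=1e-4)

    def test_matches_counting_oracles_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            m = ev.compute_metrics(scores, labels)
            assert m["auc"] == pytest.approx(auc_oracle(scores, labels), abs=1e-10)
            assert m["aupr"] == pytest.approx(aupr_oracle(scores, labels), abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.compute_metrics(np.array([0.1, 0.9]), np.array([1, 1]))


class TestNegativeSampling:
    def test_ratio_count_and_disjointness(self, study_bundle):
        A = study_bundle.associations
        negs = ev.sample_negatives(A, 1.0, seed=0)
        assert len(negs) == A.n_positive
        pos = set(ev.positive_pairs(A))
        assert not (set(negs) & pos)
        li = {e: i for i, e in enumerate(A.lncrna_ids)}
        di = {e: i for i, e in enumerate(A.disease_ids)}
        assert all(A.values[li[l], di[d]] == 0 for l, d in negs)

    def test_seeded_determinism(self, study_bundle):
        A = study_bundle.associations
        assert ev.sample_negatives(A, 1.0, 3) == ev.sample_negatives(A, 1.0, 3)

    def test_insufficient_zero_cells(self):
        A = AssociationMatrix(["L1", "L2"], ["D1"], np.array([[1], [1]], dtype=np.int8))
        with pytest.raises(ValueError, match="sample"):
            ev.sample_negatives(A, 1.0, 0)


class TestFolds:
    def test_every_labeled_pair_in_exactly_one_test_fold(self):
        labels = np.array([1] * 30 + [0] * 30 + [-1] * 5, dtype=np.int8)
        folds = ev.make_folds(labels, 5, seed=0)
        all_test = np.concatenate(folds)
        assert sorted(all_test) == list(range(60))

    def test_fold_safe_gip_zeroes_test_positives(self, tiny_bundle):
        A = tiny_bundle.associations
        nodes = ev.make_pair_nodes(ev.positive_pairs(A), ev.sample_negatives(A, 1.0, 0))
        folds = ev.make_folds(nodes.labels, 3, 0)
        test_idx = folds[0]
        pos_test = test_idx[nodes.labels[test_idx] == 1]
        A_fold = ev._fold_safe_associations(tiny_bundle, nodes, pos_test, True)
        li = {e: i for i, e in enumerate(A.lncrna_ids)}
        di = {e: i for i, e in enumerate(A.disease_ids)}
        for t in pos_test:
            l, d = nodes.pairs[t]
            assert A_fold.values[li[l], di[d]] == 0
        # and no other cell was touched
        diff = (A.values != A_fold.values).sum()
        assert diff == len(pos_test)


class TestCrossValidate:
    def test_report_shape_and_determinism(self, tiny_bundle, fast_config):
        r1, p1 = ev.cross_validate(tiny_bundle, fast_config)
        assert len(r1.rows) == fast_config.evaluation.k_folds
        assert set(ev.METRIC_COLUMNS) <= set(r1.average)
        r2, p2 = ev.cross_validate(tiny_bundle, fast_config)
        assert p1.equals(p2)
        assert r1.rows == r2.rows

    def test_unknown_ablation_variant_rejected(self, tiny_bundle, fast_config):
        with pytest.raises(ValueError, match="unknown"):
            ev.run_ablation(tiny_bundle, fast_config, ["full", "bogus"])

    def test_leave_one_out_table_shape(self, tiny_bundle, fast_config):
        cfg = fast_config.model_copy(deep=True)
        for v in ("lncrna_rbp", "lncrna_protein", "disease_circrna"):
            cfg.similarity.views[v] = False  # keep runtime down: 2 active views
        table = ev.leave_one_omic_out(tiny_bundle, cfg)
        assert len(table) == 3  # full data + 2 exclusions
        assert table.config_hash.nunique() == 3


class TestRanking:
    def test_truncation_sorting_and_block_enrichment(self):
        """In a noise-free world the top-ranked candidates for a disease are
        enriched for same-block lncRNAs (hypergeometric p < 0.01).

        The association density is kept low (within 0.3) so a sizeable pool
        of same-block cells stays unlabeled and rankable."""
        world = PlantedWorld(
            n_lncrna=60, n_disease=40, n_blocks=2,
            within_block_assoc_prob=0.3, cross_block_assoc_prob=0.01,
            noise_flip_prob=0.0, seed=11,
        )
        bundle = simulate_world(world)
        cfg = RunConfig(seed=7)
        disease = bundle.associations.disease_ids[0]
        top = ev.rank_candidates(bundle, cfg, disease, top_k=10)
        assert len(top) <= 10
        assert (np.diff(top.score.to_numpy()) <= 1e-12).all()
        target_block = world.block_assignment_d[disease]
        n_same = sum(world.block_assignment_l[l] == target_block for l in top.lncrna_id)
        # population: the same candidate set rank_candidates scores
        A = bundle.associations
        labeled = set(ev.positive_pairs(A)) | set(
            ev.sample_negatives(A, cfg.evaluation.negative_ratio, cfg.seed)
        )
        j = A.disease_ids.index(disease)
        cand = [l for i, l in enumerate(A.lncrna_ids)
                if A.values[i, j] == 0 and (l, disease) not in labeled]
        K = sum(world.block_assignment_l[l] == target_block for l in cand)
        p = hypergeom.sf(n_same - 1, len(cand), K, len(top))
        assert p < 0.01
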