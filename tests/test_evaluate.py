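import numpy as np
import pytest

from mlmda import FixtureConfig, generate_fixture
from mlmda.evaluate import (
    EvalConfig,
    compute_metrics,
    crossvalidate,
    fit_full_model,
    rank_candidates,
    train_rf,
)


class TestMetrics:
    def test_perfect_separation(self):
        m, _ = compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.1])
        assert m.auc == 1.0 and m.accuracy == 1.0
        assert m.recall == m.precision == m.f1 == 1.0

    def test_hand_built_confusion_matrix(self):
        # scores [0.9, 0.6, 0.4, 0.1], labels [1, 0, 1, 0]:
        # rank pairs: 3 of 4 (pos, neg) pairs ordered correctly -> AUC 0.75;
        # at threshold 0.5 preds are [1, 1, 0, 0] -> TP=1 FP=1 FN=1 TN=1.
        m, _ = compute_metrics([1, 0, 1, 0], [0.9, 0.6, 0.4, 0.1])
        assert m.auc == pytest.approx(0.75)
        assert m.accuracy == pytest.approx(0.5)
        assert m.recall == pytest.approx(0.5)
        assert m.precision == pytest.approx(0.5)
        assert m.f1 == pytest.approx(0.5)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.random(50)
        base, _ = compute_metrics(y, s)
        squashed, _ = compute_metrics(y, 1 / (1 + np.exp(-7 * s)))
        assert base.auc == pytest.approx(squashed.auc, abs=1e-12)

    def test_auc_matches_rank_statistic_oracle(self):
        """Trapezoidal ROC area equals the Mann-Whitney pair statistic."""
        rng = np.random.default_rng(5)
        y = np.array([1] * 20 + [0] * 30)
        s = np.concatenate([rng.normal(0.6, 0.2, 20), rng.normal(0.4, 0.2, 30)])
        m, _ = compute_metrics(y, s)
        pos, neg = s[y == 1], s[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert m.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


class TestTrainRf:
    def test_separable_blobs_fit_perfectly(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 0.3, (40, 64)), rng.normal(3, 0.3, (40, 64))])
        y = np.array([0] * 40 + [1] * 40)
        clf = train_rf(X, y, seed=0)
        m, _ = compute_metrics(y, clf.predict_proba(X)[:, 1])
        assert m.auc == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            train_rf(np.zeros((5, 3)), np.ones(5))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        X, y = rng.random((60, 10)), rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        p1 = train_rf(X, y, seed=3).predict_proba(X)
        p2 = train_rf(X, y, seed=3).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_permuted_labels_score_near_chance(self):
        """Out-of-fold AUC on label-permuted data stays near 0.5."""
        from sklearn.model_selection import cross_val_predict

        rng = np.random.default_rng(11)
        X = rng.random((200, 20))
        aucs = []
        for s in range(10):
            y = np.random.default_rng(s).permutation([0, 1] * 100)
            clf = train_rf(X, y, n_trees=50, seed=s)
            scores = cross_val_predict(
                clf, X, y, cv=3, method="predict_proba"
            )[:, 1]
            m, _ = compute_metrics(y, scores)
            aucs.append(m.auc)
        assert abs(float(np.mean(aucs)) - 0.5) < 0.07


@pytest.fixture(scope="module")
def tiny_cv_config():
    from mlmda.autoencoder import AETrainConfig

    return EvalConfig(n_trees=50, ae=AETrainConfig(epochs=100), seed=0)


class TestCrossvalidate:
    def test_separable_fixture_reaches_auc_one(self, tiny_cv_config):
        """Deterministic block-diagonal associations are fully learnable."""
        fx = generate_fixture(
            FixtureConfig(
                n_diseases=16, n_mirnas=20, n_blocks=2,
                within_block_assoc_prob=1.0, background_assoc_prob=0.0, seed=2,
            )
        )
        rep = crossvalidate(fx.assoc, fx.dag_forest, fx.records, None, tiny_cv_config)
        assert rep.mean("auc") >= 0.99

    def test_report_shape_and_metric_ranges(self, small_fixture, tiny_cv_config):
        fx = small_fixture
        rep = crossvalidate(fx.assoc, fx.dag_forest, fx.records, None, tiny_cv_config)
        assert len(rep.per_fold) == 5
        for fold in rep.per_fold:
            for v in fold.as_dict().values():
                assert 0.0 <= v <= 1.0
        summary = rep.summary()
        assert summary["auc"]["mean"] == pytest.approx(rep.mean("auc"))

    def test_masked_protocol_runs_and_scores_above_chance(
        self, small_fixture, tiny_cv_config
    ):
        from dataclasses import replace

        fx = small_fixture
        rep = crossvalidate(
            fx.assoc, fx.dag_forest, fx.records, None,
            replace(tiny_cv_config, mask_held_out=True),
        )
        assert rep.mean("auc") > 0.7

    def test_too_many_folds_error(self, tiny_cv_config):
        from dataclasses import replace

        fx = generate_fixture(
            FixtureConfig(n_diseases=4, n_mirnas=4, n_blocks=2, seed=3)
        )
        n_samples = 2 * int(fx.assoc.values.sum())
        with pytest.raises(ValueError):
            crossvalidate(
                fx.assoc, fx.dag_forest, fx.records, None,
                replace(tiny_cv_config, folds=n_samples + 1),
            )


class _ConstantScorer:
    def predict_proba(self, X):
        return np.tile([0.5, 0.5], (len(X), 1))


@pytest.fixture(scope="module")
def fitted(small_fixture, tiny_cv_config):
    fx = small_fixture
    return fit_full_model(fx.assoc, fx.dag_forest, fx.records, None, tiny_cv_config)


class TestRankCandidates:
    def test_known_pairs_excluded_and_sorted(self, fitted, small_fixture):
        disease = small_fixture.assoc.disease_ids[0]
        known = {
            m for d, m in small_fixture.assoc.pairs() if d == disease
        }
        plist = rank_candidates(fitted, disease)
        names = [m for m, _ in plist.ranked]
        assert not known & set(names)
        assert len(names) == small_fixture.assoc.nm - len(known)
        scores = [s for _, s in plist.ranked]
        assert scores == sorted(scores, reverse=True)
        assert len(set(names)) == len(names)

    def test_tie_break_is_lexicographic(self, fitted):
        from dataclasses import replace

        stub = replace(fitted, classifier=_ConstantScorer())
        plist = rank_candidates(stub, "disease000")
        names = [m for m, _ in plist.ranked]
        assert names == sorted(names)

    def test_unknown_disease_errors(self, fitted):
        with pytest.raises(KeyError, match="unknown disease"):
            rank_candidates(fitted, "not-a-disease")

    def test_planted_candidates_recovered_in_top_ranks(self, tiny_cv_config):
        """Unassociated same-block miRNAs dominate the head of the ranking.

        For each disease the planted candidates are the miRNAs of its own
        block that are not yet associated with it; the check is the
        precision of the ranking at that planted count (median over seeds).
        """
        hit_rates = []
        for seed in range(5):
            fx = generate_fixture(
                FixtureConfig(n_diseases=24, n_mirnas=32, n_blocks=2, seed=seed)
            )
            model = fit_full_model(
                fx.assoc, fx.dag_forest, fx.records, None, tiny_cv_config
            )
            disease = fx.assoc.disease_ids[0]
            block = fx.disease_blocks[0]
            known = {m for d, m in fx.assoc.pairs() if d == disease}
            planted = {
                m
                for m, b in zip(fx.assoc.mirna_ids, fx.mirna_blocks)
                if b == block and m not in known
            }
            top = rank_candidates(model, disease).top(len(planted))
            hit_rates.append(sum(m in planted for m, _ in top) / len(planted))
        assert float(np.median(hit_rates)) >= 0.8
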