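import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirlink import (
    auc_score,
    compute_metrics,
    fit,
    metrics_from_counts,
    predict_scores,
)
from mirlink.lstm import (
    ClassifierModel,
    SingleClassError,
    _init_model,
    average_rows,
    shape_rows,
)


class TestShaping:
    def test_flat_single_step(self):
        X = np.ones((3, 10))
        assert shape_rows(X, "flat").shape == (3, 1, 10)

    def test_tokens3_chunks_and_padding(self):
        X = np.arange(2 * 150).reshape(2, 150).astype(float)
        seq = shape_rows(X, "tokens3", step_width=64)
        assert seq.shape == (2, 3, 64)
        assert np.array_equal(seq[0, 0], X[0, :64])
        assert np.all(seq[:, 2, 22:] == 0)  # zero padding of last chunk

    def test_aligned_interleaves_segments(self):
        X = np.arange(1 * 12).reshape(1, 12).astype(float)
        seq = shape_rows(X, "aligned", layout=(4, 4, 4), n_steps=2)
        assert seq.shape == (1, 2, 6)
        # step 0 carries the first half of each segment
        assert seq[0, 0].tolist() == [0, 1, 4, 5, 8, 9]
        assert seq[0, 1].tolist() == [2, 3, 6, 7, 10, 11]

    def test_aligned_single_segment_is_flat(self):
        X = np.ones((2, 8))
        assert shape_rows(X, "aligned", layout=(8,)).shape == (2, 1, 8)


def _separable_features(n=300, d=24, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, d))
    X[:, :3] += 6.0 * y[:, None]   # wide margin on three coordinates
    return X, y


class TestFit:
    def test_separable_data_high_training_accuracy(self):
        # oracle: logistic regression reaches ~1.0 on the same rows
        from sklearn.linear_model import LogisticRegression

        X, y = _separable_features()
        assert LogisticRegression().fit(X, y).score(X, y) >= 0.99
        model = fit(X, y, epochs=30, batch=64, seed=0, shaping="flat",
                    weight_decay=0.0, input_dropout=0.0)
        scores = predict_scores(model, X)
        acc = ((scores >= 0.5).astype(int) == y).mean()
        assert acc >= 0.99

    def test_deterministic_under_seed(self):
        X, y = _separable_features(n=80)
        m1 = fit(X, y, epochs=3, seed=5, shaping="flat")
        m2 = fit(X, y, epochs=3, seed=5, shaping="flat")
        assert np.array_equal(predict_scores(m1, X), predict_scores(m2, X))

    def test_single_class_labels_rejected(self):
        X = np.ones((10, 4))
        with pytest.raises(SingleClassError):
            fit(X, np.ones(10), epochs=1)

    def test_training_reduces_loss(self):
        X, y = _separable_features(n=200)
        m_short = fit(X, y, epochs=1, seed=1, shaping="flat", ema_decay=0.0)
        m_long = fit(X, y, epochs=25, seed=1, shaping="flat", ema_decay=0.0)

        def bce(model):
            s = np.clip(predict_scores(model, X), 1e-9, 1 - 1e-9)
            return float(-(y * np.log(s) + (1 - y) * np.log(1 - s)).mean())

        assert bce(m_long) < bce(m_short)


class TestPredict:
    def test_zeroed_head_gives_half_scores(self):
        rng = np.random.default_rng(0)
        model = _init_model(6, "flat", 64, hidden=8, n_layers=2, rng=rng)
        model.head_w[:] = 0.0
        model.head_b = 0.0
        scores = model.forward(np.zeros((4, 1, 6), dtype=np.float32))
        assert np.allclose(scores, 0.5)

    def test_scores_in_unit_interval_and_order_preserved(self):
        X, y = _separable_features(n=60)
        model = fit(X, y, epochs=2, seed=0, shaping="flat")
        s = predict_scores(model, X)
        assert np.all((s >= 0) & (s <= 1))
        perm = np.random.default_rng(1).permutation(len(X))
        s_perm = predict_scores(model, X[perm])
        assert np.allclose(s[perm], s_perm)

    def test_dimension_mismatch_rejected(self):
        X, y = _separable_features(n=40, d=8)
        model = fit(X, y, epochs=1, seed=0, shaping="flat")
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 1, 5), dtype=np.float32))


class TestMetrics:
    def test_printed_confusion_counts_give_printed_accuracy(self):
        row = metrics_from_counts(tp=66099, tn=70048, fp=1723, fn=5618)
        assert round(row.accuracy, 3) == 0.949

    def test_perfect_scores(self):
        y = np.array([0, 1, 1, 0, 1])
        row = compute_metrics(y, y.astype(float))
        assert row.auc == 1.0
        assert row.accuracy == 1.0
        assert row.f1 == 1.0

    def test_auc_matches_brute_force_concordance(self):
        # exhaustive O(n^2) oracle with ties counted one half
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 10)
        while len(set(y)) < 2:
            y = rng.integers(0, 2, 10)
        s = rng.choice([0.1, 0.4, 0.4, 0.8], size=10)
        conc = 0.0
        n_pairs = 0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                n_pairs += 1
                if s[i] > s[j]:
                    conc += 1.0
                elif s[i] == s[j]:
                    conc += 0.5
        assert auc_score(y, s) == pytest.approx(conc / n_pairs)

    def test_auc_matches_sklearn_on_random_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        assert auc_score(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_auc_nan_but_confusion_reported(self, caplog):
        with caplog.at_level("WARNING", logger="mirlink"):
            row = compute_metrics(np.ones(4), np.array([0.9, 0.8, 0.2, 0.7]))
        assert np.isnan(row.auc)
        assert row.tp + row.fn == 4
        with pytest.raises(SingleClassError):
            auc_score(np.ones(4), np.array([0.9, 0.8, 0.2, 0.7]))

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_confusion_identities_exact(self, tp, tn, fp, fn):
        row = metrics_from_counts(tp, tn, fp, fn)
        total = tp + tn + fp + fn
        if total:
            assert row.accuracy == pytest.approx((tp + tn) / total)
        if tp + fp:
            assert row.precision == pytest.approx(tp / (tp + fp))
        if tp + fn:
            assert row.recall == pytest.approx(tp / (tp + fn))
        if tp + fp and tp + fn and row.precision + row.recall > 0:
            assert row.f1 == pytest.approx(
                2 * row.precision * row.recall / (row.precision + row.recall)
            )

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 100)
        s = rng.random(100)
        assert auc_score(y, s) == pytest.approx(auc_score(y, 1 / (1 + np.exp(-5 * s))))

    def test_average_row_is_arithmetic_mean(self):
        # fold precisions from a published-style 5-fold table
        rows = [
            metrics_from_counts(10, 10, 1, 1, name=f"Fold-{i}", auc=a)
            for i, a in enumerate([0.9814, 0.9854, 0.9852, 0.9857, 0.9851], 1)
        ]
        for r, p in zip(rows, [0.966, 0.944, 0.961, 0.976, 0.982]):
            r.precision = p
        avg = average_rows(rows)
        assert round(avg.precision, 4) == 0.9658
        assert round(avg.auc, 4) == 0.9846


class TestRocPoints:
    def test_matches_sklearn_roc_curve(self):
        from sklearn.metrics import roc_curve

        from mirlink.lstm import roc_points

        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 50)
        s = rng.random(50)
        pts = roc_points(y, s)
        fpr, tpr, _ = roc_curve(y, s)
        # every sklearn vertex appears on our per-sample curve
        ours = {(round(a, 9), round(b, 9)) for a, b in pts}
        assert all((round(a, 9), round(b, 9)) in ours for a, b in zip(fpr, tpr))

    def test_tsv_export(self, tmp_path):
        from mirlink.lstm import roc_points_to_tsv

        p = tmp_path / "roc.tsv"
        roc_points_to_tsv(np.array([0, 1, 1]), np.array([0.1, 0.9, 0.6]), p)
        lines = p.read_text().splitlines()
        assert lines[0] == "fpr\ttpr"
        assert lines[1] == "0.000000\t0.000000"
        assert lines[-1] == "1.000000\t1.000000"


class TestCrossValidation:
    @pytest.fixture(scope="class")
    def small_world(self):
        from mirlink import AssociationTable, EmbeddingTable
        from mirlink.negatives import LabeledPairSet

        rng = np.random.default_rng(0)
        mids = [f"m{i:02d}" for i in range(12)]
        gids = [f"g{i:02d}" for i in range(12)]
        table = EmbeddingTable(8, {k: rng.normal(size=8) for k in mids + gids})
        pos = AssociationTable([(m, g, 1) for m, g in zip(mids, gids)])
        neg = AssociationTable(
            [(m, g, 0) for m, g in zip(mids, reversed(gids))
             if (m, g) not in {(a, b) for a, b in zip(mids, gids)}][:12]
        )
        pair_set = LabeledPairSet(pos, neg.subset(list(neg.keys())[:12]), 0)
        return pair_set, table

    def test_folds_partition_data(self, small_world):
        from mirlink import CVConfig, cross_validate

        pair_set, table = small_world
        cfg = CVConfig(folds=3, latent_dim=4, ae_epochs=2, cls_epochs=1, seed=1)
        report = cross_validate(pair_set, table, cfg)
        seen = np.concatenate([te for _, te in report.fold_indices])
        assert sorted(seen.tolist()) == list(range(len(pair_set)))
        assert len(report.rows) == 3

    def test_default_mode_never_fits_ae_on_evaluation_rows(self, small_world):
        from mirlink import CVConfig, cross_validate

        pair_set, table = small_world
        cfg = CVConfig(folds=3, latent_dim=4, ae_epochs=2, cls_epochs=1, seed=1)
        report = cross_validate(pair_set, table, cfg)
        for ae_idx, (_, test_idx) in zip(report.ae_fit_indices,
                                         report.fold_indices):
            assert not set(ae_idx.tolist()) & set(test_idx.tolist())

    def test_paper_mode_fits_ae_once_on_all_rows(self, small_world):
        from mirlink import CVConfig, cross_validate

        pair_set, table = small_world
        cfg = CVConfig(folds=3, latent_dim=4, ae_epochs=2, cls_epochs=1,
                       seed=1, paper_mode=True)
        report = cross_validate(pair_set, table, cfg)
        for ae_idx in report.ae_fit_indices:
            assert ae_idx.size == len(pair_set)

    def test_average_row_is_mean_of_folds(self, small_world):
        from mirlink import CVConfig, cross_validate

        pair_set, table = small_world
        cfg = CVConfig(folds=3, latent_dim=4, ae_epochs=2, cls_epochs=1, seed=2)
        report = cross_validate(pair_set, table, cfg)
        assert report.average.accuracy == pytest.approx(
            np.mean([r.accuracy for r in report.rows])
        )
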