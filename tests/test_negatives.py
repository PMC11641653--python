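import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirlink import (
    AssociationTable,
    EmbeddingTable,
    compute_thresholds,
    filter_negative_candidates,
    pair_distance,
    sample_negatives,
    build_labeled_set,
)
from mirlink.negatives import DistanceThresholds, LabeledPairSet


class TestPairDistance:
    def test_euclidean_analytic(self):
        assert pair_distance([1, 0], [0, 1], "euclidean") == pytest.approx(np.sqrt(2))

    @pytest.mark.parametrize("metric", ["euclidean", "cosine", "mahalanobis"])
    def test_identical_vectors_give_zero(self, metric):
        v = np.array([1.0, 2.0, 3.0])
        cov = np.eye(3) if metric == "mahalanobis" else None
        assert pair_distance(v, v, metric, cov) == pytest.approx(0.0, abs=1e-12)

    def test_mahalanobis_identity_covariance_equals_euclidean(self):
        # brute-force equality over 100 random vector pairs
        rng = np.random.default_rng(7)
        for _ in range(100):
            u, v = rng.normal(size=8), rng.normal(size=8)
            assert pair_distance(u, v, "mahalanobis", np.eye(8)) == pytest.approx(
                pair_distance(u, v, "euclidean"), abs=1e-10
            )

    def test_zero_vector_cosine_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            pair_distance([0, 0], [1, 1], "cosine")

    def test_non_spd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            pair_distance([1, 0], [0, 1], "mahalanobis", np.array([[1, 0], [0, -1.0]]))

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_cosine_range(self, a, b):
        u, v = np.array(a), np.array(b)
        assert pair_distance(u, v, "euclidean") == pytest.approx(
            pair_distance(v, u, "euclidean")
        )
        if np.linalg.norm(u) > 1e-6 and np.linalg.norm(v) > 1e-6:
            d_uv = pair_distance(u, v, "cosine")
            assert d_uv == pytest.approx(pair_distance(v, u, "cosine"))
            assert -1e-12 <= d_uv <= 2 + 1e-12


class TestThresholds:
    def test_tau_is_mean_of_pair_distances(self):
        # two positive pairs with euclidean distances 1 and 3 -> tau 2
        table = EmbeddingTable(2, {
            "m1": np.array([1.0, 0.0]), "g1": np.array([2.0, 0.0]),
            "m2": np.array([0.0, 1.0]), "g2": np.array([0.0, 4.0]),
        })
        pos = AssociationTable([("m1", "g1", 1), ("m2", "g2", 1)])
        th = compute_thresholds(pos, table)
        assert th.tau_euclidean == pytest.approx(2.0)

    def test_fewer_than_two_positives_rejected(self, toy_table):
        with pytest.raises(ValueError, match=">= 2"):
            compute_thresholds(AssociationTable([("mir-a", "g1", 1)]), toy_table)

    def test_degenerate_covariance_rescued_by_epsilon(self):
        table = EmbeddingTable(2, {
            k: np.array([1.0, 1.0]) for k in ["m1", "m2", "g1", "g2"]
        })
        pos = AssociationTable([("m1", "g1", 1), ("m2", "g2", 1)])
        th = compute_thresholds(pos, table, epsilon=1e-6)
        assert np.isfinite(th.tau_mahalanobis)
        assert np.all(np.linalg.eigvalsh(th.covariance) > 0)

    def test_taus_match_brute_force_oracle(self, toy_table, toy_positives):
        th = compute_thresholds(toy_positives, toy_table)
        # independent oracle: plain python mean over explicit per-pair loops
        prec = np.linalg.inv(th.covariance)
        expected = {"euclidean": [], "cosine": [], "mahalanobis": []}
        for m, g, _ in toy_positives:
            u, v = toy_table[m], toy_table[g]
            expected["euclidean"].append(float(np.sqrt(((u - v) ** 2).sum())))
            expected["cosine"].append(
                1 - float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
            )
            d = u - v
            expected["mahalanobis"].append(float(np.sqrt(d @ prec @ d)))
        assert th.tau_euclidean == pytest.approx(np.mean(expected["euclidean"]))
        assert th.tau_cosine == pytest.approx(np.mean(expected["cosine"]))
        assert th.tau_mahalanobis == pytest.approx(np.mean(expected["mahalanobis"]))


def _toy_universe(mirna_ids, gene_ids):
    return AssociationTable(
        [(m, g, None) for m, g in itertools.product(mirna_ids, gene_ids)]
    )


class TestFilter:
    @pytest.fixture
    def five_by_five(self):
        rng = np.random.default_rng(11)
        mids = [f"m{i}" for i in range(5)]
        gids = [f"g{i}" for i in range(5)]
        table = EmbeddingTable(6, {
            k: rng.normal(size=6) for k in mids + gids
        })
        pos = AssociationTable([("m0", "g0", 1), ("m1", "g1", 1), ("m2", "g2", 1)])
        return mids, gids, table, pos

    def test_matches_exhaustive_oracle(self, five_by_five):
        mids, gids, table, pos = five_by_five
        th = compute_thresholds(pos, table)
        universe = _toy_universe(mids, gids)
        got = filter_negative_candidates(universe, pos, table, th)
        # exhaustive oracle over all 25 pairs
        prec = np.linalg.inv(th.covariance)
        expected = []
        for m, g in itertools.product(mids, gids):
            if (m, g) in pos.keys():
                continue
            u, v = table[m], table[g]
            d = u - v
            euc = np.sqrt((d ** 2).sum())
            cos = 1 - (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
            mah = np.sqrt(d @ prec @ d)
            if euc > th.tau_euclidean and cos > th.tau_cosine and mah > th.tau_mahalanobis:
                expected.append((m, g))
        assert [(m, g) for m, g, _ in got] == sorted(expected)

    def test_conjunction_excludes_single_metric_failure(self, five_by_five):
        mids, gids, table, pos = five_by_five
        th = compute_thresholds(pos, table)
        universe = _toy_universe(mids, gids)
        all_mode = filter_negative_candidates(universe, pos, table, th, mode="all")
        any_mode = filter_negative_candidates(universe, pos, table, th, mode="any")
        assert set(all_mode.keys()) <= set(any_mode.keys())

    def test_zero_thresholds_keep_everything(self, five_by_five):
        mids, gids, table, pos = five_by_five
        th = compute_thresholds(pos, table)
        th0 = DistanceThresholds(0.0, 0.0, 0.0, th.covariance, th.epsilon)
        universe = _toy_universe(mids, gids)
        got = filter_negative_candidates(universe, pos, table, th0)
        assert len(got) == len(universe) - len(pos)  # positives removed first

    def test_raising_any_tau_never_enlarges(self, five_by_five):
        mids, gids, table, pos = five_by_five
        th = compute_thresholds(pos, table)
        universe = _toy_universe(mids, gids)
        base = filter_negative_candidates(universe, pos, table, th)
        for bump in ("tau_euclidean", "tau_cosine", "tau_mahalanobis"):
            kwargs = th.as_dict()
            kwargs.pop("epsilon")
            kwargs[bump] = kwargs[bump] * 1.5
            th2 = DistanceThresholds(covariance=th.covariance, epsilon=th.epsilon, **kwargs)
            bigger = filter_negative_candidates(universe, pos, table, th2)
            assert set(bigger.keys()) <= set(base.keys())


class TestSampling:
    def test_n_equals_pool_returns_all(self):
        cands = AssociationTable([("m", f"g{i}", None) for i in range(4)])
        got = sample_negatives(cands, 4, seed=0)
        assert got.keys() == cands.keys()
        assert all(lab == 0 for _, _, lab in got)

    def test_deterministic_under_seed(self):
        cands = AssociationTable([("m", f"g{i}", None) for i in range(50)])
        a = sample_negatives(cands, 10, seed=17)
        b = sample_negatives(cands, 10, seed=17)
        assert a.pairs == b.pairs

    def test_shortfall_reported(self):
        cands = AssociationTable([("m", "g", None)])
        with pytest.raises(ValueError, match="short by 2"):
            sample_negatives(cands, 3, seed=0)


class TestLabeledSet:
    def test_balance_disjointness_and_thresholds(self):
        rng = np.random.default_rng(23)
        mids = [f"m{i}" for i in range(8)]
        gids = [f"g{i}" for i in range(8)]
        table = EmbeddingTable(5, {k: rng.normal(size=5) for k in mids + gids})
        pos = AssociationTable([(f"m{i}", f"g{i}", 1) for i in range(4)])
        universe = _toy_universe(mids, gids)
        pair_set, th = build_labeled_set(pos, universe, table, seed=3)
        assert len(pair_set.negatives) == len(pair_set.positives)
        assert not pair_set.positives.keys() & pair_set.negatives.keys()
        prec = np.linalg.inv(th.covariance)
        for m, g, _ in pair_set.negatives:
            u, v = table[m], table[g]
            d = u - v
            assert np.sqrt((d ** 2).sum()) > th.tau_euclidean
            assert 1 - (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)) > th.tau_cosine
            assert np.sqrt(d @ prec @ d) > th.tau_mahalanobis

    def test_unbalanced_set_rejected(self):
        pos = AssociationTable([("m", "g", 1)])
        neg = AssociationTable([("a", "b", 0), ("c", "d", 0)])
        with pytest.raises(ValueError, match="unbalanced"):
            LabeledPairSet(pos, neg, seed=0)
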