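import numpy as np
import pytest

from sigdendro.io import standardize_rows
from sigdendro.linkage import agglomerate, normalized_heights
from sigdendro.null_reference import qq_table, reference_heights
from sigdendro.synthetic import (
    ScenarioConfig,
    draw_cluster_sizes,
    draw_profiles,
    figure1_scenario,
    generate_dataset,
    generate_null,
)


class TestDrawProfiles:
    def test_single_profile_is_zero(self):
        p = draw_profiles(1, 8, 2.0, np.random.default_rng(0))
        np.testing.assert_array_equal(p, np.zeros((1, 8)))

    def test_first_profile_zero_rest_scaled(self):
        rng = np.random.default_rng(1)
        p = draw_profiles(20, 10, 5.0, rng)
        np.testing.assert_array_equal(p[0], 0)
        entries = p[1:].ravel()
        se = 5.0 / np.sqrt(2 * (entries.size - 1))
        assert abs(entries.std(ddof=1) - 5.0) < 3 * se

    def test_seed_reproducibility(self):
        a = draw_profiles(5, 6, 2.0, np.random.default_rng(7))
        b = draw_profiles(5, 6, 2.0, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestGenerateDataset:
    def test_single_cluster_degenerates_to_null(self):
        cfg = ScenarioConfig(n_c=1, n_v=4, n_s=50, sigma=2.0, seed=0)
        X, labels, _ = generate_dataset(cfg)
        assert len(set(labels)) == 1
        assert X.values.shape == (4, 50)

    def test_within_cluster_moment_recovery(self):
        cfg = ScenarioConfig(n_c=3, n_v=4, n_s=300, sigma=10.0, seed=1)
        X, labels, profiles = generate_dataset(cfg)
        for c in (1, 2, 3):
            members = X.values[:, labels == c]
            m = members.shape[1]
            se = 1.0 / np.sqrt(m)
            assert np.all(np.abs(members.mean(axis=1) - profiles[c - 1]) < 4 * se)

    def test_sizes_sum_and_floor(self):
        cfg = ScenarioConfig(n_c=6, n_v=5, n_s=200, sigma=2.0, min_cluster_size=4, seed=2)
        _, labels, _ = generate_dataset(cfg)
        _, counts = np.unique(labels, return_counts=True)
        assert counts.sum() == 200 and counts.min() >= 4 and counts.size == 6

    def test_within_cluster_covariance_tends_to_identity(self):
        cfg = ScenarioConfig(
            n_c=2, n_v=3, n_s=2000, sigma=5.0, fixed_sizes=[1000, 1000], seed=3
        )
        X, labels, _ = generate_dataset(cfg)
        members = X.values[:, labels == 1]
        C = np.cov(members)
        assert np.linalg.norm(C - np.eye(3)) < 0.2

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError, match="cannot hold"):
            ScenarioConfig(n_c=10, n_v=4, n_s=15, sigma=2.0)

    def test_reproducible_from_seed(self):
        cfg = ScenarioConfig(n_c=4, n_v=5, n_s=120, sigma=2.0, seed=11)
        X1, l1, p1 = generate_dataset(cfg)
        X2, l2, p2 = generate_dataset(cfg)
        np.testing.assert_array_equal(X1.values, X2.values)
        np.testing.assert_array_equal(l1, l2)


class TestDrawClusterSizes:
    def test_constraints_respected(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            sizes = draw_cluster_sizes(8, 400, rng, min_size=3, max_size=200)
            assert sizes.sum() == 400 and sizes.min() >= 3 and sizes.max() <= 200


class TestGenerateNull:
    def test_standardizes_cleanly(self):
        X = generate_null(6, 80, 3.0, np.random.default_rng(5))
        Z = standardize_rows(X)
        np.testing.assert_allclose(Z.values.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(Z.values.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_seed_reproducibility(self):
        a = generate_null(4, 30, 1.0, np.random.default_rng(6)).values
        b = generate_null(4, 30, 1.0, np.random.default_rng(6)).values
        np.testing.assert_array_equal(a, b)


class TestFigure1Scenario:
    def test_shape_and_size_constraints(self):
        X, labels = figure1_scenario(seed=0)
        assert X.values.shape == (16, 2000)
        _, counts = np.unique(labels, return_counts=True)
        assert counts.size == 13
        assert counts.min() >= 2 and counts.max() <= 532 and counts.sum() == 2000

    def test_observed_heights_below_reference(self):
        """Clustered data concentrate agglomeration heights below the
        reshuffled-data reference (the median contrast of the worked example)."""
        X, _ = figure1_scenario(seed=1)
        Z = standardize_rows(X)
        D_o = normalized_heights(agglomerate(Z), Z.n_v)
        ref = reference_heights(Z, r=3, seed=1)
        assert np.median(D_o.values) < np.median(ref.values)

    def test_qq_departure_from_diagonal(self):
        """Clustered data bend the QQ curve: the bulk of observed heights sits
        well below the reference, while the between-cluster merges in the
        extreme tail rise past the reference's 95th percentile (the cut that
        separates significant clades)."""
        X, _ = figure1_scenario(seed=2)
        Z = standardize_rows(X)
        D_o = normalized_heights(agglomerate(Z), Z.n_v)
        ref = reference_heights(Z, r=3, seed=2)
        tab = qq_table(D_o, ref)
        m = len(tab)
        lo = tab.iloc[: m // 10]
        assert (lo["observed"] < lo["expected"]).mean() > 0.9
        thr = np.percentile(ref.values, 95)
        assert np.sum(D_o.values > thr) >= 8  # ~ n_c - 1 between-cluster merges


class TestSeparationTrend:
    def test_profile_separation_grows_with_dimension(self):
        """Expected normalized distance between distinct true profiles grows
        with the number of variables."""
        rng = np.random.default_rng(8)
        means = []
        for n_v in (2, 8, 20):
            d = []
            for _ in range(300):
                p = draw_profiles(2, n_v, 2.0, rng)
                d.append(np.linalg.norm(p[0] - p[1]))
            means.append(np.mean(d))
        assert means[0] < means[1] < means[2]
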