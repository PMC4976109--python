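import numpy as np
import pytest

from sigdendro.io import DataMatrix, standardize_rows
from sigdendro.linkage import MergeHeights, agglomerate, normalized_heights
from sigdendro.null_reference import (
    percentile,
    permute_rows,
    qq_table,
    reference_heights,
)

from _oracles import exact_reference_mean


class TestPermuteRows:
    def test_rows_are_permutations(self):
        rng = np.random.default_rng(0)
        Z = standardize_rows(DataMatrix(rng.normal(size=(5, 30))))
        P = permute_rows(Z, np.random.default_rng(1))
        for i in range(5):
            np.testing.assert_allclose(np.sort(P.values[i]), np.sort(Z.values[i]))

    def test_permuted_matrix_stays_standardized(self):
        rng = np.random.default_rng(2)
        Z = standardize_rows(DataMatrix(rng.normal(size=(6, 40))))
        P = permute_rows(Z, np.random.default_rng(3))
        np.testing.assert_allclose(P.values.mean(axis=1), 0, atol=1e-8)
        np.testing.assert_allclose(P.values.std(axis=1, ddof=1), 1, atol=1e-8)

    def test_two_samples_distance_invariant(self):
        rng = np.random.default_rng(4)
        Z = standardize_rows(DataMatrix(rng.normal(size=(4, 2))))
        d0 = np.linalg.norm(Z.values[:, 0] - Z.values[:, 1])
        for s in range(5):
            P = permute_rows(Z, np.random.default_rng(s))
            assert np.isclose(np.linalg.norm(P.values[:, 0] - P.values[:, 1]), d0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        Z = standardize_rows(DataMatrix(rng.normal(size=(3, 10))))
        a = permute_rows(Z, np.random.default_rng(9)).values
        b = permute_rows(Z, np.random.default_rng(9)).values
        np.testing.assert_array_equal(a, b)


class TestReferenceHeights:
    def test_two_samples_reference_equals_observed(self):
        rng = np.random.default_rng(6)
        Z = standardize_rows(DataMatrix(rng.normal(size=(5, 2))))
        D_o = normalized_heights(agglomerate(Z), Z.n_v)
        for r in (1, 3, 10):
            ref = reference_heights(Z, r=r, seed=0)
            np.testing.assert_array_equal(ref.values, D_o.values)

    def test_matches_exhaustive_enumeration(self, small_standardized):
        """Monte-Carlo D_e converges to the exact all-permutations mean."""
        Z = small_standardized
        exact = exact_reference_mean(Z.values)
        r = 2000
        ref = reference_heights(Z, r=r, seed=123)
        # element-wise MC standard error from an independent replicate batch
        rng = np.random.default_rng(321)
        draws = np.array([
            np.sort(agglomerate(permute_rows(Z, rng)).heights) / np.sqrt(Z.n_v)
            for _ in range(400)
        ])
        se = draws.std(axis=0, ddof=1) / np.sqrt(r)
        assert np.all(np.abs(ref.values - exact) <= 3 * se + 1e-12)

    def test_variance_scales_inversely_with_r(self, small_standardized):
        Z = small_standardized
        def batch_var(r, n=120, seed0=0):
            vals = np.array([
                reference_heights(Z, r=r, seed=seed0 + i).values for i in range(n)
            ])
            return vals.var(axis=0, ddof=1).mean()
        v1, v16 = batch_var(1), batch_var(16, seed0=10_000)
        assert v16 < v1 / 8  # ~1/16 expected, allow MC slack

    def test_bit_reproducible(self):
        rng = np.random.default_rng(7)
        Z = standardize_rows(DataMatrix(rng.normal(size=(4, 15))))
        a = reference_heights(Z, r=5, seed=99)
        b = reference_heights(Z, r=5, seed=99)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.r == 5 and a.seed == 99

    def test_sorted_and_sized(self):
        rng = np.random.default_rng(8)
        Z = standardize_rows(DataMatrix(rng.normal(size=(3, 12))))
        ref = reference_heights(Z, r=4, seed=1)
        assert len(ref) == 11
        assert np.all(np.diff(ref.values) >= 0)

    def test_r_validation(self):
        rng = np.random.default_rng(9)
        Z = standardize_rows(DataMatrix(rng.normal(size=(3, 5))))
        with pytest.raises(ValueError, match="r must be"):
            reference_heights(Z, r=0, seed=1)


class TestPercentile:
    def test_median_and_max(self):
        rng = np.random.default_rng(10)
        Z = standardize_rows(DataMatrix(rng.normal(size=(3, 6))))
        ref = reference_heights(Z, r=2, seed=0)
        ref.values = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert percentile(ref, 50) == 3.0
        assert percentile(ref, 100) == 5.0
        assert np.isclose(percentile(ref, 95), 4.8)  # type-7 interpolation

    @pytest.mark.parametrize("p", [0.0, -1.0, 101.0])
    def test_range_validation(self, p, small_standardized):
        ref = reference_heights(small_standardized, r=1, seed=0)
        with pytest.raises(ValueError):
            percentile(ref, p)


class TestQQTable:
    def test_identical_vectors_on_diagonal(self, small_standardized):
        ref = reference_heights(small_standardized, r=3, seed=0)
        mh = MergeHeights(ref.values.copy(), normalized=True)
        tab = qq_table(mh, ref)
        np.testing.assert_allclose(tab["observed"], tab["expected"])

    def test_length_mismatch_rejected(self, small_standardized):
        ref = reference_heights(small_standardized, r=1, seed=0)
        with pytest.raises(ValueError, match="equal length"):
            qq_table(MergeHeights(np.array([1.0, 2.0, 3.0])), ref)

    def test_null_data_stays_near_diagonal(self):
        """Without clusters the observed heights track the reference closely."""
        rng = np.random.default_rng(11)
        Z = standardize_rows(DataMatrix(rng.normal(size=(8, 120))))
        D_o = normalized_heights(agglomerate(Z), Z.n_v)
        ref = reference_heights(Z, r=10, seed=2)
        tab = qq_table(D_o, ref)
        spread = ref.values.max() - ref.values.min()
        assert np.abs(tab["observed"] - tab["expected"]).max() < 0.25 * spread
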