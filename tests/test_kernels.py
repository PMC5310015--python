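import numpy as np
import pytest

from tskcca import (
    DegenerateBankError,
    InvalidInputError,
    ViewMatrix,
    build_bank,
    combine,
    cross_bank,
    feature_wise_bank,
    median_bandwidth,
    normalize_bank,
    pair_wise_bank,
    rkhs_variance,
)


class TestMedianBandwidth:
    def test_scalar_inputs_enumerated_by_hand(self):
        # distances {1, 2, 3}, median 2 -> gamma = 0.5
        assert median_bandwidth(np.array([[0.0], [1.0], [3.0]])) == pytest.approx(0.5)

    def test_two_points_single_distance(self):
        assert median_bandwidth(np.array([[0.0], [4.0]])) == pytest.approx(0.25)

    def test_constant_input_falls_back_to_one(self):
        assert median_bandwidth(np.full((3, 1), 2.7)) == 1.0

    def test_single_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            median_bandwidth(np.array([[1.0]]))


class TestFeatureWiseBank:
    def test_one_kernel_per_feature_with_unit_diagonal(self, rng):
        view = ViewMatrix(rng.uniform(size=(8, 5)))
        bank = feature_wise_bank(view)
        assert len(bank) == 5
        for m, k in enumerate(bank.kernels):
            assert k.source == m
            np.testing.assert_allclose(np.diag(k.gram), 1.0)
            assert ((k.gram > 0) & (k.gram <= 1)).all()

    def test_off_diagonal_value_of_unit_gap(self):
        bank = feature_wise_bank(ViewMatrix(np.array([[0.0], [1.0]])), gamma=1.0)
        assert bank.kernels[0].gram[0, 1] == pytest.approx(np.exp(-1))

    def test_non_finite_view_rejected(self):
        with pytest.raises(InvalidInputError):
            ViewMatrix(np.array([[0.0], [np.nan]]))


class TestPairWiseBank:
    @pytest.mark.parametrize("d", range(2, 16))
    def test_counts_match_enumeration(self, rng, d):
        view = ViewMatrix(rng.uniform(size=(6, d)))
        pairs = [(m, m2) for m in range(d) for m2 in range(m + 1, d)]
        only_pairs = pair_wise_bank(view, include_features=False)
        assert len(only_pairs) == len(pairs) == d * (d - 1) // 2
        assert [k.source for k in only_pairs.kernels] == pairs
        full = pair_wise_bank(view, include_features=True)
        assert len(full) == d + d * (d - 1) // 2

    def test_two_features_single_pair(self, rng):
        bank = pair_wise_bank(
            ViewMatrix(rng.uniform(size=(5, 2))), include_features=False
        )
        assert len(bank) == 1 and bank.kernels[0].source == (0, 1)

    def test_single_feature_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            pair_wise_bank(ViewMatrix(rng.uniform(size=(5, 1))))


def test_all_grams_are_symmetric_psd(rng):
    view = ViewMatrix(rng.normal(size=(20, 4)))
    for bank in (feature_wise_bank(view), pair_wise_bank(view)):
        for k in bank.kernels:
            np.testing.assert_allclose(k.gram, k.gram.T)
            assert np.linalg.eigvalsh(k.gram).min() >= -1e-8


class TestRkhsVariance:
    def test_identity_gram(self):
        assert rkhs_variance(np.eye(2)) == pytest.approx(0.5)

    def test_constant_kernel_has_zero_variance(self):
        assert rkhs_variance(np.ones((4, 4))) == 0.0

    def test_normalization_fixed_point(self, rng):
        bank = normalize_bank(feature_wise_bank(ViewMatrix(rng.normal(size=(9, 3)))))
        for k in bank.kernels:
            assert rkhs_variance(k) == pytest.approx(1.0, abs=1e-10)


class TestNormalizeBank:
    def test_divides_by_variance(self, rng):
        bank = feature_wise_bank(ViewMatrix(rng.uniform(size=(7, 2))))
        normed = normalize_bank(bank)
        for raw, out in zip(bank.kernels, normed.kernels):
            np.testing.assert_allclose(out.gram, raw.gram / rkhs_variance(raw))

    def test_zero_variance_kernel_dropped(self, rng):
        values = rng.uniform(size=(6, 3))
        values[:, 1] = 0.42  # constant feature -> all-ones gram
        bank = normalize_bank(feature_wise_bank(ViewMatrix(values)))
        assert len(bank) == 2 and [k.source for k in bank.kernels] == [0, 2]

    def test_idempotent(self, rng):
        bank = normalize_bank(feature_wise_bank(ViewMatrix(rng.normal(size=(6, 2)))))
        assert normalize_bank(bank) is bank

    def test_empty_after_dropping_raises(self):
        view = ViewMatrix(np.full((5, 2), 3.0))
        with pytest.raises(DegenerateBankError):
            normalize_bank(feature_wise_bank(view))


class TestCombine:
    def test_one_hot_returns_that_kernel(self, rng):
        bank = feature_wise_bank(ViewMatrix(rng.uniform(size=(6, 3))))
        np.testing.assert_allclose(
            combine(bank, np.array([0.0, 1.0, 0.0])), bank.kernels[1].gram
        )

    def test_zero_weights_give_zero_matrix(self, rng):
        bank = feature_wise_bank(ViewMatrix(rng.uniform(size=(6, 3))))
        assert not combine(bank, np.zeros(3)).any()

    def test_uniform_weights_equal_brute_force_mean(self, rng):
        bank = feature_wise_bank(ViewMatrix(rng.uniform(size=(6, 4))))
        acc = np.zeros((6, 6))
        for k in bank.kernels:
            acc += k.gram / 4
        np.testing.assert_allclose(combine(bank, np.full(4, 0.25)), acc, atol=1e-12)

    def test_bad_weights_rejected(self, rng):
        bank = feature_wise_bank(ViewMatrix(rng.uniform(size=(6, 3))))
        with pytest.raises(InvalidInputError):
            combine(bank, np.ones(2))
        with pytest.raises(InvalidInputError):
            combine(bank, np.array([0.5, -0.1, 0.6]))


class TestCrossBank:
    def test_self_consistency_and_metadata_reuse(self, rng):
        train = ViewMatrix(rng.uniform(size=(8, 3)))
        bank = normalize_bank(build_bank(train, "feature+pair"))
        crosses = cross_bank(train, train, bank)
        for cross, k in zip(crosses, bank.kernels):
            np.testing.assert_allclose(cross, k.gram, atol=1e-12)

    def test_test_point_equal_to_training_point(self, rng):
        train = ViewMatrix(rng.uniform(size=(8, 2)))
        test = ViewMatrix(train.values[[3]].repeat(2, axis=0), train.feature_names)
        bank = normalize_bank(feature_wise_bank(train))
        for cross, k in zip(cross_bank(train, test, bank), bank.kernels):
            np.testing.assert_allclose(cross[0], k.gram[3], atol=1e-12)

    def test_feature_mismatch_rejected(self, rng):
        train = ViewMatrix(rng.uniform(size=(6, 2)), ["a", "b"])
        test = ViewMatrix(rng.uniform(size=(4, 2)), ["a", "c"])
        bank = normalize_bank(feature_wise_bank(train))
        with pytest.raises(InvalidInputError):
            cross_bank(train, test, bank)
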