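import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tskcca import (
    DegenerateVectorError,
    InvalidInputError,
    l1_bound_delta,
    pmd_decompose,
    pmd_rank1,
    soft_threshold,
)
from tskcca.pmd import _sparse_unit


class TestSoftThreshold:
    def test_printed_formula(self):
        np.testing.assert_allclose(
            soft_threshold(np.array([3.0, -1.0, 0.5]), 1.0), [2.0, 0.0, 0.0]
        )

    def test_zero_threshold_is_identity(self, rng):
        a = rng.normal(size=6)
        np.testing.assert_allclose(soft_threshold(a, 0.0), a)

    def test_full_shrinkage(self, rng):
        a = rng.normal(size=6)
        assert not soft_threshold(a, np.abs(a).max()).any()


class TestL1BoundDelta:
    def test_unit_coordinate_needs_no_threshold(self):
        assert l1_bound_delta(np.array([1.0, 0.0]), 1.0) == 0.0

    def test_two_equal_entries_forced_to_one_nonzero(self):
        # normalized L1 of two equal entries is sqrt(2) > 1, so thresholding
        # alone cannot satisfy c=1; the half-update breaks the tie by index
        u = _sparse_unit(np.array([1.0, 1.0]), 1.0)
        np.testing.assert_allclose(u, [1.0, 0.0])

    def test_bisection_matches_brute_force_two_element_case(self):
        a, c = np.array([2.0, 1.0]), 1.2
        delta = l1_bound_delta(a, c)
        # brute-force oracle: scan a fine delta grid for the smallest feasible
        grid = np.linspace(0, 2, 200001)
        s = np.sign(a) * np.maximum(np.abs(a)[None, :] - grid[:, None], 0)
        nrm = np.linalg.norm(s, axis=1)
        feasible = grid[(nrm > 0) & (np.abs(s).sum(axis=1) <= c * nrm)]
        assert delta == pytest.approx(feasible.min(), abs=1e-4)
        u = _sparse_unit(a, c)
        assert np.abs(u).sum() <= c + 1e-6
        assert np.linalg.norm(u) == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=12))
    def test_budget_at_cauchy_schwarz_bound_never_binds(self, values):
        a = np.asarray(values)
        if not np.any(a):
            return
        assert l1_bound_delta(a, np.sqrt(len(a))) == 0.0

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateVectorError):
            l1_bound_delta(np.zeros(3), 1.0)


class TestPmdRank1:
    def test_diagonal_matrix_unconstrained(self):
        pair = pmd_rank1(np.diag([3.0, 1.0]), np.sqrt(2), np.sqrt(2))
        np.testing.assert_allclose(pair.eta, [1.0, 0.0], atol=1e-8)
        np.testing.assert_allclose(pair.mu, [1.0, 0.0], atol=1e-8)
        assert pair.d == pytest.approx(3.0)

    def test_unit_budget_forces_coordinate_vectors(self, rng):
        m = rng.uniform(size=(6, 5))
        pair = pmd_rank1(m, 1.0, 1.0)
        assert np.count_nonzero(pair.eta) == 1
        assert np.count_nonzero(pair.mu) == 1

    def test_unconstrained_budget_matches_dense_svd(self, rng):
        # Perron-Frobenius: the top singular pair of a positive matrix is
        # positive, so the non-negativity constraint is inactive
        m = rng.uniform(0.1, 1.0, size=(6, 5))
        u, s, vt = np.linalg.svd(m)
        pair = pmd_rank1(m, np.sqrt(6), np.sqrt(5))
        assert pair.d == pytest.approx(s[0], abs=1e-6)
        np.testing.assert_allclose(pair.eta, np.abs(u[:, 0]), atol=1e-6)
        np.testing.assert_allclose(pair.mu, np.abs(vt[0]), atol=1e-6)

    def test_constraints_hold_on_random_instances(self, rng):
        for _ in range(10):
            m = rng.normal(size=(7, 6))
            c1 = rng.uniform(1, np.sqrt(7))
            c2 = rng.uniform(1, np.sqrt(6))
            pair = pmd_rank1(m, c1, c2)
            for v, c in ((pair.eta, c1), (pair.mu, c2)):
                assert (v >= 0).all()
                assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-8)
                assert np.abs(v).sum() <= c + 1e-6

    def test_objective_monotone_over_sweeps(self, rng):
        m = rng.normal(size=(8, 8))
        c1 = c2 = 1.5
        eta = np.abs(np.linalg.svd(m)[0][:, 0])
        eta /= np.linalg.norm(eta)
        obj = -np.inf
        for _ in range(25):
            mu = _sparse_unit(m.T @ eta, c2)
            eta = _sparse_unit(m @ mu, c1)
            new = eta @ m @ mu
            assert new >= obj - 1e-7  # allow Delta-bisection jitter
            obj = new

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(InvalidInputError):
            pmd_rank1(np.zeros((3, 3)), 1.0, 1.0)


def _disjoint_rank_k(rng, shape=(6, 5), k=2):
    """Non-negative matrix whose singular vectors are non-negative with
    disjoint supports, so the constrained decomposition can match the SVD."""
    m = np.zeros(shape)
    svals = [5.0, 2.0]
    us, vs = [], []
    for i in range(k):
        u = np.zeros(shape[0])
        v = np.zeros(shape[1])
        u[3 * i : 3 * i + 3] = rng.uniform(0.5, 1.0, 3)
        v[2 * i : 2 * i + 2] = rng.uniform(0.5, 1.0, 2)
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        m += svals[i] * np.outer(u, v)
        us.append(u)
        vs.append(v)
    return m, svals, us, vs


class TestPmdDecompose:
    def test_rank1_matrix_recovered_then_exhausted(self, rng):
        u = rng.uniform(0.2, 1.0, 5)
        v = rng.uniform(0.2, 1.0, 4)
        m = np.outer(u, v)
        pairs = pmd_decompose(m, np.sqrt(5), np.sqrt(4), n_components=2)
        np.testing.assert_allclose(pairs[0].eta, u / np.linalg.norm(u), atol=1e-6)
        np.testing.assert_allclose(pairs[0].mu, v / np.linalg.norm(v), atol=1e-6)
        assert len(pairs) == 1 or abs(pairs[1].d) < 1e-8

    def test_disjoint_support_factors_match_svd(self, rng):
        m, svals, us, vs = _disjoint_rank_k(rng)
        pairs = pmd_decompose(m, np.sqrt(6), np.sqrt(5), n_components=2)
        for pair, s, u, v in zip(pairs, svals, us, vs):
            assert pair.d == pytest.approx(s, abs=1e-6)
            np.testing.assert_allclose(pair.eta, u, atol=1e-6)
            np.testing.assert_allclose(pair.mu, v, atol=1e-6)

    def test_deflation_exhausts_factorizable_matrix(self, rng):
        m, *_ = _disjoint_rank_k(rng)
        pairs = pmd_decompose(m, np.sqrt(6), np.sqrt(5), n_components=2)
        residual = m.copy()
        for pair in pairs:
            residual -= pair.d * np.outer(pair.eta, pair.mu)
        assert np.linalg.norm(residual) < 1e-8

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            pmd_decompose(rng.uniform(size=(3, 2)), 1.0, 1.0, n_components=3)
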