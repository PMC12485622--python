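import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import omicsgp as og
from omicsgp.kernels import KernelError, min_eigenvalue_ratio

from conftest import make_feature_matrix, random_psd_kernel


class TestLinearKernel:
    def test_two_by_two_hand_example(self):
        fm = make_feature_matrix([[1.0, -1.0], [-1.0, 1.0]])
        K = og.linear_kernel(fm)
        np.testing.assert_allclose(K.values, [[1, -1], [-1, 1]])

    def test_zero_input_gives_zero_kernel(self):
        fm = make_feature_matrix(np.zeros((3, 2)))
        np.testing.assert_array_equal(og.linear_kernel(fm).values, np.zeros((3, 3)))

    def test_matches_elementwise_sum(self, rng):
        X = rng.standard_normal((5, 3))
        K = og.linear_kernel(make_feature_matrix(X)).values
        for i in range(5):
            for j in range(5):
                assert K[i, j] == pytest.approx(
                    sum(X[i, k] * X[j, k] for k in range(3)) / 3
                )

    def test_psd_without_repair(self, rng):
        K = og.linear_kernel(make_feature_matrix(rng.standard_normal((8, 4))))
        assert min_eigenvalue_ratio(K) >= -1e-10


class TestVanRaden:
    def test_hand_example(self):
        geno = make_feature_matrix([[0, 2], [1, 1], [2, 0]], layer="genomic")
        K = og.vanraden_kernel(geno)
        # p = (0.5, 0.5); denominator = 2*(0.25+0.25) = 1; Z = M - 1
        Z = np.array([[0, 2], [1, 1], [2, 0]], dtype=float) - 1.0
        np.testing.assert_allclose(K.values, Z @ Z.T)

    def test_matches_brute_force_formula(self, rng):
        M = rng.integers(0, 3, size=(6, 10)).astype(float)
        M[:, 0] = [0, 1, 2, 0, 1, 2]  # guarantee polymorphism
        K = og.vanraden_kernel(make_feature_matrix(M, layer="genomic")).values
        p = M.mean(axis=0) / 2
        expected = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                expected[i, j] = sum(
                    (M[i, k] - 2 * p[k]) * (M[j, k] - 2 * p[k]) for k in range(10)
                ) / (2 * sum(pk * (1 - pk) for pk in p))
        np.testing.assert_allclose(K, expected, atol=1e-12)
        assert min_eigenvalue_ratio(
            og.vanraden_kernel(make_feature_matrix(M, layer="genomic"))
        ) >= -1e-10

    def test_monomorphic_only_errors(self):
        geno = make_feature_matrix([[2, 0], [2, 0], [2, 0]], layer="genomic")
        with pytest.raises(KernelError, match="monomorphic"):
            og.vanraden_kernel(geno)

    def test_non_dosage_coding_rejected(self):
        geno = make_feature_matrix([[0.5, 1], [1, 2], [2, 0]], layer="genomic")
        with pytest.raises(KernelError, match="0/1/2"):
            og.vanraden_kernel(geno)


class TestGaussianKernel:
    def test_diagonal_exactly_one(self, rng):
        K = og.gaussian_kernel(make_feature_matrix(rng.standard_normal((6, 3))))
        np.testing.assert_array_equal(np.diag(K.values), np.ones(6))

    def test_two_lines_give_exp_minus_one(self, rng):
        K = og.gaussian_kernel(make_feature_matrix(rng.standard_normal((2, 4))))
        assert K.values[0, 1] == pytest.approx(np.exp(-1.0))

    def test_matches_brute_force(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 1.0]])
        K = og.gaussian_kernel(make_feature_matrix(X))
        d2 = np.array(
            [[np.sum((X[i] - X[j]) ** 2) for j in range(4)] for i in range(4)]
        )
        sigma = np.median(d2[np.triu_indices(4, k=1)])
        np.testing.assert_allclose(K.values, np.exp(-d2 / sigma), atol=1e-12)
        assert K.bandwidth == pytest.approx(sigma)

    def test_entries_in_unit_interval_and_identity_iff_equal_rows(self, rng):
        X = rng.standard_normal((5, 3))
        X[3] = X[1]  # duplicated line
        K = og.gaussian_kernel(make_feature_matrix(X)).values
        assert (K > 0).all() and (K <= 1).all()
        off = K[np.triu_indices(5, k=1)]
        eq = np.isclose(off, 1.0)
        assert eq.sum() == 1 and K[1, 3] == pytest.approx(1.0)

    def test_identical_rows_degenerate_bandwidth(self):
        X = np.ones((3, 2))
        with pytest.raises(KernelError, match="bandwidth"):
            og.gaussian_kernel(make_feature_matrix(X))


class TestHybridKernels:
    def test_identity_bases(self):
        ids = ["L1", "L2", "L3"]
        I = og.KernelMatrix(line_ids=ids, values=np.eye(3), recipe="i")
        K_cc, K_pp = og.hybrid_kernels(I, I)
        np.testing.assert_array_equal(K_cc.values, 2 * np.eye(3))
        np.testing.assert_array_equal(K_pp.values, np.zeros((3, 3)))

    def test_three_by_three_triangle_decomposition(self):
        ids = ["L1", "L2", "L3"]
        K1 = og.KernelMatrix(
            ids, np.array([[2.0, 1.0, 0.5], [1.0, 2.0, 1.0], [0.5, 1.0, 2.0]]), "k1"
        )
        K2 = og.KernelMatrix(
            ids, np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.5], [0.2, 0.5, 1.0]]), "k2"
        )
        P = K1.values @ K2.values
        UT = np.zeros((3, 3))
        LT = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if j >= i:
                    UT[i, j] = P[i, j]
                else:
                    LT[i, j] = P[i, j]
        K_cc, K_pp = og.hybrid_kernels(K1, K2)
        np.testing.assert_allclose(K_cc.values, UT + UT.T, atol=1e-12)
        np.testing.assert_allclose(K_pp.values, LT + LT.T, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 12))
    def test_cc_plus_pp_equals_symmetrized_product(self, seed, n):
        rng = np.random.default_rng(seed)
        ids = [f"L{i}" for i in range(n)]
        K1 = random_psd_kernel(rng, n, ids)
        K2 = random_psd_kernel(rng, n, ids)
        K_cc, K_pp = og.hybrid_kernels(K1, K2)
        P = K1.values @ K2.values
        np.testing.assert_allclose(K_cc.values + K_pp.values, P + P.T, atol=1e-10)

    def test_commuting_bases_give_symmetric_psd_product(self, rng):
        # K2 a polynomial of K1: the product itself is symmetric PSD, so
        # repairing it is a no-op (the symmetrized triangles still shift the
        # diagonal and are repaired separately).
        K1 = random_psd_kernel(rng, 6)
        K2 = og.KernelMatrix(K1.line_ids, K1.values @ K1.values, "k1sq")
        P = og.KernelMatrix(K1.line_ids, K1.values @ K2.values, "prod")
        np.testing.assert_allclose(og.psd_repair(P).values, P.values, atol=1e-8)
        K_cc, K_pp = og.hybrid_kernels(K1, K2)
        np.testing.assert_allclose(
            K_cc.values + K_pp.values, 2 * P.values, atol=1e-10
        )

    def test_id_mismatch_rejected(self, rng):
        K1 = random_psd_kernel(rng, 4, ids=["A", "B", "C", "D"])
        K2 = random_psd_kernel(rng, 4, ids=["A", "B", "C", "E"])
        with pytest.raises(KernelError, match="mismatch"):
            og.hybrid_kernels(K1, K2)


class TestHadamard:
    def test_all_ones_is_identity_element(self, rng):
        K1 = random_psd_kernel(rng, 5)
        ones = og.KernelMatrix(K1.line_ids, np.ones((5, 5)), "ones")
        np.testing.assert_array_equal(
            og.hadamard_kernel(K1, ones).values, K1.values
        )

    def test_psd_preserved(self, rng):
        K1, K2 = random_psd_kernel(rng, 7), random_psd_kernel(rng, 7)
        K = og.hadamard_kernel(K1, K2)
        assert min_eigenvalue_ratio(K) >= -1e-10


class TestScaleAndRepair:
    def test_scale_two_i(self):
        K = og.KernelMatrix(["A", "B"], 2 * np.eye(2), "k")
        np.testing.assert_array_equal(og.scale_kernel(K).values, np.eye(2))

    def test_scale_idempotent_and_mean_diag_one(self, rng):
        K = og.scale_kernel(random_psd_kernel(rng, 6))
        assert np.diag(K.values).mean() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(og.scale_kernel(K).values, K.values)

    def test_scale_preserves_eigenvectors(self, rng):
        K = random_psd_kernel(rng, 5)
        scaled = og.scale_kernel(K)
        ratio = scaled.values / K.values
        assert np.allclose(ratio, ratio.flat[0])

    def test_repair_psd_input_unchanged(self, rng):
        K = random_psd_kernel(rng, 6)
        np.testing.assert_allclose(og.psd_repair(K).values, K.values, atol=1e-10)

    def test_repair_two_by_two_hand_example(self):
        # eigenvalues 3 and -1; clipping keeps 1.5 * ones(2, 2)
        K = og.KernelMatrix(["A", "B"], np.array([[1.0, 2.0], [2.0, 1.0]]), "k")
        np.testing.assert_allclose(
            og.psd_repair(K).values, 1.5 * np.ones((2, 2)), atol=1e-12
        )

    def test_repair_postcondition_on_indefinite_inputs(self, rng):
        for _ in range(10):
            A = rng.standard_normal((6, 6))
            K = og.KernelMatrix(
                [f"L{i}" for i in range(6)], (A + A.T) / 2, "indef"
            )
            assert min_eigenvalue_ratio(og.psd_repair(K)) >= -1e-8

    def test_repair_rejects_asymmetry(self):
        with pytest.raises(KernelError):
            og.KernelMatrix(["A", "B"], np.array([[1.0, 2.0], [0.0, 1.0]]), "bad")
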