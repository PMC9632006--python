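import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xgbcda import (
    AssociationMatrix,
    ExpressionProfileSet,
    GipConfig,
    PearsonConfig,
    SimilarityMatrix,
    ValidationError,
    expand_similarity,
    expression_profile_similarity,
    gip_kernel,
    integrate_similarity,
)
from oracles import gip_kernel_brute


def expr_of(rows, ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    ids = ids or [f"c{i}" for i in range(rows.shape[0])]
    return ExpressionProfileSet(ids, [f"s{j}" for j in range(rows.shape[1])], rows)


class TestExpressionProfileSimilarity:
    def test_identical_profiles_similar(self):
        sim = expression_profile_similarity(expr_of([[1, 2, 3], [1, 2, 3]]))
        assert sim.values[0, 1] == 1.0

    def test_anticorrelated_profiles_dissimilar(self):
        # hand evaluation: r([1,2,3],[3,2,1]) = -1 < 0.4
        sim = expression_profile_similarity(expr_of([[1, 2, 3], [3, 2, 1]]))
        assert sim.values[0, 1] == 0.0

    def test_constant_profile_scores_zero(self):
        sim = expression_profile_similarity(expr_of([[1, 1, 1], [1, 2, 3]]))
        assert sim.values[0, 1] == 0.0
        assert sim.values[0, 0] == 1.0  # diagonal forced

    def test_threshold_is_strict(self):
        # r = 1 exactly for identical profiles: not *strictly* above threshold 1
        sim = expression_profile_similarity(
            expr_of([[1, 2, 3], [1, 2, 3]]), PearsonConfig(threshold=1.0)
        )
        assert sim.values[0, 1] == 0.0
        assert sim.values[0, 0] == 1.0  # diagonal still forced

    @settings(derandomize=True, max_examples=25)
    @given(
        scale=st.floats(0.1, 50.0),
        shift=st.floats(-20.0, 20.0),
        seed=st.integers(0, 10_000),
    )
    def test_affine_rescaling_invariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(4, 8))
        base = expression_profile_similarity(expr_of(X))
        X2 = X.copy()
        X2[1] = scale * X2[1] + shift
        rescaled = expression_profile_similarity(expr_of(X2))
        np.testing.assert_array_equal(base.values, rescaled.values)


class TestGipKernel:
    def test_worked_two_profile_value(self):
        # y1=[1,0], y2=[0,1], gamma'=1 -> gamma = 1/((1+1)/2) = 1, K12 = exp(-2)
        assoc = AssociationMatrix(["c1", "c2"], ["d1", "d2"], np.eye(2, dtype=int))
        K = gip_kernel(assoc, "circRNA", GipConfig(1.0))
        assert K.values[0, 1] == pytest.approx(math.exp(-2), abs=1e-9)

    def test_identical_profiles_have_unit_similarity(self):
        assoc = AssociationMatrix(["c1", "c2"], ["d1", "d2"], np.array([[1, 0], [1, 0]]))
        K = gip_kernel(assoc, "circRNA")
        assert K.values[0, 1] == 1.0

    def test_all_zero_matrix_raises(self):
        assoc = AssociationMatrix(["c1"], ["d1", "d2"], np.zeros((1, 2), dtype=int))
        with pytest.raises(ValidationError, match="division by zero"):
            gip_kernel(assoc, "circRNA")

    @pytest.mark.parametrize("axis", ["circRNA", "disease"])
    def test_matches_brute_force_double_loop(self, axis):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_c, n_d = rng.integers(2, 10, size=2)
            A = rng.integers(0, 2, size=(n_c, n_d))
            if not A.any():
                A[0, 0] = 1
            assoc = AssociationMatrix([f"c{i}" for i in range(n_c)], [f"d{j}" for j in range(n_d)], A)
            K = gip_kernel(assoc, axis)
            expected = gip_kernel_brute(A.astype(float), axis)
            np.testing.assert_allclose(K.values, expected, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        A = rng.integers(0, 2, size=(6, 4))
        A[0, 0] = 1
        ids_c = [f"c{i}" for i in range(6)]
        ids_d = [f"d{j}" for j in range(4)]
        K = gip_kernel(AssociationMatrix(ids_c, ids_d, A), "circRNA").values
        perm = rng.permutation(6)
        Kp = gip_kernel(
            AssociationMatrix([ids_c[i] for i in perm], ids_d, A[perm]), "circRNA"
        ).values
        np.testing.assert_allclose(Kp, K[np.ix_(perm, perm)], atol=1e-12)


class TestIntegration:
    def rand_sim(self, rng, n, binary=False):
        M = rng.random((n, n))
        M = (M + M.T) / 2
        if binary:
            M = (M > 0.5).astype(float)
        np.fill_diagonal(M, 1.0)
        return SimilarityMatrix([f"x{i}" for i in range(n)], M)

    def test_primary_wins_wherever_nonzero(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = rng.integers(2, 8)
            primary = self.rand_sim(rng, n, binary=True)
            fallback = self.rand_sim(rng, n)
            out = integrate_similarity(primary, fallback)
            mask = primary.values != 0
            np.testing.assert_array_equal(out.values[mask], primary.values[mask])
            np.testing.assert_array_equal(out.values[~mask], fallback.values[~mask])

    def test_support_is_union(self):
        rng = np.random.default_rng(2)
        primary = self.rand_sim(rng, 6, binary=True)
        fallback = self.rand_sim(rng, 6, binary=True)
        out = integrate_similarity(primary, fallback)
        np.testing.assert_array_equal(
            out.values != 0, (primary.values != 0) | (fallback.values != 0)
        )

    def test_idempotent_when_equal(self):
        rng = np.random.default_rng(4)
        sim = self.rand_sim(rng, 5)
        out = integrate_similarity(sim, sim)
        np.testing.assert_array_equal(out.values, sim.values)

    def test_id_mismatch_rejected(self):
        a = SimilarityMatrix(["x"], np.array([[1.0]]))
        b = SimilarityMatrix(["y"], np.array([[1.0]]))
        with pytest.raises(ValidationError, match="id"):
            integrate_similarity(a, b)


class TestExpand:
    def test_missing_ids_get_zero_rows_and_unit_diagonal(self):
        sim = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        big = expand_similarity(sim, ["a", "c", "b"])
        assert big.values[big.ids.index("c"), big.ids.index("c")] == 1.0
        assert big.values[big.ids.index("c"), big.ids.index("a")] == 0.0
        assert big.values[big.ids.index("a"), big.ids.index("b")] == 0.5
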