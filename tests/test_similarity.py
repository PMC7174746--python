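import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hetelink import AssociationMatrix, fuse_ef_similarity, gip_kernel, logistic_transform
from hetelink.core_io import SimilarityMatrix, ValidationError


def assoc_from(values):
    values = np.asarray(values, float)
    nl, ne = values.shape
    return AssociationMatrix(
        values, tuple(f"L{i}" for i in range(nl)), tuple(f"E{j}" for j in range(ne))
    )


class TestGipKernel:
    def test_identity_association_closed_form(self, tiny_assoc):
        # profiles (1,0) and (0,1): mean squared norm 1 -> gamma=1, off-diag exp(-2)
        K = gip_kernel(tiny_assoc, "lnc", 1.0)
        np.testing.assert_allclose(K.values[0, 1], np.exp(-2), atol=1e-12)
        np.testing.assert_allclose(np.diag(K.values), 1.0)

    def test_identical_profiles_score_one(self):
        A = assoc_from([[1, 0], [1, 0], [0, 1]])
        K = gip_kernel(A, "lnc")
        assert K.values[0, 1] == pytest.approx(1.0)

    def test_all_ones_matrix_gives_all_ones_kernel(self):
        K = gip_kernel(assoc_from(np.ones((3, 2))), "lnc")
        np.testing.assert_allclose(K.values, 1.0)

    def test_all_zero_profiles_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            gip_kernel(assoc_from(np.zeros((2, 2))), "ef")

    def test_ef_axis_uses_columns(self):
        A = assoc_from([[1, 0], [0, 1], [1, 0]])
        K = gip_kernel(A, "ef")
        assert K.n == 2

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(np.int8, (5, 4), elements=st.integers(0, 1)).filter(
            lambda a: a.sum() > 0
        ),
        st.floats(0.1, 5.0),
    )
    def test_kernel_is_valid_similarity(self, values, gamma_prime):
        K = gip_kernel(assoc_from(values), "lnc", gamma_prime)
        assert np.allclose(K.values, K.values.T)
        assert np.all(np.diag(K.values) == 1.0)
        assert K.values.min() > 0 and K.values.max() <= 1

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        values = (rng.random((6, 4)) < 0.4).astype(float)
        values[0, 0] = 1  # ensure non-degenerate
        A = assoc_from(values)
        K = gip_kernel(A, "lnc").values
        perm = rng.permutation(6)
        Ap = AssociationMatrix(
            values[perm], tuple(f"L{i}" for i in perm), A.ef_ids
        )
        Kp = gip_kernel(Ap, "lnc").values
        np.testing.assert_allclose(Kp, K[np.ix_(perm, perm)], atol=1e-12)


class TestLogisticTransform:
    def test_kernel_zero_maps_to_1e4(self, tiny_assoc):
        K = SimilarityMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), ("L1", "L2"), "gip_lnc")
        S = logistic_transform(K)
        assert S.values[0, 1] == pytest.approx(1e-4, rel=1e-9)

    def test_kernel_one_maps_near_one(self):
        K = SimilarityMatrix(np.ones((2, 2)), ("L1", "L2"), "gip_lnc")
        S = logistic_transform(K)
        expected = 1.0 / (1.0 + 9999.0 * np.exp(-15.0))
        assert S.values[0, 0] == pytest.approx(expected, rel=1e-9)
        assert S.values[0, 0] == pytest.approx(0.99695, abs=5e-5)

    def test_degenerate_coefficients_give_constant_half(self):
        K = SimilarityMatrix(np.eye(3), tuple("abc"), "gip_lnc")
        S = logistic_transform(K, c=0.0, v=0.0)
        np.testing.assert_allclose(S.values, 0.5)

    def test_monotone_in_kernel_for_negative_c(self):
        k = np.linspace(0, 1, 11)
        K = SimilarityMatrix(
            np.minimum(k[:, None], k[None, :]) * 0 + np.add.outer(k, k) / 2,
            tuple(str(i) for i in range(11)),
            "gip_lnc",
        )
        S = logistic_transform(K)
        flat_k = K.values.ravel()
        flat_s = S.values.ravel()
        order = np.argsort(flat_k)
        assert np.all(np.diff(flat_s[order]) >= -1e-15)


class TestFuseEfSimilarity:
    def _ke(self, values, ids):
        return SimilarityMatrix(np.asarray(values, float), ids, "gip_ef")

    def test_weighted_blend_closed_form(self):
        E = SimilarityMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), ("E1", "E2"), "chemical")
        KE = self._ke([[1.0, 0.3], [0.3, 1.0]], ("E1", "E2"))
        SE = fuse_ef_similarity(E, KE, ew=0.7)
        assert SE.values[0, 1] == pytest.approx(0.7 * 0.5 + 0.3 * 0.3)
        assert SE.values[0, 1] == pytest.approx(0.44)

    def test_zero_chemical_entry_falls_back_to_kernel(self):
        E = SimilarityMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), ("E1", "E2"), "chemical")
        KE = self._ke([[1.0, 0.3], [0.3, 1.0]], ("E1", "E2"))
        SE = fuse_ef_similarity(E, KE, ew=0.7)
        assert SE.values[0, 1] == pytest.approx(0.3)

    def test_zero_weight_returns_kernel(self):
        E = SimilarityMatrix(np.full((2, 2), 0.5), ("E1", "E2"), "chemical")
        KE = self._ke([[1.0, 0.3], [0.3, 1.0]], ("E1", "E2"))
        SE = fuse_ef_similarity(E, KE, ew=0.0)
        assert SE.values[0, 1] == pytest.approx(0.3)

    def test_missing_chemical_ids_take_fallback_branch(self):
        E = SimilarityMatrix(np.array([[1.0]]), ("E1",), "chemical")
        KE = self._ke([[1.0, 0.3], [0.3, 1.0]], ("E1", "E2"))
        SE = fuse_ef_similarity(E, KE, ew=0.7)
        assert SE.values[0, 1] == pytest.approx(0.3)

    def test_absent_chemical_matrix_returns_kernel_with_unit_diagonal(self):
        KE = self._ke([[0.9, 0.3], [0.3, 0.9]], ("E1", "E2"))
        SE = fuse_ef_similarity(None, KE, ew=0.7)
        assert SE.values[0, 1] == pytest.approx(0.3)
        np.testing.assert_allclose(np.diag(SE.values), 1.0)

    def test_unknown_chemical_id_rejected(self):
        E = SimilarityMatrix(np.array([[1.0]]), ("EX",), "chemical")
        KE = self._ke([[1.0, 0.3], [0.3, 1.0]], ("E1", "E2"))
        with pytest.raises(ValidationError):
            fuse_ef_similarity(E, KE)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.01, 1.0), st.floats(0.0, 1.0))
    def test_fused_value_between_inputs_when_chemical_nonzero(self, ew, e, ke):
        E = SimilarityMatrix(np.array([[1.0, e], [e, 1.0]]), ("E1", "E2"), "chemical")
        KE = self._ke([[1.0, ke], [ke, 1.0]], ("E1", "E2"))
        fused = fuse_ef_similarity(E, KE, ew=ew).values[0, 1]
        assert min(e, ke) - 1e-12 <= fused <= max(e, ke) + 1e-12
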