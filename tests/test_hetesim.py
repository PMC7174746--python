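from itertools import product

import numpy as np
import pytest

from hetelink import (
    AssociationMatrix,
    MetaPath,
    SimilarityMatrix,
    build_transitions,
    enumerate_metapaths,
    hetesim_features,
    hetesim_score,
    reachable_matrix,
)

TABLE_PATHS = [
    "LLE", "LEE",
    "LLLE", "LELE", "LLEE", "LEEE",
    "LLLLE", "LLLEE", "LLELE", "LLEEE", "LELLE", "LELEE", "LEELE", "LEEEE",
]


def trans_from(SL, A, SE):
    SL, A, SE = (np.asarray(m, float) for m in (SL, A, SE))
    nl, ne = A.shape
    lnc = tuple(f"L{i}" for i in range(nl))
    ef = tuple(f"E{j}" for j in range(ne))
    return build_transitions(
        SimilarityMatrix(SL, lnc, "fused_lnc"),
        AssociationMatrix(A, lnc, ef),
        SimilarityMatrix(SE, ef, "fused_ef"),
    )


def brute_force_reachable(trans, types):
    """Explicit path-instance probability summation (independent oracle).

    Sums, over every concrete node sequence matching the type sequence,
    the product of one-step transition probabilities.
    """
    sizes = {"L": trans.nl, "E": trans.ne}
    n_src, n_dst = sizes[types[0]], sizes[types[-1]]
    R = np.zeros((n_src, n_dst))
    interiors = [range(sizes[t]) for t in types[1:-1]]
    for i in range(n_src):
        for nodes in product(*interiors):
            for j in range(n_dst):
                seq = (i, *nodes, j)
                prob = 1.0
                for (a, b), (ta, tb) in zip(
                    zip(seq[:-1], seq[1:]), zip(types[:-1], types[1:])
                ):
                    prob *= trans.step(ta, tb)[a, b]
                R[i, j] += prob
    return R


def brute_force_hetesim(trans, types, mid):
    """Evaluate one midpoint split directly from oracle reachable vectors."""
    left = types[:mid]
    right_rev = types[mid - 1:][::-1]
    L = brute_force_reachable(trans, left)
    R = brute_force_reachable(trans, right_rev)
    out = np.zeros((L.shape[0], R.shape[0]))
    for i in range(L.shape[0]):
        for j in range(R.shape[0]):
            ln, rn = np.linalg.norm(L[i]), np.linalg.norm(R[j])
            out[i, j] = (L[i] @ R[j]) / (ln * rn) if ln > 0 and rn > 0 else 0.0
    return out


class TestEnumeration:
    def test_canonical_fourteen_paths(self):
        paths = enumerate_metapaths(4)
        assert len(paths) == 14
        assert [p.name for p in paths[:2]] == ["LLE", "LEE"]
        by_len = {}
        for p in paths:
            by_len.setdefault(p.m, []).append(p.name)
        assert {m: len(v) for m, v in by_len.items()} == {2: 2, 3: 4, 4: 8}
        # the canonical listing, compared as a set per length
        for m in (2, 3, 4):
            expected = {n for n in TABLE_PATHS if len(n) == m + 1}
            assert set(by_len[m]) == expected

    def test_minimum_limit_gives_two_paths(self):
        assert [p.name for p in enumerate_metapaths(2)] == ["LLE", "LEE"]

    def test_limit_five_gives_thirty(self):
        paths = enumerate_metapaths(5)
        assert len(paths) == 30
        assert len({p.name for p in paths}) == 30

    def test_limit_below_two_rejected(self):
        with pytest.raises(ValueError):
            enumerate_metapaths(1)

    def test_invalid_metapath_rejected(self):
        with pytest.raises(ValueError):
            MetaPath(("E", "L", "E"))
        with pytest.raises(ValueError):
            MetaPath(("L", "E"))


class TestTransitions:
    def test_row_normalization_hand_example(self):
        trans = trans_from(np.eye(2), [[1, 1], [0, 1]], np.eye(2))
        np.testing.assert_allclose(trans.M_LE, [[0.5, 0.5], [0, 1]])
        np.testing.assert_allclose(trans.M_LL, np.eye(2))
        np.testing.assert_allclose(trans.M_EL, [[1, 0], [0.5, 0.5]])

    def test_zero_association_row_stays_zero(self):
        trans = trans_from(np.eye(2), [[1, 1], [0, 0]], np.eye(2))
        assert trans.M_LE[1].sum() == 0

    def test_rows_stochastic_on_fixture(self, fixture_stack):
        from hetelink.hetesim import build_transitions as bt

        trans = bt(fixture_stack.SL, fixture_stack.A, fixture_stack.SE)
        for M in (trans.M_LL, trans.M_LE, trans.M_EL, trans.M_EE):
            sums = M.sum(axis=1)
            nonzero = sums > 0
            np.testing.assert_allclose(sums[nonzero], 1.0, atol=1e-12)


class TestReachableMatrix:
    def test_single_step_is_the_step_matrix(self):
        trans = trans_from(np.eye(2), [[1, 0], [1, 1]], np.eye(2))
        np.testing.assert_array_equal(
            reachable_matrix(trans, ("L", "E")), trans.M_LE
        )

    def test_two_step_product(self):
        trans = trans_from([[1, 0.5], [0.5, 1]], [[1, 0], [1, 1]], np.eye(2))
        np.testing.assert_allclose(
            reachable_matrix(trans, ("L", "L", "E")), trans.M_LL @ trans.M_LE
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize(
        "types", [("L", "L", "E"), ("L", "E", "E"), ("L", "E", "L", "E"),
                  ("E", "E", "L"), ("L", "L", "E", "E", "E")]
    )
    def test_matches_path_instance_summation_oracle(self, seed, types):
        rng = np.random.default_rng(seed)
        SL = rng.random((3, 3))
        SL = np.clip((SL + SL.T) / 2, 0, 1)
        SE = rng.random((3, 3))
        SE = np.clip((SE + SE.T) / 2, 0, 1)
        A = (rng.random((3, 3)) < 0.6).astype(float)
        A[0, 0] = 1
        trans = trans_from(SL, A, SE)
        np.testing.assert_allclose(
            reachable_matrix(trans, types),
            brute_force_reachable(trans, types),
            atol=1e-10,
        )

    def test_invalid_type_pair_rejected(self):
        trans = trans_from(np.eye(2), [[1, 0], [0, 1]], np.eye(2))
        with pytest.raises(ValueError):
            trans.step("L", "X")


class TestHeteSimScore:
    def test_identity_toy_scores_matched_pairs(self):
        # SL = I, A = I: each lncRNA reaches exactly its own EF
        trans = trans_from(np.eye(2), np.eye(2), np.eye(2))
        score = hetesim_score(trans, MetaPath(("L", "L", "E")))
        np.testing.assert_allclose(score, np.eye(2), atol=1e-12)

    @pytest.mark.parametrize("name", TABLE_PATHS)
    def test_scores_within_unit_interval(self, name, fixture_stack):
        from hetelink.hetesim import build_transitions as bt

        trans = bt(fixture_stack.SL, fixture_stack.A, fixture_stack.SE)
        score = hetesim_score(trans, MetaPath(tuple(name)))
        assert score.min() >= 0.0 and score.max() <= 1.0 + 1e-12

    @pytest.mark.parametrize("name", ["LLE", "LELE", "LLEEE", "LEEE"])
    def test_matches_brute_force_split_oracle(self, name):
        rng = np.random.default_rng(7)
        SL = rng.random((3, 3))
        SL = np.clip((SL + SL.T) / 2, 0, 1)
        SE = rng.random((2, 2))
        SE = np.clip((SE + SE.T) / 2, 0, 1)
        A = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        trans = trans_from(SL, A, SE)
        types = tuple(name)
        m = len(types) - 1
        if m % 2 == 0:
            expected = brute_force_hetesim(trans, types, m // 2 + 1)
        else:
            expected = 0.5 * (
                brute_force_hetesim(trans, types, (m + 1) // 2)
                + brute_force_hetesim(trans, types, (m + 3) // 2)
            )
        np.testing.assert_allclose(
            hetesim_score(trans, MetaPath(types)), expected, atol=1e-10
        )

    def test_isolated_nodes_score_zero_without_nan(self):
        trans = trans_from(np.eye(2), [[1, 0], [0, 0]], [[1, 0], [0, 0]])
        score = hetesim_score(trans, MetaPath(("L", "E", "E")))
        assert np.isfinite(score).all()
        assert score[1].sum() == 0  # isolated lncRNA

    def test_scale_invariance_of_similarity_blocks(self):
        rng = np.random.default_rng(9)
        SL = rng.random((4, 4))
        SL = np.clip((SL + SL.T) / 2, 0.01, 1)
        A = (rng.random((4, 3)) < 0.5).astype(float)
        A[0, 0] = 1
        SE = np.clip(np.eye(3) + 0.2, 0, 1)
        base = trans_from(SL, A, SE)
        scaled = trans_from(SL * 0.25, A, SE)
        for name in ("LLE", "LLLE"):
            np.testing.assert_allclose(
                hetesim_score(base, MetaPath(tuple(name))),
                hetesim_score(scaled, MetaPath(tuple(name))),
                atol=1e-12,
            )


class TestHeteSimFeatures:
    def test_default_stack_has_fourteen_channels(self, fixture_stack):
        assert fixture_stack.hetesim.K == 14
        assert [p.name for p in fixture_stack.hetesim.path_order] == sorted(
            TABLE_PATHS, key=lambda n: (len(n), n.replace("L", "0").replace("E", "1"))
        )

    def test_single_path_gives_one_channel(self):
        trans = trans_from(np.eye(2), np.eye(2), np.eye(2))
        hs = hetesim_features(trans, [MetaPath(("L", "L", "E"))])
        assert hs.K == 1

    def test_ef_permutation_permutes_columns(self):
        rng = np.random.default_rng(4)
        SL = np.eye(3)
        A = (rng.random((3, 3)) < 0.6).astype(float)
        A[0, 0] = 1
        SE = np.clip(np.eye(3) + 0.3, 0, 1)
        trans = trans_from(SL, A, SE)
        hs = hetesim_features(trans)
        perm = np.array([2, 0, 1])
        trans_p = trans_from(SL, A[:, perm], SE[np.ix_(perm, perm)])
        hs_p = hetesim_features(trans_p)
        np.testing.assert_allclose(hs_p.scores, hs.scores[:, perm, :], atol=1e-12)
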