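"""Tests for the differentiation-tree data model and covariance builders."""

import json

import numpy as np
import pytest

from btime.celltree import (
    CovarianceStructure,
    DifferentiationTree,
    block_mask,
    build_expdecay_correlation,
    build_multilevel_covariance,
    build_scaled_tree_covariance,
    build_tree_covariance,
    lca_root_distance,
    level_indicator,
    path_distance,
)

from conftest import random_tree

ACT_CYTO = "CD3+CD8+CD69+"
CYTO = "CD3+CD8+"
HELPER = "CD3+CD4+"
TREG = "CD3+CD4+FOXP3+"
ACT_TREG = "CD3+CD4+FOXP3+CD69+"


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

class TestPathDistance:
    @pytest.mark.parametrize(
        "s,t,expected",
        [
            ("CD3", ACT_CYTO, 1.5),     # functional change + activation
            (CYTO, HELPER, 2.0),        # two functional changes via CD3
            ("CD3", "CD3", 0.0),
            (TREG, ACT_TREG, 0.5),
            (ACT_CYTO, ACT_TREG, 1.5 + 2.5),  # full cross-branch path
        ],
    )
    def test_known_distances(self, nhs, s, t, expected):
        assert path_distance(nhs, s, t) == pytest.approx(expected)
        assert path_distance(nhs, t, s) == pytest.approx(expected)

    def test_zero_iff_same_node(self, nhs):
        for s in nhs.nodes:
            assert path_distance(nhs, s, s) == 0.0

    def test_unknown_node_named_in_error(self, nhs):
        with pytest.raises(KeyError, match="CD56"):
            path_distance(nhs, "CD3", "CD56")


class TestLCARootDistance:
    def test_worked_example_cytotoxic_pair(self, nhs):
        # shared ancestors are the T-cell (root distance 1) and the cytotoxic
        # T-cell (root distance 2); the deeper one gives the covariance
        assert lca_root_distance(nhs, CYTO, ACT_CYTO) == pytest.approx(2.0)

    def test_self_lca_is_own_depth(self, nhs):
        assert lca_root_distance(nhs, "CD3", "CD3") == pytest.approx(1.0)
        # root(1) + functional(1) + functional(1) + activation(0.5)
        assert lca_root_distance(nhs, ACT_TREG, ACT_TREG) == pytest.approx(3.5)

    def test_cross_branch_pairs_share_only_root(self, nhs):
        assert lca_root_distance(nhs, ACT_CYTO, TREG) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# covariance builders vs brute-force oracles
# ---------------------------------------------------------------------------

def _brute_lca_matrix(tree):
    """Independent oracle: enumerate inclusive ancestor sets and take the
    maximum root distance over the intersection."""
    def ancestors(n):
        out = []
        while n is not None:
            out.append(n)
            n = tree.parent[n]
        return out

    def depth(n):
        d = tree.root_distance
        chain = ancestors(n)
        for child in chain[:-1]:
            d += tree.edge_distance[child]
        return d

    m = tree.m
    T = np.zeros((m, m))
    for i, s in enumerate(tree.nodes):
        for j, t in enumerate(tree.nodes):
            shared = set(ancestors(s)) & set(ancestors(t))
            T[i, j] = max(depth(a) for a in shared)
    return T


class TestTreeCovariance:
    def test_matches_bruteforce_on_nhs(self, nhs):
        T = build_tree_covariance(nhs)
        np.testing.assert_allclose(T, _brute_lca_matrix(nhs), atol=1e-12)

    def test_worked_entry(self, nhs):
        T = build_tree_covariance(nhs)
        i, j = nhs.index(CYTO), nhs.index(ACT_CYTO)
        assert T[i, j] == pytest.approx(2.0)

    def test_single_node_tree(self):
        t = DifferentiationTree(["X"], {"X": None}, {"X": 0.0}, {"X": 1}, root_distance=1.0)
        np.testing.assert_allclose(build_tree_covariance(t), [[1.0]])

    def test_unit_distance_chain_counts_shared_ancestors(self, chain3):
        # with unit distances and root_distance 1, tau = 1 + shared non-root
        # ancestors: e.g. (B, C) share {A, B}, so tau = 2
        T = build_tree_covariance(chain3)
        expected = np.array([[1, 1, 1], [1, 2, 2], [1, 2, 3]], dtype=float)
        np.testing.assert_allclose(T, expected, atol=1e-12)

    def test_block_zeroes_only_cross_branch(self, nhs):
        full = build_tree_covariance(nhs, block=False)
        blocked = build_tree_covariance(nhs, block=True)
        i, j = nhs.index(ACT_CYTO), nhs.index(TREG)
        assert blocked[i, j] == 0.0
        # within-branch entries unchanged (helper branch)
        a, b = nhs.index(HELPER), nhs.index(ACT_TREG)
        assert blocked[a, b] == pytest.approx(full[a, b])
        # ancestor/descendant pairs stay: CD3 is on every branch
        r = nhs.index("CD3")
        assert blocked[r, i] == pytest.approx(full[r, i])

    def test_psd(self, nhs):
        for block in (False, True):
            T = build_tree_covariance(nhs, block=block)
            assert np.linalg.eigvalsh(T)[0] >= -1e-8
            np.testing.assert_allclose(T, T.T)


class TestScaledTree:
    def test_lambda_one_reduces_to_tree(self, nhs):
        np.testing.assert_allclose(
            build_scaled_tree_covariance(nhs, 1.0), build_tree_covariance(nhs)
        )

    def test_lambda_scales_entries_and_eigenvalues(self, nhs):
        T1 = build_tree_covariance(nhs)
        T2 = build_scaled_tree_covariance(nhs, 2.0)
        np.testing.assert_allclose(T2, 2.0 * T1)
        np.testing.assert_allclose(
            np.linalg.eigvalsh(T2), 2.0 * np.linalg.eigvalsh(T1), rtol=1e-10
        )

    def test_invalid_lambda(self, nhs):
        with pytest.raises(ValueError):
            build_scaled_tree_covariance(nhs, 0.0)


class TestExpDecay:
    def test_known_entry(self, nhs):
        D = build_expdecay_correlation(nhs, zeta=1.0)
        i, j = nhs.index("CD3"), nhs.index(ACT_CYTO)
        assert D[i, j] == pytest.approx(np.exp(-1.5))

    def test_unit_diagonal_and_range(self, nhs):
        D = build_expdecay_correlation(nhs, zeta=1.3)
        np.testing.assert_allclose(np.diag(D), 1.0)
        assert np.all((D >= 0) & (D <= 1))

    def test_monotone_in_zeta(self, nhs):
        D1 = build_expdecay_correlation(nhs, zeta=1.0)
        D2 = build_expdecay_correlation(nhs, zeta=2.0)
        off = ~np.eye(nhs.m, dtype=bool)
        assert np.all(D2[off] > D1[off])

    def test_limits(self, nhs):
        near_identity = build_expdecay_correlation(nhs, zeta=1e-6)
        np.testing.assert_allclose(near_identity, np.eye(nhs.m), atol=1e-12)
        ones = build_expdecay_correlation(nhs, zeta=1e6)
        np.testing.assert_allclose(ones, np.ones((nhs.m, nhs.m)), atol=1e-5)

    def test_invalid_zeta(self, nhs):
        with pytest.raises(ValueError):
            build_expdecay_correlation(nhs, zeta=-1.0)


class TestLevelIndicator:
    def test_treg_worked_example_level3(self, nhs):
        # at level 3 only the T-reg lineage (T-reg and recently activated
        # T-reg carry CD3+CD4+FOXP3) gets ones
        B = level_indicator(nhs, 3)
        idx = [nhs.index(TREG), nhs.index(ACT_TREG)]
        expected = np.zeros((nhs.m, nhs.m))
        for a in idx:
            for b in idx:
                expected[a, b] = 1.0
        np.testing.assert_allclose(B, expected)

    def test_level1_is_all_ones(self, nhs):
        np.testing.assert_allclose(level_indicator(nhs, 1), 1.0)

    def test_two_node_chain_leaf_level(self, chain2):
        B = level_indicator(chain2, 2)
        np.testing.assert_allclose(B, [[0, 0], [0, 1]])

    def test_out_of_range(self, nhs):
        with pytest.raises(ValueError):
            level_indicator(nhs, 5)
        with pytest.raises(ValueError):
            level_indicator(nhs, 0)


class TestMultilevel:
    def test_unit_weights_worked_entry(self, nhs):
        # T-reg and activated T-reg share ancestors at levels 1, 2 and 3
        T = build_multilevel_covariance(nhs, np.ones(4))
        assert T[nhs.index(TREG), nhs.index(ACT_TREG)] == pytest.approx(3.0)

    def test_matches_direct_summation(self, nhs):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.5, 2.0, size=4)
        direct = sum(w[l] * level_indicator(nhs, l + 1) for l in range(4))
        np.testing.assert_allclose(build_multilevel_covariance(nhs, w), direct, atol=1e-8)

    def test_small_weights_approach_zero_matrix(self, nhs):
        T = build_multilevel_covariance(nhs, np.full(4, 1e-12))
        assert np.abs(T).max() < 1e-6

    def test_wrong_weight_count(self, nhs):
        with pytest.raises(ValueError):
            build_multilevel_covariance(nhs, np.ones(3))


# ---------------------------------------------------------------------------
# structural invariants on random trees
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(8))
def test_constructions_symmetric_psd_on_random_trees(seed):
    rng = np.random.default_rng(seed)
    tree = random_tree(rng, n_nodes=int(rng.integers(2, 9)))
    mats = [
        build_tree_covariance(tree),
        build_tree_covariance(tree, block=True),
        build_expdecay_correlation(tree, zeta=float(rng.uniform(0.2, 3.0))),
        build_multilevel_covariance(
            tree, rng.uniform(0.2, 2.0, size=tree.max_level)
        ),
    ]
    for T in mats:
        np.testing.assert_allclose(T, T.T, atol=1e-10)
        assert np.linalg.eigvalsh(T)[0] >= -1e-8


def test_block_mask_symmetric_with_unit_diagonal(nhs):
    M = block_mask(nhs)
    np.testing.assert_allclose(M, M.T)
    np.testing.assert_allclose(np.diag(M), 1.0)


# ---------------------------------------------------------------------------
# validation and serialization
# ---------------------------------------------------------------------------

class TestTreeValidation:
    def test_requires_single_root(self):
        with pytest.raises(ValueError, match="root"):
            DifferentiationTree(
                ["A", "B"], {"A": None, "B": None}, {"A": 0, "B": 0},
                {"A": 1, "B": 1},
            )

    def test_rejects_negative_distance(self):
        with pytest.raises(ValueError):
            DifferentiationTree(
                ["A", "B"], {"A": None, "B": "A"}, {"A": 0, "B": -1},
                {"A": 1, "B": 2},
            )

    def test_rejects_child_level_below_parent(self):
        with pytest.raises(ValueError, match="level"):
            DifferentiationTree(
                ["A", "B"], {"A": None, "B": "A"}, {"A": 0, "B": 1},
                {"A": 2, "B": 1},
            )

    def test_json_roundtrip(self, nhs):
        text = nhs.to_json()
        back = DifferentiationTree.from_json(text)
        assert back.nodes == nhs.nodes
        assert back.parent == nhs.parent
        assert back.level == nhs.level
        assert back.root_distance == nhs.root_distance
        np.testing.assert_allclose(
            build_tree_covariance(back), build_tree_covariance(nhs)
        )

    def test_json_has_expected_fields(self, sim_tree):
        obj = json.loads(sim_tree.to_json())
        assert set(obj) == {"root_distance", "nodes"}
        assert {rec["name"] for rec in obj["nodes"]} == set(sim_tree.nodes)


def test_matrix_to_frame_labels(nhs):
    from btime.celltree import matrix_to_frame

    T = build_tree_covariance(nhs)
    frame = matrix_to_frame(nhs, T)
    assert list(frame.index) == list(nhs.nodes)
    assert list(frame.columns) == list(nhs.nodes)
    text = frame.to_csv()
    assert text.startswith(",CD3,")
    with pytest.raises(ValueError):
        matrix_to_frame(nhs, np.eye(3))


def test_covariance_structure_rejects_bad_kind():
    with pytest.raises(ValueError):
        CovarianceStructure("fancy")
    with pytest.raises(ValueError):
        CovarianceStructure("expdecay", block=True)
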