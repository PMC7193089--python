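"""Z-scoring, correlation distance, complete linkage vs brute-force oracle."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from gbmregions.clustering import (
    ClusteringConfig,
    ConstantColumnError,
    NonComputablePairError,
    complete_linkage,
    cut_tree,
    cut_tree_k,
    distance_matrix,
    profile_distance,
    to_newick,
    zscore_columns,
)
from gbmregions.panel import MARKERS
from gbmregions.synthetic import CohortSpec, simulate_cohort


def _table(values: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(values, columns=MARKERS[: values.shape[1]])
    df.insert(0, "tumor_id", "T1")
    df.insert(1, "roi_id", [f"R{i}" for i in range(len(df))])
    df.insert(2, "relapse", 0)
    return df


class TestZscore:
    def test_three_point_column_hand_computed(self):
        # mean 0.5, sample sd 0.5 -> exactly (-1, 0, 1)
        t = _table(np.tile(np.array([[0.0], [0.5], [1.0]]), (1, 9)))
        z = zscore_columns(t)
        assert np.allclose(z[MARKERS[0]], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_column(self, small_table):
        z1 = zscore_columns(small_table)
        z2 = zscore_columns(z1)
        assert np.allclose(
            z1[list(MARKERS)].to_numpy(), z2[list(MARKERS)].to_numpy(), atol=1e-12
        )

    def test_missing_cells_pass_through(self, small_table):
        t = small_table.copy()
        t.loc[t.index[0], MARKERS[0]] = np.nan
        z = zscore_columns(t)
        assert np.isnan(z.loc[z.index[0], MARKERS[0]])
        col = z[MARKERS[0]].dropna()
        assert abs(col.mean()) < 1e-9 and abs(col.std(ddof=1) - 1) < 1e-9

    def test_constant_column_error_names_marker(self, small_table):
        t = small_table.copy()
        t["Mib1"] = 0.2
        with pytest.raises(ConstantColumnError, match="Mib1"):
            zscore_columns(t)


class TestProfileDistance:
    def test_identical_profiles_at_zero(self):
        x = np.array([1.0, 0, -1, 0, 1, 0, -1, 0, 1])
        assert profile_distance(x, x) == pytest.approx(0.0)

    def test_negated_profile_at_two(self):
        x = np.array([1.0, 0, -1, 0, 1, 0, -1, 0, 1])
        assert profile_distance(x, -x) == pytest.approx(2.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(9), rng.standard_normal(9)
        xc, yc = x - x.mean(), y - y.mean()
        r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert profile_distance(x, y) == pytest.approx(1 - r, abs=1e-12)

    def test_sqrt_variant(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal(9), rng.standard_normal(9)
        d1 = profile_distance(x, y)
        d2 = profile_distance(x, y, ClusteringConfig(distance_variant="sqrt-2-1-minus-r"))
        assert d2 == pytest.approx(np.sqrt(2 * d1))

    def test_too_few_shared_markers_flagged(self):
        x = np.full(9, np.nan)
        x[:5] = 1.0
        y = np.ones(9)
        with pytest.raises(NonComputablePairError):
            profile_distance(x, y)

    def test_distance_matrix_reports_bad_pairs(self):
        vals = np.random.default_rng(7).random((4, 9))
        vals[0, :4] = np.nan  # leaves 5 shared markers with complete rows
        t = _table(vals)
        z = t  # distances don't require prior z-scoring for this check
        d, shared, bad = distance_matrix(z)
        assert ("R0", "R1") in bad
        assert np.isnan(d[0, 1]) and shared[0, 1] == 5


def _oracle_complete_linkage(d: np.ndarray):
    """Exhaustive re-scan oracle: clusters as leaf sets, distance recomputed
    from the original matrix at every step; same id-based tie-break."""
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dm = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or dm < best[0] or (dm == best[0] and (a, b) < best[1:]):
                best = (dm, a, b)
        h, a, b = best
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        merges.append((a, b, h, next_id))
        next_id += 1
    return merges


class TestCompleteLinkage:
    def test_two_leaves(self):
        tree = complete_linkage(np.array([[0, 0.4], [0.4, 0]]), ["A", "B"])
        assert len(tree.merges) == 1
        assert tree.merges[0].height == pytest.approx(0.4)

    def test_three_leaf_enumeration(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]])
        tree = complete_linkage(d, ["A", "B", "C"])
        assert (tree.merges[0].left, tree.merges[0].right) == (0, 1)
        assert tree.merges[0].height == pytest.approx(0.1)
        # complete linkage: max(0.9, 0.8) = 0.9
        assert tree.merges[1].height == pytest.approx(0.9)

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(3, 11))
            x = rng.random((n, 3))
            d = np.array([[np.abs(x[i] - x[j]).sum() for j in range(n)] for i in range(n)])
            tree = complete_linkage(d)
            oracle = _oracle_complete_linkage(d)
            got = [(m.left, m.right, m.height, m.node_id) for m in tree.merges]
            assert got == pytest.approx(oracle)

    def test_agrees_with_scipy_heights(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            cond = rng.random(n * (n - 1) // 2)
            tree = complete_linkage(squareform(cond))
            Z = scipy_linkage(cond, method="complete")
            assert sorted(m.height for m in tree.merges) == pytest.approx(sorted(Z[:, 2]))

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(17)
        d = squareform(rng.random(45))
        heights = [m.height for m in complete_linkage(d).merges]
        assert all(b >= a for a, b in zip(heights, heights[1:]))

    def test_non_computable_pairs_refused_with_guidance(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(NonComputablePairError, match="impute"):
            complete_linkage(d)

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 10))
    def test_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        d = squareform(rng.random(15))
        t1 = complete_linkage(d)
        t2 = complete_linkage(c * d)
        assert [(m.left, m.right) for m in t1.merges] == [(m.left, m.right) for m in t2.merges]
        assert [m.height * c for m in t1.merges] == pytest.approx([m.height for m in t2.merges])


class TestCutTree:
    def _tree(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]])
        return complete_linkage(d, ["A", "B", "C"])

    def test_above_root_single_cluster(self):
        assert set(cut_tree(self._tree(), 1.5).values()) == {1}

    def test_below_all_heights_singletons(self):
        assignment = cut_tree(self._tree(), 0.05)
        assert sorted(assignment.values()) == [1, 2, 3]

    def test_midway_cut(self):
        assignment = cut_tree(self._tree(), 0.5)
        assert assignment["A"] == assignment["B"] != assignment["C"]

    def test_cluster_ids_follow_leaf_order(self):
        assignment = cut_tree(self._tree(), 0.5)
        # smaller cluster id sits left: the root's left child is leaf C (id 2),
        # its right child the (A,B) subtree (id 3), so C is cluster 1
        assert assignment["C"] == 1 and assignment["A"] == assignment["B"] == 2

    def test_cut_into_k(self):
        tree = self._tree()
        assert len(set(cut_tree_k(tree, 2).values())) == 2
        assert len(set(cut_tree_k(tree, 3).values())) == 3
        with pytest.raises(ValueError):
            cut_tree_k(tree, 4)


class TestNewick:
    def test_two_leaf_ultrametric_split(self):
        tree = complete_linkage(np.array([[0, 0.4], [0.4, 0]]), ["A", "B"])
        assert to_newick(tree) == "(A:0.200000,B:0.200000);"

    def test_roundtrip_preserves_leaves_and_depths(self):
        rng = np.random.default_rng(19)
        d = squareform(rng.random(28))
        names = [f"R{i}" for i in range(8)]
        tree = complete_linkage(d, names)
        parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(names)
        # ultrametric: every root-to-leaf path has depth root_height / 2
        depths = [leaf.distance_from_root() for leaf in parsed.leaf_node_iter()]
        assert np.allclose(depths, tree.root_height / 2, atol=1e-4)


class TestArchetypeRecovery:
    def test_eight_cluster_cut_recovers_planted_archetypes(self):
        """Default 8-archetype cohort (structural-marker sd 0.1), no
        missingness: cutting into 8 clusters gives ARI >= 0.9 vs truth."""
        spec = CohortSpec(n_tumors=45, missing_rate=0.0, seed=21)
        cohort = simulate_cohort(spec)
        assert len(cohort.table) >= 150
        z = zscore_columns(cohort.table)
        d, _, bad = distance_matrix(z)
        assert not bad
        tree = complete_linkage(d, leaf_names=list(z["roi_id"]))
        assignment = cut_tree_k(tree, 8)
        pred = [assignment[r] for r in cohort.truth_labels.index]
        assert adjusted_rand_score(cohort.truth_labels.values, pred) >= 0.9
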