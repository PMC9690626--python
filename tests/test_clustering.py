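"""Similarity coefficients, UPGMA, Newick, PCA and heatmap layout."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from phytodiv.band_matrix import BandMatrix
from phytodiv.clustering import (
    DistanceMatrix,
    HeatmapScale,
    heatmap_prepare,
    pca,
    similarity,
    to_newick,
    upgma,
)


def _mat(rows, ids=("C1", "C2", "C3")):
    return BandMatrix("p", "OTHER", list(ids), np.array(rows))


class TestSimilarity:
    def test_identical_profiles_have_zero_distance(self):
        d = similarity(_mat([[1, 0, 1], [1, 0, 1], [0, 1, 1]]))
        assert d.get("C1", "C2") == 0.0

    def test_disjoint_profiles_jaccard_distance_one(self):
        d = similarity(_mat([[1, 1, 0], [0, 0, 1], [1, 1, 1]]), "jaccard")
        assert d.get("C1", "C2") == 1.0

    def test_jaccard_and_dice_on_hand_counted_pair(self):
        m = _mat([[1, 1, 0], [0, 1, 1], [1, 1, 1]])
        jac = similarity(m, "jaccard")
        dice = similarity(m, "dice")
        assert jac.get("C1", "C2") == pytest.approx(1 - 1 / 3)
        assert dice.get("C1", "C2") == pytest.approx(1 - 1 / 2)

    def test_bandless_pair_undefined_under_jaccard(self):
        m = _mat([[0, 0], [0, 0], [1, 1]])  # C1 and C2 carry no bands at all
        with pytest.raises(ValueError, match="bandless"):
            similarity(m, "jaccard")
        sm = similarity(m, "simple_matching")
        assert sm.get("C1", "C2") == 0.0  # joint absences count as agreement


class TestUPGMA:
    def test_analytically_forced_three_leaf_tree(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float))
        t = upgma(d)
        assert to_newick(t) == "((A:1,B:1):2,C:3);"

    def test_two_leaves(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 4], [4, 0]], float))
        t = upgma(d)
        assert t.root.height == 2.0
        assert to_newick(t) == "(A:2,B:2);"

    def test_nan_distance_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, np.nan], [np.nan, 0]]))

    @staticmethod
    def _random_ultrametric(rng, n=5):
        """Random ultrametric via a random merge order with growing heights."""
        active = {i: [i] for i in range(n)}
        height = 0.0
        d = np.zeros((n, n))
        while len(active) > 1:
            height += float(rng.uniform(0.5, 2.0))
            keys = sorted(active)
            i, j = rng.choice(keys, size=2, replace=False)
            for a in active[i]:
                for b in active[j]:
                    d[a, b] = d[b, a] = 2 * height
            active[i] = active[i] + active[j]
            del active[j]
        return DistanceMatrix([f"L{k}" for k in range(n)], d)

    def test_cophenetic_distances_reproduce_ultrametric_input(self, rng):
        for _ in range(10):
            d = self._random_ultrametric(rng)
            cd = upgma(d).cophenetic()
            expect = d.to_frame().loc[cd.labels, cd.labels].to_numpy()
            assert np.allclose(cd.values, expect)

    def test_heights_agree_with_scipy_average_linkage(self, rng):
        for _ in range(10):
            n = 6
            condensed = rng.uniform(0.2, 3.0, size=n * (n - 1) // 2)
            d = DistanceMatrix([f"L{k}" for k in range(n)], squareform(condensed))
            t = upgma(d)
            z = average(condensed)
            coph = squareform(cophenet(z))
            mine = t.cophenetic()
            frame = pd.DataFrame(coph, index=d.labels, columns=d.labels)
            assert np.allclose(
                mine.values, frame.loc[mine.labels, mine.labels].to_numpy()
            )

    def test_heights_monotone_from_leaves_to_root(self, rng):
        for _ in range(10):
            n = 7
            d = DistanceMatrix(
                [f"L{k}" for k in range(n)],
                squareform(rng.uniform(0.1, 5.0, size=n * (n - 1) // 2)),
            )
            t = upgma(d)

            def check(node):
                for c in node.children:
                    assert c.height <= node.height + 1e-12
                    check(c)

            check(t.root)

    def test_divergent_accession_splits_off_first(self):
        # C3 carries most unique bands; C1 and C2 should pair first
        rows = [
            [1, 1, 1, 1, 0, 0, 0, 0, 1],
            [1, 1, 1, 0, 0, 0, 0, 1, 1],
            [1, 1, 1, 0, 1, 1, 1, 0, 0],
        ]
        t = upgma(similarity(_mat(rows), "jaccard"))
        first_pair = min(t.internal_nodes(), key=lambda nd: nd.height)
        assert sorted(first_pair.leaf_labels()) == ["C1", "C2"]


class TestNewick:
    def test_single_leaf(self):
        from phytodiv.clustering import TreeNode, UPGMATree

        assert to_newick(UPGMATree(root=TreeNode(label="A"))) == "A;"

    def test_round_trip_through_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        d = DistanceMatrix(["A", "B", "C", "D"],
                           np.array([[0, 2, 8, 8], [2, 0, 8, 8],
                                     [8, 8, 0, 4], [8, 8, 4, 0]], float))
        t = upgma(d)
        text = to_newick(t)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in parsed.taxon_namespace}
        coph = t.cophenetic()
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        coph.get(a, b)
                    )


class TestPCA:
    def test_collinear_variables_put_everything_on_pc1(self):
        x = np.array([1.0, 2, 3, 4])
        data = pd.DataFrame({"u": x, "v": 2 * x})
        res = pca(data)
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_three_samples_are_rank_two(self, rng):
        data = pd.DataFrame(rng.normal(size=(3, 8)),
                            index=["C1", "C2", "C3"])
        res = pca(data)
        assert res.explained_pct[:2].sum() == pytest.approx(100.0)

    def test_scores_match_dense_eigendecomposition_oracle(self, rng):
        data = pd.DataFrame(rng.normal(size=(4, 3)), columns=list("xyz"))
        res = pca(data)
        x = data.to_numpy() - data.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(x.T @ x / (x.shape[0] - 1))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(res.eigenvalues, evals[: len(res.eigenvalues)], atol=1e-9)
        for c in range(res.scores.shape[1]):
            got = res.scores.iloc[:, c].to_numpy()
            want = x @ evecs[:, c]
            assert np.allclose(got, want, atol=1e-9) or np.allclose(
                got, -want, atol=1e-9
            )

    def test_translation_invariance_and_ordering(self, rng):
        data = pd.DataFrame(rng.normal(size=(5, 4)))
        res = pca(data)
        shifted = pca(data + 100.0)
        assert np.allclose(res.scores, shifted.scores, atol=1e-9)
        reordered = pca(data.iloc[[4, 2, 0, 1, 3]])
        assert np.allclose(res.explained_pct, reordered.explained_pct, atol=1e-9)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            pca(pd.DataFrame({"a": [1.0]}))


class TestHeatmap:
    def test_minus1_1_maps_extremes_and_constant_column(self):
        data = pd.DataFrame(
            {"a": [0.0, 5.0, 10.0], "b": [3.0, 3.0, 3.0], "c": [1.0, 2.0, 4.0]},
            index=["r1", "r2", "r3"],
        )
        with pytest.warns(UserWarning, match="constant"):
            layout = heatmap_prepare(data, HeatmapScale.MINUS1_1)
        assert layout.scaled["a"].tolist() == [-1.0, 0.0, 1.0]
        assert layout.scaled["b"].tolist() == [0.0, 0.0, 0.0]
        assert layout.scaled["c"].min() == -1.0 and layout.scaled["c"].max() == 1.0

    def test_row_order_matches_hand_agglomeration(self):
        # r1 and r2 nearly equal, r3 far: hand UPGMA pairs r1,r2 first
        data = pd.DataFrame(
            {"a": [0.0, 0.5, 10.0], "b": [1.0, 1.5, 9.0], "c": [0.0, 0.0, 8.0],
             "d": [2.0, 2.1, 7.0]},
            index=["r1", "r2", "r3"],
        )
        layout = heatmap_prepare(data, HeatmapScale.ZSCORE)
        order = layout.row_order
        assert {order[0], order[1]} == {"r1", "r2"} or {order[1], order[2]} == {
            "r1",
            "r2",
        }
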