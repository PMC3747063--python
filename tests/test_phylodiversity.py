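"""Taxonomy trees, UniFrac (vs independent per-branch oracle), PCoA, Procrustes."""

import itertools

import numpy as np
import pytest

import mycodyn as md
from conftest import random_lineage_set

# ---------------------------------------------------------------------------
# independent per-branch oracle: identifies every unit branch by its
# name-path prefix (leaf branches by path + otu id) and sums over branches


def _leaf_path(lineage, otu):
    parts = tuple(p.strip() for p in lineage.split(";") if p.strip())
    return parts + (otu,)


def _branches(lineages):
    out = set()
    for otu, lineage in lineages.items():
        path = _leaf_path(lineage, otu)
        for k in range(1, len(path) + 1):
            out.add(path[:k])
    return out


def _descendants(branch, lineages):
    return [
        otu
        for otu, lin in lineages.items()
        if _leaf_path(lin, otu)[: len(branch)] == branch
    ]


def oracle_unweighted(lineages, counts_i, counts_j):
    num = den = 0
    for b in _branches(lineages):
        desc = _descendants(b, lineages)
        pi = any(counts_i[o] > 0 for o in desc)
        pj = any(counts_j[o] > 0 for o in desc)
        num += pi != pj
        den += pi or pj
    return num / den


def oracle_weighted(lineages, counts_i, counts_j, normalized=True):
    ti = sum(counts_i.values())
    tj = sum(counts_j.values())
    raw = 0.0
    for b in _branches(lineages):
        desc = _descendants(b, lineages)
        a = sum(counts_i[o] for o in desc) / ti
        bb = sum(counts_j[o] for o in desc) / tj
        raw += abs(a - bb)
    if not normalized:
        return raw
    dmax = sum(
        len(_leaf_path(lin, o)) * (counts_i[o] / ti + counts_j[o] / tj)
        for o, lin in lineages.items()
    )
    return raw / dmax


# ---------------------------------------------------------------------------


class TestBuildTree:
    def test_shared_prefix_example(self):
        tree = md.build_taxonomy_tree(
            {"o1": "Fungi;Ascomycota;Candida", "o2": "Fungi;Ascomycota;Pichia"}
        )
        assert tree.depth(tree.leaf_index["o1"]) == 4
        assert tree.depth(tree.leaf_index["o2"]) == 4
        # 4 name-paths (Fungi, Ascomycota, 2 genera) + 2 leaves
        assert tree.n_edges == 6

    def test_single_lineage_is_path(self):
        tree = md.build_taxonomy_tree({"o1": "A;B;C;D"})
        assert tree.n_edges == 5
        assert tree.depth(tree.leaf_index["o1"]) == 5

    def test_total_branch_length_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            lineages = random_lineage_set(rng)
            tree = md.build_taxonomy_tree(lineages)
            name_paths = set()
            for otu, lin in lineages.items():
                parts = [p for p in lin.split(";") if p]
                for k in range(1, len(parts) + 1):
                    name_paths.add(tuple(parts[:k]))
            assert tree.total_branch_length == len(name_paths) + len(lineages)

    def test_empty_lineage_rejected(self):
        with pytest.raises(ValueError):
            md.build_taxonomy_tree({"o1": "  "})


class TestUniFracOracle:
    def _random_case(self, rng):
        lineages = random_lineage_set(rng)
        otus = list(lineages)
        while True:
            ci = {o: int(rng.integers(0, 5)) for o in otus}
            cj = {o: int(rng.integers(0, 5)) for o in otus}
            if sum(ci.values()) > 0 and sum(cj.values()) > 0:
                return lineages, otus, ci, cj

    def test_matches_brute_force_on_random_trees(self):
        """Both variants equal per-branch summation on 100 random <=6-leaf trees."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            lineages, otus, ci, cj = self._random_case(rng)
            tree = md.build_taxonomy_tree(lineages)
            vi = np.array([ci[o] for o in otus])
            vj = np.array([cj[o] for o in otus])
            assert md.unweighted_unifrac(tree, otus, vi, vj) == pytest.approx(
                oracle_unweighted(lineages, ci, cj), abs=1e-12
            )
            for norm in (True, False):
                assert md.weighted_unifrac(
                    tree, otus, vi, vj, normalized=norm
                ) == pytest.approx(
                    oracle_weighted(lineages, ci, cj, normalized=norm),
                    abs=1e-12,
                )

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(5)
        lineages = random_lineage_set(rng)
        otus = list(lineages)
        counts = rng.integers(1, 20, size=(len(otus), 5))
        table = md.OtuTable(otus, [f"s{j}" for j in range(5)], counts, lineages)
        tree = md.build_taxonomy_tree(lineages)
        for w in (False, True):
            dm = md.unifrac_matrix(tree, table, weighted=w)
            for i, j in itertools.combinations(range(5), 2):
                f = md.weighted_unifrac if w else md.unweighted_unifrac
                assert dm.values[i, j] == pytest.approx(
                    f(tree, otus, counts[:, i], counts[:, j]), abs=1e-12
                )

    def test_identical_samples_are_zero_distance(self):
        tree = md.build_taxonomy_tree({"a": "K;P;G1", "b": "K;P;G2"})
        assert md.unweighted_unifrac(tree, ["a", "b"], [3, 1], [5, 9]) == 0.0
        assert md.weighted_unifrac(tree, ["a", "b"], [3, 1], [6, 2]) == 0.0

    def test_disjoint_samples_are_unit_distance(self):
        tree = md.build_taxonomy_tree({"a": "K1;P1;G1", "b": "K2;P2;G2"})
        assert md.unweighted_unifrac(tree, ["a", "b"], [4, 0], [0, 7]) == 1.0
        assert md.weighted_unifrac(tree, ["a", "b"], [4, 0], [0, 7]) == 1.0

    def test_both_empty_rejected(self):
        tree = md.build_taxonomy_tree({"a": "K;P;G"})
        with pytest.raises(ValueError):
            md.unweighted_unifrac(tree, ["a"], [0], [0])
        with pytest.raises(ValueError):
            md.weighted_unifrac(tree, ["a"], [0], [1])

    def test_triangle_inequality_unweighted(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            lineages = random_lineage_set(rng)
            otus = list(lineages)
            c = rng.integers(0, 4, size=(len(otus), 3))
            if (c.sum(axis=0) == 0).any():
                continue
            tree = md.build_taxonomy_tree(lineages)
            d = lambda i, j: md.unweighted_unifrac(tree, otus, c[:, i], c[:, j])
            d01, d02, d12 = d(0, 1), d(0, 2), d(1, 2)
            assert d01 <= d02 + d12 + 1e-12
            assert d02 <= d01 + d12 + 1e-12
            assert d12 <= d01 + d02 + 1e-12
            checked += 1

    def test_all_zero_otus_do_not_affect_distance(self):
        """Uncovered branches contribute nothing to either UniFrac variant."""
        lineages = {"a": "K;P;G1", "b": "K;P;G2"}
        tree = md.build_taxonomy_tree(lineages)
        d0 = md.unweighted_unifrac(tree, ["a", "b"], [3, 0], [0, 4])
        w0 = md.weighted_unifrac(tree, ["a", "b"], [3, 0], [0, 4])
        extended = dict(lineages, c="K;P;G1;Extra", d="K;Q;G3")
        tree2 = md.build_taxonomy_tree(extended)
        otus = ["a", "b", "c", "d"]
        assert md.unweighted_unifrac(
            tree2, otus, [3, 0, 0, 0], [0, 4, 0, 0]
        ) == pytest.approx(d0, abs=1e-12)
        assert md.weighted_unifrac(
            tree2, otus, [3, 0, 0, 0], [0, 4, 0, 0]
        ) == pytest.approx(w0, abs=1e-12)


class TestSkbioCrossCheck:
    """Dual route: our taxonomy-tree UniFrac vs scikit-bio on the exported tree."""

    def test_unifrac_agrees_with_skbio(self, tmp_path):
        import skbio
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(11)
        lineages = {
            "x1": "Fungi;Ascomycota;Saccharomycetes;Candida",
            "x2": "Fungi;Ascomycota;Saccharomycetes;Pichia",
            "x3": "Fungi;Basidiomycota;Malassezia",
            "x4": "Fungi;Ascomycota;Eurotiomycetes;Aspergillus",
        }
        otus = list(lineages)
        counts = rng.integers(1, 30, size=(4, 6))
        table = md.OtuTable(otus, [f"s{j}" for j in range(6)], counts, lineages)
        tree = md.build_taxonomy_tree(lineages)
        nwk = tmp_path / "t.nwk"
        nwk.write_text(tree.to_newick() + "\n")
        sktree = skbio.TreeNode.read(str(nwk))
        ours_u = md.unifrac_matrix(tree, table, weighted=False)
        ours_w = md.unifrac_matrix(tree, table, weighted=True)
        sk_u = beta_diversity(
            "unweighted_unifrac", counts.T, ids=table.sample_ids,
            taxa=otus, tree=sktree,
        )
        sk_w = beta_diversity(
            "weighted_unifrac", counts.T, ids=table.sample_ids,
            taxa=otus, tree=sktree, normalized=True,
        )
        np.testing.assert_allclose(ours_u.values, sk_u.data, atol=1e-10)
        np.testing.assert_allclose(ours_w.values, sk_w.data, atol=1e-10)


class TestPcoa:
    def test_points_on_a_line_reconstruct_distances(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        d = np.abs(x[:, None] - x[None, :])
        ordn = md.pcoa(md.DistanceMatrix([f"s{i}" for i in range(4)], d))
        got = np.abs(
            ordn.coordinates[:, 0][:, None] - ordn.coordinates[:, 0][None, :]
        )
        np.testing.assert_allclose(got, d, atol=1e-8)

    def test_zero_matrix_gives_zero_coordinates(self):
        ordn = md.pcoa(md.DistanceMatrix(["a", "b", "c"], np.zeros((3, 3))))
        assert np.allclose(ordn.coordinates, 0)

    def test_coordinates_centered_eigenvalues_sorted(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        ordn = md.pcoa(md.DistanceMatrix([f"s{i}" for i in range(8)], d))
        assert np.allclose(ordn.coordinates.mean(axis=0), 0, atol=1e-10)
        assert np.all(np.diff(ordn.eigenvalues) <= 1e-9)

    def test_euclidean_input_has_no_negative_eigenvalues(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        ordn = md.pcoa(md.DistanceMatrix([f"s{i}" for i in range(10)], d))
        assert ordn.eigenvalues.min() >= -1e-8

    def test_agrees_with_skbio(self):
        from skbio.stats.ordination import pcoa as sk_pcoa

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(7, 3))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        ours = md.pcoa(md.DistanceMatrix([f"s{i}" for i in range(7)], d))
        theirs = sk_pcoa(d, method="eigh")
        k = ours.coordinates.shape[1]
        sk_coords = theirs.samples.to_numpy()[:, :k]
        for axis in range(k):  # axes defined up to sign
            a, b = ours.coordinates[:, axis], sk_coords[:, axis]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            md.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestProcrustes:
    def _ordination(self, coords):
        return md.Ordination(
            [f"s{i}" for i in range(len(coords))],
            np.asarray(coords, dtype=float),
            np.ones(np.asarray(coords).shape[1]),
        )

    def test_perfect_fit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 2))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        y = x @ rot * 3.1 + np.array([2.0, -1.0])
        m2, p = md.procrustes_test(
            self._ordination(x), self._ordination(y), n_perm=99, rng=1
        )
        assert m2 <= 1e-10
        assert p == pytest.approx(1 / 100)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        m2a, _ = md.procrustes_test(
            self._ordination(x), self._ordination(y), n_perm=19, rng=0
        )
        perm = rng.permutation(6)
        m2b, _ = md.procrustes_test(
            self._ordination(x[perm]), self._ordination(y[perm]), n_perm=19, rng=0
        )
        assert m2a == pytest.approx(m2b, rel=1e-9)

    def test_null_p_is_roughly_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            x = rng.normal(size=(10, 2))
            y = rng.normal(size=(10, 2))
            _, p = md.procrustes_test(
                self._ordination(x), self._ordination(y), n_perm=49, rng=rng
            )
            ps.append(p)
        ps = np.array(ps)
        assert 0.42 < ps.mean() < 0.60
        assert 0.016 < (ps <= 0.1).mean() < 0.19

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            md.procrustes_test(
                self._ordination([[0.0], [1.0]]), self._ordination([[0.0], [1.0]])
            )

    def test_mismatched_samples_rejected(self):
        a = self._ordination(np.zeros((4, 2)))
        b = md.Ordination(["x0", "x1", "x2", "x3"], np.zeros((4, 2)), np.ones(2))
        with pytest.raises(ValueError):
            md.procrustes_test(a, b)
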