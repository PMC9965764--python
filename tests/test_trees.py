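import itertools

import numpy as np
import pytest
import skbio

from chemophen import preprocess as prep, trees
from chemophen.io_core import read_newick
from chemophen.simulate import SynthConfig, generate
from conftest import make_feature_table


def _dm(mat, ids):
    return skbio.DistanceMatrix(np.asarray(mat, dtype=float), ids=ids)


def _random_dm(rng, n):
    pts = rng.normal(size=(n, 3))
    from scipy.spatial.distance import pdist, squareform

    return _dm(squareform(pdist(pts)), [f"t{i}" for i in range(n)])


class TestTaxonDistance:
    def test_three_four_five(self):
        table = make_feature_table([[0.0, 0.0], [3.0, 4.0]], taxa=["A", "B"])
        D = trees.taxon_distance(table)
        assert D["A", "B"] == pytest.approx(5.0, abs=1e-12)

    def test_identical_profiles_distance_zero(self):
        table = make_feature_table([[1, 2], [1, 2]], taxa=["A", "B"])
        assert trees.taxon_distance(table)["A", "B"] == 0.0

    def test_replicates_averaged_then_brute_force_oracle(self, rng):
        vals = rng.uniform(0, 5, size=(8, 6))
        taxa = ["A", "A", "B", "B", "C", "C", "D", "D"]
        table = make_feature_table(vals, taxa=taxa)
        D = trees.taxon_distance(table)
        means = {t: vals[[i for i, x in enumerate(taxa) if x == t]].mean(axis=0)
                 for t in "ABCD"}
        for t1, t2 in itertools.combinations("ABCD", 2):
            expected = np.sqrt(((means[t1] - means[t2]) ** 2).sum())
            assert D[t1, t2] == pytest.approx(expected, abs=1e-12)


class TestCompleteLinkage:
    def test_points_on_a_line(self):
        # {0, 1, 5}: merge (0,1) at height 1, then with 5 at height 5
        mat = [[0, 1, 5], [1, 0, 4], [5, 4, 0]]
        tree = trees.complete_linkage_tree(_dm(mat, ["x0", "x1", "x5"]))
        coph = trees.cophenetic_matrix(tree)
        assert coph["x0", "x1"] == pytest.approx(1.0, abs=1e-12)
        assert coph["x0", "x5"] == pytest.approx(5.0, abs=1e-12)
        assert coph["x1", "x5"] == pytest.approx(5.0, abs=1e-12)

    def test_two_tips_single_merge(self):
        tree = trees.complete_linkage_tree(_dm([[0, 3.5], [3.5, 0]], ["A", "B"]))
        assert trees.cophenetic_matrix(tree)["A", "B"] == pytest.approx(3.5)

    def test_matches_scipy_cophenet_oracle(self, rng):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        for _ in range(5):
            D = _random_dm(rng, 6)
            tree = trees.complete_linkage_tree(D)
            ours = trees.cophenetic_matrix(tree)
            condensed = squareform(np.array(D.data))
            ref = squareform(cophenet(linkage(condensed, method="complete")))
            ref_dm = _dm(ref, list(D.ids))
            for a, b in itertools.combinations(D.ids, 2):
                assert ours[a, b] == pytest.approx(ref_dm[a, b], abs=1e-10)

    def test_tree_is_ultrametric_and_heights_monotone(self, rng):
        tree = trees.complete_linkage_tree(_random_dm(rng, 7))
        assert tree.is_ultrametric()

    def test_scaling_distances_preserves_topology(self, rng):
        D = _random_dm(rng, 6)
        t1 = trees.complete_linkage_tree(D)
        t2 = trees.complete_linkage_tree(_dm(np.array(D.data) * 7.25, list(D.ids)))
        assert trees.robinson_foulds(t1, t2) == 0

    def test_nan_rejected(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = mat[1, 0] = np.nan
        import skbio

        D = skbio.DistanceMatrix.__new__(skbio.DistanceMatrix)
        with pytest.raises(Exception):
            trees.complete_linkage_tree(_dm(mat, list("abc")))


class TestCopheneticMatrix:
    def test_phylogram_path_lengths(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        coph = trees.cophenetic_matrix(tree)
        assert coph["A", "B"] == pytest.approx(2.0)
        assert coph["A", "C"] == pytest.approx(4.0)
        assert coph["B", "C"] == pytest.approx(4.0)

    def test_star_tree_unit_branches(self):
        tree = read_newick("(A:1,B:1,C:1,D:1);")
        coph = trees.cophenetic_matrix(tree)
        for a, b in itertools.combinations("ABCD", 2):
            assert coph[a, b] == pytest.approx(2.0)

    def test_fixed_point_of_complete_linkage(self, rng):
        D = _random_dm(rng, 5)
        tree = trees.complete_linkage_tree(D)
        coph = trees.cophenetic_matrix(tree)
        tree2 = trees.complete_linkage_tree(coph)
        coph2 = trees.cophenetic_matrix(tree2)
        for a, b in itertools.combinations(D.ids, 2):
            assert coph[a, b] == pytest.approx(coph2[a, b], abs=1e-10)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        D = _random_dm(rng, 5)
        M, p = trees.mantel(D, D, n_perm=99, seed=0)
        assert M == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        D = _random_dm(rng, 5)
        mat = np.array(D.data) * 2.0 + 5.0
        np.fill_diagonal(mat, 0.0)
        M, _ = trees.mantel(D, _dm(mat, list(D.ids)), n_perm=0)
        assert M == pytest.approx(1.0, abs=1e-12)

    def test_matches_scikit_bio(self, rng):
        from skbio.stats.distance import mantel as skbio_mantel

        D1, D2 = _random_dm(rng, 7), _random_dm(rng, 7)
        M, _ = trees.mantel(D1, D2, n_perm=0)
        ref, _, _ = skbio_mantel(D1, D2, permutations=0)
        assert M == pytest.approx(float(ref), abs=1e-12)

    def test_exhaustive_p_matches_enumeration(self, rng):
        D1, D2 = _random_dm(rng, 4), _random_dm(rng, 4)
        M, p = trees.mantel(D1, D2, exhaustive=True)
        m2 = np.array(D2.data)
        iu = np.tril_indices(4, k=-1)
        v1 = np.array(D1.data)[iu]
        count = 0
        for perm in itertools.permutations(range(4)):
            vp = m2[np.ix_(perm, perm)][iu]
            if np.corrcoef(v1, vp)[0, 1] >= M - 1e-12:
                count += 1
        assert p == pytest.approx(count / 24, abs=1e-12)

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            trees.mantel(_dm([[0, 1], [1, 0]], ["a", "b"]),
                         _dm([[0, 2], [2, 0]], ["a", "b"]))


class TestCopheneticCorrelation:
    def test_tree_with_itself_is_one(self):
        tree = read_newick("((A:1,B:1):1,(C:1.5,D:0.5):1);")
        assert trees.cophenetic_correlation(tree, tree) == pytest.approx(1.0, abs=1e-12)

    def test_conflicting_three_tip_dendrograms(self):
        # merge heights (1, 2): vectors (1,2,2) vs (2,1,2) -> r = -0.5
        t1 = trees.complete_linkage_tree(
            _dm([[0, 1, 2], [1, 0, 2], [2, 2, 0]], ["A", "B", "C"])
        )
        t2 = trees.complete_linkage_tree(
            _dm([[0, 2, 1], [2, 0, 2], [1, 2, 0]], ["A", "B", "C"])
        )
        assert trees.cophenetic_correlation(t1, t2) == pytest.approx(-0.5, abs=1e-12)

    def test_doubling_branch_lengths_keeps_correlation_one(self):
        t1 = read_newick("((A:1,B:1):1,(C:2,D:1):3);")
        t2 = read_newick("((A:2,B:2):2,(C:4,D:2):6);")
        assert trees.cophenetic_correlation(t1, t2) == pytest.approx(1.0, abs=1e-12)

    def test_star_tree_returns_nan(self):
        star = read_newick("(A:1,B:1,C:1);")
        other = read_newick("((A:1,B:1):1,C:2);")
        assert np.isnan(trees.cophenetic_correlation(star, other))


class TestRobinsonFoulds:
    def test_matches_dendropy_oracle(self, rng):
        import dendropy
        from dendropy.calculate import treecompare

        for s in range(5):
            b1 = generate(SynthConfig(seed=s, n_features=10, n_markers_per_taxon=0,
                                      n_taxa=6))
            b2 = generate(SynthConfig(seed=s + 100, n_features=10,
                                      n_markers_per_taxon=0, n_taxa=6))
            t1, t2 = b1.true_tree, b2.true_tree
            ours = trees.robinson_foulds(t1, t2)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=str(t1.tree), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=str(t2.tree), schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            ref = treecompare.symmetric_difference(d1, d2)
            assert ours == ref


class TestCompareToReference:
    def test_self_congruence(self, rng):
        vals = rng.uniform(0, 10, size=(8, 12))
        taxa = ["A", "A", "B", "B", "C", "C", "D", "D"]
        table = make_feature_table(vals, taxa=taxa, transformed=True)
        reference, _ = trees.compare_to_reference(
            table, read_newick("((A:1,B:1):1,(C:1,D:1):1);"), n_perm=0
        )
        # compare the table against the tree built from itself: the trees are
        # identical (c = 1 exactly); M correlates the raw distances with their
        # own complete-linkage cophenetic transform, a strong but not perfect
        # monotone association
        _, report = trees.compare_to_reference(table, reference, n_perm=0)
        assert report.c == pytest.approx(1.0, abs=1e-12)
        assert 0.0 < report.M <= 1.0

    def test_permuted_labels_destroy_signal(self):
        ms = []
        for s in range(12):
            b = generate(SynthConfig(seed=s, n_features=150, brownian_sd=1.0,
                                     replicate_sd=0.2, n_markers_per_taxon=0))
            t = prep.log_transform(b.feature_table)
            rng = np.random.default_rng(s)
            perm = rng.permutation(t.sample_meta["taxon"].unique())
            mapping = dict(zip(t.sample_meta["taxon"].unique(), perm))
            t.sample_meta["taxon"] = t.sample_meta["taxon"].map(mapping)
            _, rep = trees.compare_to_reference(t, b.true_tree, n_perm=0)
            ms.append(rep.M)
        # a random relabelling should not systematically align with the tree
        assert abs(np.mean(ms)) < 0.9

    def test_unknown_taxon_rejected(self, rng):
        table = make_feature_table(rng.uniform(0, 1, (2, 3)), taxa=["A", "Z"])
        with pytest.raises(ValueError, match="Z"):
            trees.compare_to_reference(table, read_newick("((A:1,B:1):1,C:2);"), n_perm=0)
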