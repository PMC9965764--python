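"""Chemotaxonomic tree construction and congruence with a reference phylogeny.

A chemotaxonomic tree is the complete-linkage dendrogram of Euclidean
distances between taxon-mean profiles.  Congruence with a reference tree is
quantified two ways: the Mantel statistic M (Pearson correlation of the two
distance matrices' lower triangles, permutation-tested by jointly permuting
the rows/columns of one matrix) and the cophenetic correlation c (Pearson
correlation of the trees' cophenetic distance vectors over shared tips).

Cophenetic convention: dendrograms use the merge height of the lowest common
ancestor (half the tip-to-tip path length of the ultrametric tree);
phylograms use the tip-to-tip path length.  Each tree contributes distances
in its own convention; Pearson correlation absorbs the scale.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform

from .io_core import FeatureTable, TaxonTree

logger = logging.getLogger(__name__)

__all__ = [
    "taxon_distance",
    "complete_linkage_tree",
    "cophenetic_matrix",
    "mantel",
    "cophenetic_correlation",
    "robinson_foulds",
    "CongruenceReport",
    "compare_distance_to_reference",
    "compare_to_reference",
]

DistanceMatrix = skbio.DistanceMatrix


def _abundance_frame(table) -> tuple[pd.DataFrame, pd.Series]:
    """Accept a FeatureTable or a (samples x variables) DataFrame plus taxa."""
    if isinstance(table, FeatureTable):
        return table.abundance, table.sample_meta["taxon"]
    raise TypeError("expected a FeatureTable; for plain matrices use taxon_distance_frame")


def taxon_distance_frame(matrix: pd.DataFrame, taxa: pd.Series, aggregate: str = "mean") -> DistanceMatrix:
    """Euclidean distances between per-taxon aggregated profiles of a plain matrix."""
    if aggregate not in ("mean", "median"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    taxa = taxa.reindex(matrix.index)
    if taxa.isna().any():
        raise ValueError("every sample needs a taxon label")
    grouped = matrix.groupby(taxa, sort=False).agg(aggregate)
    if grouped.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    dm = pdist(grouped.to_numpy(dtype=float), metric="euclidean")
    return DistanceMatrix(squareform(dm), ids=list(grouped.index))


def taxon_distance(table: FeatureTable, aggregate: str = "mean") -> DistanceMatrix:
    """Replicates averaged per taxon, then pairwise Euclidean distances."""
    matrix, taxa = _abundance_frame(table)
    return taxon_distance_frame(matrix, taxa, aggregate=aggregate)


def complete_linkage_tree(D: DistanceMatrix) -> TaxonTree:
    """Agglomerative clustering with complete (maximum) linkage.

    Merge heights become node heights (tips at height 0; branch length =
    parent height - child height), so the dendrogram is exactly ultrametric.
    Among equal-distance merges the pair whose (lexicographically smallest
    member, other smallest member) label pair sorts first merges first, which
    makes the topology deterministic under ties.
    """
    labels = list(D.ids)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels to cluster")
    mat = np.array(D.data, dtype=float)
    if np.isnan(mat).any():
        raise ValueError("distance matrix contains NaN")

    class _Cluster:
        __slots__ = ("node", "height", "label", "members")

        def __init__(self, node, height, label, members):
            self.node, self.height, self.label, self.members = node, height, label, members

    clusters: dict[int, _Cluster] = {
        i: _Cluster(skbio.TreeNode(name=lab), 0.0, lab, {i}) for i, lab in enumerate(labels)
    }
    dist: dict[frozenset, float] = {
        frozenset((i, j)): mat[i, j] for i, j in itertools.combinations(range(len(labels)), 2)
    }
    next_id = len(labels)
    while len(clusters) > 1:
        # minimal distance, ties broken by the lexicographically smallest label pair
        def _key(pair):
            i, j = sorted(pair, key=lambda k: clusters[k].label)
            return (dist[pair], clusters[i].label, clusters[j].label)

        pair = min(dist, key=_key)
        h = dist[pair]
        i, j = sorted(pair, key=lambda k: clusters[k].label)
        ci, cj = clusters.pop(i), clusters.pop(j)
        ci.node.length = h - ci.height
        cj.node.length = h - cj.height
        parent = skbio.TreeNode(children=[ci.node, cj.node])
        merged = _Cluster(parent, h, min(ci.label, cj.label), ci.members | cj.members)
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        # complete linkage: distance to the new cluster is the max over member pairs
        for k, ck in clusters.items():
            dist[frozenset((k, next_id))] = max(
                mat[a, b] for a in merged.members for b in ck.members
            )
        clusters[next_id] = merged
        next_id += 1
    root = clusters.popitem()[1].node
    root.length = 0.0
    return TaxonTree(tree=root, is_dendrogram=True)


def cophenetic_matrix(tree: TaxonTree) -> DistanceMatrix:
    """Cophenetic distances between tips in the tree's own convention."""
    tips = tree.tip_names
    if len(tips) < 2:
        raise ValueError("need at least 2 tips")
    for node in tree.tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("tree has missing branch lengths")
    dm = tree.tree.tip_tip_distances(endpoints=tips)
    data = np.array(dm.data, dtype=float)
    if tree.is_dendrogram:
        data = data / 2.0  # path length -> LCA merge height on an ultrametric tree
    return DistanceMatrix(data, ids=list(dm.ids))


def _aligned_condensed(d1: DistanceMatrix, d2: DistanceMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    ids1, ids2 = set(d1.ids), set(d2.ids)
    if ids1 != ids2:
        raise ValueError(f"label sets differ: {sorted(ids1 ^ ids2)}")
    order = sorted(ids1)
    m1 = np.array(d1.filter(order).data, dtype=float)
    m2 = np.array(d2.filter(order).data, dtype=float)
    iu = np.tril_indices(len(order), k=-1)
    return m1[iu], m2, order  # second matrix returned square for permutation reuse


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt((x @ x) * (y @ y))
    if denom == 0:
        return float("nan")
    return float((x @ y) / denom)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> tuple[float, float | None]:
    """Mantel statistic M and one-sided permutation p-value.

    M is the Pearson correlation of the lower-triangle vectors (diagonal
    excluded) after aligning labels.  The test jointly permutes rows and
    columns of the second matrix; with sampled permutations
    p = (1 + #{M* >= M}) / (n_perm + 1), while ``exhaustive=True`` enumerates
    all n! relabelings (identity included) and reports the exact fraction.
    ``n_perm=0`` (non-exhaustive) returns p = None.
    """
    v1, m2, order = _aligned_condensed(d1, d2)
    n = len(order)
    if n < 3:
        raise ValueError("Mantel needs at least 3 labels")
    iu = np.tril_indices(n, k=-1)
    M = _pearson(v1, m2[iu])

    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            pm = m2[np.ix_(perm, perm)]
            if _pearson(v1, pm[iu]) >= M - 1e-12:
                count += 1
            total += 1
        return M, count / total
    if n_perm == 0:
        return M, None
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pm = m2[np.ix_(perm, perm)]
        if _pearson(v1, pm[iu]) >= M:
            count += 1
    return M, (1 + count) / (n_perm + 1)


def cophenetic_correlation(tree1: TaxonTree, tree2: TaxonTree) -> float:
    """Pearson correlation of the two cophenetic vectors over shared tips.

    Returns NaN (logged) when either vector has zero variance (star tree).
    """
    shared = sorted(set(tree1.tip_names) & set(tree2.tip_names))
    if len(shared) < 3:
        raise ValueError("cophenetic correlation needs at least 3 shared tips")
    v = []
    for t in (tree1, tree2):
        dm = cophenetic_matrix(t).filter(shared)
        m = np.array(dm.data, dtype=float)
        v.append(m[np.tril_indices(len(shared), k=-1)])
    c = _pearson(v[0], v[1])
    if math.isnan(c):
        logger.warning("zero-variance cophenetic vector; correlation undefined")
    return c


def _splits(tree: TaxonTree, tips: frozenset[str]) -> set[frozenset]:
    """Non-trivial unrooted bipartitions restricted to ``tips``."""
    out = set()
    for node in tree.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips()) & tips
        other = tips - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset((side, other)))
    return out


def robinson_foulds(tree1: TaxonTree, tree2: TaxonTree) -> int:
    """Unrooted Robinson-Foulds distance over shared tips."""
    tips = frozenset(tree1.tip_names) & frozenset(tree2.tip_names)
    if len(tips) < 4:
        # fewer than 4 shared tips admit no non-trivial unrooted split
        return 0
    s1, s2 = _splits(tree1, tips), _splits(tree2, tips)
    return len(s1 ^ s2)


@dataclass
class CongruenceReport:
    M: float
    mantel_p: float | None
    c: float
    shared_tips: list[str]


def compare_distance_to_reference(
    D: DistanceMatrix,
    reference: TaxonTree,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[TaxonTree, CongruenceReport]:
    """Cluster a taxon distance matrix and score it against the reference tree."""
    missing = set(D.ids) - set(reference.tip_names)
    if missing:
        raise ValueError(f"taxa not in reference tree: {sorted(missing)}")
    chemo = complete_linkage_tree(D)
    shared = sorted(set(D.ids) & set(reference.tip_names))
    ref_coph = cophenetic_matrix(reference).filter(shared)
    # M correlates the raw chemical distances with the reference's cophenetic
    # distances; c correlates the two trees' cophenetic vectors.  The two
    # statistics deliberately differ: M sees the data-space distances before
    # the clustering distorts them, c sees only the trees.
    M, p = mantel(D.filter(shared), ref_coph, n_perm=n_perm, seed=seed)
    c = cophenetic_correlation(chemo, reference)
    return chemo, CongruenceReport(M=M, mantel_p=p, c=c, shared_tips=shared)


def compare_to_reference(
    table: FeatureTable,
    reference: TaxonTree,
    n_perm: int = 999,
    seed: int | None = None,
    aggregate: str = "mean",
) -> tuple[TaxonTree, CongruenceReport]:
    """Build the chemotaxonomic tree and score it against the reference.

    Chains taxon-mean Euclidean distances -> complete-linkage dendrogram;
    M compares the chemical distance matrix with the reference's cophenetic
    matrix, c compares the two trees' cophenetic vectors.
    """
    D = taxon_distance(table, aggregate=aggregate)
    return compare_distance_to_reference(D, reference, n_perm=n_perm, seed=seed)
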