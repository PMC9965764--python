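"""Validated in-memory representations and readers/writers for the pipeline's file formats.

The pipeline moves five kinds of objects around: intensity feature tables
(samples x features with per-feature ion mode, m/z, retention time and an
MS2-acquired flag), ranked structure-annotation tables, a single-parent
compound-class ontology, rooted taxon trees (both reference phylogenies and
chemotaxonomic dendrograms), and per-feature molecular-descriptor matrices.
Everything is plain text: CSV/TSV for tables, Newick for trees.

File layout for feature tables (this package's convention): the matrix CSV has
``sample_id, taxon, replicate`` as its first three columns followed by one
column per feature; a sidecar TSV carries per-feature metadata
(``feature_id, ion_mode, mz, rt, has_ms2``) plus a ``# transformed=`` header
line recording whether intensities are on the log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "StateError",
    "FeatureTable",
    "AnnotationTable",
    "Ontology",
    "TaxonTree",
    "read_feature_table",
    "write_feature_table",
    "read_annotations",
    "write_annotations",
    "select_best_annotation",
    "read_ontology",
    "write_ontology",
    "read_newick",
    "write_newick",
    "read_descriptor_matrix",
    "write_descriptor_matrix",
]


class FormatError(ValueError):
    """An input file or in-memory object violates the documented format."""


class StateError(RuntimeError):
    """An operation was applied to a table in the wrong state (e.g. double log)."""


_ION_MODES = frozenset({"pos", "neg"})
_FEATURE_META_COLS = ["ion_mode", "mz", "rt", "has_ms2"]
_SAMPLE_META_COLS = ["taxon", "replicate"]


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with per-feature and per-sample metadata.

    ``abundance`` is a DataFrame indexed by sample id with one column per
    feature id.  ``feature_meta`` is indexed by feature id with columns
    ``ion_mode`` ('pos'/'neg'), ``mz`` (Da), ``rt`` (seconds), ``has_ms2``
    (bool).  ``sample_meta`` is indexed by sample id with columns ``taxon``
    and ``replicate``.  Raw tables hold non-negative intensities; once
    ``transformed`` is set the entries are natural-log scale.
    """

    abundance: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        ab = self.abundance
        if ab.index.duplicated().any():
            dup = ab.index[ab.index.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if ab.columns.duplicated().any():
            dup = ab.columns[ab.columns.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        if not ab.index.equals(self.sample_meta.index):
            raise FormatError("sample ids of abundance and sample_meta differ")
        if not ab.columns.equals(self.feature_meta.index):
            raise FormatError("feature ids of abundance and feature_meta differ")
        vals = ab.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise FormatError("abundance matrix contains non-finite values")
        if not self.transformed and (vals < 0).any():
            s, f = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative raw intensity at sample {ab.index[s]!r}, feature {ab.columns[f]!r}"
            )
        missing_cols = [c for c in _FEATURE_META_COLS if c not in self.feature_meta.columns]
        if missing_cols:
            raise FormatError(f"feature_meta lacks columns {missing_cols}")
        bad_modes = set(self.feature_meta["ion_mode"]) - _ION_MODES
        if bad_modes:
            raise FormatError(f"unknown ion mode(s): {sorted(bad_modes)}")
        if (self.feature_meta["mz"].to_numpy(dtype=float) <= 0).any():
            raise FormatError("m/z values must be > 0")
        if (self.feature_meta["rt"].to_numpy(dtype=float) < 0).any():
            raise FormatError("retention times must be >= 0")
        missing_cols = [c for c in _SAMPLE_META_COLS if c not in self.sample_meta.columns]
        if missing_cols:
            raise FormatError(f"sample_meta lacks columns {missing_cols}")
        if self.sample_meta["taxon"].isna().any() or (self.sample_meta["taxon"] == "").any():
            raise FormatError("every sample needs a taxon label")
        reps = self.sample_meta["replicate"].to_numpy(dtype=int)
        if (reps < 1).any():
            raise FormatError("replicate numbers must be positive integers")

    # -- conveniences ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.sample_meta["taxon"]:
            seen.setdefault(t, None)
        return list(seen)

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundance.shape[1]

    def select_features(self, feature_ids) -> "FeatureTable":
        """Sub-table keeping the given features (order preserved as given)."""
        ids = list(feature_ids)
        return FeatureTable(
            abundance=self.abundance.loc[:, ids].copy(),
            feature_meta=self.feature_meta.loc[ids].copy(),
            sample_meta=self.sample_meta.copy(),
            transformed=self.transformed,
        )

    def with_abundance(self, abundance: pd.DataFrame, transformed: bool | None = None) -> "FeatureTable":
        return FeatureTable(
            abundance=abundance,
            feature_meta=self.feature_meta.copy(),
            sample_meta=self.sample_meta.copy(),
            transformed=self.transformed if transformed is None else transformed,
        )

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.transformed == other.transformed
            and self.abundance.equals(other.abundance)
            and self.feature_meta.equals(other.feature_meta)
            and self.sample_meta.equals(other.sample_meta)
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.tsv")


def write_feature_table(table: FeatureTable, path, sidecar=None, dialect: str = "csv") -> None:
    """Write the matrix CSV/TSV plus the per-feature metadata sidecar TSV."""
    path = Path(path)
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    sep = "," if dialect == "csv" else "\t"
    out = pd.concat([table.sample_meta[_SAMPLE_META_COLS], table.abundance], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)
    with open(sidecar, "w") as fh:
        fh.write(f"# transformed={str(table.transformed).lower()}\n")
        meta = table.feature_meta[_FEATURE_META_COLS].copy()
        meta.index.name = "feature_id"
        meta.to_csv(fh, sep="\t")


def read_feature_table(path, sidecar=None, dialect: str = "csv") -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`.

    Missing matrix cells are imputed with 0 (logged count); duplicated ids or
    negative raw intensities raise :class:`FormatError` naming the offender.
    """
    path = Path(path)
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    sep = "," if dialect == "csv" else "\t"
    import csv as _csv

    with open(path, newline="") as fh:
        header = next(_csv.reader(fh, delimiter=sep))
    seen: set[str] = set()
    for col in header[1:]:
        if col in seen:
            raise FormatError(f"duplicate feature id: {col!r}")
        seen.add(col)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    for col in _SAMPLE_META_COLS:
        if col not in raw.columns:
            raise FormatError(f"feature table lacks reserved column {col!r}")
    sample_meta = raw[_SAMPLE_META_COLS].copy()
    sample_meta["replicate"] = sample_meta["replicate"].astype(int)
    abundance = raw.drop(columns=_SAMPLE_META_COLS).astype(float)

    n_missing = int(abundance.isna().to_numpy().sum())
    if n_missing:
        logger.info("imputed %d missing cell(s) with 0 in %s", n_missing, path.name)
        abundance = abundance.fillna(0.0)

    with open(sidecar) as fh:
        first = fh.readline().strip()
        transformed = first.replace(" ", "") == "#transformed=true"
        meta = pd.read_csv(fh, sep="\t", index_col=0)
    meta["has_ms2"] = meta["has_ms2"].astype(bool)
    if not set(abundance.columns) == set(meta.index):
        raise FormatError("sidecar feature ids do not match matrix columns")
    meta = meta.loc[abundance.columns]
    return FeatureTable(abundance=abundance, feature_meta=meta, sample_meta=sample_meta,
                        transformed=transformed)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_ANNOT_COLS = ["feature_id", "rank", "structure_id", "formula", "score", "class_id"]


@dataclass
class AnnotationTable:
    """Ranked structure candidates per feature.

    Columns: ``feature_id, rank, structure_id, formula, score, class_id``.
    ``score`` may be missing (NaN); ``(feature_id, rank)`` pairs are unique.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _ANNOT_COLS if c not in self.rows.columns]
        if missing:
            raise FormatError(f"annotation table lacks columns {missing}")
        self.rows = self.rows[_ANNOT_COLS].reset_index(drop=True)
        self.rows["rank"] = self.rows["rank"].astype(int)
        if (self.rows["rank"] < 1).any():
            raise FormatError("annotation ranks must be positive integers")
        dup = self.rows.duplicated(subset=["feature_id", "rank"])
        if dup.any():
            pair = self.rows.loc[dup, ["feature_id", "rank"]].iloc[0]
            raise FormatError(
                f"duplicate (feature_id, rank) pair: ({pair.feature_id!r}, {pair['rank']})"
            )

    @property
    def feature_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.rows["feature_id"]:
            seen.setdefault(f, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.rows)

    def validate_against(self, ontology: "Ontology") -> None:
        unknown = set(self.rows["class_id"]) - set(ontology.term_ids)
        if unknown:
            raise FormatError(f"annotation class not in ontology: {sorted(unknown)[0]!r}")


def read_annotations(path) -> AnnotationTable:
    rows = pd.read_csv(path, sep="\t")
    return AnnotationTable(rows=rows)


def write_annotations(annotations: AnnotationTable, path) -> None:
    annotations.rows.to_csv(path, sep="\t", index=False)


def select_best_annotation(annotations: AnnotationTable) -> AnnotationTable:
    """Reduce to one candidate per feature.

    If any candidate of a feature carries a score, the maximal-score candidate
    wins; otherwise the rank-1 candidate.  Ties break by lower rank, then by
    lexicographically smaller structure_id.  An empty table reduces to an
    empty table.
    """
    rows = annotations.rows
    if rows.empty:
        return AnnotationTable(rows=rows.copy())
    df = rows.copy()
    df["_has_score"] = df["score"].notna()
    # features with any score: drop their unscored candidates
    any_score = df.groupby("feature_id")["_has_score"].transform("any")
    df = df[~any_score | df["_has_score"]]
    df = df.sort_values(
        by=["score", "rank", "structure_id"],
        ascending=[False, True, True],
        na_position="last",
        kind="mergesort",
    )
    best = df.drop_duplicates(subset="feature_id", keep="first").drop(columns="_has_score")
    # restore first-appearance feature order
    order = {f: i for i, f in enumerate(annotations.feature_ids)}
    best = best.sort_values(by="feature_id", key=lambda s: s.map(order), kind="mergesort")
    return AnnotationTable(rows=best.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------


@dataclass
class Ontology:
    """Single-parent compound-class tree, conventionally rooted at "Organic compounds".

    ``terms`` holds one row per term: ``term_id, name, parent_id, level``
    (root: empty parent, level 0; every child sits one level below its parent).
    """

    terms: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.terms
        for col in ("term_id", "name", "parent_id", "level"):
            if col not in t.columns:
                raise FormatError(f"ontology lacks column {col!r}")
        t = t.copy().reset_index(drop=True)
        t["parent_id"] = t["parent_id"].fillna("")
        t["level"] = t["level"].astype(int)
        if t["term_id"].duplicated().any():
            raise FormatError("duplicate ontology term id")
        self.terms = t
        self._parent = dict(zip(t["term_id"], t["parent_id"]))
        self._level = dict(zip(t["term_id"], t["level"]))
        self._name = dict(zip(t["term_id"], t["name"]))
        roots = [tid for tid, p in self._parent.items() if p == ""]
        if len(roots) != 1:
            raise FormatError(f"ontology must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        if self._level[self.root] != 0:
            raise FormatError("root term must have level 0")
        for tid, p in self._parent.items():
            if tid == self.root:
                continue
            if p not in self._parent:
                raise FormatError(f"term {tid!r} has unknown parent {p!r}")
            if self._level[tid] != self._level[p] + 1:
                raise FormatError(
                    f"term {tid!r} has level {self._level[tid]}, expected parent level + 1"
                )

    @property
    def term_ids(self) -> list[str]:
        return list(self.terms["term_id"])

    def name(self, term_id: str) -> str:
        return self._name[term_id]

    def level(self, term_id: str) -> int:
        return self._level[term_id]

    def ancestors(self, term_id: str) -> list[str]:
        """Root-to-term path, inclusive of both ends."""
        if term_id not in self._parent:
            raise KeyError(f"unknown ontology term {term_id!r}")
        path = [term_id]
        while path[-1] != self.root:
            path.append(self._parent[path[-1]])
        return path[::-1]

    def leaves(self) -> list[str]:
        parents = set(self._parent.values())
        return [tid for tid in self.term_ids if tid not in parents]

    def superclass_of(self, term_id: str) -> str | None:
        """The level-1 ancestor (child of the root) on the term's path, if any."""
        path = self.ancestors(term_id)
        return path[1] if len(path) > 1 else None


def read_ontology(path) -> Ontology:
    terms = pd.read_csv(path, sep="\t", dtype={"term_id": str, "name": str, "parent_id": str})
    return Ontology(terms=terms)


def write_ontology(ontology: Ontology, path) -> None:
    ontology.terms.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class TaxonTree:
    """A rooted tree with branch lengths and uniquely labelled tips.

    ``is_dendrogram`` marks ultrametric trees built by agglomerative
    clustering, whose natural tip-tip dissimilarity is the merge height of the
    lowest common ancestor (half the tip-to-tip path length); reference
    phylogenies read from Newick use plain path lengths.
    """

    tree: skbio.TreeNode
    is_dendrogram: bool = False

    def __post_init__(self) -> None:
        tips = self.tip_names
        if len(tips) != len(set(tips)):
            dup = sorted({t for t in tips if tips.count(t) > 1})[0]
            raise FormatError(f"duplicate tip label: {dup!r}")

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def copy(self) -> "TaxonTree":
        return TaxonTree(tree=self.tree.copy(), is_dendrogram=self.is_dendrogram)

    def is_ultrametric(self, rtol: float = 1e-9) -> bool:
        depths = []
        for tip in self.tree.tips():
            d = 0.0
            node = tip
            while node.parent is not None:
                d += node.length or 0.0
                node = node.parent
            depths.append(d)
        depths = np.asarray(depths)
        scale = max(abs(depths).max(), 1.0)
        return bool(np.ptp(depths) <= rtol * scale)


def read_newick(path_or_str, is_dendrogram: bool = False) -> TaxonTree:
    """Parse Newick; omitted branch lengths default to 1.0 (logged)."""
    src = str(path_or_str)
    try:
        if "(" in src or ";" in src:  # literal newick string
            import io

            tree = skbio.TreeNode.read(io.StringIO(src), format="newick",
                                       convert_underscores=False)
        else:
            tree = skbio.TreeNode.read(src, format="newick",
                                       convert_underscores=False)
    except Exception as exc:  # skbio NewickFormatError carries position detail
        raise FormatError(f"newick parse error: {exc}") from exc
    n_defaulted = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 1.0
            n_defaulted += 1
        elif node.length < 0:
            raise FormatError(f"negative branch length on node {node.name!r}")
    if n_defaulted:
        logger.info("defaulted %d missing branch length(s) to 1.0", n_defaulted)
    if tree.length is None:
        tree.length = 0.0
    return TaxonTree(tree=tree, is_dendrogram=is_dendrogram)


def write_newick(taxon_tree: TaxonTree, path) -> None:
    taxon_tree.tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Descriptor matrices
# ---------------------------------------------------------------------------


def read_descriptor_matrix(path) -> pd.DataFrame:
    """Feature x descriptor matrix; incomplete rows are dropped with a log note."""
    mat = pd.read_csv(path, index_col=0)
    if mat.index.duplicated().any():
        raise FormatError("duplicate feature id in descriptor matrix")
    incomplete = mat.isna().any(axis=1)
    if incomplete.any():
        logger.warning("dropping %d incomplete descriptor row(s)", int(incomplete.sum()))
        mat = mat[~incomplete]
    return mat.astype(float)


def write_descriptor_matrix(mat: pd.DataFrame, path) -> None:
    out = mat.copy()
    out.index.name = "feature_id"
    out.to_csv(path)
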