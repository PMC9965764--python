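"""Projection of feature abundances into compound-class and descriptor spaces.

Each annotated feature carries one compound-class path (root -> ... -> most
specific class).  A class-abundance table entry C[s, c] is the sum of the
sample's abundances over annotated features whose path contains c, restricted
to the requested level: the feature's own most-specific class, its superclass
(the child of the root on its path), or every term on the path.  The
descriptor-abundance table is the plain matrix product of the sample x
annotated-feature abundances with the feature x descriptor matrix.  Sunburst
counts tally, per ontology term, the annotated features detected in at least
one sample of a group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import AnnotationTable, FeatureTable, Ontology

logger = logging.getLogger(__name__)

__all__ = ["ClassAbundanceTable", "class_table", "descriptor_table", "sunburst_counts"]


@dataclass
class ClassAbundanceTable:
    """Samples x ontology-term abundances with each term's ontology level."""

    abundance: pd.DataFrame
    term_levels: pd.Series

    def to_feature_like(self) -> pd.DataFrame:
        return self.abundance


def _reduced_annotation_map(annotations: AnnotationTable) -> dict[str, str]:
    rows = annotations.rows
    if rows["feature_id"].duplicated().any():
        raise ValueError("annotations must be reduced to one row per feature "
                         "(see select_best_annotation)")
    return dict(zip(rows["feature_id"], rows["class_id"]))


def class_table(
    table: FeatureTable,
    annotations: AnnotationTable,
    ontology: Ontology,
    level: str = "most_specific",
) -> ClassAbundanceTable:
    """Project abundances onto ontology terms at the requested level.

    ``level`` is one of ``most_specific`` (each feature contributes to its own
    class only), ``superclass`` (to the level-1 ancestor on its path), or
    ``all`` (to every term on its path).  Unannotated features contribute
    nothing.
    """
    if level not in ("most_specific", "superclass", "all"):
        raise ValueError(f"unknown level {level!r}")
    class_of = _reduced_annotation_map(annotations)
    unknown = set(class_of.values()) - set(ontology.term_ids)
    if unknown:
        raise KeyError(f"annotation class not in ontology: {sorted(unknown)[0]!r}")

    contributions: dict[str, list[str]] = {}  # term -> contributing features
    for fid in table.feature_ids:
        cid = class_of.get(fid)
        if cid is None:
            continue
        if level == "most_specific":
            terms = [cid]
        elif level == "superclass":
            sc = ontology.superclass_of(cid)
            if sc is None:
                logger.info("feature %s annotated at the root; no superclass", fid)
                continue
            terms = [sc]
        else:
            terms = ontology.ancestors(cid)
        for term in terms:
            contributions.setdefault(term, []).append(fid)

    terms = [t for t in ontology.term_ids if t in contributions]  # ontology order
    data = {t: table.abundance[contributions[t]].sum(axis=1) for t in terms}
    ab = pd.DataFrame(data, index=table.abundance.index) if terms else pd.DataFrame(
        index=table.abundance.index
    )
    levels = pd.Series({t: ontology.level(t) for t in terms}, dtype=int)
    return ClassAbundanceTable(abundance=ab, term_levels=levels)


def descriptor_table(table: FeatureTable, descriptors: pd.DataFrame) -> pd.DataFrame:
    """Samples x descriptors = abundances (samples x features) . descriptors.

    Every feature of ``table`` must have a descriptor row; the table is
    expected to be restricted to annotated features beforehand.
    """
    missing = [f for f in table.feature_ids if f not in descriptors.index]
    if missing:
        raise KeyError(f"descriptor rows missing for features: {missing[:5]}")
    X = descriptors.loc[table.feature_ids]
    A = table.abundance.to_numpy(dtype=float)
    D = A @ X.to_numpy(dtype=float)
    return pd.DataFrame(D, index=table.abundance.index, columns=X.columns)


def sunburst_counts(
    annotations: AnnotationTable,
    ontology: Ontology,
    presence: pd.DataFrame,
    group: list[str],
) -> pd.DataFrame:
    """Per-term counts of annotated features detected in >= 1 sample of ``group``.

    ``presence`` is the boolean samples x features matrix from
    :func:`chemophen.preprocess.presence_absence`.  Returns a tidy frame
    (term_id, name, level, count) ordered inside-out, root first.
    """
    group = list(group)
    if not group:
        raise ValueError("group of samples must be non-empty")
    missing = [s for s in group if s not in presence.index]
    if missing:
        raise KeyError(f"unknown sample(s) in group: {missing}")
    class_of = _reduced_annotation_map(annotations)
    detected = presence.loc[group].any(axis=0)

    counts: dict[str, int] = {}
    for fid, cid in class_of.items():
        if fid not in detected.index or not bool(detected[fid]):
            continue
        for term in ontology.ancestors(cid):
            counts[term] = counts.get(term, 0) + 1

    records = [
        {"term_id": t, "name": ontology.name(t), "level": ontology.level(t),
         "count": counts.get(t, 0)}
        for t in ontology.term_ids
        if t in counts
    ]
    out = pd.DataFrame(records, columns=["term_id", "name", "level", "count"])
    return out.sort_values(["level", "term_id"], kind="mergesort").reset_index(drop=True)
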