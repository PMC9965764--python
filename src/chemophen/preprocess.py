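"""Conditioning of MS1 feature tables.

The conditioning chain mirrors common untargeted LC-MS practice: keep features
inside the chromatographic window (RT < 1020 s by default), natural-log
transform intensities with zero imputation (x -> ln(1+x), so missing and true
zeros coincide at 0), derive presence/absence calls against a tiny fraction of
the global median intensity, restrict to features with acquired MS2 spectra,
and join the positive- and negative-mode tables after checking that their
median and variance agree within 10%.  A column-centered PCA is provided as a
diagnostic overview.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io_core import AnnotationTable, FeatureTable, StateError

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessingParams",
    "filter_rt",
    "log_transform",
    "PresenceResult",
    "presence_absence",
    "JoinResult",
    "join_modes",
    "filter_to_annotated",
    "PcaResult",
    "pca_overview",
]


@dataclass(frozen=True)
class ProcessingParams:
    """Conditioning defaults.

    rt_max: retention-time cutoff in seconds (strict ``<``).
    presence_fraction: percent of the global non-zero median below which a
        value counts as absent (1e-8 % by default).
    mode_join_tolerance: allowed relative deviation of medians/variances when
        joining ion modes.
    log_offset: the 1 in ln(1 + x).
    """

    rt_max: float = 1020.0
    presence_fraction: float = 1e-8
    mode_join_tolerance: float = 0.10
    log_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.rt_max <= 0:
            raise ValueError("rt_max must be > 0")
        if self.presence_fraction < 0:
            raise ValueError("presence_fraction must be >= 0")
        if not 0.0 <= self.mode_join_tolerance <= 1.0:
            raise ValueError("mode_join_tolerance must be in [0, 1]")


def filter_rt(table: FeatureTable, rt_max: float = 1020.0) -> FeatureTable:
    """Keep features with retention time strictly below ``rt_max`` seconds."""
    keep = table.feature_meta.index[table.feature_meta["rt"].astype(float) < rt_max]
    if len(keep) == 0:
        logger.warning("RT filter at %.1f s retained zero features", rt_max)
    return table.select_features(keep)


def log_transform(table: FeatureTable) -> FeatureTable:
    """x -> ln(1 + x); imputed zeros remain exactly 0.  Refuses double application."""
    if table.transformed:
        raise StateError("table is already log-transformed")
    return table.with_abundance(np.log1p(table.abundance), transformed=True)


class PresenceResult(NamedTuple):
    present: pd.DataFrame  # boolean, samples x features
    threshold: float


def presence_absence(table: FeatureTable, presence_fraction: float = 1e-8) -> PresenceResult:
    """Presence calls: present iff abundance >= threshold.

    The threshold is ``presence_fraction`` *percent* of the global median of
    non-zero raw abundances, so calls are invariant to rescaling the whole
    table.  Strictly smaller values are absent.
    """
    if table.transformed:
        raise StateError("presence/absence is defined on raw intensities")
    vals = table.abundance.to_numpy(dtype=float)
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero table: median of non-zero abundances is undefined")
    threshold = float(np.median(nonzero)) * (presence_fraction / 100.0)
    present = table.abundance >= threshold
    return PresenceResult(present=present, threshold=threshold)


class JoinResult(NamedTuple):
    table: FeatureTable
    median_deviation: float
    variance_deviation: float
    warning: bool  # True when either deviation exceeded the tolerance


def _relative_deviation(a: float, b: float) -> float:
    denom = (a + b) / 2.0
    if denom == 0:
        return 0.0 if a == b else math.inf
    return abs(a - b) / denom


def join_modes(pos: FeatureTable, neg: FeatureTable, tolerance: float = 0.10) -> JoinResult:
    """Join positive- and negative-mode tables of the same samples.

    Feature ids get ``pos_``/``neg_`` prefixes.  The medians and variances of
    the two tables' non-zero entries must agree within ``tolerance`` relative
    deviation; a violation does not abort the join but sets the warning flag.
    """
    if pos.sample_ids != neg.sample_ids:
        mismatch = set(pos.sample_ids) ^ set(neg.sample_ids)
        raise ValueError(
            f"sample sets of the two modes differ (mismatch: {sorted(mismatch) or 'ordering'})"
        )
    if pos.transformed != neg.transformed:
        raise StateError("both tables must be on the same scale (raw or transformed)")

    devs = {}
    for stat_name, stat in (("median", np.median), ("variance", np.var)):
        pair = []
        for t in (pos, neg):
            vals = t.abundance.to_numpy(dtype=float)
            nz = vals[vals != 0]
            pair.append(float(stat(nz)) if nz.size else 0.0)
        devs[stat_name] = _relative_deviation(*pair)
    warning = any(d > tolerance for d in devs.values())
    if warning:
        logger.warning(
            "mode join deviations exceed %.0f%%: median %.3f, variance %.3f",
            100 * tolerance, devs["median"], devs["variance"],
        )

    def _prefixed(t: FeatureTable, prefix: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        ab = t.abundance.copy()
        ab.columns = [f"{prefix}_{c}" for c in ab.columns]
        meta = t.feature_meta.copy()
        meta.index = ab.columns
        return ab, meta

    ab_p, meta_p = _prefixed(pos, "pos")
    ab_n, meta_n = _prefixed(neg, "neg")
    joined = FeatureTable(
        abundance=pd.concat([ab_p, ab_n], axis=1),
        feature_meta=pd.concat([meta_p, meta_n]),
        sample_meta=pos.sample_meta.copy(),
        transformed=pos.transformed,
    )
    return JoinResult(joined, devs["median"], devs["variance"], warning)


def filter_to_annotated(table: FeatureTable, annotations: AnnotationTable | None = None) -> FeatureTable:
    """Keep features with acquired MS2 spectra and (optionally) an annotation row."""
    keep = table.feature_meta.index[table.feature_meta["has_ms2"].astype(bool)]
    if annotations is not None:
        annotated = set(annotations.rows["feature_id"])
        keep = [f for f in keep if f in annotated]
    return table.select_features(keep)


class PcaResult(NamedTuple):
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # features x components
    explained_variance_ratio: np.ndarray


def pca_overview(table: FeatureTable, n_components: int | None = None) -> PcaResult:
    """Column-centered PCA of the (transformed) table for diagnostics."""
    X = table.abundance.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_comp = min(n - 1, p)
    n_components = max_comp if n_components is None else n_components
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= min(samples-1, features) = {max_comp}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=table.abundance.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=table.abundance.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
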