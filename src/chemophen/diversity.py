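"""Chemical-diversity statistics.

Per sample: richness (number of variables called present), Shannon diversity
H' = -sum p_i ln p_i in nats, and Pielou evenness J = H' / ln(richness).
Per taxon: the unique variables, i.e. those present in that taxon but in no
replicate of any other taxon.  Group differences are assessed by one-way
ANOVA with a post-hoc Tukey HSD test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io_core import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "richness",
    "shannon",
    "pielou",
    "unique_variables",
    "diversity_table",
    "AnovaTukeyResult",
    "anova_tukey",
]


def richness(row, threshold: float = 0.0) -> int:
    """Number of entries called present (``>= threshold``; with the default
    threshold 0, strictly positive entries)."""
    x = np.asarray(row, dtype=float)
    if threshold > 0:
        return int(np.count_nonzero(x >= threshold))
    return int(np.count_nonzero(x > 0))


def shannon(row) -> float:
    """Shannon H' in nats over the positive entries."""
    x = np.asarray(row, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("zero-sum vector: Shannon index undefined")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def pielou(row, threshold: float = 0.0) -> float:
    """Pielou evenness J = H' / ln(richness); NaN (logged) when richness < 2."""
    r = richness(row, threshold)
    if r < 2:
        logger.info("Pielou J undefined for richness %d", r)
        return float("nan")
    return shannon(row) / np.log(r)


def unique_variables(
    table: FeatureTable,
    taxon: str,
    presence: pd.DataFrame | None = None,
    all_replicates: bool = False,
) -> set[str]:
    """Features present in ``taxon`` but absent from every other taxon.

    Presence defaults to "abundance > 0"; pass the matrix from
    :func:`chemophen.preprocess.presence_absence` for threshold-based calls.
    ``all_replicates=True`` additionally requires presence in every replicate
    of the focal taxon (default: any replicate).
    """
    taxa = set(table.sample_meta["taxon"])
    if len(taxa) < 2:
        raise ValueError("unique variables need at least 2 taxa")
    if taxon not in taxa:
        raise KeyError(f"unknown taxon {taxon!r}")
    if presence is None:
        presence = table.abundance > 0
    is_focal = (table.sample_meta["taxon"] == taxon).to_numpy()
    focal = presence.loc[is_focal]
    others = presence.loc[~is_focal]
    in_focal = focal.all(axis=0) if all_replicates else focal.any(axis=0)
    keep = in_focal & ~others.any(axis=0)
    return set(presence.columns[keep])


def diversity_table(
    table: FeatureTable, threshold: float = 0.0, presence: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample (richness, H', J) and per-taxon unique-variable counts."""
    per_sample = pd.DataFrame(
        {
            "taxon": table.sample_meta["taxon"],
            "richness": [richness(r, threshold) for _, r in table.abundance.iterrows()],
            "shannon_H": [shannon(r) for _, r in table.abundance.iterrows()],
            "pielou_J": [pielou(r, threshold) for _, r in table.abundance.iterrows()],
        },
        index=table.abundance.index,
    )
    per_taxon = pd.DataFrame(
        {
            "n_unique": {
                t: len(unique_variables(table, t, presence=presence)) for t in table.taxa
            }
        }
    )
    per_taxon.index.name = "taxon"
    return per_sample, per_taxon


@dataclass
class AnovaTukeyResult:
    F: float
    p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, significant


def anova_tukey(values, groups, alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA F/p plus Tukey HSD adjusted pairwise p-values."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    by_group = [values[groups == g] for g in labels]
    if any(len(v) < 2 for v in by_group):
        raise ValueError("every group needs at least 2 observations")
    if all(np.var(v) == 0 for v in by_group):
        raise ValueError("zero within-group variance everywhere: F undefined")
    F, p = stats.f_oneway(*by_group)
    hsd = pairwise_tukeyhsd(values, groups, alpha=alpha)
    frame = pd.DataFrame(
        hsd.summary().data[1:], columns=[c.strip() for c in hsd.summary().data[0]]
    )
    tukey = pd.DataFrame(
        {
            "group1": frame["group1"],
            "group2": frame["group2"],
            "meandiff": frame["meandiff"].astype(float),
            "p_adj": frame["p-adj"].astype(float),
        }
    )
    tukey["significant"] = tukey["p_adj"] < alpha
    return AnovaTukeyResult(F=float(F), p=float(p), tukey=tukey)
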