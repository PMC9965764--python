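"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates an untargeted LC-MS chemotaxonomy study: a rooted
species tree whose Brownian-evolving species effects shift log-normal
feature intensities, a shared core metabolome plus planted species-specific
marker features, two ion modes, missing values, compound-class annotations
for a subset of features over a small three-level ontology, and molecular
descriptors correlated with class membership.

The log intensity of feature f in replicate r of taxon t is

    L = mu0 + u_f + b_{t,f} + m_{t,f} + eps,

with u_f ~ N(0, 1) a per-feature baseline shared by all taxa (the core
metabolome), b_{t,f} a Brownian motion along the species tree with variance
sigma_b^2 per unit branch length, m_{t,f} the planted marker log-effect
(ln 4 by default) when f is a marker of t, and eps ~ N(0, sigma_e^2)
replicate noise.  Intensities are exp(L), with entries zeroed independently
at the missing rate.  The same seed reproduces the bundle bit for bit.

Defaults mirror the emulated study design: 4 taxa x 3 biological replicates.
Retention times are drawn inside the retained analytic window, i.e. the
table emulates data after upstream RT-window filtering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .io_core import AnnotationTable, FeatureTable, Ontology, TaxonTree, read_newick

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "SynthBundle", "generate", "default_ontology", "make_reference_images"]

# affine map from a taxon-replicate's mean log-abundance in the three
# designated compound classes to the image's mean channel values
IMAGE_CHANNEL_OFFSET = 40.0
IMAGE_CHANNEL_SLOPE = 8.0
IMAGE_PIXEL_NOISE_SD = 2.0


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; all bounds enforced at construction."""

    n_taxa: int = 4
    n_replicates: int = 3
    n_features: int = 300
    frac_annotated: float = 0.6
    n_markers_per_taxon: int = 10
    marker_log_effect: float = math.log(4.0)
    brownian_sd: float = 0.5
    replicate_sd: float = 0.3
    baseline_log_mean: float = math.log(1e5)
    missing_rate: float = 0.02
    frac_negative_mode: float = 0.4
    seed: int = 0
    tree: str | None = None
    n_descriptors: int = 8

    def __post_init__(self) -> None:
        checks = [
            (self.n_taxa >= 2, "n_taxa >= 2"),
            (self.n_replicates >= 2, "n_replicates >= 2"),
            (self.n_features >= 10, "n_features >= 10"),
            (0 < self.frac_annotated <= 1, "frac_annotated in (0, 1]"),
            (self.n_markers_per_taxon >= 0, "n_markers_per_taxon >= 0"),
            (self.brownian_sd >= 0, "brownian_sd >= 0"),
            (self.replicate_sd >= 0, "replicate_sd >= 0"),
            (0 <= self.missing_rate < 1, "missing_rate in [0, 1)"),
            (0 <= self.frac_negative_mode <= 1, "frac_negative_mode in [0, 1]"),
            (self.n_descriptors >= 1, "n_descriptors >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid SynthConfig: requires {msg}")
        if self.n_markers_per_taxon * self.n_taxa > self.n_features:
            raise ValueError("n_markers_per_taxon x n_taxa exceeds n_features")


@dataclass
class SynthBundle:
    """Everything a downstream stage needs, with the generating ground truth."""

    feature_table: FeatureTable
    annotations: AnnotationTable
    ontology: Ontology
    descriptors: pd.DataFrame
    true_tree: TaxonTree
    planted_markers: dict[str, set[str]]
    config: SynthConfig


_SUPERCLASSES = [
    "Lipids and lipid-like molecules",
    "Phenylpropanoids and polyketides",
    "Organic oxygen compounds",
    "Benzenoids",
]
_LEAF_CLASSES = [
    "Fatty acyls", "Glycerophospholipids", "Prenol lipids",
    "Flavonoids", "Coumarins and derivatives", "Stilbenes",
    "Carbohydrates and conjugates", "Alcohols and polyols", "Carbonyl compounds",
    "Phenols", "Benzene and substituted derivatives", "Anthracenes",
]
_DESCRIPTOR_NAMES = [
    "MolWt", "LogP", "TPSA", "NumHDonors", "NumHAcceptors",
    "RingCount", "FractionCSP3", "EState_VSA1",
]


def default_ontology() -> Ontology:
    """Three-level fixture: root -> 4 superclasses -> 12 leaf classes."""
    rows = [{"term_id": "C000", "name": "Organic compounds", "parent_id": "", "level": 0}]
    for i, sc in enumerate(_SUPERCLASSES):
        rows.append({"term_id": f"C1{i:02d}", "name": sc, "parent_id": "C000", "level": 1})
    for j, leaf in enumerate(_LEAF_CLASSES):
        parent = f"C1{j // 3:02d}"
        rows.append({"term_id": f"C2{j:02d}", "name": leaf, "parent_id": parent, "level": 2})
    return Ontology(terms=pd.DataFrame(rows))


def _random_topology(rng: np.random.Generator, taxa: list[str]) -> TaxonTree:
    """Coalescent-style topology: uniformly random sequential joins, unit branches."""
    nodes = [skbio.TreeNode(name=t, length=1.0) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = skbio.TreeNode(children=[a, b], length=1.0)
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return TaxonTree(tree=root, is_dendrogram=False)


def _brownian_tip_effects(
    tree: TaxonTree, n_features: int, sigma_b: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Brownian motion along the tree; per-branch variance sigma_b^2 * length."""
    values: dict[int, np.ndarray] = {id(tree.tree): np.zeros(n_features)}
    out: dict[str, np.ndarray] = {}
    for node in tree.tree.preorder(include_self=False):
        length = node.length if node.length is not None else 1.0
        step = rng.normal(0.0, sigma_b * math.sqrt(length), n_features) if sigma_b > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return out


def generate(config: SynthConfig) -> SynthBundle:
    """Generate a reproducible bundle under ``config`` (same seed, same bits)."""
    rng = np.random.default_rng(config.seed)
    n_t, n_r, n_f = config.n_taxa, config.n_replicates, config.n_features

    taxa = [f"taxon_{i + 1:02d}" for i in range(n_t)]
    feature_ids = [f"F{j + 1:04d}" for j in range(n_f)]
    sample_ids = [f"{t}_r{r + 1}" for t in taxa for r in range(n_r)]
    sample_meta = pd.DataFrame(
        {"taxon": [t for t in taxa for _ in range(n_r)],
         "replicate": [r + 1 for _ in taxa for r in range(n_r)]},
        index=sample_ids,
    )

    if config.tree is not None:
        tree = read_newick(config.tree)
        tips = set(tree.tip_names)
        if tips != set(taxa):
            if len(tips) != n_t:
                raise ValueError("supplied tree must have n_taxa tips")
            taxa = sorted(tips)  # honour the supplied labels
            sample_ids = [f"{t}_r{r + 1}" for t in taxa for r in range(n_r)]
            sample_meta = pd.DataFrame(
                {"taxon": [t for t in taxa for _ in range(n_r)],
                 "replicate": [r + 1 for _ in taxa for r in range(n_r)]},
                index=sample_ids,
            )
    else:
        tree = _random_topology(rng, taxa)

    # per-feature shared baseline (core metabolome) and species effects
    u = rng.normal(0.0, 1.0, n_f)
    b = _brownian_tip_effects(tree, n_f, config.brownian_sd, rng)

    # planted markers: disjoint feature sets per taxon
    markers: dict[str, set[str]] = {t: set() for t in taxa}
    marker_effect = np.zeros((n_t, n_f))
    if config.n_markers_per_taxon > 0:
        chosen = rng.choice(n_f, size=n_t * config.n_markers_per_taxon, replace=False)
        for i, t in enumerate(taxa):
            idx = chosen[i * config.n_markers_per_taxon:(i + 1) * config.n_markers_per_taxon]
            markers[t] = {feature_ids[j] for j in idx}
            marker_effect[i, idx] = config.marker_log_effect

    log_int = np.empty((len(sample_ids), n_f))
    for s, sid in enumerate(sample_ids):
        t_idx = taxa.index(sample_meta.loc[sid, "taxon"])
        eps = rng.normal(0.0, config.replicate_sd, n_f) if config.replicate_sd > 0 else 0.0
        log_int[s] = (
            config.baseline_log_mean + u + b[taxa[t_idx]] + marker_effect[t_idx] + eps
        )
    intensity = np.exp(log_int)
    if config.missing_rate > 0:
        missing = rng.random(intensity.shape) < config.missing_rate
        intensity[missing] = 0.0

    neg = rng.random(n_f) < config.frac_negative_mode
    feature_meta = pd.DataFrame(
        {
            "ion_mode": np.where(neg, "neg", "pos"),
            "mz": rng.uniform(100.0, 1200.0, n_f).round(4),
            "rt": rng.uniform(30.0, 1000.0, n_f).round(1),
            "has_ms2": False,
        },
        index=feature_ids,
    )

    n_annot = max(1, int(round(config.frac_annotated * n_f)))
    annotated_idx = np.sort(rng.choice(n_f, size=n_annot, replace=False))
    annotated = [feature_ids[j] for j in annotated_idx]
    feature_meta.loc[annotated, "has_ms2"] = True

    ontology = default_ontology()
    leaves = ontology.leaves()
    leaf_of = {fid: leaves[k] for fid, k in zip(annotated, rng.integers(0, len(leaves), n_annot))}

    annot_rows = []
    for fid in annotated:
        n_cand = int(rng.integers(1, 4))
        scores = np.sort(rng.uniform(0.1, 1.0, n_cand))[::-1]
        for rank in range(1, n_cand + 1):
            annot_rows.append(
                {
                    "feature_id": fid,
                    "rank": rank,
                    "structure_id": f"STRUCT_{fid}_{rank}",
                    "formula": f"C{int(rng.integers(5, 40))}H{int(rng.integers(6, 60))}O{int(rng.integers(1, 12))}",
                    "score": round(float(scores[rank - 1]), 6),
                    "class_id": leaf_of[fid],
                }
            )
    annotations = AnnotationTable(rows=pd.DataFrame(annot_rows))

    # descriptors: class-specific mean vector + unit noise
    names = (_DESCRIPTOR_NAMES + [f"D{k:02d}" for k in range(len(_DESCRIPTOR_NAMES), config.n_descriptors)])[: config.n_descriptors]
    class_means = {leaf: rng.normal(0.0, 2.0, config.n_descriptors) for leaf in leaves}
    desc = np.vstack([class_means[leaf_of[fid]] + rng.normal(0.0, 1.0, config.n_descriptors)
                      for fid in annotated])
    descriptors = pd.DataFrame(desc, index=annotated, columns=names)

    table = FeatureTable(
        abundance=pd.DataFrame(intensity, index=sample_ids, columns=feature_ids),
        feature_meta=feature_meta,
        sample_meta=sample_meta,
        transformed=False,
    )
    return SynthBundle(
        feature_table=table,
        annotations=annotations,
        ontology=ontology,
        descriptors=descriptors,
        true_tree=tree,
        planted_markers=markers,
        config=config,
    )


def designated_classes(ontology: Ontology) -> list[str]:
    """The three leaf classes whose abundance drives the R, G, B channels."""
    return ontology.leaves()[:3]


def class_channel_signal(bundle: SynthBundle) -> pd.DataFrame:
    """Per-sample mean log(1+x) abundance in the three designated classes."""
    classes = designated_classes(bundle.ontology)
    from .io_core import select_best_annotation

    best = select_best_annotation(bundle.annotations)
    class_of = dict(zip(best.rows["feature_id"], best.rows["class_id"]))
    logab = np.log1p(bundle.feature_table.abundance)
    out = {}
    for c in classes:
        members = [f for f, cl in class_of.items() if cl == c]
        out[c] = logab[members].mean(axis=1) if members else pd.Series(0.0, index=logab.index)
    return pd.DataFrame(out)


def make_reference_images(
    bundle: SynthBundle, pixels_per_image: int = 4096, seed: int = 0
) -> dict[str, np.ndarray]:
    """One RGB image per taxon-replicate with class-driven channel means.

    The mean R, G, B values of the non-border pixels are an affine function
    (offset ``IMAGE_CHANNEL_OFFSET``, slope ``IMAGE_CHANNEL_SLOPE``) of the
    sample's mean log abundance in the three designated compound classes;
    doubling a designated class's raw abundance therefore shifts the matching
    channel by about slope x ln 2.  The first pixel row is pure black and the
    last pure white, emulating segmentation borders.  Same seed, same arrays.
    """
    if pixels_per_image < 16:
        raise ValueError("pixels_per_image must be >= 16")
    rng = np.random.default_rng(seed)
    side = max(4, int(round(math.sqrt(pixels_per_image))))
    signal = class_channel_signal(bundle)
    images: dict[str, np.ndarray] = {}
    for sid in bundle.feature_table.sample_ids:
        mean_rgb = IMAGE_CHANNEL_OFFSET + IMAGE_CHANNEL_SLOPE * signal.loc[sid].to_numpy()
        mean_rgb = np.clip(mean_rgb, 20.0, 235.0)
        img = rng.normal(mean_rgb, IMAGE_PIXEL_NOISE_SD, size=(side, side, 3))
        img = np.clip(np.rint(img), 1, 254).astype(np.uint8)
        img[0, :, :] = 0    # pure black border row
        img[-1, :, :] = 255  # pure white border row
        images[sid] = img
    return images
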