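"""End-to-end orchestration: simulate -> process -> project -> diversity ->
select -> tree -> imaging, with per-stage provenance sidecars.

Every stage writes its outputs plus a JSON sidecar carrying the stage name,
its parameters, the seed it used, SHA-256 checksums of its file inputs, and
any warnings, so a single stage can be re-run in isolation.  All randomness
flows from one global seed through named per-stage substreams (a stage's
seed depends only on the global seed and the stage name, so toggling one
stage never changes another's results).  Sidecars carry no timestamps, which
keeps identical runs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as div
from . import imaging as img
from . import plsda
from . import preprocess as prep
from . import project as proj
from . import simulate as sim
from . import trees
from .io_core import (
    AnnotationTable,
    FeatureTable,
    read_annotations,
    read_descriptor_matrix,
    read_feature_table,
    read_newick,
    read_ontology,
    select_best_annotation,
    write_annotations,
    write_feature_table,
    write_newick,
    write_ontology,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "stage_seed", "load_config", "run_all", "DEFAULT_CONFIG"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {},  # SynthConfig overrides; remove and supply "inputs" for real data
    "processing": {"rt_max": 1020.0, "presence_fraction": 1e-8, "mode_join_tolerance": 0.10},
    "selection": {
        "levels": ["feature", "class", "superclass", "descriptor"],
        "quantile": 0.995,
        "folds": 10,
        "max_components": 5,
    },
    "tree": {"n_perm": 999, "aggregate": "mean"},
    "imaging": {"enabled": True, "pixels_per_image": 1024, "n_perm": 199},
}

_INPUT_KEYS = ["feature_table", "annotations", "ontology", "descriptors", "reference_tree"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        import yaml

        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if "inputs" in user and "simulate" not in user:
        cfg.pop("simulate", None)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _sidecar(out_dir: Path, stage: str, params: dict, seed: int,
             inputs: list[Path], warnings: list[str]) -> None:
    payload = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "warnings": warnings,
    }
    with open(out_dir / f"{stage}.sidecar.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def _preflight(cfg: dict) -> None:
    if "simulate" not in cfg and "inputs" not in cfg:
        raise PipelineError("pre-flight: config needs either 'simulate' or 'inputs'")
    if "inputs" in cfg:
        missing = [k for k in _INPUT_KEYS if k not in cfg["inputs"]]
        if missing:
            raise PipelineError(
                f"pre-flight: config field 'inputs.{missing[0]}' is missing"
            )
        for key in _INPUT_KEYS:
            if not Path(cfg["inputs"][key]).exists():
                raise PipelineError(
                    f"pre-flight: inputs.{key} path does not exist: {cfg['inputs'][key]}"
                )


def _split_modes(table: FeatureTable) -> tuple[FeatureTable | None, FeatureTable | None]:
    out = []
    for mode in ("pos", "neg"):
        ids = table.feature_meta.index[table.feature_meta["ion_mode"] == mode]
        out.append(table.select_features(ids) if len(ids) else None)
    return tuple(out)


def _prefix_single(table: FeatureTable, prefix: str) -> FeatureTable:
    ab = table.abundance.copy()
    ab.columns = [f"{prefix}_{c}" for c in ab.columns]
    meta = table.feature_meta.copy()
    meta.index = ab.columns
    return FeatureTable(ab, meta, table.sample_meta.copy(), transformed=table.transformed)


def _prefix_annotations(annotations: AnnotationTable, feature_meta: pd.DataFrame) -> AnnotationTable:
    """Re-key annotation feature ids with their ion-mode prefix."""
    mode = feature_meta["ion_mode"].to_dict()
    rows = annotations.rows.copy()
    rows["feature_id"] = [
        f"{mode[f]}_{f}" if f in mode else f for f in rows["feature_id"]
    ]
    return AnnotationTable(rows=rows)


def run_all(config, out_dir) -> dict:
    """Execute all stages; returns the provenance manifest (also written)."""
    cfg = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 1))
    _preflight(cfg)
    manifest: dict = {"seed": seed, "stages": {}}

    # ---- stage: simulate or load ---------------------------------------
    if "simulate" in cfg:
        s_seed = stage_seed(seed, "simulate")
        synth_cfg = sim.SynthConfig(**{**cfg["simulate"], "seed": s_seed})
        bundle = sim.generate(synth_cfg)
        ft_path = out_dir / "feature_table.csv"
        write_feature_table(bundle.feature_table, ft_path)
        write_annotations(bundle.annotations, out_dir / "annotations.tsv")
        write_ontology(bundle.ontology, out_dir / "ontology.tsv")
        bundle.descriptors.to_csv(out_dir / "descriptors.csv")
        write_newick(bundle.true_tree, out_dir / "true_tree.nwk")
        with open(out_dir / "markers.json", "w") as fh:
            json.dump({t: sorted(v) for t, v in bundle.planted_markers.items()},
                      fh, indent=2, sort_keys=True)
        _sidecar(out_dir, "simulate",
                 {k: getattr(synth_cfg, k) for k in vars(synth_cfg)}, s_seed, [], [])
        table, annotations, ontology = bundle.feature_table, bundle.annotations, bundle.ontology
        descriptors, reference = bundle.descriptors, bundle.true_tree
        manifest["stages"]["simulate"] = {"n_features": synth_cfg.n_features}
    else:
        paths = {k: Path(v) for k, v in cfg["inputs"].items()}
        table = read_feature_table(paths["feature_table"])
        annotations = read_annotations(paths["annotations"])
        ontology = read_ontology(paths["ontology"])
        descriptors = read_descriptor_matrix(paths["descriptors"])
        reference = read_newick(paths["reference_tree"])
        bundle = None
        manifest["stages"]["load"] = {"n_features": table.n_features}

    try:
        # ---- stage: process --------------------------------------------
        p = cfg["processing"]
        pos, neg = _split_modes(table)
        pos = prep.filter_rt(pos, p["rt_max"]) if pos is not None else None
        neg = prep.filter_rt(neg, p["rt_max"]) if neg is not None else None
        join_warnings: list[str] = []
        if pos is not None and neg is not None:
            raw_join = prep.join_modes(pos, neg, p["mode_join_tolerance"])
            log_join = prep.join_modes(
                prep.log_transform(pos), prep.log_transform(neg), p["mode_join_tolerance"]
            )
            if log_join.warning:
                join_warnings.append(
                    f"mode deviations exceed tolerance: median {log_join.median_deviation:.4f}, "
                    f"variance {log_join.variance_deviation:.4f}"
                )
            raw_table, processed = raw_join.table, log_join.table
            deviations = {"median": log_join.median_deviation,
                          "variance": log_join.variance_deviation}
        else:
            single = pos if pos is not None else neg
            prefix = "pos" if pos is not None else "neg"
            raw_table = _prefix_single(single, prefix)
            processed = prep.log_transform(raw_table)
            deviations = {}
        presence = prep.presence_absence(raw_table, p["presence_fraction"])
        write_feature_table(processed, out_dir / "processed.csv")
        presence.present.to_csv(out_dir / "presence.csv")
        with open(out_dir / "process.json", "w") as fh:
            json.dump({"presence_threshold": presence.threshold,
                       "deviations": deviations, "warnings": join_warnings},
                      fh, indent=2, sort_keys=True)
        _sidecar(out_dir, "process", p, stage_seed(seed, "process"),
                 [], join_warnings)
        manifest["stages"]["process"] = {"n_features": processed.n_features,
                                         "warnings": join_warnings}

        # ---- stage: project --------------------------------------------
        best = select_best_annotation(annotations)
        best_prefixed = _prefix_annotations(best, table.feature_meta)
        annotated = prep.filter_to_annotated(processed, best_prefixed)
        cls_tab = proj.class_table(annotated, best_prefixed, ontology, level="most_specific")
        sup_tab = proj.class_table(annotated, best_prefixed, ontology, level="superclass")
        desc_prefixed = descriptors.copy()
        mode = table.feature_meta["ion_mode"].to_dict()
        desc_prefixed.index = [f"{mode[f]}_{f}" if f in mode else f for f in desc_prefixed.index]
        desc_tab = proj.descriptor_table(
            annotated.select_features([f for f in annotated.feature_ids
                                       if f in desc_prefixed.index]),
            desc_prefixed,
        )
        cls_tab.abundance.to_csv(out_dir / "class_table.csv")
        sup_tab.abundance.to_csv(out_dir / "superclass_table.csv")
        desc_tab.to_csv(out_dir / "descriptor_table.csv")
        sunburst_frames = []
        for taxon in processed.taxa:
            samples = list(processed.sample_meta.index[processed.sample_meta["taxon"] == taxon])
            counts = proj.sunburst_counts(best_prefixed, ontology, presence.present, samples)
            counts.insert(0, "group", taxon)
            sunburst_frames.append(counts)
        pd.concat(sunburst_frames).to_csv(out_dir / "sunburst.tsv", sep="\t", index=False)
        _sidecar(out_dir, "project", {"levels": ["most_specific", "superclass", "descriptor"]},
                 stage_seed(seed, "project"), [], [])
        manifest["stages"]["project"] = {
            "n_annotated": annotated.n_features,
            "n_classes": cls_tab.abundance.shape[1],
            "n_superclasses": sup_tab.abundance.shape[1],
        }

        # ---- stage: diversity ------------------------------------------
        per_sample, per_taxon = div.diversity_table(
            processed, presence=presence.present.reindex(columns=processed.feature_ids)
        )
        per_sample.to_csv(out_dir / "diversity_samples.tsv", sep="\t")
        per_taxon.to_csv(out_dir / "diversity_taxa.tsv", sep="\t")
        anova = div.anova_tukey(per_sample["shannon_H"], per_sample["taxon"])
        anova.tukey.to_csv(out_dir / "anova_tukey.tsv", sep="\t", index=False)
        with open(out_dir / "diversity.json", "w") as fh:
            json.dump({"anova_F": anova.F, "anova_p": anova.p}, fh, indent=2, sort_keys=True)
        _sidecar(out_dir, "diversity", {}, stage_seed(seed, "diversity"), [], [])
        manifest["stages"]["diversity"] = {"anova_F": anova.F, "anova_p": anova.p}

        # ---- stage: select ---------------------------------------------
        level_tables = {
            "feature": processed.abundance,
            "class": cls_tab.abundance,
            "superclass": sup_tab.abundance,
            "descriptor": desc_tab,
        }
        sel_cfg = cfg["selection"]
        y = processed.sample_meta["taxon"].to_numpy()
        metrics: dict = {}
        for level in sel_cfg["levels"]:
            X = level_tables[level]
            if X.shape[1] < 2:
                logger.warning("level %s has < 2 variables; skipped", level)
                continue
            lseed = stage_seed(seed, f"select:{level}")
            model = plsda.fit_plsda(X, y, max_components=sel_cfg["max_components"], seed=lseed)
            importance = plsda.variable_importance(model)
            selection = plsda.select_markers(importance, sel_cfg["quantile"])
            ev = plsda.evaluate(model, X, y, k_folds=sel_cfg["folds"], seed=lseed)
            rows = []
            for cls_name, variables in selection.per_class.items():
                for v in variables:
                    rows.append({"variable": v, "class": cls_name,
                                 "importance": float(importance.loc[v, cls_name])})
            pd.DataFrame(rows, columns=["variable", "class", "importance"]).to_csv(
                out_dir / f"markers_{level}.tsv", sep="\t", index=False
            )
            if selection.selected:
                hm = plsda.heatmap_matrix(X, sorted(selection.selected), y, importance)
                hm.to_csv(out_dir / f"heatmap_{level}.csv")
            metrics[level] = {
                "n_components": model.n_components,
                "accuracy": ev.accuracy,
                "r2": ev.r2,
                "macro_auc": ev.macro_auc,
                "macro_auc_pr": ev.macro_auc_pr,
                "k_folds": ev.k_folds,
                "n_selected": len(selection.selected),
            }
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
        _sidecar(out_dir, "select", sel_cfg, stage_seed(seed, "select"), [], [])
        manifest["stages"]["select"] = metrics

        # ---- stage: tree ------------------------------------------------
        t_cfg = cfg["tree"]
        taxa_series = processed.sample_meta["taxon"]
        congruence: dict = {}
        for level, X in level_tables.items():
            if X.shape[1] < 2:
                continue
            D = trees.taxon_distance_frame(X, taxa_series, aggregate=t_cfg["aggregate"])
            chemo, report = trees.compare_distance_to_reference(
                D, reference, n_perm=t_cfg["n_perm"],
                seed=stage_seed(seed, f"tree:{level}"),
            )
            write_newick(chemo, out_dir / f"chemo_tree_{level}.nwk")
            congruence[level] = {"M": report.M, "mantel_p": report.mantel_p, "c": report.c}
        with open(out_dir / "congruence.json", "w") as fh:
            json.dump(congruence, fh, indent=2, sort_keys=True)
        _sidecar(out_dir, "tree", t_cfg, stage_seed(seed, "tree"), [], [])
        manifest["stages"]["tree"] = congruence

        # ---- stage: imaging ---------------------------------------------
        i_cfg = cfg.get("imaging", {})
        if i_cfg.get("enabled", False) and bundle is not None:
            iseed = stage_seed(seed, "imaging")
            images = sim.make_reference_images(
                bundle, pixels_per_image=i_cfg.get("pixels_per_image", 1024), seed=iseed
            )
            traits = img.traits_matrix(
                [img.extract_rgb_histograms(arr, label=sid) for sid, arr in images.items()]
            )
            constraints = sim.class_channel_signal(bundle)
            selected, trace = img.forward_select(
                traits, constraints, n_perm=i_cfg.get("n_perm", 199), seed=iseed
            )
            result = img.dbrda(traits, constraints)
            envfit = {}
            if result.site_scores.shape[1] >= 2:
                for name in constraints.columns:
                    r2, pval = img.envfit_r2(
                        result.site_scores, constraints[name],
                        n_perm=i_cfg.get("n_perm", 199), seed=iseed,
                    )
                    envfit[str(name)] = {"r2": r2, "p": pval}
            result.site_scores.to_csv(out_dir / "dbrda_site_scores.csv")
            with open(out_dir / "dbrda.json", "w") as fh:
                json.dump(
                    {
                        "constrained_fraction": result.constrained_fraction,
                        "selected_constraints": [str(s) for s in selected],
                        "envfit": envfit,
                    },
                    fh, indent=2, sort_keys=True,
                )
            _sidecar(out_dir, "imaging", i_cfg, iseed, [], [])
            manifest["stages"]["imaging"] = {
                "constrained_fraction": result.constrained_fraction,
                "selected_constraints": [str(s) for s in selected],
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage failed: {exc}") from exc

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
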