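import numpy as np
import pandas as pd
import pytest

from chemophen.io_core import AnnotationTable, FeatureTable, Ontology


def make_feature_table(
    values,
    sample_ids=None,
    feature_ids=None,
    taxa=None,
    rt=None,
    ion_mode="pos",
    has_ms2=True,
    transformed=False,
):
    """Small FeatureTable builder for fixtures."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j + 1}" for j in range(p)]
    taxa = taxa or ["A"] * n
    rt = rt if rt is not None else [100.0] * p
    modes = [ion_mode] * p if isinstance(ion_mode, str) else list(ion_mode)
    ms2 = [has_ms2] * p if isinstance(has_ms2, bool) else list(has_ms2)
    reps = []
    seen = {}
    for t in taxa:
        seen[t] = seen.get(t, 0) + 1
        reps.append(seen[t])
    return FeatureTable(
        abundance=pd.DataFrame(values, index=sample_ids, columns=feature_ids),
        feature_meta=pd.DataFrame(
            {"ion_mode": modes, "mz": [100.0 + j for j in range(p)], "rt": rt, "has_ms2": ms2},
            index=feature_ids,
        ),
        sample_meta=pd.DataFrame({"taxon": taxa, "replicate": reps}, index=sample_ids),
        transformed=transformed,
    )


def make_ontology(rows):
    """rows: list of (term_id, name, parent_id, level)."""
    return Ontology(
        terms=pd.DataFrame(rows, columns=["term_id", "name", "parent_id", "level"])
    )


def make_annotations(rows):
    """rows: list of (feature_id, rank, structure_id, formula, score, class_id)."""
    return AnnotationTable(
        rows=pd.DataFrame(
            rows,
            columns=["feature_id", "rank", "structure_id", "formula", "score", "class_id"],
        )
    )


@pytest.fixture
def flavonoid_ontology():
    """root -> {Flavonoids -> Flavonoid-7-O-glycosides, Lipids -> Fatty acyls}."""
    return make_ontology(
        [
            ("root", "Organic compounds", "", 0),
            ("flav", "Flavonoids", "root", 1),
            ("lip", "Lipids", "root", 1),
            ("f7og", "Flavonoid-7-O-glycosides", "flav", 2),
            ("fa", "Fatty acyls", "lip", 2),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
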