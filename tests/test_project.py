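import numpy as np
import pandas as pd
import pytest

from chemophen import project as proj
from conftest import make_annotations, make_feature_table, make_ontology


@pytest.fixture
def two_feature_setup(flavonoid_ontology):
    table = make_feature_table([[2.0, 3.0]], feature_ids=["f1", "f2"], transformed=True)
    annots = make_annotations(
        [("f1", 1, "s1", "C6", 0.9, "f7og"), ("f2", 1, "s2", "C6", 0.8, "fa")]
    )
    return table, annots, flavonoid_ontology


class TestClassTable:
    def test_most_specific_level(self, two_feature_setup):
        table, annots, onto = two_feature_setup
        out = proj.class_table(table, annots, onto, level="most_specific")
        assert out.abundance.loc["s1", "f7og"] == 2.0
        assert out.abundance.loc["s1", "fa"] == 3.0
        assert set(out.abundance.columns) == {"f7og", "fa"}

    def test_all_levels_root_accumulates_everything(self, two_feature_setup):
        table, annots, onto = two_feature_setup
        out = proj.class_table(table, annots, onto, level="all")
        assert out.abundance.loc["s1", "root"] == 5.0
        assert out.abundance.loc["s1", "flav"] == 2.0
        assert out.abundance.loc["s1", "lip"] == 3.0

    def test_superclass_level(self, two_feature_setup):
        table, annots, onto = two_feature_setup
        out = proj.class_table(table, annots, onto, level="superclass")
        assert out.abundance.loc["s1", "flav"] == 2.0
        assert "f7og" not in out.abundance.columns

    def test_unannotated_features_contribute_nothing(self, flavonoid_ontology):
        table = make_feature_table([[9.0, 1.0]], transformed=True)
        annots = make_annotations([("f2", 1, "s", "C6", 0.5, "fa")])
        out = proj.class_table(table, annots, flavonoid_ontology, level="all")
        assert out.abundance.loc["s1", "root"] == 1.0

    def test_zero_abundance_gives_zero_class_value(self, two_feature_setup):
        table, annots, onto = two_feature_setup
        table.abundance.loc["s1", "f1"] = 0.0
        out = proj.class_table(table, annots, onto, level="most_specific")
        assert out.abundance.loc["s1", "f7og"] == 0.0

    def test_unknown_class_named_in_error(self, flavonoid_ontology):
        table = make_feature_table([[1.0]])
        annots = make_annotations([("f1", 1, "s", "C6", 0.5, "nope")])
        with pytest.raises(KeyError, match="nope"):
            proj.class_table(table, annots, flavonoid_ontology)

    def test_unreduced_annotations_rejected(self, flavonoid_ontology):
        table = make_feature_table([[1.0]])
        annots = make_annotations(
            [("f1", 1, "a", "C6", 0.5, "fa"), ("f1", 2, "b", "C6", 0.4, "fa")]
        )
        with pytest.raises(ValueError, match="reduced"):
            proj.class_table(table, annots, flavonoid_ontology)

    def test_level_hierarchy_conservation(self, rng):
        # random fixture: parent count equals the sum over children plus
        # features annotated at the parent itself
        onto = make_ontology(
            [("root", "Organic compounds", "", 0),
             ("p1", "P1", "root", 1), ("p2", "P2", "root", 1),
             ("c11", "C11", "p1", 2), ("c12", "C12", "p1", 2), ("c21", "C21", "p2", 2)]
        )
        terms = ["p1", "c11", "c12", "p2", "c21"]
        n_feat = 12
        vals = rng.uniform(0, 10, size=(3, n_feat))
        table = make_feature_table(vals, transformed=True)
        rows = [(f"f{j + 1}", 1, f"s{j}", "C6", 0.5, terms[rng.integers(0, len(terms))])
                for j in range(n_feat)]
        annots = make_annotations(rows)
        out = proj.class_table(table, annots, onto, level="all").abundance
        class_of = dict((r[0], r[5]) for r in rows)
        for parent, children in (("p1", ["c11", "c12"]), ("p2", ["c21"])):
            child_sum = sum(
                out[c] for c in children if c in out.columns
            )
            own = sum(
                table.abundance[f] for f, cl in class_of.items() if cl == parent
            )
            expected = (child_sum if not np.isscalar(child_sum) else 0.0) + own
            if parent in out.columns:
                assert np.allclose(out[parent], expected, atol=1e-10)


class TestDescriptorTable:
    def test_identity_descriptors_reproduce_abundances(self):
        table = make_feature_table([[1.0, 2.0], [3.0, 4.0]])
        X = pd.DataFrame(np.eye(2), index=["f1", "f2"], columns=["d1", "d2"])
        out = proj.descriptor_table(table, X)
        assert np.allclose(out.to_numpy(), table.abundance.to_numpy())

    def test_hand_product(self):
        table = make_feature_table([[1.0, 2.0]])
        X = pd.DataFrame([[1.0, 0.0], [0.0, 3.0]], index=["f1", "f2"], columns=["d1", "d2"])
        out = proj.descriptor_table(table, X)
        assert out.iloc[0].tolist() == [1.0, 6.0]

    def test_zero_descriptor_column_gives_zero_output_column(self, rng):
        table = make_feature_table(rng.uniform(0, 5, (3, 4)))
        X = pd.DataFrame(rng.normal(size=(4, 3)), index=table.feature_ids,
                         columns=["d1", "d2", "d3"])
        X["d2"] = 0.0
        out = proj.descriptor_table(table, X)
        assert np.allclose(out["d2"], 0.0)

    def test_triple_loop_oracle(self, rng):
        A = rng.uniform(0, 10, size=(5, 8))
        X = rng.normal(size=(8, 4))
        table = make_feature_table(A)
        desc = pd.DataFrame(X, index=table.feature_ids, columns=[f"d{k}" for k in range(4)])
        out = proj.descriptor_table(table, desc).to_numpy()
        expected = np.zeros((5, 4))
        for s in range(5):
            for d in range(4):
                for f in range(8):
                    expected[s, d] += A[s, f] * X[f, d]
        assert np.allclose(out, expected, atol=1e-10)

    def test_missing_descriptor_row_rejected(self):
        table = make_feature_table([[1.0, 2.0]])
        X = pd.DataFrame([[1.0]], index=["f1"], columns=["d1"])
        with pytest.raises(KeyError, match="f2"):
            proj.descriptor_table(table, X)


class TestSunburstCounts:
    @pytest.fixture
    def detected_setup(self, flavonoid_ontology):
        annots = make_annotations(
            [("f1", 1, "a", "C6", 0.9, "f7og"),
             ("f2", 1, "b", "C6", 0.9, "fa"),
             ("f3", 1, "c", "C6", 0.9, "flav")]
        )
        presence = pd.DataFrame(
            [[True, True, True], [False, False, False]],
            index=["s1", "s2"], columns=["f1", "f2", "f3"],
        )
        return annots, flavonoid_ontology, presence

    def test_root_counts_all_detected_annotated_features(self, detected_setup):
        annots, onto, presence = detected_setup
        out = proj.sunburst_counts(annots, onto, presence, ["s1"])
        assert out.set_index("term_id").loc["root", "count"] == 3

    def test_sibling_and_parent_counting(self, detected_setup):
        annots, onto, presence = detected_setup
        out = proj.sunburst_counts(annots, onto, presence, ["s1"]).set_index("term_id")
        assert out.loc["f7og", "count"] == 1
        assert out.loc["fa", "count"] == 1
        assert out.loc["flav", "count"] == 2  # f1 path + f3 annotated at flav itself

    def test_absent_feature_counts_nowhere(self, detected_setup):
        annots, onto, presence = detected_setup
        out = proj.sunburst_counts(annots, onto, presence, ["s2"])
        assert out.empty or (out["count"] == 0).all()

    def test_empty_group_rejected(self, detected_setup):
        annots, onto, presence = detected_setup
        with pytest.raises(ValueError):
            proj.sunburst_counts(annots, onto, presence, [])
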