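"""Log-odds tables, physicochemical deltas and the 25-feature vector."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinvar import (
    FEATURE_ORDER,
    Dataset,
    LogOddsTable,
    ValidationError,
    VariantFeaturizer,
    VariantRecord,
    biochemical_deltas,
    build_lor_table,
    featurize,
    generate,
    log_odds,
    sum_lor,
)
from kinvar.synthetic import preset


class TestLogOdds:
    def test_enriched_group_example(self):
        assert log_odds(4, 2, 10, 20) == pytest.approx(2.0, abs=1e-12)

    def test_equal_frequencies_are_zero(self):
        assert log_odds(5, 10, 50, 100) == pytest.approx(0.0, abs=1e-12)

    def test_zero_neutral_count_stays_finite(self):
        # exact-arithmetic oracle: log2(((1 + 1e-20)/100) / (1e-20/200)) = log2(2e20)
        value = log_odds(1, 0, 100, 200, xi=1e-20)
        assert math.isfinite(value)
        assert value == pytest.approx(67.43856189774725, abs=1e-9)

    def test_zero_class_total_is_domain_error(self):
        with pytest.raises(ValidationError):
            log_odds(0, 0, 0, 10)
        with pytest.raises(ValidationError):
            log_odds(1, 1, 10, 10, xi=0.0)

    @given(
        d=st.integers(1, 500),
        n=st.integers(1, 500),
        extra_d=st.integers(0, 500),
        extra_n=st.integers(0, 500),
    )
    @settings(derandomize=True, max_examples=200)
    def test_antisymmetry_under_class_swap(self, d, n, extra_d, extra_n):
        """lor(d,n,D,N) = -lor(n,d,N,D) when both counts are positive."""
        D, N = d + extra_d, n + extra_n
        assert log_odds(d, n, D, N) == pytest.approx(-log_odds(n, d, N, D), abs=1e-9)


class TestBuildLorTable:
    def test_group_toy_reduces_to_log_odds(self, group_toy):
        data, bundle = group_toy
        table = build_lor_table("group", data, bundle)
        assert table.lor["TK"] == pytest.approx(2.0, abs=1e-9)
        assert table.disease_total == 10
        assert table.neutral_total == 20

    def test_category_without_variants_absent(self, group_toy):
        data, bundle = group_toy
        bundle.kinase_group["PEMPTY"] = "NEVER_SEEN"  # protein with no variants
        table = build_lor_table("group", data, bundle)
        assert "NEVER_SEEN" not in table.lor

    def test_go_counts_propagate_to_ancestors(self, diamond_ontology):
        """A protein annotated only with a child term increments all parents."""
        bundle_vars = [
            VariantRecord("P1", i, "A", "V", "disease") for i in range(1, 4)
        ] + [VariantRecord("P2", i, "A", "V", "neutral") for i in range(1, 5)]
        from kinvar import AnnotationBundle

        bundle = AnnotationBundle()
        bundle.go_direct["P1"] = {"D"}  # leaf of the diamond
        bundle.go_direct["P2"] = {"B"}
        table = build_lor_table("go", Dataset(bundle_vars), bundle, diamond_ontology)
        # P1's 3 disease variants count toward D, B, C and A; P2's 4 neutral
        # variants toward B and A only.
        assert table.disease_counts == {"A": 3, "B": 3, "C": 3, "D": 3}
        assert table.neutral_counts == {"A": 4, "B": 4}
        assert table.lor["A"] == pytest.approx(math.log2((3 / 3) / (4 / 4)), abs=1e-9)

    def test_domain_membership_is_positional(self):
        from kinvar import AnnotationBundle

        bundle = AnnotationBundle()
        bundle.domains["P1"] = [("D1", 10, 20)]
        inside = VariantRecord("P1", 15, "A", "V", "disease")
        outside = VariantRecord("P1", 25, "A", "V", "neutral")
        table = build_lor_table("pfam", Dataset([inside, outside]), bundle)
        assert table.disease_counts == {"D1": 1}
        assert table.neutral_counts == {}

    def test_unclassified_labels_are_precondition_error(self, group_toy):
        data, bundle = group_toy
        bad = Dataset(data.variants + [VariantRecord("PX", 1, "A", "V", "unclassified")])
        with pytest.raises(ValidationError, match="classified"):
            build_lor_table("group", bad, bundle)

    def test_label_swap_negates_every_two_sided_lor(self, small_strong):
        """Swapping every label negates stored lors for xi-negligible categories."""
        data, bundle, graph, _ = small_strong
        table = build_lor_table("group", data, bundle)
        flipped = Dataset(
            [
                VariantRecord(
                    v.protein_id, v.position, v.wt_aa, v.mut_aa,
                    "neutral" if v.label == "disease" else "disease",
                )
                for v in data
            ]
        )
        swapped = build_lor_table("group", flipped, bundle)
        for cat, value in table.lor.items():
            if table.disease_counts.get(cat, 0) > 0 and table.neutral_counts.get(cat, 0) > 0:
                assert swapped.lor[cat] == pytest.approx(-value, abs=1e-9)


class TestSumLor:
    TABLE = LogOddsTable(
        kind="go",
        lor={"a": 2.0, "b": -1.0, "c": 0.5},
        disease_counts={}, neutral_counts={},
        disease_total=1, neutral_total=1,
    )

    def test_plain_summation(self):
        assert sum_lor(self.TABLE, {"a", "b", "c"}) == pytest.approx(1.5)

    def test_empty_set_sums_to_zero(self):
        assert sum_lor(self.TABLE, set()) == 0.0

    def test_unseen_category_contributes_zero(self):
        assert sum_lor(self.TABLE, {"a", "unseen"}) == pytest.approx(2.0)


class TestBiochemicalDeltas:
    def test_identity_substitution_is_all_zero(self):
        assert biochemical_deltas("A", "A") == (0.0, 0.0, 0, 0)

    @pytest.mark.parametrize(
        "wt, mut, idx, expected",
        [
            ("I", "R", 1, -9.0),   # hydrophobicity: Kyte-Doolittle I=4.5, R=-4.5
            ("D", "K", 3, 2),      # charge: -1 -> +1
            ("V", "A", 2, -1),     # C-beta branching: V branches, A does not
            ("G", "W", 0, 167.7),  # volume: 60.1 -> 227.8
        ],
    )
    def test_published_scale_deltas(self, wt, mut, idx, expected):
        assert biochemical_deltas(wt, mut)[idx] == pytest.approx(expected)

    def test_mutant_minus_wildtype_antisymmetry(self):
        fwd = biochemical_deltas("D", "K")
        rev = biochemical_deltas("K", "D")
        assert all(a == pytest.approx(-b) for a, b in zip(fwd, rev))

    def test_non_canonical_residue_rejected(self):
        with pytest.raises(ValidationError):
            biochemical_deltas("A", "X")


class TestFeaturize:
    def _tables(self):
        def t(kind, lor):
            return LogOddsTable(kind=kind, lor=lor, disease_counts={}, neutral_counts={},
                                disease_total=1, neutral_total=1)
        return {
            "group": t("group", {"TK": 2.0}),
            "go": t("go", {"D": 1.0, "B": 0.5}),
            "pfam": t("pfam", {"Pkinase": -1.0}),
        }

    def test_lor_feature_composition(self, toy_bundle, diamond_ontology):
        """Toy composition: group 2.0; GO leaf 1.0 + seen ancestor 0.5; domain -1.0."""
        v = VariantRecord("P1", 100, "A", "V", "disease")
        row = featurize(v, toy_bundle, diamond_ontology, self._tables())
        assert row["kinase_group_lor"] == pytest.approx(2.0)
        assert row["sum_go_lor"] == pytest.approx(1.5)  # D(1.0) + B(0.5); A, C unseen
        assert row["sum_pfam_lor"] == pytest.approx(-1.0)
        assert row["sift_score"] == pytest.approx(0.02)

    def test_site_flags_and_any_uniprot(self, toy_bundle, diamond_ontology):
        v = VariantRecord("P1", 100, "A", "V", "disease")
        row = featurize(v, toy_bundle, diamond_ontology, self._tables())
        assert row["act_site"] == 1
        assert row["any_uniprot"] == 1
        others = [c for c in FEATURE_ORDER[13:] if c != "act_site"]
        assert all(row[c] == 0 for c in others)

    def test_position_outside_all_domains_sums_zero(self, toy_bundle, diamond_ontology):
        v = VariantRecord("P1", 300, "A", "V", "neutral")
        row = featurize(v, toy_bundle, diamond_ontology, self._tables())
        assert row["sum_pfam_lor"] == 0.0

    def test_unannotated_protein_still_featurized(self, toy_bundle, diamond_ontology):
        v = VariantRecord("GHOST", 5, "K", "E", "neutral")
        row = featurize(v, toy_bundle, diamond_ontology, self._tables())
        assert row["kinase_group_lor"] == 0.0
        assert row["sum_go_lor"] == 0.0
        assert math.isnan(row["sift_score"])


class TestVariantFeaturizer:
    def test_feature_order_and_determinism(self, small_strong):
        data, bundle, graph, _ = small_strong
        f1 = VariantFeaturizer(bundle, graph).fit(data).transform(data)
        f2 = VariantFeaturizer(bundle, graph).fit(data).transform(data)
        assert list(f1.columns) == list(FEATURE_ORDER)
        pd.testing.assert_frame_equal(f1, f2)  # bit-identical

    def test_any_uniprot_is_or_of_site_flags_corpus_wide(self, small_strong):
        data, bundle, graph, _ = small_strong
        frame = VariantFeaturizer(bundle, graph).fit(data).transform(data)
        flags = frame[list(FEATURE_ORDER[13:])]
        assert (frame["any_uniprot"] == flags.any(axis=1).astype(int)).all()

    def test_unfitted_transform_raises(self, small_strong):
        data, bundle, graph, _ = small_strong
        with pytest.raises(ValidationError, match="not fitted"):
            VariantFeaturizer(bundle, graph).transform(data)

    def test_sklearn_get_set_params(self):
        f = VariantFeaturizer(xi=1e-6)
        assert f.get_params()["xi"] == 1e-6
        f.set_params(xi=1e-3)
        assert f.xi == 1e-3
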