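import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ripcall import benchmarks
from ripcall.enrichment import EnrichedList
from ripcall.errors import ParameterError

from conftest import make_annotation, make_records


def make_list(lfc_by_gene, label="test", **kw):
    rec = make_records(lfc_by_gene, **kw)
    return EnrichedList(label, set(rec["gene_id_norm"]), -10.0, 0.05, rec)


class TestContamination:
    def test_ratio_of_off_target_to_called(self):
        lst = make_list({g: 1 for g in "abcd"})
        assert benchmarks.contamination_frequency(lst, {"c", "x"}) == 0.25
        assert benchmarks.contamination_frequency(lst, {"x", "y"}) == 0.0
        assert benchmarks.contamination_frequency(lst, set("abcdef")) == 1.0

    def test_empty_list_reports_missing(self, caplog):
        empty = EnrichedList("x", set(), 0, 0.05, make_records({}))
        with caplog.at_level("WARNING"):
            assert benchmarks.contamination_frequency(empty, {"a"}) is None

    @given(st.sets(st.integers(0, 30), min_size=1), st.sets(st.integers(0, 30)))
    @settings(deadline=None, max_examples=50)
    def test_complement_sums_to_one(self, called, off):
        lst = make_list({f"g{i}": 1 for i in called})
        freq = benchmarks.contamination_frequency(lst, {f"g{i}" for i in off})
        clean = len(lst.genes - {f"g{i}" for i in off}) / len(lst.genes)
        assert freq + clean == pytest.approx(1.0)


class TestSecretorySpecificity:
    def test_any_of_four_flags_counts(self):
        genes = ["m1", "m2", "m3", "m4"]
        lst = make_list({g: 1 for g in genes})
        annot = make_annotation(
            genes,
            secretory_phobius={"m1": True, "m4": True},
            secretory_tmhmm={"m2": True, "m4": True},
            secretory_signalp={"m4": True},
            secretory_gocc={"m4": True},
        )
        assert benchmarks.secretory_specificity(lst, annot) == 0.75

    def test_all_flags_false_gives_zero(self):
        lst = make_list({"m1": 1, "m2": 1})
        assert benchmarks.secretory_specificity(lst, make_annotation(["m1", "m2"])) == 0.0

    def test_noncoding_only_list_is_undefined(self):
        lst = make_list({"l1": 1}, biotype="lincRNA")
        assert benchmarks.secretory_specificity(lst, make_annotation(["l1"])) is None

    def test_unmatched_genes_count_only_in_inclusive_denominator(self):
        lst = make_list({"m1": 1, "m2": 1})
        annot = make_annotation(["m1"], secretory_phobius={"m1": True})
        assert benchmarks.secretory_specificity(lst, annot) == 0.5
        assert benchmarks.secretory_specificity(lst, annot, matched_only=True) == 1.0


class TestRecall:
    def test_fraction_of_reference_recovered(self):
        lst = make_list({g: 1 for g in ["a", "b", "c"]})
        assert benchmarks.recall(lst, {"a", "b", "c", "d"}) == 0.75
        assert benchmarks.recall(lst, {"a", "b"}) == 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ParameterError):
            benchmarks.recall(make_list({"a": 1}), set())

    @given(st.sets(st.integers(0, 20), min_size=1), st.sets(st.integers(0, 20), min_size=1))
    @settings(deadline=None, max_examples=50)
    def test_monotone_under_list_growth(self, called, extra):
        ref = {f"g{i}" for i in range(10)}
        small = make_list({f"g{i}": 1 for i in called})
        big = make_list({f"g{i}": 1 for i in called | extra})
        assert benchmarks.recall(big, ref) >= benchmarks.recall(small, ref)


class TestSensitivityFloor:
    def test_constant_abundance_at_any_quantile(self):
        lst = make_list({f"g{i}": 1 for i in range(5)}, mean_pre=2.0)
        for q in (0.05, 0.5, 0.95):
            assert benchmarks.sensitivity_floor(lst, q) == 2.0

    def test_linear_interpolation_matches_sorted_oracle(self):
        lst = make_list(
            {f"g{i}": 1 for i in range(1, 101)},
            mean_pre={f"g{i}": float(i) for i in range(1, 101)},
        )
        # order statistics 1..100: 5th percentile = 1 + 0.05*99
        assert benchmarks.sensitivity_floor(lst, 0.05) == pytest.approx(5.95)

    def test_adding_high_abundance_gene_barely_moves_floor(self):
        base = {f"g{i}": float(i) for i in range(1, 21)}
        lst = make_list({g: 1 for g in base}, mean_pre=base)
        grown = dict(base, g_huge=1e6)
        lst2 = make_list({g: 1 for g in grown}, mean_pre=grown)
        f1 = benchmarks.sensitivity_floor(lst, 0.05)
        f2 = benchmarks.sensitivity_floor(lst2, 0.05)
        sorted_vals = sorted(base.values())
        step = sorted_vals[1] - sorted_vals[0]
        assert f1 <= f2 <= f1 + step

    def test_bad_quantile_rejected(self):
        with pytest.raises(ParameterError):
            benchmarks.sensitivity_floor(make_list({"a": 1}), 1.0)


class TestComposition:
    def test_biotype_counts_and_conservation(self):
        rec = make_records({"m1": 1, "m2": 1, "m3": 1})
        rec.loc[2, "biotype"] = "lincRNA"
        lst = EnrichedList("x", set(rec["gene_id_norm"]), 0, 0.05, rec)
        counts = benchmarks.biotype_composition(lst)
        assert counts == {"protein_coding": 2, "lincRNA": 1}
        assert sum(counts.values()) == len(lst.genes)
        empty = EnrichedList("x", set(), 0, 0.05, make_records({}))
        assert benchmarks.biotype_composition(empty) == {}

    def test_submito_fractions_sum_to_one(self):
        genes = [f"g{i}" for i in range(6)]
        lst = make_list({g: 1 for g in genes})
        annot = make_annotation(
            genes,
            is_mito=True,
            submito_location={
                "g0": "OMM", "g1": "OMM", "g2": "IMM", "g3": "matrix",
                "g4": "unknown", "g5": "IMS",
            },
        )
        fractions, n = benchmarks.submito_composition(lst, annot)
        assert n == 5  # the unknown gene is excluded from the denominator
        assert sum(fractions.values()) == pytest.approx(1.0)
        assert fractions["OMM"] == pytest.approx(2 / 5)

    def test_single_annotated_gene_gets_full_fraction(self):
        lst = make_list({"g0": 1})
        annot = make_annotation(["g0"], is_mito=True, submito_location={"g0": "IMM"})
        fractions, n = benchmarks.submito_composition(lst, annot)
        assert n == 1 and fractions["IMM"] == 1.0

    def test_no_annotation_reports_missing(self):
        lst = make_list({"g0": 1})
        fractions, n = benchmarks.submito_composition(lst, make_annotation(["g0"]))
        assert fractions == {} and n == 0


class TestTransmembraneEnrichment:
    def test_list_vs_background_fractions(self):
        genes = ["a", "b", "c", "w", "x", "y", "z"]
        annot = make_annotation(
            genes,
            is_mito=True,
            secretory_tmhmm={"a": True, "b": True, "w": True},
        )
        lst = make_list({"a": 1, "b": 1, "c": 1})
        frac_list, frac_bg = benchmarks.transmembrane_enrichment(
            lst, annot, {"w", "x", "y", "z"}
        )
        assert frac_list == pytest.approx(2 / 3)
        assert frac_bg == pytest.approx(0.25)

    def test_identical_list_and_background_match(self):
        genes = ["a", "b"]
        annot = make_annotation(genes, is_mito=True, secretory_tmhmm={"a": True})
        lst = make_list({"a": 1, "b": 1})
        frac_list, frac_bg = benchmarks.transmembrane_enrichment(lst, annot, set(genes))
        assert frac_list == frac_bg

    def test_no_mito_genes_reports_missing(self):
        annot = make_annotation(["a"], is_mito=False)
        lst = make_list({"a": 1})
        frac_list, _ = benchmarks.transmembrane_enrichment(lst, annot, {"a"})
        assert frac_list is None


def test_full_report_assembles_all_metrics():
    genes = ["m1", "m2", "l1"]
    rec = make_records({"m1": 2, "m2": 1, "l1": 3}, mean_pre={"m1": 1.0, "m2": 4.0, "l1": 9.0})
    rec.loc[2, "biotype"] = "lincRNA"
    lst = EnrichedList("er", set(rec["gene_id_norm"]), 0.5, 0.05, rec)
    annot = make_annotation(genes, secretory_phobius={"m1": True})
    report = benchmarks.benchmark(
        lst, annot, off_target={"l1"}, reference={"m1", "m2", "zzz"}
    )
    assert report.n_enriched == 3
    assert report.contamination_frequency == pytest.approx(1 / 3)
    assert report.secretory_specificity == pytest.approx(0.5)
    assert report.recall == pytest.approx(2 / 3)
    assert report.sensitivity_floor_fpkm == pytest.approx(
        np.quantile([1.0, 4.0, 9.0], 0.05)
    )
    assert sum(report.biotype_counts.values()) == report.n_enriched
    frame = report.to_frame()
    assert {"metric", "value", "denominator"} <= set(frame.columns)
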