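import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ripcall import enrichment
from ripcall.errors import ParameterError, ValidationError
from ripcall.io_tables import ReferenceSets

from conftest import make_expression, make_records
from oracles import youden_scan


class TestFoldChanges:
    def test_mean_ratio_on_replicates(self):
        table = make_expression(pre=[[1, 3]], post=[[8, 8]])
        rec = enrichment.compute_fold_changes(table, pseudocount=0.0)
        assert rec.loc[0, "log2_fc"] == pytest.approx(2.0)
        assert rec.loc[0, "mean_pre"] == 2.0 and rec.loc[0, "mean_post"] == 8.0

    def test_identity_when_pre_equals_post(self):
        table = make_expression(pre=[[4, 6], [1, 1]], post=[[5, 5], [1, 1]])
        rec = enrichment.compute_fold_changes(table)
        np.testing.assert_allclose(rec["log2_fc"], [0.0, 0.0])

    def test_pseudocount_guards_zero_pre(self):
        table = make_expression(pre=[[0, 0]], post=[[1, 1]])
        rec = enrichment.compute_fold_changes(table, pseudocount=0.1)
        assert rec.loc[0, "log2_fc"] == pytest.approx(math.log2(1.1 / 0.1))

    def test_all_zero_genes_dropped(self):
        table = make_expression(pre=[[0, 0], [1, 1]], post=[[0, 0], [2, 2]])
        rec = enrichment.compute_fold_changes(table)
        assert list(rec["gene_id"]) == ["G2"]

    def test_negative_pseudocount_rejected(self):
        table = make_expression(pre=[[1]], post=[[1]])
        with pytest.raises(ParameterError):
            enrichment.compute_fold_changes(table, pseudocount=-0.1)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=30)
    def test_scale_invariance(self, scale):
        pre = np.array([[1.0, 2.0], [5.0, 5.0], [0.5, 1.5]])
        post = np.array([[4.0, 4.0], [5.0, 5.0], [0.1, 0.3]])
        base = enrichment.compute_fold_changes(make_expression(pre, post))
        scaled = enrichment.compute_fold_changes(
            make_expression(pre * scale, post * scale)
        )
        np.testing.assert_allclose(scaled["log2_fc"], base["log2_fc"], rtol=1e-10)


class TestCombinedFoldChanges:
    def test_ratio_of_post_means(self):
        a = make_expression(pre=[[1, 1]], post=[[8, 8]])
        b = make_expression(pre=[[1, 1]], post=[[2, 2]])
        rec = enrichment.compute_combined_fold_changes(a, b)
        assert rec.loc[0, "log2_fc"] == pytest.approx(2.0)

    def test_equal_means_give_zero_and_swap_negates(self):
        a = make_expression(pre=[[1]] * 3, post=[[4], [2], [7]])
        b = make_expression(pre=[[1]] * 3, post=[[4], [8], [1]])
        ab = enrichment.compute_combined_fold_changes(a, b)
        ba = enrichment.compute_combined_fold_changes(b, a)
        assert ab.loc[0, "log2_fc"] == 0.0
        np.testing.assert_allclose(ab["log2_fc"], -ba["log2_fc"])

    def test_disjoint_gene_sets_error(self):
        a = make_expression(pre=[[1]], post=[[1]], gene_ids=["G1"])
        b = make_expression(pre=[[1]], post=[[1]], gene_ids=["G2"])
        with pytest.raises(ValidationError, match="shared"):
            enrichment.compute_combined_fold_changes(a, b)


class TestSignificanceFilter:
    def test_missing_pvalue_treated_as_not_significant(self):
        rec = make_records(
            {"G1": 1, "G2": 1, "G3": 1},
            p_value={"G1": 0.01, "G2": 0.06, "G3": np.nan},
        )
        kept = enrichment.filter_significant(rec, alpha=0.05)
        assert list(kept["gene_id"]) == ["G1"]

    def test_abundance_floor_is_inclusive(self):
        rec = make_records(
            {"G1": 1, "G2": 1, "G3": 1},
            mean_pre={"G1": 9.9, "G2": 10.0, "G3": 11.0},
        )
        kept = enrichment.filter_significant(rec, alpha=0.05, min_pre_fpkm=10.0)
        assert list(kept["gene_id"]) == ["G2", "G3"]

    def test_alpha_one_keeps_everything_tested(self):
        rec = make_records({"G1": 1, "G2": 2}, p_value={"G1": 1.0, "G2": 0.5})
        assert len(enrichment.filter_significant(rec, alpha=1.0)) == 2

    def test_bad_alpha_rejected(self):
        rec = make_records({"G1": 1})
        with pytest.raises(ParameterError):
            enrichment.filter_significant(rec, alpha=0.0)


class TestRocCurve:
    def test_separable_sets_give_perfect_j(self):
        rec = make_records({"T1": 2, "T2": 3, "F1": 0, "F2": 1})
        refs = ReferenceSets({"T1", "T2"}, {"F1", "F2"}, label="toy")
        curve = enrichment.roc_curve(rec, refs)
        assert curve.chosen_threshold == 2.0
        assert curve.chosen_j == 1.0

    def test_identical_multisets_give_zero_j(self):
        rec = make_records({"T1": 0, "T2": 1, "F1": 0, "F2": 1})
        refs = ReferenceSets({"T1", "T2"}, {"F1", "F2"})
        assert enrichment.roc_curve(rec, refs).chosen_j == 0.0

    def test_inverted_separation_chooses_sentinel(self):
        rec = make_records({"T1": 0, "F1": 5})
        refs = ReferenceSets({"T1"}, {"F1"})
        curve = enrichment.roc_curve(rec, refs)
        assert curve.chosen_j == 0.0
        assert curve.chosen_threshold > 5.0  # nothing is called

    def test_rates_non_increasing_and_missing_refs_dropped(self):
        rec = make_records({"T1": 2, "T2": -1, "F1": 0})
        refs = ReferenceSets({"T1", "T2", "ABSENT"}, {"F1"})
        curve = enrichment.roc_curve(rec, refs)
        assert curve.n_tp == 2  # ABSENT excluded from the denominator
        assert (np.diff(curve.tpr) <= 0).all() and (np.diff(curve.fpr) <= 0).all()
        np.testing.assert_allclose(curve.youden, curve.tpr - curve.fpr)

    def test_empty_effective_reference_set_errors(self):
        rec = make_records({"G1": 1})
        with pytest.raises(ValidationError, match="true-positive"):
            enrichment.roc_curve(rec, ReferenceSets({"NOPE"}, {"G1"}))
        with pytest.raises(ValidationError, match="false-positive"):
            enrichment.roc_curve(rec, ReferenceSets({"G1"}, {"NOPE"}))

    def test_matches_brute_force_on_random_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_tp = rng.integers(1, 10)
            n_fp = rng.integers(1, 10)
            # half-integer grid forces ties between and within classes
            tp = rng.integers(-4, 5, n_tp) / 2.0
            fp = rng.integers(-4, 5, n_fp) / 2.0
            genes = {f"T{i}": v for i, v in enumerate(tp)}
            genes.update({f"F{i}": v for i, v in enumerate(fp)})
            rec = make_records(genes)
            refs = ReferenceSets(
                {f"T{i}" for i in range(n_tp)}, {f"F{i}" for i in range(n_fp)}
            )
            curve = enrichment.roc_curve(rec, refs)
            best_j, best_t = youden_scan(tp, fp)
            assert curve.chosen_j == pytest.approx(float(best_j), abs=1e-12)
            assert curve.chosen_threshold == pytest.approx(best_t, abs=1e-12)


class TestCallEnriched:
    def test_inclusive_threshold_and_alpha(self):
        rec = make_records({"G1": -1, "G2": 0.5, "G3": 1.2, "G4": 3})
        called = enrichment.call_enriched(rec, threshold=1.0, alpha=0.05)
        assert called.genes == {"G3", "G4"}
        assert len(enrichment.call_enriched(rec, threshold=-np.inf).genes) == 4
        assert len(enrichment.call_enriched(rec, threshold=4.0).genes) == 0

    def test_threshold_exactly_at_value_calls_it(self):
        rec = make_records({"G1": 0.904})
        assert enrichment.call_enriched(rec, threshold=0.904).genes == {"G1"}

    @given(
        thresholds=st.lists(
            st.floats(min_value=-5, max_value=5), min_size=2, max_size=2
        )
    )
    @settings(deadline=None, max_examples=30)
    def test_raising_threshold_never_adds_genes(self, thresholds):
        lo, hi = sorted(thresholds)
        rec = make_records({f"G{i}": v for i, v in enumerate(np.linspace(-4, 4, 17))})
        assert enrichment.call_enriched(rec, hi).genes <= enrichment.call_enriched(rec, lo).genes


class TestBidirectional:
    def test_perfect_partition(self):
        genes = {"NT1": 2.0, "NT2": 2.0, "CT1": -2.0, "CT2": -2.0, "F1": 0.0, "F2": 0.0}
        rec = make_records(genes)
        nuclear, cytosolic = enrichment.call_bidirectional(
            rec,
            ReferenceSets({"NT1", "NT2"}, {"F1", "F2"}, "nuclear"),
            ReferenceSets({"CT1", "CT2"}, {"F1", "F2"}, "cytosolic"),
        )
        assert nuclear.genes == {"NT1", "NT2"}
        assert cytosolic.genes == {"CT1", "CT2"}
        assert nuclear.threshold == pytest.approx(2.0)
        assert cytosolic.threshold == pytest.approx(-2.0)
        assert not nuclear.genes & cytosolic.genes
        # the cytosolic records keep the shared sign convention
        assert (cytosolic.records["log2_fc"] <= -2.0).all()

    def test_no_separation_yields_zero_j_lists(self):
        rec = make_records({f"G{i}": 0.0 for i in range(6)})
        nuclear, cytosolic = enrichment.call_bidirectional(
            rec,
            ReferenceSets({"G0"}, {"G2"}, "nuclear"),
            ReferenceSets({"G1"}, {"G3"}, "cytosolic"),
        )
        assert nuclear.genes.isdisjoint(cytosolic.genes)

    def test_disjoint_for_random_inputs(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 2, 40)
        rec = make_records({f"G{i}": v for i, v in enumerate(vals)})
        order = np.argsort(vals)
        refs_n = ReferenceSets({f"G{i}" for i in order[-5:]}, {f"G{i}" for i in order[15:20]})
        refs_c = ReferenceSets({f"G{i}" for i in order[:5]}, {f"G{i}" for i in order[20:25]})
        nuclear, cytosolic = enrichment.call_bidirectional(rec, refs_n, refs_c)
        assert nuclear.genes.isdisjoint(cytosolic.genes)
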