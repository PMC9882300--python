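"""Counting arithmetic, RPM normalization, fold changes, comparisons,
precursor histograms, CapSeq enrichment, and reporter scoring."""

from __future__ import annotations

import math

import pytest

from pirnaquant.annotation import Feature, FeatureClass
from pirnaquant.classify import ClassifiedRead
from pirnaquant.quantify import (
    CountTable,
    UndefinedMetricError,
    capseq_enrichment_metric,
    compare_gene_classes,
    count,
    fold_changes,
    precursor_histogram,
    score_reporter,
    snpc4_dependency_sets,
)


def _cr(rid, cls, features, weight=1.0, n_loci=1, length=21, first="T"):
    features = list(features)
    return ClassifiedRead(
        read_id=rid,
        assigned_class=cls,
        feature_ids=sorted(set(features)),
        weight=weight,
        length=length,
        first_base=first,
        n_loci=n_loci,
        class_locus_count=len(features) if features else n_loci,
        feature_hits=features,
    )


def _pirna(fid, start=0, type_="I"):
    return Feature(
        fid, "chr1", start, start + 21, "+", FeatureClass.PIRNA,
        pirna_type=type_, mature_seq="T" * 21,
    )


def _gene(fid, start=0, gene_class="none"):
    return Feature(
        fid, "chr1", start, start + 300, "+", FeatureClass.PROTEIN_CODING,
        gene_class=gene_class,
    )


class TestCounting:
    def test_single_unique_read(self):
        feats = [_pirna("p1")]
        table = count([_cr("r1", "pirna_mature", ["p1"])], feats)
        assert table.per_class["pirna_mature"] == 1.0
        assert table.per_feature["p1"] == 1.0
        assert table.total_mapped == 1.0

    def test_four_locus_multimapper_split(self):
        feats = [_pirna(f"p{i}", start=100 * i) for i in range(4)]
        cr = _cr("r1", "pirna_mature", [f.id for f in feats], weight=0.25, n_loci=4)
        table = count([cr], feats)
        assert all(table.per_feature[f.id] == pytest.approx(0.25) for f in feats)
        assert table.per_class["pirna_mature"] == pytest.approx(1.0)

    def test_rpm_formula_example(self):
        # 5 counts, 2000 mapped, 1000 structural -> 5e6/1000 = 5000 RPM
        feats = [_pirna("p1")]
        table = CountTable.from_feature_class_counts(
            {("p1", "pirna_mature"): 5.0},
            feats,
            total_mapped=2000.0,
            structural_sense=1000.0,
        )
        assert table.per_feature_rpm["p1"] == pytest.approx(5000.0)

    def test_empty_library_degenerate_not_division_error(self):
        table = count([], [_pirna("p1")])
        assert table.degenerate
        with pytest.raises(UndefinedMetricError):
            table.per_class_rpm

    def test_class_totals_sum_to_read_count(self):
        feats = [_pirna("p1"), _gene("g1", start=500)]
        classified = [
            _cr("r1", "pirna_mature", ["p1"]),
            _cr("r2", "coding_sense", ["g1"]),
            _cr("r3", "other", [], n_loci=2, weight=0.5),
        ]
        table = count(classified, feats)
        assert sum(table.per_class.values()) == pytest.approx(table.total_mapped)


class TestFoldChanges:
    def _tables(self, control_counts, treatment_counts, feats):
        return (
            CountTable.from_feature_class_counts(treatment_counts, feats),
            CountTable.from_feature_class_counts(control_counts, feats),
        )

    def test_halving_gives_minus_one_log2(self):
        feats = [_pirna("p1")]
        # identical totals so RPM ratio equals count ratio
        treat, ctrl = self._tables(
            {("p1", "pirna_mature"): 100.0, ("x", "other"): 900.0},
            {("p1", "pirna_mature"): 50.0, ("x", "other"): 950.0},
            feats,
        )
        [r] = [
            r for r in fold_changes(treat, ctrl, pseudocount=0.0, group_by="feature")
            if r.key == "p1"
        ]
        assert r.log2fc == pytest.approx(-1.0)

    def test_zero_vs_zero_with_pseudocount_is_flat(self):
        feats = [_pirna("p1")]
        treat, ctrl = self._tables(
            {("bg", "other"): 100.0}, {("bg", "other"): 100.0}, feats
        )
        [r] = [
            r for r in fold_changes(treat, ctrl, pseudocount=1.0, group_by="feature")
            if r.key == "p1"
        ]
        assert r.log2fc == 0.0

    def test_mismatched_annotations_rejected(self):
        t1 = CountTable.from_feature_class_counts({("p1", "x"): 1.0}, [_pirna("p1")])
        t2 = CountTable.from_feature_class_counts({("p2", "x"): 1.0}, [_pirna("p2")])
        with pytest.raises(ValueError):
            fold_changes(t1, t2)


class TestGeneClassComparison:
    def _fc(self, values, feats):
        from pirnaquant.quantify import FoldChangeResult

        return [
            FoldChangeResult(f.id, 0.0, 0.0, 0.1, v) for f, v in zip(feats, values)
        ]

    def test_identical_vectors_maximal_p(self):
        feats = [_gene(f"a{i}", gene_class="csr1_target") for i in range(3)] + [
            _gene(f"b{i}", gene_class="wago_target") for i in range(3)
        ]
        res = compare_gene_classes(self._fc([-1.0] * 6, feats), feats)
        assert res.pvalue == 1.0
        assert res.statistic == pytest.approx(4.5)  # n_a*n_b/2

    def test_exact_p_for_separated_three_vs_three(self):
        # fully separated groups: two-sided exact p = 2/C(6,3) = 0.1
        feats = [_gene(f"a{i}", gene_class="csr1_target") for i in range(3)] + [
            _gene(f"b{i}", gene_class="wago_target") for i in range(3)
        ]
        fc = self._fc([-2.0, -2.1, -1.9, 0.0, -0.1, 0.1], feats)
        res = compare_gene_classes(fc, feats)
        assert res.pvalue == pytest.approx(0.1)
        assert res.statistic == 0.0  # class_a entirely below class_b

    def test_empty_class_is_error(self):
        feats = [_gene("a1", gene_class="csr1_target")]
        with pytest.raises(ValueError):
            compare_gene_classes(self._fc([-1.0], feats), feats)


class TestDependencySets:
    def test_lowest_quartile(self):
        dep, all_loci = snpc4_dependency_sets(
            {"a": 0.1, "b": 0.2, "c": 0.9, "d": 1.0}, quantile=0.25
        )
        assert dep == {"a"}
        assert all_loci == {"a", "b", "c", "d"}

    def test_quantile_one_returns_all(self):
        folds = {c: 0.5 for c in "abcdef"}
        dep, all_loci = snpc4_dependency_sets(folds, quantile=1.0)
        assert dep == all_loci == set("abcdef")

    def test_boundary_ties_break_by_locus_id(self):
        dep, _ = snpc4_dependency_sets(
            {"b": 0.2, "a": 0.2, "c": 0.9, "d": 1.0}, quantile=0.25
        )
        assert dep == {"a"}

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            snpc4_dependency_sets({}, 0.25)
        with pytest.raises(ValueError):
            snpc4_dependency_sets({"a": 1.0}, 0.0)


class TestPrecursorHistogram:
    def _cr_seq(self, rid, cls="pirna_precursor"):
        return _cr(rid, cls, ["p1"], length=0)

    def test_counts_lengths_of_distinct_sequences(self):
        seqs = {"r1": "A" * 25, "r2": "C" * 25, "r3": "G" * 41}
        classified = [self._cr_seq(r) for r in seqs]
        hist = precursor_histogram(classified, seqs)
        assert hist.counts == {25: 2, 41: 1}

    def test_duplicate_sequence_counts_once(self):
        seqs = {f"r{i}": "A" * 25 for i in range(100)}
        classified = [self._cr_seq(r) for r in seqs]
        hist = precursor_histogram(classified, seqs)
        assert hist.counts == {25: 1}

    def test_non_precursor_reads_ignored_and_empty_ok(self):
        seqs = {"r1": "A" * 30}
        hist = precursor_histogram([self._cr_seq("r1", cls="pirna_mature")], seqs)
        assert hist.counts == {} and hist.peaks == []

    def test_peaks_are_strict_local_maxima(self):
        seqs = {}
        i = 0
        for length, n in [(24, 1), (25, 5), (26, 2), (41, 3), (42, 3)]:
            for _ in range(n):
                seqs[f"r{i}"] = _unique_seq(i, length)
                i += 1
        classified = [self._cr_seq(r) for r in seqs]
        hist = precursor_histogram(classified, seqs)
        # 25 exceeds both neighbors; 41 and 42 tie so neither is a peak
        assert hist.peaks == [25]


def _unique_seq(i: int, length: int) -> str:
    """Distinct sequence of the requested length for each i."""
    prefix = format(i, "08b").replace("0", "A").replace("1", "C")
    return prefix.ljust(length, "G")[:length]


class TestCapseqMetric:
    def _table(self, prec, mat, other=1000.0):
        feats = [_pirna("p1")]
        return CountTable.from_feature_class_counts(
            {
                ("p1", "pirna_precursor"): prec,
                ("p1", "pirna_mature"): mat,
                ("bg", "other"): other,
            },
            feats,
        )

    def test_identical_libraries_give_one(self):
        t = self._table(10.0, 100.0)
        assert capseq_enrichment_metric(t, t) == pytest.approx(1.0)

    def test_ideal_capture_is_infinite(self):
        cap = self._table(50.0, 0.0)
        std = self._table(10.0, 100.0)
        assert capseq_enrichment_metric(cap, std) == math.inf

    def test_standard_without_precursors_is_undefined(self):
        cap = self._table(50.0, 5.0)
        std = self._table(0.0, 100.0)
        with pytest.raises(UndefinedMetricError):
            capseq_enrichment_metric(cap, std)

    def test_pseudocount_gives_finite_value(self):
        cap = self._table(50.0, 0.0)
        std = self._table(10.0, 100.0)
        v = capseq_enrichment_metric(cap, std, pseudocount=0.1)
        assert math.isfinite(v) and v > 10


class TestReporterScoring:
    def test_three_of_ten_is_activated(self):
        [res] = score_reporter({"t": [True] * 3 + [False] * 7})
        assert res.percent_activated == pytest.approx(30.0)
        assert res.activated_call

    def test_two_of_ten_is_not_activated_strict_threshold(self):
        [res] = score_reporter({"t": [True] * 2 + [False] * 8})
        assert res.percent_activated == pytest.approx(20.0)
        assert not res.activated_call

    def test_zero_positive(self):
        [res] = score_reporter({"t": [False] * 12})
        assert res.percent_activated == 0.0 and not res.activated_call

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            score_reporter({})
        with pytest.raises(ValueError):
            score_reporter({"t": []})
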