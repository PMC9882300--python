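"""Weighted counting, RPM normalization, fold changes, and derived analyses.

Counting follows the multi-mapper convention of the alignment stage: each
read carries weight 1/n_loci per qualifying locus of its winning class, and
"total mapped reads" counts each read once. RPM normalization excludes
sense structural-RNA reads from the denominator:

    RPM(x) = 1e6 * count(x) / (total_mapped - structural_sense)

Fold changes are pseudocounted log2 ratios of RPM values between a
treatment (RNAi knockdown) library and its empty-vector control. Gene-class
comparisons (CSR-1 vs WAGO targets) use a two-sided Mann-Whitney rank-sum
test on per-gene 22G-RNA log2 fold changes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from scipy import stats

from .annotation import Feature, FeatureClass
from .classify import ClassifiedRead


class UndefinedMetricError(ValueError):
    """A ratio metric could not be formed (zero denominator counts)."""


@dataclass
class CountTable:
    """Weighted raw and RPM-normalized counts for one library.

    ``per_feature_class`` keeps (feature_id, class) resolution so that
    class-restricted groupings (per-gene 22G counts, piRNA-type partitions)
    can be formed without re-counting. ``degenerate`` is set instead of
    dividing by zero when the library is empty or all-structural.
    """

    features: list[Feature]
    per_feature_class: dict[tuple[str, str], float] = field(default_factory=dict)
    per_class: dict[str, float] = field(default_factory=dict)
    total_mapped: float = 0.0
    structural_sense: float = 0.0
    rpm_denominator: float = 0.0
    degenerate: bool = False

    @property
    def per_feature(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (fid, _cls), c in self.per_feature_class.items():
            out[fid] = out.get(fid, 0.0) + c
        return out

    @property
    def annotation_ids(self) -> frozenset[str]:
        return frozenset(f.id for f in self.features)

    def rpm(self, raw_count: float) -> float:
        if self.degenerate:
            raise UndefinedMetricError("RPM undefined for a degenerate library")
        return 1e6 * raw_count / self.rpm_denominator

    @property
    def per_feature_rpm(self) -> dict[str, float]:
        if self.degenerate:
            raise UndefinedMetricError("RPM undefined for a degenerate library")
        return {fid: self.rpm(c) for fid, c in self.per_feature.items()}

    @property
    def per_class_rpm(self) -> dict[str, float]:
        if self.degenerate:
            raise UndefinedMetricError("RPM undefined for a degenerate library")
        return {cls: self.rpm(c) for cls, c in self.per_class.items()}

    @classmethod
    def from_feature_class_counts(
        cls,
        feature_class_counts: dict[tuple[str, str], float],
        features: list[Feature],
        total_mapped: float | None = None,
        structural_sense: float = 0.0,
    ) -> "CountTable":
        """Build a table directly from per-(feature, class) counts.

        Used by count-level simulations (e.g. test-calibration replicates)
        where reads are never materialized. ``total_mapped`` defaults to the
        sum of the supplied counts plus ``structural_sense``.
        """
        if total_mapped is None:
            total_mapped = sum(feature_class_counts.values()) + structural_sense
        per_class: dict[str, float] = {}
        for (_fid, c), v in feature_class_counts.items():
            per_class[c] = per_class.get(c, 0.0) + v
        if structural_sense:
            per_class["structural_sense"] = (
                per_class.get("structural_sense", 0.0) + structural_sense
            )
        denom = total_mapped - structural_sense
        return cls(
            features=features,
            per_feature_class=dict(feature_class_counts),
            per_class=per_class,
            total_mapped=total_mapped,
            structural_sense=structural_sense,
            rpm_denominator=denom,
            degenerate=(total_mapped == 0 or denom <= 0),
        )


def count(classified: list[ClassifiedRead], features: list[Feature]) -> CountTable:
    """Weighted per-feature and per-class counts with RPM normalization.

    Each read contributes 1 to ``total_mapped``; its winning class receives
    weight * (number of qualifying loci), and each feature hit of the
    winning class receives weight. On annotations where every locus of a
    read carries its winning class, class totals therefore sum to the
    number of classified reads.
    """
    per_feature_class: dict[tuple[str, str], float] = {}
    per_class: dict[str, float] = {}
    total = 0.0
    for cr in classified:
        total += 1.0
        per_class[cr.assigned_class] = (
            per_class.get(cr.assigned_class, 0.0) + cr.weight * cr.class_locus_count
        )
        for fid in cr.feature_hits:
            key = (fid, cr.assigned_class)
            per_feature_class[key] = per_feature_class.get(key, 0.0) + cr.weight
    structural = per_class.get("structural_sense", 0.0)
    denom = total - structural
    return CountTable(
        features=features,
        per_feature_class=per_feature_class,
        per_class=per_class,
        total_mapped=total,
        structural_sense=structural,
        rpm_denominator=denom,
        degenerate=(total == 0 or denom <= 0),
    )


@dataclass(frozen=True)
class FoldChangeResult:
    """Treatment-vs-control RPM ratio for one grouping key."""

    key: object
    control_rpm: float
    treatment_rpm: float
    pseudocount: float
    log2fc: float

    @property
    def fold(self) -> float:
        """Linear fold change (2**log2fc)."""
        return 2.0 ** self.log2fc


def _grouped_rpm(table: CountTable, group_by: str) -> dict[object, float]:
    feat_by_id = {f.id: f for f in table.features}
    if group_by == "class":
        return dict(table.per_class_rpm)
    if group_by == "feature":
        out: dict[object, float] = {f.id: 0.0 for f in table.features}
        out.update(table.per_feature_rpm)
        return out
    if group_by == "feature_22g":
        out = {
            f.id: 0.0
            for f in table.features
            if f.feature_class
            in {
                FeatureClass.PROTEIN_CODING,
                FeatureClass.PSEUDOGENE,
                FeatureClass.TRANSPOSON,
            }
        }
        for (fid, cls), c in table.per_feature_class.items():
            if cls == "twenty_two_g" and fid in out:
                out[fid] += table.rpm(c)
        return out
    if group_by == "class_gene_class":
        out = {}
        for (fid, cls), c in table.per_feature_class.items():
            feat = feat_by_id[fid]
            key = (cls, feat.gene_class or "none")
            out[key] = out.get(key, 0.0) + table.rpm(c)
        return out
    if group_by == "pirna_type":
        out = {}
        for (fid, cls), c in table.per_feature_class.items():
            feat = feat_by_id[fid]
            if feat.feature_class is not FeatureClass.PIRNA:
                continue
            key = (cls, feat.pirna_type)
            out[key] = out.get(key, 0.0) + table.rpm(c)
        return out
    raise ValueError(f"unknown grouping {group_by!r}")


def fold_changes(
    treatment: CountTable,
    control: CountTable,
    pseudocount: float = 0.1,
    group_by: str = "class",
) -> list[FoldChangeResult]:
    """Pseudocounted log2 fold changes of treatment vs control RPM.

    ``group_by`` is one of ``class``, ``feature``, ``feature_22g`` (per-gene
    22G-RNA counts over 22G target features), ``class_gene_class``
    ((class, gene_class) sums), or ``pirna_type`` ((class, I|II) sums over
    piRNA loci). Both tables must be built on the same annotation.
    """
    if treatment.annotation_ids != control.annotation_ids:
        raise ValueError("treatment and control tables use different annotations")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    t = _grouped_rpm(treatment, group_by)
    c = _grouped_rpm(control, group_by)
    results = []
    for key in sorted(set(t) | set(c), key=repr):
        t_rpm = t.get(key, 0.0)
        c_rpm = c.get(key, 0.0)
        log2fc = math.log2((t_rpm + pseudocount) / (c_rpm + pseudocount))
        results.append(
            FoldChangeResult(
                key=key,
                control_rpm=c_rpm,
                treatment_rpm=t_rpm,
                pseudocount=pseudocount,
                log2fc=log2fc,
            )
        )
    return results


@dataclass(frozen=True)
class GeneClassComparison:
    """Rank-sum comparison of per-gene fold changes between two gene classes."""

    class_a: str
    class_b: str
    n_a: int
    n_b: int
    statistic: float
    pvalue: float


def compare_gene_classes(
    fc: list[FoldChangeResult],
    features: list[Feature],
    class_a: str = "csr1_target",
    class_b: str = "wago_target",
) -> GeneClassComparison:
    """Two-sided Mann-Whitney rank-sum test on per-gene log2 fold changes.

    ``fc`` must be per-feature fold changes (grouping ``feature_22g`` or
    ``feature``); genes are split by their ``gene_class`` label.
    """
    gene_class = {f.id: f.gene_class for f in features}
    a = [r.log2fc for r in fc if gene_class.get(r.key) == class_a]
    b = [r.log2fc for r in fc if gene_class.get(r.key) == class_b]
    if not a or not b:
        raise ValueError(
            f"gene class comparison needs members in both classes "
            f"({class_a}: {len(a)}, {class_b}: {len(b)})"
        )
    if len(set(a) | set(b)) == 1:
        # all values tied: null center, maximal p
        return GeneClassComparison(
            class_a, class_b, len(a), len(b), len(a) * len(b) / 2.0, 1.0
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GeneClassComparison(
        class_a, class_b, len(a), len(b), float(res.statistic), float(res.pvalue)
    )


def snpc4_dependency_sets(
    mature_fold: dict[str, float], quantile: float = 0.25
) -> tuple[set[str], set[str]]:
    """Loci most dependent on SNPC-4 for mature piRNA accumulation.

    The dependent set is the ``quantile`` fraction of loci with the lowest
    knockdown-vs-control fold changes (most reduced = most dependent). Ties
    at the boundary break by locus id for determinism.
    """
    if not mature_fold:
        raise ValueError("fold map is empty")
    if not (0 < quantile <= 1):
        raise ValueError("quantile must be in (0, 1]")
    ranked = sorted(mature_fold, key=lambda k: (mature_fold[k], k))
    k = max(1, math.floor(quantile * len(ranked) + 1e-9))
    return set(ranked[:k]), set(ranked)


@dataclass
class PrecursorHistogram:
    """Length histogram of unique piRNA precursor sequences.

    Counts are over distinct sequences, not read multiplicity: a precursor
    molecule observed 100 times contributes once. ``peaks`` are strict local
    maxima (count exceeds both neighboring lengths) at or above a minimum
    count floor.
    """

    counts: dict[int, int]
    peaks: list[int]


def precursor_histogram(
    classified_capseq: list[ClassifiedRead],
    read_seqs: dict[str, str],
    min_peak_count: int = 1,
) -> PrecursorHistogram:
    """Histogram of unique precursor sequence lengths, with peak calling."""
    unique_seqs = {
        read_seqs[cr.read_id]
        for cr in classified_capseq
        if cr.assigned_class == "pirna_precursor"
    }
    counts = dict(Counter(len(s) for s in unique_seqs))
    peaks = [
        length
        for length, c in sorted(counts.items())
        if c >= min_peak_count
        and c > counts.get(length - 1, 0)
        and c > counts.get(length + 1, 0)
    ]
    return PrecursorHistogram(counts=counts, peaks=peaks)


def capseq_enrichment_metric(
    capseq: CountTable, standard: CountTable, pseudocount: float = 0.0
) -> float:
    """Precursor-over-mature enrichment of a CapSeq library vs a standard one.

    Returns (precursor/mature RPM in CapSeq) / (precursor/mature RPM in the
    standard library); values > 1 indicate successful cap-dependent
    enrichment. With ``pseudocount`` 0, the metric is undefined
    (:class:`UndefinedMetricError`) when the standard-library ratio cannot
    be formed, and +inf when an ideal CapSeq library contains precursors but
    no mature reads at all. A positive pseudocount (RPM) always yields a
    finite smoothed value.
    """
    for table, name in ((capseq, "capseq"), (standard, "standard")):
        if table.degenerate:
            raise UndefinedMetricError(f"{name} library is degenerate")
    cap_prec = capseq.per_class_rpm.get("pirna_precursor", 0.0)
    cap_mat = capseq.per_class_rpm.get("pirna_mature", 0.0)
    std_prec = standard.per_class_rpm.get("pirna_precursor", 0.0)
    std_mat = standard.per_class_rpm.get("pirna_mature", 0.0)
    if pseudocount > 0:
        return ((cap_prec + pseudocount) / (cap_mat + pseudocount)) / (
            (std_prec + pseudocount) / (std_mat + pseudocount)
        )
    if std_mat == 0 or std_prec == 0:
        raise UndefinedMetricError(
            "standard library precursor/mature ratio undefined "
            f"(precursor RPM {std_prec}, mature RPM {std_mat})"
        )
    std_ratio = std_prec / std_mat
    if cap_mat == 0:
        if cap_prec == 0:
            raise UndefinedMetricError("capseq library has no piRNA reads")
        return math.inf
    return (cap_prec / cap_mat) / std_ratio


@dataclass(frozen=True)
class ReporterAssayResult:
    """Scored outcome of one RNAi treatment in the reporter screen."""

    treatment: str
    n_scored: int
    n_activated: int
    percent_activated: float
    activated_call: bool


def score_reporter(calls: dict[str, list[bool]]) -> list[ReporterAssayResult]:
    """Score per-animal GFP calls per treatment against the 20% threshold.

    A treatment is called positive only if strictly more than 20% of scored
    animals show reporter activation (control treatments occasionally show
    spurious activation, but never above 20%).
    """
    if not calls:
        raise ValueError("no treatments to score")
    results = []
    for treatment in sorted(calls):
        animal_calls = calls[treatment]
        if not animal_calls:
            raise ValueError(f"treatment {treatment!r} has no scored animals")
        n = len(animal_calls)
        n_pos = sum(bool(c) for c in animal_calls)
        pct = 100.0 * n_pos / n
        results.append(
            ReporterAssayResult(
                treatment=treatment,
                n_scored=n,
                n_activated=n_pos,
                percent_activated=pct,
                activated_call=pct > 20.0,
            )
        )
    return results
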