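"""Reference simulation scenarios: the knockdown conditions the pipeline
is validated against.

Each scenario builds a genome, simulates control and treatment libraries,
runs the full stage chain (length filter -> align -> overlap -> classify ->
count), and measures the quantity the corresponding analysis asks for:

* ``ints1_scenario`` — Integrator-like knockdown: mature piRNAs reduced to
  0.3x; recovers the class-level fold change.
* ``npp7_scenario`` — nuclear-pore-like knockdown: 22G-RNAs of CSR-1 target
  genes reduced to 0.4x and of WAGO targets to 0.8x; recovers per-gene-class
  fold changes and the CSR-1-vs-WAGO rank-sum comparison.
* ``snpc4_scenario`` — SNPC-4-like knockdown: a designated subset of type I
  piRNA loci reduced to 0.1x; recovers the most-dependent locus set.
* ``capseq_scenario`` — idealized cap-dependent enrichment: precursor
  length histogram and the precursor/mature enrichment metric.
* ``null_calibration`` — count-level null replicates for the gene-class
  rank-sum test's type-I error.

Library sizes default to 100k reads (50k for CapSeq), which keeps every
class' expected counts large enough for the stated recovery tolerances
while remaining desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import GenomeIndex, Read, align_all
from .annotation import Feature, FeatureClass, overlap
from .classify import ClassifiedRead, classify, length_filter
from .genome import Genome
from .pipeline import CAPSEQ_WINDOW, SMALL_RNA_WINDOW
from .quantify import (
    CountTable,
    GeneClassComparison,
    compare_gene_classes,
    capseq_enrichment_metric,
    count,
    fold_changes,
    precursor_histogram,
    snpc4_dependency_sets,
)
from .simulate import (
    ConditionSpec,
    SimGenomeConfig,
    SimReadTruth,
    TRUTH_TO_ASSIGNED,
    apply_capseq_enrichment,
    simulate_genome,
    simulate_library,
)

#: Class mix for piRNA-focused simulations (locus-level piRNA analyses need
#: per-locus depth; mature piRNAs are a major component here).
PIRNA_RICH_MIX = {
    "structural": 0.28,
    "mirna": 0.25,
    "twenty_two_g": 0.10,
    "mature_pirna": 0.25,
    "pirna_precursor": 0.02,
    "other": 0.10,
}

#: Class mix for the npp-7-like scenario: no sense gene fragments, so the
#: per-gene locus multipliers act on 22G-RNAs alone. The 22G share is kept
#: small enough that the compositional bias of fixed-depth RPM fold changes
#: stays under ~5% regardless of how 22G abundance splits across gene
#: classes (worst case: 0.6 * 0.05 / 0.68 ~ 4.4%).
NPP7_MIX = {
    "structural": 0.32,
    "mirna": 0.58,
    "twenty_two_g": 0.05,
    "mature_pirna": 0.04,
    "pirna_precursor": 0.01,
}


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


@dataclass
class LibraryRun:
    """All stage outputs for one simulated library."""

    reads: list[Read]
    truth: list[SimReadTruth]
    classified: list[ClassifiedRead]
    table: CountTable

    @property
    def read_seqs(self) -> dict[str, str]:
        return {r.id: r.sequence for r in self.reads}


def process_library(
    genome: Genome,
    features: list[Feature],
    reads: list[Read],
    truth: list[SimReadTruth] | None = None,
    window: tuple[int, int] = SMALL_RNA_WINDOW,
    index: GenomeIndex | None = None,
) -> LibraryRun:
    """Run the full stage chain on an in-memory library."""
    if index is None:
        index = GenomeIndex(genome)
    kept = length_filter(reads, *window)
    alignments = align_all(kept, index)
    overlaps = overlap(alignments, features)
    classified = classify(kept, alignments, overlaps, features, genome)
    return LibraryRun(
        reads=kept, truth=truth or [], classified=classified, table=count(classified, features)
    )


@dataclass
class FoldScenarioResult:
    genome: Genome
    features: list[Feature]
    control: LibraryRun
    treatment: LibraryRun
    class_fold: dict[str, float]  # recovered linear fold per class


def _run_pair(
    config: SimGenomeConfig,
    condition: ConditionSpec,
    n_reads: int,
    seed: int,
    class_mix: dict[str, float] | None,
    window: tuple[int, int] = SMALL_RNA_WINDOW,
) -> FoldScenarioResult:
    genome, features = simulate_genome(config)
    s_control, s_treat = _subseeds(seed, 2)
    index = GenomeIndex(genome)
    runs = {}
    for name, cond, s in (
        ("control", ConditionSpec.control(), s_control),
        ("treatment", condition, s_treat),
    ):
        reads, truth = simulate_library(
            genome, features, cond, n_reads, s, class_mix=class_mix
        )
        runs[name] = process_library(
            genome, features, reads, truth, window=window, index=index
        )
    fc = fold_changes(runs["treatment"].table, runs["control"].table, group_by="class")
    return FoldScenarioResult(
        genome=genome,
        features=features,
        control=runs["control"],
        treatment=runs["treatment"],
        class_fold={r.key: r.fold for r in fc},
    )


def ints1_scenario(seed: int, n_reads: int = 100_000) -> FoldScenarioResult:
    """Integrator-like knockdown: mature piRNA class scaled to 0.3x."""
    config = SimGenomeConfig(seed=_subseeds(seed, 3)[2])
    condition = ConditionSpec(name="ints-1", class_fold={"mature_pirna": 0.3})
    return _run_pair(config, condition, n_reads, seed, class_mix=None)


@dataclass
class Npp7Result:
    base: FoldScenarioResult
    gene_class_fold: dict[str, float]  # recovered 22G fold per gene class
    comparison: GeneClassComparison


def npp7_scenario(seed: int, n_reads: int = 100_000) -> Npp7Result:
    """Nuclear-pore-like knockdown: CSR-1 target 22Gs x0.4, WAGO x0.8."""
    sub = _subseeds(seed, 4)
    config = SimGenomeConfig(n_coding_genes=80, seed=sub[2])
    genome, features = simulate_genome(config)
    locus_fold = {}
    for f in features:
        if f.gene_class == "csr1_target":
            locus_fold[f.id] = 0.4
        elif f.gene_class == "wago_target":
            locus_fold[f.id] = 0.8
    condition = ConditionSpec(name="npp-7", locus_fold=locus_fold)
    base = _run_pair(config, condition, n_reads, seed, class_mix=NPP7_MIX)
    by_gc = fold_changes(
        base.treatment.table, base.control.table, group_by="class_gene_class"
    )
    gene_class_fold = {
        key[1]: r.fold
        for r in by_gc
        for key in [r.key]
        if key[0] == "twenty_two_g"
    }
    per_gene = fold_changes(
        base.treatment.table, base.control.table, group_by="feature_22g"
    )
    comparison = compare_gene_classes(per_gene, base.features)
    return Npp7Result(base=base, gene_class_fold=gene_class_fold, comparison=comparison)


@dataclass
class Snpc4Result:
    base: FoldScenarioResult
    designated: set[str]  # loci simulated as SNPC-4 dependent
    dependent: set[str]  # loci recovered as most dependent
    jaccard: float
    type_fold: dict[str, float]  # recovered mature piRNA fold per type (I/II)


def snpc4_scenario(
    seed: int,
    n_reads: int = 100_000,
    n_type1: int = 200,
    dependent_fraction: float = 0.25,
) -> Snpc4Result:
    """SNPC-4-like knockdown: a designated type-I subset scaled to 0.1x.

    The dependent set is recovered from per-locus mature piRNA fold changes
    at the same quantile as the designated fraction.
    """
    sub = _subseeds(seed, 4)
    config = SimGenomeConfig(
        n_type1_pirna_loci=n_type1,
        n_type2_pirna_loci=20,
        n_chromosomes=4,
        chrom_length=40_000,
        seed=sub[2],
    )
    genome, features = simulate_genome(config)
    type1_ids = sorted(
        f.id
        for f in features
        if f.feature_class is FeatureClass.PIRNA and f.pirna_type == "I"
    )
    pick_rng = np.random.default_rng(sub[3])
    n_dep = max(1, round(dependent_fraction * len(type1_ids)))
    designated = set(
        pick_rng.choice(type1_ids, size=n_dep, replace=False).tolist()
    )
    condition = ConditionSpec(
        name="snpc-4", locus_fold={fid: 0.1 for fid in sorted(designated)}
    )
    base = _run_pair(config, condition, n_reads, seed, class_mix=PIRNA_RICH_MIX)

    pc = 0.1
    t_table, c_table = base.treatment.table, base.control.table
    fold_map = {}
    for fid in type1_ids:
        t_rpm = t_table.rpm(t_table.per_feature_class.get((fid, "pirna_mature"), 0.0))
        c_rpm = c_table.rpm(c_table.per_feature_class.get((fid, "pirna_mature"), 0.0))
        fold_map[fid] = (t_rpm + pc) / (c_rpm + pc)
    dependent, _all_loci = snpc4_dependency_sets(fold_map, quantile=dependent_fraction)
    jaccard = len(dependent & designated) / len(dependent | designated)

    by_type = fold_changes(t_table, c_table, group_by="pirna_type")
    type_fold = {
        key[1]: r.fold
        for r in by_type
        for key in [r.key]
        if key[0] == "pirna_mature"
    }
    return Snpc4Result(
        base=base,
        designated=designated,
        dependent=dependent,
        jaccard=jaccard,
        type_fold=type_fold,
    )


@dataclass
class CapseqResult:
    standard: LibraryRun
    capseq: LibraryRun
    histogram_counts: dict[int, int]
    peaks: list[int]
    enrichment: float  # +inf for the idealized filter
    enrichment_smoothed: float  # finite, 0.1-RPM pseudocount


def capseq_scenario(seed: int, n_reads: int = 50_000) -> CapseqResult:
    """Idealized CapSeq next to a standard library from the same genome."""
    sub = _subseeds(seed, 4)
    config = SimGenomeConfig(seed=sub[2])
    genome, features = simulate_genome(config)
    index = GenomeIndex(genome)
    control = ConditionSpec.control()

    std_reads, std_truth = simulate_library(
        genome, features, control, n_reads, sub[0], class_mix=PIRNA_RICH_MIX
    )
    standard = process_library(
        genome, features, std_reads, std_truth, window=SMALL_RNA_WINDOW, index=index
    )

    raw_reads, raw_truth = simulate_library(
        genome, features, control, n_reads, sub[1], class_mix=PIRNA_RICH_MIX
    )
    cap_reads, cap_truth = apply_capseq_enrichment(raw_reads, raw_truth)
    capseq = process_library(
        genome, features, cap_reads, cap_truth, window=CAPSEQ_WINDOW, index=index
    )

    hist = precursor_histogram(capseq.classified, capseq.read_seqs)
    return CapseqResult(
        standard=standard,
        capseq=capseq,
        histogram_counts=hist.counts,
        peaks=hist.peaks,
        enrichment=capseq_enrichment_metric(capseq.table, standard.table),
        enrichment_smoothed=capseq_enrichment_metric(
            capseq.table, standard.table, pseudocount=0.1
        ),
    )


@dataclass
class TruthRecoveryResult:
    run: LibraryRun
    n_evaluated: int
    per_class_precision: dict[str, float]
    per_class_recall: dict[str, float]
    accuracy: float


def truth_recovery_scenario(seed: int, n_reads: int = 50_000) -> TruthRecoveryResult:
    """Noise-free control library: classifier output vs simulator truth.

    Evaluated over reads surviving the length filter (longer precursor
    isoforms fall outside the standard 17-40 nt window by design).
    """
    sub = _subseeds(seed, 2)
    config = SimGenomeConfig(seed=sub[1])
    genome, features = simulate_genome(config)
    reads, truth = simulate_library(
        genome, features, ConditionSpec.control(), n_reads, sub[0]
    )
    run = process_library(genome, features, reads, truth)
    truth_by_id = {t.read_id: t for t in truth}
    expected = {
        cr.read_id: TRUTH_TO_ASSIGNED[truth_by_id[cr.read_id].true_class]
        for cr in run.classified
    }
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    n_correct = 0
    for cr in run.classified:
        want = expected[cr.read_id]
        got = cr.assigned_class
        if got == want:
            tp[want] = tp.get(want, 0) + 1
            n_correct += 1
        else:
            fp[got] = fp.get(got, 0) + 1
            fn[want] = fn.get(want, 0) + 1
    classes = sorted(set(tp) | set(fp) | set(fn))
    precision = {
        c: tp.get(c, 0) / (tp.get(c, 0) + fp.get(c, 0))
        for c in classes
        if tp.get(c, 0) + fp.get(c, 0) > 0
    }
    recall = {
        c: tp.get(c, 0) / (tp.get(c, 0) + fn.get(c, 0))
        for c in classes
        if tp.get(c, 0) + fn.get(c, 0) > 0
    }
    return TruthRecoveryResult(
        run=run,
        n_evaluated=len(run.classified),
        per_class_precision=precision,
        per_class_recall=recall,
        accuracy=n_correct / len(run.classified) if run.classified else 0.0,
    )


def null_calibration(
    seed: int,
    n_replicates: int = 200,
    n_genes_per_class: int = 30,
    alpha: float = 0.05,
    mean_count: float = 100.0,
) -> float:
    """Empirical type-I error of the gene-class rank-sum test under the null.

    Replicates are simulated at the count level: each gene's expected 22G
    count is log-normal (shared between conditions, i.e. equal folds) and
    observed counts are independent Poisson draws; CountTables are built
    directly and pushed through fold_changes + compare_gene_classes.
    """
    rng = np.random.default_rng(seed)
    features = [
        Feature(
            id=f"g{i:03d}",
            chrom="chr1",
            start=1000 * i,
            end=1000 * i + 500,
            strand="+",
            feature_class=FeatureClass.PROTEIN_CODING,
            gene_class="csr1_target" if i < n_genes_per_class else "wago_target",
        )
        for i in range(2 * n_genes_per_class)
    ]
    n_sig = 0
    for _ in range(n_replicates):
        means = rng.lognormal(mean=np.log(mean_count), sigma=1.0, size=len(features))
        tables = []
        for _cond in range(2):
            counts = rng.poisson(means)
            fcc = {
                (f.id, "twenty_two_g"): float(c)
                for f, c in zip(features, counts)
            }
            tables.append(
                CountTable.from_feature_class_counts(fcc, features)
            )
        fc = fold_changes(tables[1], tables[0], group_by="feature_22g")
        if compare_gene_classes(fc, features).pvalue < alpha:
            n_sig += 1
    return n_sig / n_replicates
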