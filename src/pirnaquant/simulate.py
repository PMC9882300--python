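"""Synthetic genomes, annotations, and small-RNA / CapSeq libraries.

The generator builds a compact annotation universe mirroring the locus
classes a C. elegans small-RNA analysis sees — type I piRNA loci (upstream
Ruby-motif placeholder, 21-nt mature 21U-RNAs), type II piRNA loci, miRNA
loci, structural RNAs (rRNA/tRNA/snoRNA/snRNA), protein-coding genes
labelled as CSR-1 or WAGO 22G targets, and transposons — and then samples
read libraries from a categorical mixture over (read class, locus) with
known ground truth, so that every downstream stage is verifiable at desk
scale.

5'-end chemistry follows the biology of each species: piRNA precursors are
capped primary transcripts, mature piRNAs / miRNAs / degradation fragments
are monophosphorylated, and 22G-RNAs carry a 5' triphosphate. CapSeq
enrichment is modelled as the idealized Terminator -> CIP -> RppH cascade:
a pure filter keeping exactly the capped molecules.

No sequencing error or quality model is simulated (the pipeline aligns
with zero mismatches, so errors would only shrink libraries); FASTQ
qualities are written as a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .align import Read
from .annotation import Feature, FeatureClass, STRUCTURAL_CLASSES
from .genome import Genome, revcomp


class SimulationError(ValueError):
    """The requested simulation is infeasible (sizing or empty classes)."""


#: Read classes the simulator emits (truth labels).
SIM_CLASSES = (
    "mature_pirna",
    "pirna_precursor",
    "twenty_two_g",
    "mirna",
    "structural",
    "other",
)

#: 5'-end chemistry per simulated class.
CHEMISTRY = {
    "mature_pirna": "monoP",
    "pirna_precursor": "cap",
    "twenty_two_g": "triP",
    "mirna": "monoP",
    "structural": "monoP",
    "other": "monoP",
}

#: Expected classifier label for each simulated class on clean libraries.
TRUTH_TO_ASSIGNED = {
    "mature_pirna": "pirna_mature",
    "pirna_precursor": "pirna_precursor",
    "twenty_two_g": "twenty_two_g",
    "mirna": "mirna_mature",
    "structural": "structural_sense",
    "other": "coding_sense",
}

#: Default library composition: structural degradation and miRNAs dominate,
#: 22G-RNAs are a moderate component, and piRNA species are minor ones, as
#: in typical whole-animal libraries.
DEFAULT_CLASS_MIX = {
    "structural": 0.30,
    "mirna": 0.35,
    "twenty_two_g": 0.12,
    "mature_pirna": 0.04,
    "pirna_precursor": 0.01,
    "other": 0.18,
}

#: Fixed 8-nt placeholder embedded upstream of type I piRNA loci in lieu of
#: a real Ruby motif model (type labels, not motif discovery, drive the
#: analysis).
RUBY_MOTIF_PLACEHOLDER = "GTTTCAGA"

_STRUCTURAL_CYCLE = (
    (FeatureClass.RRNA, 120),
    (FeatureClass.TRNA, 72),
    (FeatureClass.SNORNA, 100),
    (FeatureClass.SNRNA, 95),
)


@dataclass
class SimGenomeConfig:
    """Sizing of the simulated genome and annotation universe."""

    n_chromosomes: int = 3
    chrom_length: int = 30_000
    n_type1_pirna_loci: int = 60
    n_type2_pirna_loci: int = 15
    n_mirna_loci: int = 20
    n_structural_loci: int = 16
    n_coding_genes: int = 60
    gene_class_fractions: dict[str, float] = field(
        default_factory=lambda: {"csr1_target": 0.4, "wago_target": 0.4, "none": 0.2}
    )
    n_transposons: int = 8
    abundance_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_chromosomes,
            self.chrom_length,
            self.n_type1_pirna_loci,
            self.n_type2_pirna_loci,
            self.n_mirna_loci,
            self.n_structural_loci,
            self.n_coding_genes,
            self.n_transposons,
        )
        if any(c < 0 for c in counts):
            raise SimulationError("all counts must be >= 0")
        if self.n_chromosomes == 0 or self.chrom_length == 0:
            raise SimulationError("genome must have at least one non-empty chromosome")
        total_frac = sum(self.gene_class_fractions.values())
        if abs(total_frac - 1.0) > 1e-9:
            raise SimulationError(
                f"gene_class_fractions must sum to 1 (got {total_frac})"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimGenomeConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class ConditionSpec:
    """An RNAi-knockdown scenario: per-class and per-locus fold multipliers.

    ``locus_fold`` overrides ``class_fold`` for that locus. The control
    condition has all multipliers equal to 1.
    """

    name: str
    class_fold: dict[str, float] = field(default_factory=dict)
    locus_fold: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for k, v in {**self.class_fold, **self.locus_fold}.items():
            if v < 0:
                raise SimulationError(f"multiplier for {k!r} must be >= 0")

    def fold_for(self, sim_class: str, locus_id: str) -> float:
        if locus_id in self.locus_fold:
            return self.locus_fold[locus_id]
        return self.class_fold.get(sim_class, 1.0)

    @classmethod
    def control(cls) -> "ConditionSpec":
        return cls(name="control")


@dataclass(frozen=True)
class SimReadTruth:
    """Ground truth for one simulated read."""

    read_id: str
    true_class: str
    source_locus: str
    five_prime_chem: str


@dataclass
class _Slot:
    """A placement request: reserved run = margin + core + margin."""

    kind: str  # feature id prefix
    core: int
    margin: int
    feature_class: FeatureClass
    pirna_type: str | None = None
    gene_class: str | None = None


def _gene_class_labels(n: int, fractions: dict[str, float], rng) -> list[str]:
    """Allocate n labels by largest-remainder rounding, then shuffle."""
    labels = sorted(fractions)
    exact = {lab: fractions[lab] * n for lab in labels}
    counts = {lab: int(exact[lab]) for lab in labels}
    short = n - sum(counts.values())
    for lab in sorted(labels, key=lambda l: exact[l] - counts[l], reverse=True)[:short]:
        counts[lab] += 1
    out = [lab for lab in labels for _ in range(counts[lab])]
    return [str(lab) for lab in rng.permutation(out)]


def simulate_genome(config: SimGenomeConfig) -> tuple[Genome, list[Feature]]:
    """Random-sequence genome with non-overlapping annotated features.

    Every piRNA locus carries a 21-nt mature sequence beginning with T on
    its annotated strand (the 21U constraint in DNA space), embedded
    verbatim in the genome at its coordinates; type I loci additionally get
    the Ruby-motif placeholder 2-10 nt upstream and a ``ruby_motif``
    attribute. Each locus carries a log-normal relative-abundance attribute
    (drawn once here so that libraries simulated under different seeds share
    per-locus expression). Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bases = np.array(list("ACGT"))
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs = {
        name: list("".join(rng.choice(bases, size=config.chrom_length)))
        for name in chrom_names
    }

    slots: list[_Slot] = []
    for i in range(config.n_type1_pirna_loci):
        slots.append(_Slot("pirna1", 21, 48, FeatureClass.PIRNA, pirna_type="I"))
    for i in range(config.n_type2_pirna_loci):
        slots.append(_Slot("pirna2", 21, 48, FeatureClass.PIRNA, pirna_type="II"))
    for i in range(config.n_mirna_loci):
        slots.append(_Slot("mirna", 22, 6, FeatureClass.MIRNA))
    for i in range(config.n_structural_loci):
        fc, length = _STRUCTURAL_CYCLE[i % len(_STRUCTURAL_CYCLE)]
        slots.append(_Slot(fc.value.lower(), length, 5, fc))
    gene_labels = _gene_class_labels(
        config.n_coding_genes, config.gene_class_fractions, rng
    )
    for i in range(config.n_coding_genes):
        slots.append(
            _Slot(
                "gene",
                int(rng.integers(300, 601)),
                10,
                FeatureClass.PROTEIN_CODING,
                gene_class=gene_labels[i],
            )
        )
    for i in range(config.n_transposons):
        slots.append(_Slot("transposon", 250, 10, FeatureClass.TRANSPOSON))

    order = rng.permutation(len(slots))
    cursors = {name: 0 for name in chrom_names}
    chrom_idx = 0
    counters: dict[str, int] = {}
    features: list[Feature] = []

    for slot_i in order:
        slot = slots[slot_i]
        gap = int(rng.integers(10, 60))
        need = slot.margin + slot.core + slot.margin + gap
        # advance to a chromosome with room
        placed = False
        for _ in range(len(chrom_names)):
            name = chrom_names[chrom_idx]
            if cursors[name] + need <= config.chrom_length:
                placed = True
                break
            chrom_idx = (chrom_idx + 1) % len(chrom_names)
        if not placed:
            raise SimulationError(
                f"annotated footprint exceeds genome length while placing a "
                f"{slot.feature_class.value} locus; enlarge the genome or "
                "reduce locus counts"
            )
        name = chrom_names[chrom_idx]
        start = cursors[name] + gap + slot.margin
        end = start + slot.core
        cursors[name] = end + slot.margin
        chrom_idx = (chrom_idx + 1) % len(chrom_names)

        counters[slot.kind] = counters.get(slot.kind, 0) + 1
        fid = f"{slot.kind}_{counters[slot.kind]:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        abundance = float(rng.lognormal(mean=0.0, sigma=config.abundance_sigma))
        attributes = {"abundance": f"{abundance:.6g}"}

        mature_seq = None
        if slot.feature_class is FeatureClass.PIRNA:
            mature_seq = "T" + "".join(rng.choice(bases, size=20))
            _embed(seqs[name], start, end, strand, mature_seq)
            if slot.pirna_type == "I":
                attributes["ruby_motif"] = RUBY_MOTIF_PLACEHOLDER
                if strand == "+":
                    _embed(seqs[name], start - 10, start - 2, "+", RUBY_MOTIF_PLACEHOLDER)
                else:
                    _embed(seqs[name], end + 2, end + 10, "-", RUBY_MOTIF_PLACEHOLDER)
        elif slot.feature_class is FeatureClass.MIRNA:
            mature_seq = "".join(rng.choice(bases, size=22))
            _embed(seqs[name], start, end, strand, mature_seq)

        features.append(
            Feature(
                id=fid,
                chrom=name,
                start=start,
                end=end,
                strand=strand,
                feature_class=slot.feature_class,
                pirna_type=slot.pirna_type,
                mature_seq=mature_seq,
                gene_class=slot.gene_class,
                attributes=attributes,
            )
        )

    genome = Genome({name: "".join(chars) for name, chars in seqs.items()})
    features.sort(key=lambda f: (f.chrom, f.start, f.id))
    return genome, features


def _embed(chars: list[str], start: int, end: int, strand: str, seq: str) -> None:
    if end - start != len(seq):
        raise SimulationError("embedding length mismatch")
    fwd = seq if strand == "+" else revcomp(seq)
    chars[start:end] = list(fwd)


def abundance_of(feature: Feature) -> float:
    return float(feature.attributes.get("abundance", 1.0))


def _eligible_22g_positions(genome: Genome, feat: Feature) -> np.ndarray:
    """Genomic anchor positions of possible 22G 5' ends within a target.

    For a + strand target the 22G read is on the - strand and its 5' base is
    the complement of the forward base at the read's rightmost position, so
    anchors are 'C' positions; for a - strand target the read is on + and
    anchors are 'G' positions.
    """
    seq = genome.chroms[feat.chrom]
    want = "C" if feat.strand == "+" else "G"
    return np.array(
        [p for p in range(feat.start, feat.end) if seq[p] == want], dtype=int
    )


def mixture_weights(
    features: list[Feature],
    condition: ConditionSpec,
    class_mix: dict[str, float] | None = None,
    genome: Genome | None = None,
) -> dict[tuple[str, str], float]:
    """Normalized sampling weights over (read class, locus id).

    Base class weights are split across eligible loci proportionally to
    their abundance attribute, scaled by the condition's multipliers, and
    renormalized. A class with positive post-fold weight but no eligible
    locus raises :class:`SimulationError`.
    """
    condition.validate()
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    loci: dict[str, list[Feature]] = {c: [] for c in SIM_CLASSES}
    for f in features:
        if f.feature_class is FeatureClass.PIRNA:
            loci["mature_pirna"].append(f)
            loci["pirna_precursor"].append(f)
        elif f.feature_class is FeatureClass.MIRNA:
            loci["mirna"].append(f)
        elif f.feature_class in STRUCTURAL_CLASSES:
            loci["structural"].append(f)
        elif f.feature_class is FeatureClass.PROTEIN_CODING:
            loci["twenty_two_g"].append(f)
            loci["other"].append(f)
        elif f.feature_class is FeatureClass.TRANSPOSON:
            loci["twenty_two_g"].append(f)

    weights: dict[tuple[str, str], float] = {}
    for sim_class, base in mix.items():
        if sim_class not in loci:
            raise SimulationError(f"unknown simulated class {sim_class!r}")
        if base <= 0:
            continue
        members = loci[sim_class]
        if not members:
            raise SimulationError(
                f"class {sim_class!r} has positive weight but no eligible locus"
            )
        total_ab = sum(abundance_of(f) for f in members)
        for f in members:
            w = (
                base
                * (abundance_of(f) / total_ab)
                * condition.fold_for(sim_class, f.id)
            )
            if w > 0:
                weights[(sim_class, f.id)] = w
    total = sum(weights.values())
    if total <= 0:
        raise SimulationError("mixture has zero total weight")
    return {k: v / total for k, v in weights.items()}


def expected_class_weights(
    features: list[Feature],
    condition: ConditionSpec,
    class_mix: dict[str, float] | None = None,
) -> dict[str, float]:
    """Class marginals of :func:`mixture_weights` (the simulated truth)."""
    weights = mixture_weights(features, condition, class_mix)
    out: dict[str, float] = {}
    for (sim_class, _locus), w in weights.items():
        out[sim_class] = out.get(sim_class, 0.0) + w
    return out


def simulate_library(
    genome: Genome,
    features: list[Feature],
    condition: ConditionSpec,
    n_reads: int,
    seed: int,
    class_mix: dict[str, float] | None = None,
    precursor_offset_modes: tuple[int, ...] = (2, 18, 38),
    precursor_offset_weights: tuple[float, ...] = (0.5, 0.3, 0.2),
    fragment_length_range: tuple[int, int] = (20, 35),
) -> tuple[list[Read], list[SimReadTruth]]:
    """Sample a read library with index-aligned ground truth.

    Reads are drawn from the (class, locus) mixture of
    :func:`mixture_weights`. Mature piRNA and miRNA reads equal the locus
    mature sequence exactly; precursor reads start exactly 2 nt upstream of
    the mature 5' end and read through the 3' end by an offset drawn from
    ``precursor_offset_modes`` (default modes 2/18/38 nt give 25/41/61-nt
    precursors of a 21-nt mature); 22G reads are 21-23 nt, begin with G,
    and are antisense to a coding/transposon target; structural and
    ``other`` reads are sense fragments of their locus.
    """
    if n_reads < 0:
        raise SimulationError("n_reads must be >= 0")
    if n_reads == 0:
        return [], []
    rng = np.random.default_rng(seed)
    weights = mixture_weights(features, condition, class_mix, genome)
    pairs = sorted(weights)
    probs = np.array([weights[p] for p in pairs])
    probs = probs / probs.sum()
    feat_by_id = {f.id: f for f in features}

    offset_modes = np.array(precursor_offset_modes, dtype=int)
    offset_probs = np.array(precursor_offset_weights, dtype=float)
    offset_probs = offset_probs / offset_probs.sum()
    frag_lo, frag_hi = fragment_length_range

    pos_22g_cache: dict[str, np.ndarray] = {}
    picks = rng.choice(len(pairs), size=n_reads, p=probs)
    reads: list[Read] = []
    truth: list[SimReadTruth] = []
    for i, pick in enumerate(picks):
        sim_class, locus_id = pairs[pick]
        feat = feat_by_id[locus_id]
        if sim_class in ("mature_pirna", "mirna"):
            seq = feat.mature_seq
        elif sim_class == "pirna_precursor":
            offset = int(offset_modes[rng.choice(len(offset_modes), p=offset_probs)])
            if feat.strand == "+":
                seq = genome.fetch(feat.chrom, feat.start - 2, feat.end + offset, "+")
            else:
                seq = genome.fetch(feat.chrom, feat.start - offset, feat.end + 2, "-")
        elif sim_class in ("structural", "other"):
            max_len = min(frag_hi, feat.length)
            length = int(rng.integers(frag_lo, max_len + 1))
            s = int(rng.integers(feat.start, feat.end - length + 1))
            seq = genome.fetch(feat.chrom, s, s + length, feat.strand)
        elif sim_class == "twenty_two_g":
            anchors = pos_22g_cache.get(locus_id)
            if anchors is None:
                anchors = _eligible_22g_positions(genome, feat)
                pos_22g_cache[locus_id] = anchors
            length = int(rng.integers(21, 24))
            if feat.strand == "+":
                ok = anchors[anchors - length + 1 >= feat.start]
            else:
                ok = anchors[anchors + length <= feat.end]
            if ok.size == 0:
                raise SimulationError(
                    f"no eligible 5'G antisense window in target {locus_id!r}"
                )
            p = int(ok[rng.integers(ok.size)])
            if feat.strand == "+":
                seq = genome.fetch(feat.chrom, p - length + 1, p + 1, "-")
            else:
                seq = genome.fetch(feat.chrom, p, p + length, "+")
        else:  # pragma: no cover - guarded by mixture_weights
            raise SimulationError(f"unknown simulated class {sim_class!r}")
        rid = f"sim{i:07d}"
        reads.append(Read(id=rid, sequence=seq))
        truth.append(
            SimReadTruth(
                read_id=rid,
                true_class=sim_class,
                source_locus=locus_id,
                five_prime_chem=CHEMISTRY[sim_class],
            )
        )
    return reads, truth


def apply_capseq_enrichment(
    reads: list[Read], truth: list[SimReadTruth]
) -> tuple[list[Read], list[SimReadTruth]]:
    """Idealized cap-dependent enrichment: keep exactly the capped reads.

    Models the Terminator (degrades monoP) -> CIP (dephosphorylates triP)
    -> RppH (decaps) cascade as a pure, order-preserving filter on 5'-end
    chemistry.
    """
    if len(reads) != len(truth):
        raise ValueError(
            f"reads ({len(reads)}) and truth ({len(truth)}) are not aligned"
        )
    kept = [(r, t) for r, t in zip(reads, truth) if t.five_prime_chem == "cap"]
    return [r for r, _ in kept], [t for _, t in kept]
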