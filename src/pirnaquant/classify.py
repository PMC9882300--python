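"""Read-class taxonomy: assign every aligned read to exactly one class.

Class definitions (all require a perfect alignment):

* ``structural_sense`` — sense overlap with an rRNA/tRNA/snoRNA/snRNA
  feature; treated downstream as degradation products and excluded from the
  RPM denominator.
* ``pirna_precursor`` — sense read whose 5' end sits exactly 2 nt upstream
  of a piRNA locus' mature 5' end and which contains the full mature
  sequence; 3' readthrough past the mature end is permitted.
* ``pirna_mature`` / ``mirna_mature`` — sense read matching the annotated
  mature interval exactly: any 5' or 3' overhang (or truncation)
  disqualifies it.
* ``twenty_two_g`` — 21-23 nt read whose 5' (sequenced) base is G, aligned
  antisense to a protein-coding gene, pseudogene, or transposon.
* ``coding_sense`` — sense overlap with a protein-coding gene.
* ``other`` — everything else that aligned.

A read can qualify for several classes at different loci; it is assigned the
highest-priority class it qualifies for anywhere (structural_sense >
pirna_precursor > pirna_mature > mirna_mature > twenty_two_g > coding_sense
> other), and its fractional weight 1/n_loci is attached to each feature of
that winning class only. Precursor outranks mature because a precursor read
always also overlaps its piRNA feature; structural ranks first because those
sense reads are discarded from the normalization denominator as degraded
fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignmentRecord, Read
from .annotation import (
    STRUCTURAL_CLASSES,
    TWENTY_TWO_G_TARGET_CLASSES,
    Feature,
    FeatureClass,
    OverlapRecord,
)
from .genome import Genome

#: Assignment priority, highest first.
CLASS_PRIORITY = (
    "structural_sense",
    "pirna_precursor",
    "pirna_mature",
    "mirna_mature",
    "twenty_two_g",
    "coding_sense",
    "other",
)

_PRIORITY_RANK = {name: i for i, name in enumerate(CLASS_PRIORITY)}


@dataclass
class ClassifiedRead:
    """An aligned read with its assigned class and fractional weight.

    ``feature_hits`` lists the features of the winning class, one entry per
    qualifying (alignment, feature) pair (with multiplicity);
    ``class_locus_count`` is the number of distinct alignments that qualify
    for the winning class (all of them, for class ``other``). Each such
    alignment contributes ``weight`` = 1/n_loci, so a read whose loci all
    carry its winning class contributes exactly 1.0 in total.
    """

    read_id: str
    assigned_class: str
    feature_ids: list[str]
    weight: float
    length: int
    first_base: str
    n_loci: int
    class_locus_count: int
    feature_hits: list[str] = field(default_factory=list)


def length_filter(reads: list[Read], min_len: int, max_len: int) -> list[Read]:
    """Retain reads with min_len <= length <= max_len (inclusive), in order."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [r for r in reads if min_len <= len(r.sequence) <= max_len]


def is_mature_match(read: Read, feature: Feature, alignment: AlignmentRecord) -> bool:
    """True iff the read matches the mature annotation sense with no overhang.

    The alignment interval must equal the mature-sequence interval exactly —
    a single extra or missing base at either end disqualifies the read as a
    mature piRNA/miRNA.
    """
    if feature.mature_seq is None:
        raise ValueError(f"feature {feature.id!r} has no mature sequence")
    return (
        alignment.strand == feature.strand
        and alignment.start == feature.start
        and alignment.end == feature.end
    )


def is_precursor(
    read: Read,
    feature: Feature,
    alignment: AlignmentRecord,
    genome: Genome | None = None,
) -> bool:
    """True iff the read is a piRNA precursor of ``feature``.

    The read must be sense, its 5' end exactly 2 nt upstream of the mature
    5' end (in the feature's strand frame), and it must contain the full
    mature sequence; 3' readthrough is allowed. Because alignment is exact,
    the 2-nt overhang automatically equals the genomic sequence immediately
    upstream, so no genome lookup is needed (``genome`` is accepted for
    interface symmetry).
    """
    if feature.feature_class is not FeatureClass.PIRNA or feature.mature_seq is None:
        raise ValueError(f"feature {feature.id!r} is not a piRNA locus")
    if alignment.strand != feature.strand:
        return False
    if feature.strand == "+":
        return alignment.start == feature.start - 2 and alignment.end >= feature.end
    return alignment.end == feature.end + 2 and alignment.start <= feature.start


def _candidate_class(
    read: Read, feature: Feature, ov: OverlapRecord
) -> str | None:
    """The most specific class this single (alignment, feature) pair supports."""
    aln = ov.alignment
    if feature.feature_class in STRUCTURAL_CLASSES:
        return "structural_sense" if ov.orientation == "sense" else None
    if feature.feature_class is FeatureClass.PIRNA:
        if is_precursor(read, feature, aln):
            return "pirna_precursor"
        if is_mature_match(read, feature, aln):
            return "pirna_mature"
        return None
    if feature.feature_class is FeatureClass.MIRNA:
        return "mirna_mature" if is_mature_match(read, feature, aln) else None
    if (
        feature.feature_class in TWENTY_TWO_G_TARGET_CLASSES
        and ov.orientation == "antisense"
        and 21 <= len(read.sequence) <= 23
        and read.sequence[0] == "G"
    ):
        return "twenty_two_g"
    if (
        feature.feature_class is FeatureClass.PROTEIN_CODING
        and ov.orientation == "sense"
    ):
        return "coding_sense"
    return None


def classify(
    reads: list[Read],
    alignments: list[AlignmentRecord],
    overlaps: list[OverlapRecord],
    features: list[Feature],
    genome: Genome | None = None,
) -> list[ClassifiedRead]:
    """Assign each aligned read exactly one class (see module docstring).

    Reads with no alignment are omitted. A read present in ``overlaps`` but
    absent from ``alignments`` is a consistency error.
    """
    read_by_id = {r.id: r for r in reads}
    feat_by_id = {f.id: f for f in features}

    aln_by_read: dict[str, list[AlignmentRecord]] = {}
    for aln in alignments:
        aln_by_read.setdefault(aln.read_id, []).append(aln)

    ov_by_read: dict[str, list[OverlapRecord]] = {}
    for ov in overlaps:
        if ov.read_id not in aln_by_read:
            raise ValueError(
                f"overlap for read {ov.read_id!r} has no matching alignment"
            )
        ov_by_read.setdefault(ov.read_id, []).append(ov)

    out: list[ClassifiedRead] = []
    for read_id in sorted(aln_by_read):
        read = read_by_id[read_id]
        alns = aln_by_read[read_id]
        n_loci = alns[0].n_loci
        weight = 1.0 / n_loci

        best_rank = _PRIORITY_RANK["other"]
        # class -> {alignment key -> [feature ids]}
        qualifying: dict[str, dict[tuple, list[str]]] = {}
        for ov in ov_by_read.get(read_id, ()):
            feat = feat_by_id[ov.feature_id]
            cls = _candidate_class(read, feat, ov)
            if cls is None:
                continue
            akey = (ov.alignment.chrom, ov.alignment.start, ov.alignment.strand)
            qualifying.setdefault(cls, {}).setdefault(akey, []).append(feat.id)
            best_rank = min(best_rank, _PRIORITY_RANK[cls])

        winner = CLASS_PRIORITY[best_rank]
        if winner == "other":
            out.append(
                ClassifiedRead(
                    read_id=read_id,
                    assigned_class="other",
                    feature_ids=[],
                    weight=weight,
                    length=len(read.sequence),
                    first_base=read.sequence[0],
                    n_loci=n_loci,
                    class_locus_count=n_loci,
                )
            )
            continue
        by_aln = qualifying[winner]
        hits = sorted(fid for fids in by_aln.values() for fid in fids)
        out.append(
            ClassifiedRead(
                read_id=read_id,
                assigned_class=winner,
                feature_ids=sorted(set(hits)),
                weight=weight,
                length=len(read.sequence),
                first_base=read.sequence[0],
                n_loci=n_loci,
                class_locus_count=len(by_aln),
                feature_hits=hits,
            )
        )
    return out
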