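"""Genomic features and read-feature overlap.

The overlap step is the package's equivalent of ``bedtools intersect``: any
alignment sharing at least one base with a feature produces a record, with
orientation (sense/antisense) and containment flags used by the classifier.
All intervals are 0-based half-open, so [a,b) and [b,c) do not overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from intervaltree import IntervalTree

from .align import AlignmentRecord

logger = logging.getLogger(__name__)


class FeatureClass(str, Enum):
    RRNA = "rRNA"
    TRNA = "tRNA"
    SNORNA = "snoRNA"
    SNRNA = "snRNA"
    MIRNA = "miRNA"
    PIRNA = "piRNA"
    PROTEIN_CODING = "protein_coding"
    PSEUDOGENE = "pseudogene"
    TRANSPOSON = "transposon"
    SIMPLE_REPEAT = "simple_repeat"
    SATELLITE = "satellite"


#: Sense reads over these classes are treated as degradation products and
#: excluded from the RPM denominator.
STRUCTURAL_CLASSES = frozenset(
    {FeatureClass.RRNA, FeatureClass.TRNA, FeatureClass.SNORNA, FeatureClass.SNRNA}
)

#: Classes whose antisense 21-23 nt 5'G reads are 22G-RNAs.
TWENTY_TWO_G_TARGET_CLASSES = frozenset(
    {FeatureClass.PROTEIN_CODING, FeatureClass.PSEUDOGENE, FeatureClass.TRANSPOSON}
)


@dataclass
class Feature:
    """An annotated genomic interval.

    For piRNA and miRNA features the interval is the mature-sequence span:
    the genome slice at (chrom, start, end, strand) equals ``mature_seq``.
    ``pirna_type`` distinguishes type I loci (upstream Ruby motif, SNPC-4
    dependent transcription) from type II loci (no motif). ``gene_class``
    labels protein-coding genes by the Argonaute pathway their antisense
    22G-RNAs feed (CSR-1 licensing vs WAGO silencing).
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_class: FeatureClass
    pirna_type: str | None = None
    mature_seq: str | None = None
    gene_class: str | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.feature_class, str):
            self.feature_class = FeatureClass(self.feature_class)
        if self.start >= self.end:
            raise ValueError(f"feature {self.id!r}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.id!r}: strand must be + or -")
        if (self.pirna_type is not None) != (self.feature_class is FeatureClass.PIRNA):
            raise ValueError(
                f"feature {self.id!r}: pirna_type is required for piRNA "
                "features and forbidden otherwise"
            )
        if self.pirna_type is not None and self.pirna_type not in {"I", "II"}:
            raise ValueError(f"feature {self.id!r}: pirna_type must be I or II")
        needs_mature = self.feature_class in {FeatureClass.PIRNA, FeatureClass.MIRNA}
        if (self.mature_seq is not None) != needs_mature:
            raise ValueError(
                f"feature {self.id!r}: mature_seq is required for piRNA/miRNA "
                "features and forbidden otherwise"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OverlapRecord:
    """One (alignment, feature) pair sharing at least one base."""

    read_id: str
    alignment: AlignmentRecord
    feature_id: str
    orientation: str  # "sense" | "antisense"
    containment: str  # "contained" | "partial"


def build_feature_trees(features: list[Feature]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees keyed by chromosome name."""
    trees: dict[str, IntervalTree] = {}
    for feat in features:
        trees.setdefault(feat.chrom, IntervalTree()).addi(feat.start, feat.end, feat)
    return trees


def overlap(
    alignments: list[AlignmentRecord], features: list[Feature]
) -> list[OverlapRecord]:
    """All (alignment, feature) pairs with >= 1 shared base.

    Orientation is sense iff the alignment strand equals the feature strand;
    containment is ``contained`` iff the alignment interval lies fully inside
    the feature interval. Alignments on chromosomes absent from the
    annotation produce no records (logged once).
    """
    trees = build_feature_trees(features)
    records: list[OverlapRecord] = []
    missing_chroms: set[str] = set()
    # memoized per distinct interval: duplicated reads share query results
    hit_cache: dict[tuple[str, int, int], list[Feature]] = {}
    for aln in alignments:
        tree = trees.get(aln.chrom)
        if tree is None:
            missing_chroms.add(aln.chrom)
            continue
        key = (aln.chrom, aln.start, aln.end)
        hits = hit_cache.get(key)
        if hits is None:
            hits = sorted(
                (iv.data for iv in tree.overlap(aln.start, aln.end)),
                key=lambda f: (f.start, f.end, f.id),
            )
            hit_cache[key] = hits
        for feat in hits:
            contained = feat.start <= aln.start and aln.end <= feat.end
            records.append(
                OverlapRecord(
                    read_id=aln.read_id,
                    alignment=aln,
                    feature_id=feat.id,
                    orientation="sense" if aln.strand == feat.strand else "antisense",
                    containment="contained" if contained else "partial",
                )
            )
    if missing_chroms:
        logger.info(
            "overlap: alignments on %d chromosome(s) absent from the annotation: %s",
            len(missing_chroms),
            ", ".join(sorted(missing_chroms)),
        )
    return records
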