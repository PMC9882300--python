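"""File-format I/O: FASTA/FASTQ, GFF3, BED, SAM, and TSV tables.

Internal coordinates are 0-based half-open; GFF3 (1-based inclusive) and
SAM (1-based) conversion happens only here. FASTA/FASTQ go through
Biopython; tables go through pandas.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentRecord, Read
from .annotation import Feature
from .classify import ClassifiedRead
from .genome import Genome, revcomp
from .quantify import CountTable, FoldChangeResult
from .simulate import SimReadTruth

#: Constant FASTQ quality character (no error model is simulated).
FASTQ_QUALITY = "I"


# --- FASTA / FASTQ ---------------------------------------------------------

def read_fasta_genome(path) -> Genome:
    return Genome(
        {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    )


def write_fasta_genome(genome: Genome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chroms.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path) -> list[Read]:
    """Read a FASTQ (.fq/.fastq) or FASTA library."""
    path = str(path)
    fmt = "fastq" if path.endswith((".fq", ".fastq")) else "fasta"
    return [Read(id=rec.id, sequence=str(rec.seq).upper()) for rec in SeqIO.parse(path, fmt)]


def write_reads(reads: list[Read], path) -> None:
    """Write a library as FASTQ (.fq/.fastq, constant quality) or FASTA."""
    path = str(path)
    if path.endswith((".fq", ".fastq")):
        with open(path, "w") as fh:
            for r in reads:
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{FASTQ_QUALITY * len(r.sequence)}\n")
    else:
        records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in reads]
        SeqIO.write(records, path, "fasta")


# --- GFF3 ------------------------------------------------------------------

_GFF_ATTR_FIELDS = ("pirna_type", "mature_seq", "gene_class")


def write_gff3(features: list[Feature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.id}", f"feature_class={f.feature_class.value}"]
            for name in _GFF_ATTR_FIELDS:
                value = getattr(f, name)
                if value is not None:
                    attrs.append(f"{name}={value}")
            for k in sorted(f.attributes):
                attrs.append(f"{k}={f.attributes[k]}")
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        "pirnaquant",
                        f.feature_class.value,
                        str(f.start + 1),  # GFF3 is 1-based inclusive
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[Feature]:
    features = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attr_col = (
                line.rstrip("\n").split("\t")
            )
            attrs = dict(
                item.split("=", 1) for item in attr_col.split(";") if "=" in item
            )
            fid = attrs.pop("ID")
            feature_class = attrs.pop("feature_class", ftype)
            known = {name: attrs.pop(name, None) for name in _GFF_ATTR_FIELDS}
            features.append(
                Feature(
                    id=fid,
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    feature_class=feature_class,
                    pirna_type=known["pirna_type"],
                    mature_seq=known["mature_seq"],
                    gene_class=known["gene_class"],
                    attributes=attrs,
                )
            )
    return features


# --- BED (+ sidecar attribute TSV) ----------------------------------------

def write_bed(features: list[Feature], bed_path, attrs_path=None) -> None:
    """6-column BED; attribute columns go to a sidecar TSV keyed by id."""
    with open(bed_path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n"
            )
    if attrs_path is not None:
        rows = []
        for f in features:
            rows.append(
                {
                    "id": f.id,
                    "feature_class": f.feature_class.value,
                    "pirna_type": f.pirna_type or "",
                    "mature_seq": f.mature_seq or "",
                    "gene_class": f.gene_class or "",
                    **f.attributes,
                }
            )
        pd.DataFrame(rows).to_csv(attrs_path, sep="\t", index=False)


def read_bed(bed_path, attrs_path) -> list[Feature]:
    attrs = pd.read_csv(attrs_path, sep="\t", dtype=str).fillna("")
    by_id = {row["id"]: row for _, row in attrs.iterrows()}
    features = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, fid, _score, strand = line.split()[:6]
            row = by_id[fid]
            extra = {
                k: v
                for k, v in row.items()
                if k
                not in {"id", "feature_class", "pirna_type", "mature_seq", "gene_class"}
                and v != ""
            }
            features.append(
                Feature(
                    id=fid,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    feature_class=row["feature_class"],
                    pirna_type=row["pirna_type"] or None,
                    mature_seq=row["mature_seq"] or None,
                    gene_class=row["gene_class"] or None,
                    attributes=extra,
                )
            )
    return features


# --- SAM -------------------------------------------------------------------

def write_sam(
    alignments: list[AlignmentRecord],
    reads: list[Read],
    genome: Genome,
    path,
) -> None:
    """Plain-text SAM with @SQ header lines and NH (locus count) tags.

    Unmapped reads are omitted; minus-strand records store the reverse
    complement of the read, per SAM convention.
    """
    seq_by_id = {r.id: r.sequence for r in reads}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in genome.lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        fh.write("@PG\tID:pirnaquant\tPN:pirnaquant\n")
        for a in alignments:
            seq = seq_by_id[a.read_id]
            flag = 0 if a.strand == "+" else 16
            stored = seq if a.strand == "+" else revcomp(seq)
            fh.write(
                f"{a.read_id}\t{flag}\t{a.chrom}\t{a.start + 1}\t255\t"
                f"{a.length}M\t*\t0\t0\t{stored}\t{'I' * a.length}\t"
                f"NH:i:{a.n_loci}\n"
            )


# --- TSV tables ------------------------------------------------------------

def write_truth_tsv(truth: list[SimReadTruth], path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": t.read_id,
                "true_class": t.true_class,
                "source_locus": t.source_locus,
                "five_prime_chem": t.five_prime_chem,
            }
            for t in truth
        ]
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[SimReadTruth]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [SimReadTruth(**row) for row in df.to_dict("records")]


def write_classified_tsv(classified: list[ClassifiedRead], path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "assigned_class": c.assigned_class,
                "feature_ids": ",".join(c.feature_ids),
                "weight": f"{c.weight:.10g}",
                "length": c.length,
                "first_base": c.first_base,
                "n_loci": c.n_loci,
            }
            for c in classified
        ]
    ).to_csv(path, sep="\t", index=False)


def write_count_tables(table: CountTable, prefix) -> None:
    """Write per-class and per-feature count/RPM tables as TSV."""
    prefix = Path(prefix)
    cls_rpm = {} if table.degenerate else table.per_class_rpm
    pd.DataFrame(
        [
            {"class": cls, "count": table.per_class[cls], "rpm": cls_rpm.get(cls, "")}
            for cls in sorted(table.per_class)
        ]
    ).to_csv(f"{prefix}.per_class.tsv", sep="\t", index=False)
    feat_counts = table.per_feature
    feat_rpm = {} if table.degenerate else table.per_feature_rpm
    pd.DataFrame(
        [
            {"feature_id": fid, "count": feat_counts[fid], "rpm": feat_rpm.get(fid, "")}
            for fid in sorted(feat_counts)
        ]
    ).to_csv(f"{prefix}.per_feature.tsv", sep="\t", index=False)


def write_fold_changes_tsv(results: list[FoldChangeResult], path) -> None:
    pd.DataFrame(
        [
            {
                "key": r.key if isinstance(r.key, str) else "|".join(map(str, r.key)),
                "control_rpm": r.control_rpm,
                "treatment_rpm": r.treatment_rpm,
                "pseudocount": r.pseudocount,
                "log2fc": r.log2fc,
                "fold": r.fold,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
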