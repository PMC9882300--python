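"""End-to-end pipeline: trim -> length filter -> align -> overlap ->
classify -> count -> compare, with a reproducibility manifest.

The manifest records parameters and per-stage read attrition (input ->
length-passing -> aligned -> classified) for every library; outputs are
deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .align import GenomeIndex, Read, align_all
from .annotation import overlap
from .classify import classify, length_filter
from .io import (
    read_fasta_genome,
    read_gff3,
    read_reads,
    write_classified_tsv,
    write_count_tables,
    write_fold_changes_tsv,
)
from .quantify import count, fold_changes, precursor_histogram

logger = logging.getLogger(__name__)

#: Read-length windows (inclusive): standard small-RNA and CapSeq analyses.
SMALL_RNA_WINDOW = (17, 40)
CAPSEQ_WINDOW = (17, 100)


class PipelineConfigError(ValueError):
    """The pipeline configuration is invalid."""


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    genome: str
    annotation: str
    libraries: dict[str, str]  # condition name -> FASTQ/FASTA path
    control: str
    output_dir: str
    length_window: tuple[int, int] | None = None  # default depends on capseq
    capseq: bool = False
    adapter: str | None = None
    pseudocount: float = 0.1
    snpc4_quantile: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.control not in self.libraries:
            raise PipelineConfigError(
                f"control condition {self.control!r} is not among the libraries"
            )
        window = self.window
        if window[0] > window[1] or window[0] < 1:
            raise PipelineConfigError(f"invalid length window {window}")
        for name, path in [("genome", self.genome), ("annotation", self.annotation)] + [
            (f"library {cond!r}", p) for cond, p in self.libraries.items()
        ]:
            if not Path(path).exists():
                raise PipelineConfigError(f"{name} path does not exist: {path}")

    @property
    def window(self) -> tuple[int, int]:
        if self.length_window is not None:
            return tuple(self.length_window)
        return CAPSEQ_WINDOW if self.capseq else SMALL_RNA_WINDOW

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "length_window" in data and data["length_window"] is not None:
            data["length_window"] = tuple(data["length_window"])
        return cls(**data)


def trim_adapter(reads: list[Read], adapter: str, min_match: int = 8) -> list[Read]:
    """Clip each read at the first exact occurrence of the adapter prefix.

    The match uses the first ``min_match`` bases of the adapter (or the
    whole adapter if shorter); reads without a match pass through
    unchanged. Reads trimmed to nothing are dropped (and would in any case
    be removed by the length filter).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    probe = adapter[:min_match]
    out = []
    for r in reads:
        pos = r.sequence.find(probe)
        if pos == -1:
            out.append(r)
        elif pos > 0:
            out.append(Read(id=r.id, sequence=r.sequence[:pos]))
        # pos == 0: adapter dimer, nothing left of the insert
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages for every library and write tables + manifest.

    Returns the manifest dictionary. Per condition, writes classified reads,
    per-class/per-feature count tables, and (for non-control conditions)
    fold-change tables for the ``class`` and ``feature`` groupings; for
    CapSeq runs, the unique-precursor length histogram as well.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = read_fasta_genome(config.genome)
    features = read_gff3(config.annotation)
    index = GenomeIndex(genome)
    lo, hi = config.window

    manifest: dict = {
        "pirnaquant_version": __version__,
        "parameters": {
            "control": config.control,
            "length_window": [lo, hi],
            "capseq": config.capseq,
            "adapter": config.adapter,
            "pseudocount": config.pseudocount,
            "snpc4_quantile": config.snpc4_quantile,
            "seed": config.seed,
        },
        "conditions": {},
    }

    tables = {}
    for cond in sorted(config.libraries):
        reads = read_reads(config.libraries[cond])
        n_input = len(reads)
        if config.adapter:
            reads = trim_adapter(reads, config.adapter)
        reads = length_filter(reads, lo, hi)
        n_length = len(reads)
        alignments = align_all(reads, index)
        aligned_ids = {a.read_id for a in alignments}
        n_aligned = len(aligned_ids)
        overlaps = overlap(alignments, features)
        classified = classify(reads, alignments, overlaps, features, genome)
        table = count(classified, features)
        tables[cond] = table

        write_classified_tsv(classified, outdir / f"{cond}.classified.tsv")
        write_count_tables(table, outdir / f"{cond}.counts")
        if config.capseq:
            seqs = {r.id: r.sequence for r in reads}
            hist = precursor_histogram(classified, seqs)
            with open(outdir / f"{cond}.precursor_hist.tsv", "w") as fh:
                fh.write("length\tunique_sequences\n")
                for length in sorted(hist.counts):
                    fh.write(f"{length}\t{hist.counts[length]}\n")
            manifest["conditions"].setdefault(cond, {})["precursor_peaks"] = hist.peaks

        stage_counts = {
            "input": n_input,
            "length_passing": n_length,
            "aligned": n_aligned,
            "classified": len(classified),
        }
        manifest["conditions"].setdefault(cond, {})["attrition"] = stage_counts
        logger.info("pipeline[%s]: %s", cond, stage_counts)

    control_table = tables[config.control]
    for cond in sorted(config.libraries):
        if cond == config.control:
            continue
        if tables[cond].degenerate or control_table.degenerate:
            which = cond if tables[cond].degenerate else config.control
            logger.warning(
                "pipeline[%s]: library %r is degenerate (no usable reads); "
                "fold changes skipped", cond, which,
            )
            manifest["conditions"][cond]["degenerate"] = True
            continue
        for group_by in ("class", "feature"):
            fc = fold_changes(
                tables[cond],
                control_table,
                pseudocount=config.pseudocount,
                group_by=group_by,
            )
            write_fold_changes_tsv(
                fc, outdir / f"{cond}.foldchange.{group_by}.tsv"
            )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
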