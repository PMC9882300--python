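"""Shared fixtures: tiny hand-built genomes and a default simulation."""

from __future__ import annotations

import numpy as np
import pytest

from pirnaquant.align import Read
from pirnaquant.annotation import Feature
from pirnaquant.genome import Genome, revcomp
from pirnaquant.simulate import ConditionSpec, SimGenomeConfig, simulate_genome


def make_random_genome(rng, n_chroms=1, length=2000) -> Genome:
    bases = np.array(list("ACGT"))
    return Genome(
        {
            f"chr{i + 1}": "".join(rng.choice(bases, size=length))
            for i in range(n_chroms)
        }
    )


def brute_force_align(reads, genome):
    """Naive O(n*m) both-strand scan; the aligner's independent oracle."""
    from pirnaquant.align import AlignmentRecord

    records = []
    for read in reads:
        m = len(read.sequence)
        hits = []
        rc = revcomp(read.sequence)
        for chrom in sorted(genome.chroms):
            seq = genome.chroms[chrom]
            for i in range(len(seq) - m + 1):
                window = seq[i : i + m]
                if window == read.sequence:
                    hits.append((chrom, i, "+"))
                if window == rc:
                    hits.append((chrom, i, "-"))
        hits.sort()
        for chrom, start, strand in hits:
            records.append(
                AlignmentRecord(
                    read_id=read.id,
                    chrom=chrom,
                    start=start,
                    length=m,
                    strand=strand,
                    n_loci=len(hits),
                )
            )
    return records


def brute_force_overlap(alignments, features):
    """Quadratic all-pairs >=1-base overlap; the overlap oracle."""
    pairs = []
    for aln in alignments:
        for feat in features:
            if feat.chrom != aln.chrom:
                continue
            if aln.start < feat.end and feat.start < aln.end:
                pairs.append(
                    (
                        aln.read_id,
                        aln.chrom,
                        aln.start,
                        aln.strand,
                        feat.id,
                        "sense" if aln.strand == feat.strand else "antisense",
                        "contained"
                        if feat.start <= aln.start and aln.end <= feat.end
                        else "partial",
                    )
                )
    return sorted(pairs)


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated genome + annotation, shared across tests."""
    return simulate_genome(SimGenomeConfig(seed=11))


@pytest.fixture()
def control_condition():
    return ConditionSpec.control()


@pytest.fixture()
def tiny_genome():
    # 21-nt piRNA mature at [30, 51) on +; its 2-nt upstream overhang and
    # readthrough room are plain genome sequence
    rng = np.random.default_rng(5)
    g = make_random_genome(rng, n_chroms=1, length=200)
    seq = list(g.chroms["chr1"])
    mature = "T" + "".join(rng.choice(np.array(list("ACGT")), size=20))
    seq[30:51] = list(mature)
    genome = Genome({"chr1": "".join(seq)})
    feature = Feature(
        id="pirna_t1",
        chrom="chr1",
        start=30,
        end=51,
        strand="+",
        feature_class="piRNA",
        pirna_type="I",
        mature_seq=mature,
    )
    return genome, feature


def read_at(genome: Genome, chrom: str, start: int, end: int, strand: str, rid: str) -> Read:
    return Read(id=rid, sequence=genome.fetch(chrom, start, end, strand))
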