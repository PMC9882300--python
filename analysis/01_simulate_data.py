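"""Generate the simulated genome, annotation, and condition libraries.

Writes the full data set (FASTA genome, GFF3/BED annotation, FASTQ
libraries, truth tables) under scratch/sim/ for the downstream drivers and
a compact summary of what was simulated to results/01_simulation_summary.tsv.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from pirnaquant import io as pio
from pirnaquant.simulate import (
    ConditionSpec,
    SimGenomeConfig,
    simulate_genome,
    simulate_library,
)

SEED = 1
N_READS = 100_000
ROOT = Path(__file__).resolve().parents[1]

CONDITIONS = {
    "control": ConditionSpec.control(),
    "ints-1": ConditionSpec("ints-1", class_fold={"mature_pirna": 0.3}),
}


def main() -> None:
    outdir = ROOT / "scratch" / "sim"
    outdir.mkdir(parents=True, exist_ok=True)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    config = SimGenomeConfig(seed=SEED)
    genome, features = simulate_genome(config)
    pio.write_fasta_genome(genome, outdir / "genome.fa")
    pio.write_gff3(features, outdir / "annotation.gff3")
    pio.write_bed(features, outdir / "annotation.bed", outdir / "annotation.attrs.tsv")

    rows = []
    feature_counts = Counter(f.feature_class.value for f in features)
    for fclass, n in sorted(feature_counts.items()):
        rows.append({"item": f"loci::{fclass}", "value": n})

    for i, (name, cond) in enumerate(sorted(CONDITIONS.items())):
        reads, truth = simulate_library(
            genome, features, cond, N_READS, seed=SEED + 100 + i
        )
        pio.write_reads(reads, outdir / f"{name}.fq")
        pio.write_truth_tsv(truth, outdir / f"{name}.truth.tsv")
        for cls, n in sorted(Counter(t.true_class for t in truth).items()):
            rows.append({"item": f"reads::{name}::{cls}", "value": n})
        print(f"{name}: {len(reads)} reads -> {outdir / (name + '.fq')}")

    pd.DataFrame(rows).to_csv(results / "01_simulation_summary.tsv", sep="\t", index=False)
    print(f"genome: {sum(genome.lengths.values())} nt over {len(genome)} chromosomes, "
          f"{len(features)} features")
    print(f"summary -> {results / '01_simulation_summary.tsv'}")


if __name__ == "__main__":
    main()
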