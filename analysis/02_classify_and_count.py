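"""Run the full pipeline on the simulated libraries and tabulate counts.

Reads the data written by 01_simulate_data.py from scratch/sim/, runs
trim-free length filtering, exact alignment, overlap, classification, and
weighted counting for each condition, and writes per-class count/RPM
tables plus a classification-vs-truth confusion summary to results/.
"""

from pathlib import Path

import pandas as pd

from pirnaquant.io import read_truth_tsv
from pirnaquant.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SIM / "genome.fa").exists():
        raise SystemExit("run analysis/01_simulate_data.py first")
    outdir = ROOT / "scratch" / "pipeline_out"
    config = PipelineConfig(
        genome=str(SIM / "genome.fa"),
        annotation=str(SIM / "annotation.gff3"),
        libraries={
            "control": str(SIM / "control.fq"),
            "ints-1": str(SIM / "ints-1.fq"),
        },
        control="control",
        output_dir=str(outdir),
    )
    manifest = run_pipeline(config)

    frames = []
    for cond in sorted(config.libraries):
        df = pd.read_csv(outdir / f"{cond}.counts.per_class.tsv", sep="\t")
        df.insert(0, "condition", cond)
        frames.append(df)
        att = manifest["conditions"][cond]["attrition"]
        print(f"{cond}: {att['input']} reads in, {att['classified']} classified")
    pd.concat(frames).to_csv(RESULTS / "02_class_counts.tsv", sep="\t", index=False)

    # classification vs simulated truth for the control library
    truth = {t.read_id: t.true_class for t in read_truth_tsv(SIM / "control.truth.tsv")}
    classified = pd.read_csv(outdir / "control.classified.tsv", sep="\t")
    classified["true_class"] = classified["read_id"].map(truth)
    confusion = (
        classified.groupby(["true_class", "assigned_class"])
        .size()
        .reset_index(name="n_reads")
    )
    confusion.to_csv(RESULTS / "02_control_confusion.tsv", sep="\t", index=False)
    n_offdiag = 0
    mapping = {
        "mature_pirna": "pirna_mature", "mirna": "mirna_mature",
        "structural": "structural_sense", "other": "coding_sense",
        "pirna_precursor": "pirna_precursor", "twenty_two_g": "twenty_two_g",
    }
    for _, row in confusion.iterrows():
        if mapping[row["true_class"]] != row["assigned_class"]:
            n_offdiag += int(row["n_reads"])
    print(f"misclassified reads vs truth: {n_offdiag}")
    print(f"tables -> {RESULTS / '02_class_counts.tsv'}, "
          f"{RESULTS / '02_control_confusion.tsv'}")


if __name__ == "__main__":
    main()
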