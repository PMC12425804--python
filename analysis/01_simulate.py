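"""Generate the synthetic degron-titration experiment.

Emits the dose design (control + five depletion levels, two replicates),
the toy genome annotation (TSSs, CTCF sites), the peak set with its
ground-truth archetypes, and NB count matrices for peaks and genes.
"""

import argparse
from pathlib import Path

from brgdose import SimConfig, make_dose_design
from brgdose.synthetic import (
    simulate_counts,
    simulate_expression_counts,
    simulate_genome_annotation,
    simulate_truth,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    design = make_dose_design()
    sim = SimConfig(seed=args.seed)
    tss, ctcf = simulate_genome_annotation(sim)
    peaks, truth = simulate_truth(sim, (tss, ctcf))
    counts = simulate_counts(design, truth, sim)
    gene_counts, lengths, gene_truth = simulate_expression_counts(design, sim)

    design.to_tsv(args.out / "design.tsv")
    tss.to_bed(args.out / "tss.bed")
    ctcf.to_bed(args.out / "ctcf.bed")
    peaks.to_bed(args.out / "peaks.bed")
    truth.to_csv(args.out / "peak_truth.tsv", sep="\t")
    counts.to_tsv(args.out / "peak_counts.tsv")
    gene_counts.to_tsv(args.out / "gene_counts.tsv")
    lengths.to_frame().to_csv(args.out / "gene_lengths.tsv", sep="\t")
    gene_truth.to_csv(args.out / "gene_truth.tsv", sep="\t")

    by_class = truth["element_class"].value_counts()
    dependent = (truth["archetype"] != "unaffected").sum()
    print(f"design: {len(design.sample_ids)} samples over {design.n_distinct_fractions} doses")
    print(f"peaks: {len(truth)} ({dict(by_class)}), {dependent} dose-dependent")
    print(f"genes: {len(gene_truth)}, "
          f"{(gene_truth['archetype'] != 'unaffected').sum()} responsive, "
          f"{gene_truth['low_expression'].sum()} low-expression")
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
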