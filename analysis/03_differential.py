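"""Call dose-dependent peaks (DARs) and differentially expressed genes.

Peaks: omnibus NB-GLM likelihood-ratio test across doses, FDR < 0.05.
Genes: the same test on FPKM-filtered genes with the additional
|fold change| > 1.5 gate; downregulated genes are then classified as
linear or buffered.
"""

import argparse
from pathlib import Path

from brgdose import SimConfig, make_dose_design, percent
from brgdose.counts import CountMatrix
from brgdose.differential import (
    call_differential,
    compute_fpkm,
    estimate_dispersions,
    nb_glm_lrt,
)
from brgdose.dose_response import fit_features
from brgdose.intervals import annotate_elements
from brgdose.normalization import normalize_to_control, upper_quartile_factors
from brgdose.synthetic import (
    simulate_counts,
    simulate_expression_counts,
    simulate_genome_annotation,
    simulate_truth,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/differential"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    design = make_dose_design()
    sim = SimConfig(seed=args.seed)
    annotation_sets = simulate_genome_annotation(sim)
    peaks, truth = simulate_truth(sim, annotation_sets)
    counts = simulate_counts(design, truth, sim)

    # --- differentially accessible peaks ---
    factors = upper_quartile_factors(counts)
    offsets = counts.library_size * factors
    disp = estimate_dispersions(counts, design, offsets)
    lrt = nb_glm_lrt(counts, design, disp, offsets)
    dars = call_differential(lrt, alpha=0.05, min_fold=None)
    dars.to_csv(args.out / "dar_calls.tsv", sep="\t")

    classes = annotate_elements(peaks, *annotation_sets)
    dep_down = dars.index[dars["dependent"] & (dars["direction"] == "down")]
    print(f"DARs: {len(dep_down)} of {len(dars)} peaks lose accessibility "
          f"({percent(len(dep_down), len(dars))}%)")
    for cls in ("promoter", "enhancer", "insulator"):
        ids = classes.index[classes == cls]
        n_dep = len(ids.intersection(dep_down))
        print(f"  {cls}: {n_dep}/{len(ids)} dependent ({percent(n_dep, len(ids))}%)")

    # --- differentially expressed genes ---
    gene_counts, lengths, gene_truth = simulate_expression_counts(design, sim)
    fpkm, expressed = compute_fpkm(gene_counts, design.control_samples)
    expr = CountMatrix(gene_counts.counts.loc[expressed],
                       lengths=lengths.loc[expressed],
                       library_size=gene_counts.library_size)
    gfactors = upper_quartile_factors(expr)
    goffsets = expr.library_size * gfactors
    gdisp = estimate_dispersions(expr, design, goffsets)
    glrt = nb_glm_lrt(expr, design, gdisp, goffsets)
    degs = call_differential(glrt, alpha=0.05, min_fold=1.5)
    degs.to_csv(args.out / "deg_calls.tsv", sep="\t")

    down = degs.index[degs["dependent"] & (degs["direction"] == "down")]
    up = degs.index[degs["dependent"] & (degs["direction"] == "up")]
    print(f"genes: {int(expressed.sum())} expressed of {len(gene_counts.counts)} "
          f"(FPKM > 1 in control)")
    print(f"DEGs: {len(down)} down ({percent(len(down), len(degs))}%), "
          f"{len(up)} up ({percent(len(up), len(degs))}%)")

    # dose-response class of the downregulated genes
    grel = normalize_to_control(expr, gfactors, design.control_samples)
    gfits = fit_features(grel.rc.loc[grel.rc.index.intersection(down)], design)
    n_buf = int((gfits["class"] == "buffered").sum())
    gfits.to_csv(args.out / "down_gene_fits.tsv", sep="\t")
    print(f"downregulated genes: {n_buf} buffered "
          f"({percent(n_buf, len(gfits))}%), "
          f"{len(gfits) - n_buf} linear ({percent(len(gfits) - n_buf, len(gfits))}%)")


if __name__ == "__main__":
    main()
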