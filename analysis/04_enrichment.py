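"""Sensitivity grouping and enrichment of dependent enhancers.

Ranks BRG1-dependent enhancers by delta into five equal-count groups
(G1 most buffered ... G5 most linear), tests each group's element-class
composition against all peaks with Fisher's exact test, and runs a
shuffled-background enrichment of the dependent peaks over the toy
genome's element territories.
"""

import argparse
from pathlib import Path

import pandas as pd

from brgdose import SimConfig, make_dose_design
from brgdose.differential import bh_adjust, call_differential, estimate_dispersions, nb_glm_lrt
from brgdose.dose_response import assign_groups, fit_features
from brgdose.enrichment import enrichment_vs_shuffled, fisher_two_by_two, haldane_odds_ratio
from brgdose.intervals import IntervalSet, annotate_elements
from brgdose.normalization import (
    filter_extreme, normalize_to_control, upper_quartile_factors, zscore_features,
)
from brgdose.synthetic import simulate_counts, simulate_genome_annotation, simulate_truth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/enrichment"))
    ap.add_argument("--n-shuffles", type=int, default=10)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    design = make_dose_design()
    sim = SimConfig(seed=args.seed)
    annotation_sets = simulate_genome_annotation(sim)
    peaks, truth = simulate_truth(sim, annotation_sets)
    counts = simulate_counts(design, truth, sim)
    classes = annotate_elements(peaks, *annotation_sets)

    factors = upper_quartile_factors(counts)
    offsets = counts.library_size * factors
    disp = estimate_dispersions(counts, design, offsets)
    calls = call_differential(nb_glm_lrt(counts, design, disp, offsets))
    dep_down = calls.index[calls["dependent"] & (calls["direction"] == "down")]

    rel = normalize_to_control(counts, factors, design.control_samples)
    rc = rel.rc.loc[rel.usable]
    mask = filter_extreme(zscore_features(rc))
    fits = fit_features(rc.loc[mask.index[mask["include"]]], design)

    dep_enh = fits.loc[
        fits.index.intersection(dep_down).intersection(classes.index[classes == "enhancer"])
    ]
    groups = assign_groups(dep_enh)
    groups.to_frame().to_csv(args.out / "groups.tsv", sep="\t")
    print(f"{len(dep_enh)} dependent enhancers -> groups "
          f"{groups.value_counts().sort_index().to_dict()}")

    rows = []
    for g in sorted(groups.unique()):
        g_ids = groups.index[groups == g]
        for cls in ("promoter", "enhancer", "insulator"):
            a = int((classes.reindex(g_ids) == cls).sum())
            c = int((classes == cls).sum()) - a
            table = [[a, len(g_ids) - a], [c, len(classes) - len(g_ids) - c]]
            try:
                oddsr, p = fisher_two_by_two(table)
            except ValueError:
                oddsr, p = float("nan"), float("nan")
            rows.append({"group": g, "element_class": cls, "n": a,
                         "odds_ratio": oddsr,
                         "odds_ratio_haldane": haldane_odds_ratio(table), "p": p})
    enr = pd.DataFrame(rows)
    enr["q"] = bh_adjust(enr["p"])
    enr.to_csv(args.out / "group_element_enrichment.tsv", sep="\t", index=False)

    # dependent peaks vs shuffled background over element territories
    genome = dict(sim.genome)
    tss, ctcf = annotation_sets
    tss_win = tss.df.copy()
    tss_win["start"] = (tss_win["start"] - sim.promoter_window).clip(lower=0)
    tss_win["end"] = tss_win["end"] + sim.promoter_window
    categories = {"promoter_territory": IntervalSet(tss_win), "ctcf_territory": ctcf}
    dep_set = peaks.subset(dep_down)
    shuf = enrichment_vs_shuffled(dep_set, categories, genome,
                                  n_shuffles=args.n_shuffles, seed=args.seed)
    shuf.to_csv(args.out / "shuffled_background_enrichment.tsv", sep="\t")
    print("dependent peaks vs shuffled background:")
    print(shuf[["target_in", "background_in", "odds_ratio", "obs_exp", "p", "q"]]
          .round(4).to_string())


if __name__ == "__main__":
    main()
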