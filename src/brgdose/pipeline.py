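"""End-to-end driver: simulate (or load) a titration experiment, then
normalize, filter, call dependent features, classify dose responses,
group, annotate, enrich and call superenhancers.

Every percentage in the summary report is stored together with its
numerator and denominator, so headline fractions are always auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential as diff
from . import dose_response as dr
from . import normalization as norm
from .counts import CountMatrix
from .design import DoseDesign, make_dose_design
from .enrichment import fisher_two_by_two, group_composition, haldane_odds_ratio
from .intervals import IntervalSet, annotate_elements
from .superenhancer import call_superenhancers, se_dependency_summary, stitch_regions
from .synthetic import (
    SimConfig,
    simulate_counts,
    simulate_expression_counts,
    simulate_genome_annotation,
    simulate_truth,
)

__all__ = ["PipelineConfig", "run_pipeline", "percent"]

log = logging.getLogger("brgdose")


def percent(numerator: int, denominator: int, digits: int = 1) -> float:
    """100 * n / d with half-up rounding at ``digits`` decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-digits)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def _frac(n: int, d: int, digits: int = 1) -> dict:
    return {"n": int(n), "d": int(d), "pct": percent(n, d, digits) if d else None}


@dataclass
class PipelineConfig:
    """Inputs, thresholds and stage toggles for one pipeline run.

    Either ``synthetic`` is set (the generator provides all inputs) or
    the data fields (``design``, ``counts``, ``peaks``, ``tss``,
    ``ctcf``) are supplied directly.
    """

    synthetic: SimConfig | None = None
    design: DoseDesign | None = None
    counts: CountMatrix | None = None
    peaks: IntervalSet | None = None
    tss: IntervalSet | None = None
    ctcf: IntervalSet | None = None

    quantile: float = 0.95
    z_threshold: float = 2.5
    alpha: float = 0.05
    deg_min_fold: float = 1.5
    n_groups: int = 5
    promoter_window: int = 1000
    stitch_gap: int = 12_500
    seed: int = 0

    stages: dict = field(
        default_factory=lambda: {
            "dependency": True,
            "respond": True,
            "annotate": True,
            "enrich": True,
            "superenhancer": True,
            "expression": True,
        }
    )

    def validate(self) -> None:
        if self.synthetic is None and (self.design is None or self.counts is None):
            raise ValueError(
                "config needs either a synthetic block or design+counts inputs"
            )


def _write(outdir: Path | None, name: str, df: pd.DataFrame) -> None:
    if outdir is not None:
        df.to_csv(outdir / name, sep="\t")


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run all enabled stages; return the summary report dict.

    With an output directory, per-stage TSV/BED artifacts and a
    ``summary.json`` are written. The run is deterministic given the
    config (including its seed).
    """
    config.validate()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": config.seed, "stages": {}}
    truth = gene_truth = None

    if config.synthetic is not None:
        sim = config.synthetic
        design = make_dose_design()
        tss, ctcf = simulate_genome_annotation(sim)
        peaks, truth = simulate_truth(sim, (tss, ctcf))
        counts = simulate_counts(design, truth, sim)
        log.info("simulated %d peaks, %d samples", len(truth), len(design.sample_ids))
        if outdir is not None:
            design.to_tsv(outdir / "design.tsv")
            peaks.to_bed(outdir / "peaks.bed")
            tss.to_bed(outdir / "tss.bed")
            ctcf.to_bed(outdir / "ctcf.bed")
            counts.to_tsv(outdir / "peak_counts.tsv")
            truth.to_csv(outdir / "truth.tsv", sep="\t")
    else:
        design, counts = config.design, config.counts
        peaks, tss, ctcf = config.peaks, config.tss, config.ctcf

    # --- normalization (always on: downstream stages need it) ---
    factors = norm.upper_quartile_factors(counts, config.quantile)
    rel = norm.normalize_to_control(counts, factors, design.control_samples)
    rc = rel.rc.loc[rel.usable]
    zm = norm.zscore_features(rc)
    mask = norm.filter_extreme(zm, config.z_threshold)
    included = mask.index[mask["include"]]
    report["stages"]["normalize"] = {
        "n_features": len(counts.counts),
        "n_usable": int(rel.usable.sum()),
        "n_modeled": len(included),
        "excluded_extreme": int((mask["reason"] == "extreme_z").sum()),
        "factors": {s: float(f) for s, f in factors.items()},
    }
    _write(outdir, "exclusion_mask.tsv", mask)

    # --- dependency calls (differential accessibility) ---
    calls = None
    if config.stages.get("dependency", True):
        offsets = counts.library_size * factors
        disp = diff.estimate_dispersions(counts, design, offsets)
        lrt = diff.nb_glm_lrt(counts, design, disp, offsets)
        calls = diff.call_differential(lrt, alpha=config.alpha, min_fold=None)
        dep_down = calls["dependent"] & (calls["direction"] == "down")
        report["stages"]["dependency"] = {
            "common_dispersion": disp.common,
            "n_dependent": _frac(int(calls["dependent"].sum()), len(calls)),
            "n_down": int(dep_down.sum()),
            "n_up": int((calls["direction"] == "up").sum()),
        }
        _write(outdir, "dependency_calls.tsv", calls)

    # --- dose-response modeling ---
    fits = None
    if config.stages.get("respond", True):
        fits = dr.fit_features(rc.loc[included], design)
        n_lin = int((fits["class"] == "linear").sum())
        report["stages"]["respond"] = {
            "n_fitted": len(fits),
            "linear": _frac(n_lin, len(fits)),
            "buffered": _frac(len(fits) - n_lin, len(fits)),
            "delta_median": float(fits["delta"].median()),
        }
        if truth is not None:
            overlap = fits.index.intersection(
                truth.index[truth["archetype"] != "unaffected"]
            )
            confusion = pd.crosstab(
                truth.loc[overlap, "archetype"], fits.loc[overlap, "class"]
            )
            report["stages"]["respond"]["truth_confusion"] = confusion.to_dict()
            _write(outdir, "respond_confusion.tsv", confusion)
        _write(outdir, "response_fits.tsv", fits)

    # --- element annotation ---
    annotation = None
    if config.stages.get("annotate", True) and peaks is not None and tss is not None:
        annotation = annotate_elements(peaks, tss, ctcf, config.promoter_window)
        comp = annotation.value_counts()
        report["stages"]["annotate"] = {
            cls: _frac(int(comp.get(cls, 0)), len(annotation))
            for cls in ("promoter", "enhancer", "insulator")
        }
        _write(outdir, "element_annotation.tsv", annotation.to_frame())

    # --- grouping + element enrichment per group ---
    groups = None
    if (
        config.stages.get("enrich", True)
        and fits is not None
        and calls is not None
        and annotation is not None
    ):
        dep_ids = calls.index[calls["dependent"] & (calls["direction"] == "down")]
        dep_fit = fits.loc[fits.index.intersection(dep_ids)]
        per_class = {}
        for cls in ("promoter", "enhancer", "insulator"):
            cls_ids = annotation.index[annotation == cls]
            n_dep = len(dep_fit.index.intersection(cls_ids))
            per_class[cls] = _frac(n_dep, len(cls_ids)) if len(cls_ids) else None
        report["stages"]["dependent_by_class"] = per_class

        dep_enh = dep_fit.loc[
            dep_fit.index.intersection(annotation.index[annotation == "enhancer"])
        ]
        enrich_rows = []
        if len(dep_enh) >= config.n_groups:
            groups = dr.assign_groups(dep_enh, config.n_groups)
            comp = group_composition(
                groups, annotation.reindex(groups.index), "element_class"
            )
            # element-class enrichment of each group against all annotated peaks
            for g in sorted(groups.unique()):
                g_ids = groups.index[groups == g]
                for cls in ("promoter", "enhancer", "insulator"):
                    a = int((annotation.reindex(g_ids) == cls).sum())
                    b = len(g_ids) - a
                    c = int((annotation == cls).sum()) - a
                    d_cell = len(annotation) - len(g_ids) - c
                    table = [[a, b], [c, d_cell]]
                    try:
                        oddsr, p = fisher_two_by_two(table)
                    except ValueError:
                        oddsr, p = np.nan, np.nan
                    obs = a / len(g_ids)
                    exp = (a + c) / len(annotation)
                    enrich_rows.append(
                        {
                            "group": g,
                            "element_class": cls,
                            "a": a,
                            "b": b,
                            "c": c,
                            "d": d_cell,
                            "odds_ratio": oddsr,
                            "odds_ratio_haldane": haldane_odds_ratio(table),
                            "p": p,
                            "obs_exp": obs / exp if exp else np.nan,
                        }
                    )
            lin_enh = int((dep_enh["class"] == "linear").sum())
            report["stages"]["enrich"] = {
                "n_dependent_enhancers": len(dep_enh),
                "group_sizes": groups.value_counts().sort_index().to_dict(),
                "dependent_enhancer_linear": _frac(lin_enh, len(dep_enh)),
            }
            _write(outdir, "groups.tsv", groups.to_frame())
            if enrich_rows:
                enr = pd.DataFrame(enrich_rows)
                enr["q"] = diff.bh_adjust(enr["p"])
                _write(outdir, "group_enrichment.tsv", enr.set_index("group"))

    # --- superenhancers ---
    if (
        config.stages.get("superenhancer", True)
        and annotation is not None
        and peaks is not None
    ):
        enh_ids = set(annotation.index[annotation == "enhancer"])
        control_signal = norm.normalize_counts(counts, factors)[
            design.control_samples
        ].mean(axis=1)
        enh_df = peaks.df[peaks.df["id"].isin(enh_ids)].copy()
        enh_df["score"] = control_signal.reindex(enh_df["id"]).to_numpy()
        stitched = stitch_regions(IntervalSet(enh_df), gap=config.stitch_gap)
        if len(stitched) >= 2:
            se = call_superenhancers(stitched)
            dep_ids = (
                set(calls.index[calls["dependent"] & (calls["direction"] == "down")])
                if calls is not None
                else set()
            )
            summary = se_dependency_summary(se, dep_ids, groups)
            n_se = len(summary)
            se_block = {
                "n_stitched": len(stitched),
                "n_se": n_se,
                "se_dependent": _frac(int(summary["dependent"].sum()), n_se)
                if n_se
                else None,
            }
            if groups is not None and n_se:
                se_block["se_per_group"] = (
                    summary["group"].value_counts().sort_index().to_dict()
                )
            report["stages"]["superenhancer"] = se_block
            if outdir is not None:
                se.intervals(se_only=True).to_bed(outdir / "superenhancers.bed")
                _write(outdir, "se_summary.tsv", summary)

    # --- expression ---
    if config.stages.get("expression", True) and config.synthetic is not None:
        gene_counts, lengths, gene_truth = simulate_expression_counts(
            design, config.synthetic
        )
        fpkm, expressed = diff.compute_fpkm(gene_counts, design.control_samples)
        expr_counts = CountMatrix(
            gene_counts.counts.loc[expressed],
            lengths=lengths.loc[expressed],
            library_size=gene_counts.library_size,
        )
        goffsets = expr_counts.library_size * norm.upper_quartile_factors(
            expr_counts, config.quantile
        )
        gdisp = diff.estimate_dispersions(expr_counts, design, goffsets)
        glrt = diff.nb_glm_lrt(expr_counts, design, gdisp, goffsets)
        deg = diff.call_differential(glrt, alpha=config.alpha, min_fold=config.deg_min_fold)
        down_ids = deg.index[deg["dependent"] & (deg["direction"] == "down")]
        gfactors = norm.upper_quartile_factors(expr_counts, config.quantile)
        grel = norm.normalize_to_control(expr_counts, gfactors, design.control_samples)
        expr_block = {
            "n_genes": len(gene_counts.counts),
            "n_expressed": _frac(int(expressed.sum()), len(gene_counts.counts)),
            "deg_down": _frac(len(down_ids), len(deg)),
            "deg_up": _frac(int((deg["direction"] == "up").sum()), len(deg)),
        }
        if len(down_ids):
            gfits = dr.fit_features(
                grel.rc.loc[grel.rc.index.intersection(down_ids)], design
            )
            n_buf = int((gfits["class"] == "buffered").sum())
            expr_block["downregulated_buffered"] = _frac(n_buf, len(gfits))
            if gene_truth is not None:
                resp = gene_truth.loc[
                    gfits.index.intersection(
                        gene_truth.index[gene_truth["archetype"] != "unaffected"]
                    )
                ]
                expr_block["down_truth_buffered"] = _frac(
                    int((resp["archetype"] == "buffered").sum()), len(resp)
                ) if len(resp) else None
            _write(outdir, "gene_response_fits.tsv", gfits)
        report["stages"]["expression"] = expr_block
        _write(outdir, "deg_calls.tsv", deg)

    if outdir is not None:
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
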