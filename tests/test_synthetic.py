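import numpy as np
import pandas as pd
import pytest

from brgdose.counts import CountMatrix
from brgdose.differential import compute_fpkm
from brgdose.dose_response import evaluate_template
from brgdose.intervals import annotate_elements
from brgdose.synthetic import (
    SimConfig,
    default_peak_counts,
    simulate_counts,
    simulate_expression_counts,
    simulate_genome_annotation,
    simulate_truth,
)
from tests.conftest import archetype_truth, simulate_flat_library


class TestGenomeAnnotation:
    def test_seed_determinism_byte_identical_bed(self, tmp_path):
        cfg = SimConfig(seed=1)
        for name in ("a", "b"):
            tss, ctcf = simulate_genome_annotation(cfg)
            tss.to_bed(tmp_path / f"tss_{name}.bed")
            ctcf.to_bed(tmp_path / f"ctcf_{name}.bed")
        assert (tmp_path / "tss_a.bed").read_bytes() == (tmp_path / "tss_b.bed").read_bytes()
        assert (tmp_path / "ctcf_a.bed").read_bytes() == (tmp_path / "ctcf_b.bed").read_bytes()

    def test_tss_are_single_bp_and_ctcf_fixed_width(self):
        cfg = SimConfig(seed=2)
        tss, ctcf = simulate_genome_annotation(cfg)
        assert (tss.lengths() == 1).all()
        assert (ctcf.lengths() == cfg.ctcf_width).all()
        assert len(tss) == cfg.n_tss and len(ctcf) == cfg.n_ctcf

    def test_ctcf_never_within_promoter_window_of_tss(self):
        cfg = SimConfig(seed=3)
        tss, ctcf = simulate_genome_annotation(cfg)
        cls = annotate_elements(ctcf, tss, ctcf, cfg.promoter_window)
        assert (cls == "insulator").all()

    def test_overfull_genome_errors(self):
        cfg = SimConfig(
            seed=0, genome=(("chrS", 5_000),), n_tss=0, n_ctcf=10,
            spacing=2_600, promoter_window=1000, peak_width=400, ctcf_width=200,
        )
        with pytest.raises(ValueError, match="genome too small"):
            simulate_genome_annotation(cfg)

    def test_no_tss_yields_no_promoters_downstream(self):
        cfg = SimConfig(seed=4, n_tss=0,
                        n_features={("enhancer", "unaffected"): 50,
                                    ("insulator", "unaffected"): 20})
        ann = simulate_genome_annotation(cfg)
        peaks, truth = simulate_truth(cfg, ann)
        cls = annotate_elements(peaks, *ann, cfg.promoter_window)
        assert set(cls) <= {"enhancer", "insulator"}


class TestTruth:
    def test_default_element_fractions_match_target(self):
        cfg = SimConfig(seed=5)
        _, truth = simulate_truth(cfg, simulate_genome_annotation(cfg))
        frac = truth["element_class"].value_counts(normalize=True)
        assert frac["promoter"] == pytest.approx(0.239, abs=0.02)
        assert frac["enhancer"] == pytest.approx(0.650, abs=0.02)
        assert frac["insulator"] == pytest.approx(0.111, abs=0.02)

    def test_annotation_round_trip_recovers_every_class(self):
        cfg = SimConfig(seed=6)
        ann = simulate_genome_annotation(cfg)
        peaks, truth = simulate_truth(cfg, ann)
        recovered = annotate_elements(peaks, *ann, cfg.promoter_window)
        assert (recovered.reindex(truth.index) == truth["element_class"]).all()

    def test_all_unaffected_config_has_no_dependent_truth(self):
        cfg = SimConfig(seed=7, n_features={("enhancer", "unaffected"): 100})
        _, truth = simulate_truth(cfg, simulate_genome_annotation(cfg))
        assert (truth["archetype"] == "unaffected").all()

    def test_baseline_means_positive(self):
        cfg = SimConfig(seed=8)
        _, truth = simulate_truth(cfg, simulate_genome_annotation(cfg))
        assert (truth["baseline_mean"] > 0).all()

    def test_too_many_peaks_for_annotation_errors(self):
        cfg = SimConfig(seed=9, n_tss=5,
                        n_features={("promoter", "unaffected"): 10})
        with pytest.raises(ValueError, match="TSS"):
            simulate_truth(cfg, simulate_genome_annotation(cfg))


class TestCounts:
    def test_seed_determinism(self, design):
        truth = archetype_truth(5, 5, 5)
        c1 = simulate_counts(design, truth, SimConfig(seed=10))
        c2 = simulate_counts(design, truth, SimConfig(seed=10))
        assert c1.counts.equals(c2.counts)

    def test_flat_template_means_track_baseline(self, design):
        truth = archetype_truth(0, 0, 10_000, baseline=200.0)
        cm = simulate_counts(design, truth, SimConfig(seed=11, dispersion=1e-9))
        means = cm.counts.mean(axis=0)
        assert np.allclose(means, 200.0, rtol=0.01)

    def test_linear_template_column_ratio(self, design):
        """At protein fraction p the linear archetype's column mean over its
        control is within the CLT band around p (10,000 features)."""
        truth = archetype_truth(10_000, 0, 0)
        cm = simulate_counts(design, truth, SimConfig(seed=12, dispersion=0.05))
        ctrl = cm.counts[design.control_samples].to_numpy().mean()
        half_idx = np.argmin(np.abs(design.protein_fractions - 0.5))
        col = design.sample_ids[half_idx]
        p = design.protein_fractions[half_idx]
        ratio = cm.counts[col].mean() / ctrl
        assert 0.47 * (p / 0.5) <= ratio <= 0.53 * (p / 0.5)

    def test_moment_convergence_all_archetypes(self, design):
        truth = pd.concat(
            [archetype_truth(4000, 0, 0),
             archetype_truth(0, 4000, 0).set_index(pd.Index([f"b{i}" for i in range(4000)])),
             archetype_truth(0, 0, 4000).set_index(pd.Index([f"u{i}" for i in range(4000)]))]
        )
        cm = simulate_counts(design, truth, SimConfig(seed=13, dispersion=0.05))
        p = design.protein_fractions
        for archetype, prefix in (("linear", "f"), ("buffered", "b"), ("unaffected", "u")):
            rows = [i for i in truth.index if i.startswith(prefix)]
            sub = cm.counts.loc[rows]
            expected = (
                np.ones_like(p) if archetype == "unaffected"
                else np.asarray(evaluate_template(archetype, p))
            ) * 500.0
            observed = sub.mean(axis=0).to_numpy()
            se = sub.std(axis=0, ddof=1).to_numpy() / np.sqrt(len(rows))
            assert (np.abs(observed - expected) < 3 * se + 1e-9).all()

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimConfig(seed=0, dispersion=-0.1)


class TestExpression:
    def test_responsive_genes_mostly_buffered_by_construction(self, design):
        cm, lengths, truth = simulate_expression_counts(design, SimConfig(seed=14))
        responsive = truth[truth["archetype"] != "unaffected"]
        assert len(responsive) == 500
        assert (responsive["archetype"] == "buffered").mean() >= 0.70

    def test_low_expression_stratum_below_fpkm_one(self, design):
        cm, lengths, truth = simulate_expression_counts(design, SimConfig(seed=15))
        fpkm, expressed = compute_fpkm(cm, design.control_samples)
        low = truth.index[truth["low_expression"]]
        assert (~expressed.loc[low]).all()

    def test_seed_determinism(self, design):
        a = simulate_expression_counts(design, SimConfig(seed=16))
        b = simulate_expression_counts(design, SimConfig(seed=16))
        assert a[0].counts.equals(b[0].counts)
        assert a[2].equals(b[2])


def test_default_peak_counts_sum_and_mix():
    counts = default_peak_counts(2000)
    assert sum(counts.values()) == 2000
    per_class = {}
    for (cls, _), n in counts.items():
        per_class[cls] = per_class.get(cls, 0) + n
    assert per_class["promoter"] == 478 and per_class["insulator"] == 222
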