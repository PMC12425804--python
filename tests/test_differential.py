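import subprocess

import numpy as np
import pandas as pd
import pytest

from brgdose.counts import CountMatrix
from brgdose.differential import (
    bh_adjust,
    call_differential,
    compute_fpkm,
    estimate_dispersions,
    nb_glm_lrt,
)
from tests.conftest import archetype_truth, simulate_flat_library


class TestDispersions:
    def test_poisson_truth_recovered_near_zero(self, design, unit_library):
        truth = archetype_truth(0, 0, 10_000, baseline=200.0)
        cm = simulate_flat_library(design, truth, seed=30, dispersion=0.0)
        est = estimate_dispersions(cm, design, unit_library)
        assert est.per_feature.median() <= 0.01

    def test_nb_dispersion_recovered_within_tolerance(self, design, unit_library):
        truth = archetype_truth(0, 0, 10_000, baseline=500.0)
        cm = simulate_flat_library(design, truth, seed=31, dispersion=0.2)
        est = estimate_dispersions(cm, design, unit_library)
        assert 0.15 <= est.per_feature.median() <= 0.25

    def test_constant_rows_shrink_to_common(self, design, unit_library):
        counts = pd.DataFrame(
            np.full((3, 12), 50), index=["a", "b", "c"], columns=design.sample_ids
        )
        est = estimate_dispersions(CountMatrix(counts, library_size=unit_library),
                                   design, unit_library)
        # zero within-group variance per feature: only the (zero) common
        # dispersion remains after shrinkage
        assert (est.per_feature == 0).all()

    def test_single_sample_errors(self, design):
        counts = pd.DataFrame({"only": [1, 2, 3]}, index=list("abc"))
        with pytest.raises(ValueError, match=">=2"):
            estimate_dispersions(CountMatrix(counts), design)


class TestLRT:
    def test_strong_effect_detected(self, design, unit_library):
        """A feature losing signal linearly from mean 500 is detected at
        vanishing p (4-fold-plus drop at the deepest doses)."""
        truth = archetype_truth(100, 0, 0, baseline=500.0)
        cm = simulate_flat_library(design, truth, seed=32, dispersion=0.05)
        disp = estimate_dispersions(cm, design, unit_library)
        res = nb_glm_lrt(cm, design, disp, unit_library)
        assert (res["p"] < 1e-6).all()
        assert (res["log2fc"] < 0).all()

    def test_df_equals_doses_minus_one(self, design, unit_library):
        truth = archetype_truth(0, 0, 10, baseline=100.0)
        cm = simulate_flat_library(design, truth, seed=33, dispersion=0.05)
        disp = estimate_dispersions(cm, design, unit_library)
        res = nb_glm_lrt(cm, design, disp, unit_library)
        assert (res["df"] == 5).all()

    def test_per_dose_contrasts_emitted(self, design, unit_library):
        truth = archetype_truth(0, 0, 10, baseline=100.0)
        cm = simulate_flat_library(design, truth, seed=34, dispersion=0.05)
        disp = estimate_dispersions(cm, design, unit_library)
        res = nb_glm_lrt(cm, design, disp, unit_library, per_dose=True)
        extra = [c for c in res.columns if c.startswith("p_")]
        assert len(extra) == 5  # one contrast per non-control dose
        assert res[extra].notna().all().all()

    def test_matches_edger_on_tiny_fixture(self, design, unit_library, tmp_path):
        """Independent cross-check: p-values agree in rank with edgeR's
        glmFit/glmLRT on a 50-feature fixture, and every true effect is
        overwhelming in both engines."""
        truth = pd.concat(
            [archetype_truth(0, 0, 30, baseline=300.0),
             archetype_truth(10, 10, 0, baseline=300.0).set_index(
                 pd.Index([f"hit{i:02d}" for i in range(20)]))]
        )
        cm = simulate_flat_library(design, truth, seed=5, dispersion=0.05)
        disp = estimate_dispersions(cm, design, unit_library)
        res = nb_glm_lrt(cm, design, disp, unit_library)

        cm.counts.to_csv(tmp_path / "counts.tsv", sep="\t")
        groups = design.dose_groups().reindex(cm.sample_ids)
        pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(
            tmp_path / "groups.tsv", sep="\t", index=False
        )
        script = f"""
suppressMessages(library(edgeR))
x <- read.delim("{tmp_path}/counts.tsv", row.names=1)
g <- read.delim("{tmp_path}/groups.tsv")
group <- factor(g$group, levels=unique(g$group))
y <- DGEList(counts=x, group=group)
y$samples$norm.factors <- 1
design <- model.matrix(~group)
y <- estimateGLMCommonDisp(y, design)
y <- estimateGLMTagwiseDisp(y, design)
fit <- glmFit(y, design)
lrt <- glmLRT(fit, coef=2:ncol(design))
write.table(data.frame(id=rownames(x), p=lrt$table$PValue),
            "{tmp_path}/edger.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
"""
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True,
                       capture_output=True, timeout=300)
        edger = pd.read_csv(tmp_path / "edger.tsv", sep="\t", index_col=0)["p"]
        edger = edger.reindex(res.index)

        from scipy.stats import spearmanr
        rho = spearmanr(res["p"], edger).statistic
        assert rho > 0.9
        hits = [i for i in truth.index if i.startswith("hit")]
        assert (res.loc[hits, "p"] < 1e-6).all()
        assert (edger.loc[hits] < 1e-4).all()


class TestBH:
    def test_step_up_hand_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_q_follows_features_not_order(self):
        p = pd.Series([0.5, 0.001, 0.04], index=["a", "b", "c"])
        q1 = bh_adjust(p)
        q2 = bh_adjust(p.iloc[[2, 0, 1]])
        assert np.allclose(q1.sort_index(), q2.sort_index())

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=100))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all() and (q <= 1).all() and (q >= p).all()


class TestCalls:
    def frame(self, p, fc):
        return pd.DataFrame({"p": p, "log2fc": np.log2(fc)},
                            index=[f"f{i}" for i in range(len(p))])

    def test_deg_gate_requires_both_fdr_and_fold(self):
        # single hypotheses: q == p
        res = call_differential(self.frame([0.04], [1.4]), min_fold=1.5)
        assert not res["dependent"].iloc[0]
        res = call_differential(self.frame([0.04], [1 / 2.0]), min_fold=1.5)
        assert res["dependent"].iloc[0] and res["direction"].iloc[0] == "down"
        res = call_differential(self.frame([0.06], [3.0]), min_fold=1.5)
        assert not res["dependent"].iloc[0]

    def test_dar_mode_ignores_fold(self):
        res = call_differential(self.frame([0.01], [1.1]), min_fold=None)
        assert res["dependent"].iloc[0]

    def test_direction_none_for_uncalled(self):
        res = call_differential(self.frame([0.9], [4.0]), min_fold=None)
        assert res["direction"].iloc[0] == "none"

    def test_q_at_least_p(self):
        rng = np.random.default_rng(1)
        res = call_differential(self.frame(rng.uniform(size=50), rng.uniform(0.5, 2, 50)))
        assert (res["q"] >= res["p"] - 1e-15).all()


class TestFPKM:
    def make(self, counts, lengths, lib):
        idx = [f"g{i}" for i in range(len(counts))]
        cm = CountMatrix(
            pd.DataFrame({"s": counts}, index=idx),
            lengths=pd.Series(lengths, index=idx, dtype=float),
            library_size=pd.Series({"s": lib}),
        )
        return compute_fpkm(cm, "s")

    def test_unit_arithmetic(self):
        fpkm, expressed = self.make([100], [1000], 1e6)
        assert fpkm.loc["g0", "s"] == pytest.approx(100.0)
        assert expressed["g0"]

    def test_low_expression_excluded(self):
        fpkm, expressed = self.make([1, 0], [2000, 1000], 1e6)
        assert fpkm.loc["g0", "s"] == pytest.approx(0.5)
        assert not expressed["g0"] and not expressed["g1"]

    def test_threshold_is_strict(self):
        fpkm, expressed = self.make([1], [1000], 1e6)
        assert fpkm.loc["g0", "s"] == pytest.approx(1.0)
        assert not expressed["g0"]  # FPKM must exceed 1

    def test_nonpositive_length_errors(self):
        with pytest.raises(ValueError, match="positive"):
            self.make([5], [0], 1e6)
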