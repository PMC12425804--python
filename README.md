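# brgdose

Dosage-sensitivity analysis for targeted-degradation titration
experiments, built around the question: when a chromatin regulator such
as BRG1 (the mSWI/SNF ATPase) is degraded to a known residual level, does
a genomic feature's signal fall **linearly** with the protein, or is it
**buffered** — held near control until deep depletion?

The package is organised as an analysis project: the library under
`src/brgdose/` carries every computation, the numbered scripts under
`analysis/` run the study end to end on a synthetic titration with known
ground truth, and `tests/` checks each stage against independent oracles.

## The model

Samples are indexed by the residual protein fraction *p* (control
*p* = 1, from western-blot quantification). For each feature, counts are
normalized to the control sample ("RC", so RC(control) = 1) and compared
against two fixed response templates:

- linear: retained(p) = *p*
- buffered: retained(p) = 1 − (1 − *p*)³

Both satisfy retained(1) = 1 and retained(0) = 0; at half protein the
buffered curve still retains 87.5% of control signal where the linear
curve retains 50%. Each template is fitted by ordinary least squares with
a free intercept and slope, and the classification statistic is

Δ = RSS_buffered − RSS_linear

so Δ > 0 marks a linear responder and Δ ≤ 0 a buffered one. Because the
fits are affine, the sign of Δ equals the sign of r²_linear − r²_buffered
(squared Pearson correlation with each template) — an identity the test
suite uses as an independent oracle. Dependent enhancers are ranked by Δ
into five equal-count sensitivity groups, G1 (most buffered) … G5 (most
linear).

Around this core the package provides: upper-quartile size factors and
control-relative normalization; an extreme-z exclusion filter; a
negative-binomial GLM likelihood-ratio test for dose-dependent features
(FDR < 0.05; genes additionally gated at |fold change| > 1.5 after an
FPKM > 1 expression filter); regulatory-element annotation (promoter =
within ±1 kb of a TSS, insulator = CTCF overlap, enhancer = the rest);
Fisher-exact enrichment against shuffled-interval backgrounds; and
ROSE-style superenhancer calling (12.5 kb stitching, slope-1 cutoff on
the scaled rank-signal curve).

## Worked example

```
python analysis/01_simulate.py --seed 1
python analysis/02_dose_response.py --seed 1
python analysis/03_differential.py --seed 1
python analysis/04_enrichment.py --seed 1
python analysis/05_superenhancers.py --seed 1
```

The generator produces a control plus five depletion levels (protein
fractions 1.0, 0.78, 0.55, 0.30, 0.12, 0.05; two replicates), 2,000 peaks
(23.9% promoters, 65.0% enhancers, 11.1% insulators; 44.2% of enhancers
dose-dependent) and 3,000 genes. With `--seed 1` the drivers print:

```
fitted 1951 of 2000 peaks (49 excluded)
linear 984 (50.4%), buffered 967 (49.6%)
templates at half protein: buffered retains 87.5%, linear 50.0%
```

— the class mix of the modeled peaks and the template predictions —

```
DARs: 704 of 2000 peaks lose accessibility (35.2%)
  promoter: 82/478 dependent (17.2%)
  enhancer: 581/1300 dependent (44.7%)
  insulator: 41/222 dependent (18.5%)
DEGs: 503 down (18.6%), 5 up (0.2%)
downregulated genes: 385 buffered (76.5%), 118 linear (23.5%)
```

— dependent-feature calls, closely tracking the generator's planted
fractions (16.1/44.2/17.8% dependent; 84.4% of responsive genes
buffered) — and

```
stitched 754 regions from 1300 enhancers; 149 superenhancers above the slope-1 cutoff
116 (77.9%) of superenhancers are BRG1-dependent
```

Tables and BED files land under `results/` (`response_fits.tsv`,
`dar_calls.tsv`, `groups.tsv`, `superenhancers.bed`, …). All outputs are
deterministic given the seed.

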