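"""Synthetic degron-titration experiment with known ground truth.

The generator emulates the data shape of a chromatin-remodeler degron
titration: a control plus five depletion levels with known residual
protein fractions, negative-binomial count matrices for peaks
(binding/accessibility) and genes (expression), and a toy genome
annotation (TSSs and CTCF sites) that makes every peak's regulatory
element class unambiguous by construction.

Per-feature expected counts follow one of three dose-response
archetypes in the protein fraction ``p``:

* ``linear`` — retained = p
* ``buffered`` — retained = 1 - (1 - p)^3
* ``unaffected`` — retained = 1

so expected count for feature *f* in sample *j* is
``L_j * b_f * r_a(p_j)`` with ``L_j`` the sample's library-size factor
(control = 1) and ``b_f`` a log-normal baseline mean. Counts are drawn
NB with shared dispersion phi (variance ``mu + phi mu^2``); ``phi=0``
degenerates to Poisson.

Default mixing proportions follow the titration study design this
package targets: element classes 23.9% promoter / 65.0% enhancer /
11.1% insulator; 44.2% of enhancers dose-dependent (16.1% of promoters,
17.8% of insulators); dependent promoters/insulators mostly buffered,
dependent enhancers split with a slight linear preference; and 84.4% of
dose-responsive genes buffered.

The genome layout uses a fixed slot grid (one potential feature site
per ``spacing`` bp) so that TSSs, CTCF sites and distal peaks are always
farther apart than the promoter window — annotation round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DoseDesign
from .counts import CountMatrix
from .dose_response import evaluate_template
from .intervals import IntervalSet

__all__ = [
    "SimConfig",
    "default_peak_counts",
    "simulate_genome_annotation",
    "simulate_truth",
    "simulate_counts",
    "simulate_expression_counts",
]

ARCHETYPES = ("linear", "buffered", "unaffected")
ELEMENT_CLASSES = ("promoter", "enhancer", "insulator")


def default_peak_counts(total: int = 2000) -> dict[tuple[str, str], int]:
    """Per (element_class, archetype) peak counts at the default mix.

    Element classes at 23.9/65.0/11.1%; dependent fractions 16.1%
    (promoters), 44.2% (enhancers), 17.8% (insulators); within the
    dependent features, promoters/insulators 75% buffered and enhancers
    55% linear.
    """
    n_pro = round(total * 0.239)
    n_ins = round(total * 0.111)
    n_enh = total - n_pro - n_ins
    counts = {}
    for cls, n, dep_frac, buf_frac in [
        ("promoter", n_pro, 0.161, 0.75),
        ("enhancer", n_enh, 0.442, 0.45),
        ("insulator", n_ins, 0.178, 0.75),
    ]:
        n_dep = round(n * dep_frac)
        n_buf = round(n_dep * buf_frac)
        counts[(cls, "buffered")] = n_buf
        counts[(cls, "linear")] = n_dep - n_buf
        counts[(cls, "unaffected")] = n - n_dep
    return counts


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic experiment; the seed fully determines output."""

    n_features: dict[tuple[str, str], int] = field(default_factory=default_peak_counts)
    dispersion: float = 0.05
    seed: int = 0
    genome: tuple[tuple[str, int], ...] = tuple(
        (f"chr{i}", 6_000_000) for i in range(1, 6)
    )
    n_tss: int = 600
    n_ctcf: int = 300
    promoter_window: int = 1000
    spacing: int = 10_000  # slot width; must exceed 2*window + widths
    peak_width: int = 400
    ctcf_width: int = 200
    baseline_mean: float = 500.0  # expected control count (log-normal mean)
    baseline_sdlog: float = 0.5
    library_sizes: dict[str, int] | None = None  # per-sample; default equal
    # expression block
    n_genes: int = 3000
    n_responsive_genes: int = 500
    responsive_buffered_frac: float = 0.844
    n_low_expression: int = 300
    gene_length_meanlog: float = np.log(2000.0)
    gene_length_sdlog: float = 0.4

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if any(v < 0 for v in self.n_features.values()):
            raise ValueError("feature counts must be >= 0")
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("chromosome lengths must be > 0")
        if self.spacing < 2 * self.promoter_window + self.peak_width + self.ctcf_width:
            raise ValueError(
                "spacing too small to keep element classes unambiguous: need "
                f">= {2 * self.promoter_window + self.peak_width + self.ctcf_width}"
            )

    def class_total(self, element_class: str) -> int:
        return sum(
            n for (cls, _), n in self.n_features.items() if cls == element_class
        )


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _slots(config: SimConfig) -> pd.DataFrame:
    rows = []
    for chrom, length in config.genome:
        n = length // config.spacing
        for k in range(n):
            rows.append((chrom, k * config.spacing + config.spacing // 2))
    return pd.DataFrame(rows, columns=["chrom", "center"])


def simulate_genome_annotation(config: SimConfig) -> tuple[IntervalSet, IntervalSet]:
    """Place TSSs (1 bp) and CTCF sites (fixed width) on the slot grid.

    Every placed feature sits at a distinct slot center, so any two
    features are >= ``spacing`` apart and in particular every CTCF site
    is farther than ``promoter_window`` from every TSS.
    """
    slots = _slots(config)
    needed = config.n_tss + config.n_ctcf
    if needed > len(slots):
        raise ValueError(
            f"genome too small: {needed} sites requested but only "
            f"{len(slots)} slots of {config.spacing} bp available"
        )
    rng = _rng(config, 1)
    order = rng.permutation(len(slots))
    tss_rows = slots.iloc[order[: config.n_tss]]
    ctcf_rows = slots.iloc[order[config.n_tss : needed]]
    half = config.ctcf_width // 2
    tss = IntervalSet.from_records(
        [
            (c, p, p + 1, f"tss_{i}")
            for i, (c, p) in enumerate(tss_rows.itertuples(index=False))
        ]
    )
    ctcf = IntervalSet.from_records(
        [
            (c, p - half, p - half + config.ctcf_width, f"ctcf_{i}")
            for i, (c, p) in enumerate(ctcf_rows.itertuples(index=False))
        ]
    )
    return tss.sort(), ctcf.sort()


def simulate_truth(
    config: SimConfig, genome_annotation: tuple[IntervalSet, IntervalSet]
) -> tuple[IntervalSet, pd.DataFrame]:
    """Place peaks matching the annotation rules and draw the truth table.

    Promoter peaks are centered on TSSs, insulator peaks on CTCF sites,
    enhancer peaks on unused slots; the truth table records each peak's
    archetype and log-normal baseline mean.
    """
    tss, ctcf = genome_annotation
    rng = _rng(config, 2)
    slots = _slots(config)
    tss_centers = list(tss.df[["chrom", "start"]].itertuples(index=False))
    ctcf_centers = [
        (c, s + config.ctcf_width // 2)
        for c, s in ctcf.df[["chrom", "start"]].itertuples(index=False)
    ]
    occupied = {(c, p) for c, p in tss_centers} | {(c, p) for c, p in ctcf_centers}
    free = [
        (c, p)
        for c, p in slots.itertuples(index=False)
        if (c, p) not in occupied
    ]

    n_pro = config.class_total("promoter")
    n_enh = config.class_total("enhancer")
    n_ins = config.class_total("insulator")
    if n_pro > len(tss_centers):
        raise ValueError(f"{n_pro} promoter peaks requested but only {len(tss_centers)} TSSs")
    if n_ins > len(ctcf_centers):
        raise ValueError(f"{n_ins} insulator peaks requested but only {len(ctcf_centers)} CTCF sites")
    if n_enh > len(free):
        raise ValueError(f"{n_enh} enhancer peaks requested but only {len(free)} free slots")

    half = config.peak_width // 2
    records, classes = [], []
    picks = {
        "promoter": [tss_centers[i] for i in rng.permutation(len(tss_centers))[:n_pro]],
        "insulator": [ctcf_centers[i] for i in rng.permutation(len(ctcf_centers))[:n_ins]],
        "enhancer": [free[i] for i in rng.permutation(len(free))[:n_enh]],
    }
    k = 0
    for cls in ELEMENT_CLASSES:
        for chrom, center in picks[cls]:
            records.append((chrom, max(center - half, 0), center + half, f"peak_{k:05d}"))
            classes.append(cls)
            k += 1
    peaks = IntervalSet.from_records(records)

    archetypes = np.empty(len(records), dtype=object)
    start = 0
    for cls in ELEMENT_CLASSES:
        n_cls = config.class_total(cls)
        labels = np.concatenate(
            [
                np.repeat(a, config.n_features.get((cls, a), 0))
                for a in ARCHETYPES
            ]
        )
        archetypes[start : start + n_cls] = labels[rng.permutation(n_cls)]
        start += n_cls

    meanlog = np.log(config.baseline_mean) - config.baseline_sdlog**2 / 2
    baseline = rng.lognormal(meanlog, config.baseline_sdlog, size=len(records))
    truth = pd.DataFrame(
        {
            "feature_id": [r[3] for r in records],
            "archetype": archetypes,
            "element_class": classes,
            "baseline_mean": baseline,
        }
    ).set_index("feature_id")
    return peaks, truth


def _library_factors(config: SimConfig, design: DoseDesign) -> np.ndarray:
    if config.library_sizes is None:
        return np.ones(len(design.sample_ids))
    sizes = np.array(
        [config.library_sizes[s] for s in design.sample_ids], dtype=float
    )
    ctrl = design.control_samples[0]
    return sizes / config.library_sizes[ctrl]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    lam = rng.gamma(shape, scale=mean * phi)
    return rng.poisson(lam)


def simulate_counts(
    design: DoseDesign,
    truth: pd.DataFrame,
    config: SimConfig,
    stream: int = 3,
) -> CountMatrix:
    """Draw the NB count matrix implied by the truth table and design."""
    p = design.protein_fractions
    L = _library_factors(config, design)
    retained = np.stack(
        [
            np.ones_like(p)
            if a == "unaffected"
            else np.asarray(evaluate_template(a, p))
            for a in truth["archetype"]
        ]
    )
    mean = truth["baseline_mean"].to_numpy()[:, None] * retained * L[None, :]
    rng = _rng(config, stream)
    counts = _nb_draw(rng, mean, config.dispersion)
    df = pd.DataFrame(counts, index=truth.index, columns=design.sample_ids)
    return CountMatrix(df)


def simulate_expression_counts(
    design: DoseDesign, config: SimConfig
) -> tuple[CountMatrix, pd.Series, pd.DataFrame]:
    """Gene-expression counts with lengths and a truth table.

    Three strata: a dose-responsive subset (``n_responsive_genes``,
    mostly buffered and all *down* at depletion), an unaffected expressed
    bulk, and a low-expression stratum built to sit below FPKM 1 in the
    control (long genes, tiny baseline) to exercise the expressed-gene
    filter.
    """
    rng = _rng(config, 4)
    n = config.n_genes
    if config.n_responsive_genes + config.n_low_expression > n:
        raise ValueError("responsive + low-expression strata exceed n_genes")
    n_buf = round(config.n_responsive_genes * config.responsive_buffered_frac)
    archetype = np.array(["unaffected"] * n, dtype=object)
    responsive_idx = rng.permutation(n - config.n_low_expression)[
        : config.n_responsive_genes
    ]
    archetype[responsive_idx[:n_buf]] = "buffered"
    archetype[responsive_idx[n_buf:]] = "linear"
    low = np.zeros(n, dtype=bool)
    low[n - config.n_low_expression :] = True  # last block: low-expression stratum

    meanlog = np.log(config.baseline_mean) - config.baseline_sdlog**2 / 2
    baseline = rng.lognormal(meanlog, config.baseline_sdlog, size=n)
    baseline[low] = 2.0
    lengths = rng.lognormal(
        config.gene_length_meanlog, config.gene_length_sdlog, size=n
    ).round()
    lengths[low] = 10_000.0

    truth = pd.DataFrame(
        {
            "feature_id": [f"gene_{i:05d}" for i in range(n)],
            "archetype": archetype,
            "baseline_mean": baseline,
            "low_expression": low,
        }
    ).set_index("feature_id")
    cm = simulate_counts(design, truth, config, stream=5)
    lengths = pd.Series(lengths, index=truth.index, name="length")
    cm = CountMatrix(cm.counts, lengths=lengths)
    return cm, lengths, truth
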