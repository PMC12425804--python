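"""Depth normalization, control-relative scaling, z-scores and the
extreme-feature exclusion filter.

The normalization scheme mirrors the upper-quartile approach used for
titration count data: per-library size factors from a high quantile of
the non-zero-filtered counts (default the 95% quantile), rescaled to a
geometric mean of one, then per-feature scaling to the untreated control
(the "RC" relative-signal matrix whose control column is 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountMatrix

__all__ = [
    "upper_quartile_factors",
    "normalize_counts",
    "normalize_to_control",
    "RelativeMatrix",
    "ZMatrix",
    "zscore_features",
    "filter_extreme",
]


def upper_quartile_factors(counts: CountMatrix, quantile: float = 0.95) -> pd.Series:
    """Per-sample upper-quartile normalization factors.

    Features that are zero in *all* libraries are removed first. Each
    library's factor is its ``quantile`` count quantile (linear
    interpolation, the R type-7 default) divided by its library size;
    factors are then rescaled so their geometric mean is 1. The effective
    normalized count is ``count / (library_size * factor)``.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must lie in (0, 1]")
    nz = counts.drop_all_zero()
    if len(nz.counts) == 0:
        raise ValueError("no feature has a nonzero count in any library")
    q = np.quantile(nz.values, quantile, axis=0, method="linear")
    if np.any(q == 0):
        bad = [s for s, v in zip(nz.sample_ids, q) if v == 0]
        raise ValueError(f"degenerate library: {quantile:.0%} quantile is 0 for {bad}")
    factors = q / nz.library_size.to_numpy()
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.counts.columns, name="factor")


def normalize_counts(counts: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Counts divided by ``library_size * factor`` per sample."""
    scale = counts.library_size * factors.reindex(counts.counts.columns)
    return counts.counts / scale


@dataclass(frozen=True)
class RelativeMatrix:
    """Control-relative signal ("RC"): normalized counts divided by the
    control sample's normalized count per feature.

    ``usable`` flags features with a nonzero control count; only those
    are meaningful for dose-response modeling (the rest would have
    infinite relative signal).
    """

    rc: pd.DataFrame = field(repr=False)
    usable: pd.Series = field(repr=False)
    control_sample: str | list[str] = "control"


def normalize_to_control(
    counts: CountMatrix, factors: pd.Series, control_sample
) -> RelativeMatrix:
    """Scale each feature's normalized counts to the control sample.

    ``control_sample`` may be one sample id or a list of replicate
    control ids, in which case their mean normalized count is the
    reference. Features with a zero control reference are flagged
    unusable rather than producing infinities.
    """
    norm = normalize_counts(counts, factors)
    controls = [control_sample] if isinstance(control_sample, str) else list(control_sample)
    missing = [c for c in controls if c not in norm.columns]
    if missing:
        raise ValueError(f"control sample(s) not in matrix: {missing}")
    ref = norm[controls].mean(axis=1)
    usable = ref > 0
    rc = norm.div(ref.where(usable, np.nan), axis=0)
    return RelativeMatrix(rc=rc, usable=usable.rename("usable"), control_sample=control_sample)


@dataclass(frozen=True)
class ZMatrix:
    """Per-feature z-scores across samples, with the mean/sd retained.

    ``constant`` flags features whose sd is 0 (z undefined; excluded
    downstream rather than erroring).
    """

    z: pd.DataFrame = field(repr=False)
    mean: pd.Series = field(repr=False)
    sd: pd.Series = field(repr=False)

    @property
    def constant(self) -> pd.Series:
        return (self.sd == 0).rename("constant")


def zscore_features(matrix: pd.DataFrame, ddof: int = 1) -> ZMatrix:
    """z = (x - mu) / sigma per feature across samples (sample sd, ddof=1)."""
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring needs >=2 samples")
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=ddof)
    z = matrix.sub(mu, axis=0).div(sd.where(sd > 0, np.nan), axis=0)
    return ZMatrix(z=z, mean=mu.rename("mean"), sd=sd.rename("sd"))


def filter_extreme(zm: ZMatrix, threshold: float = 2.5) -> pd.DataFrame:
    """Exclusion mask for features with an extreme z-score in any sample.

    A feature is excluded iff ``max_j |z_fj| > threshold``. Constant
    features (sd 0) are also excluded. ``threshold=inf`` disables the
    filter. Returns a DataFrame with ``include`` and ``reason`` columns.
    """
    max_abs = zm.z.abs().max(axis=1)
    extreme = max_abs > threshold
    constant = zm.constant
    include = ~(extreme | constant)
    reason = pd.Series("", index=zm.z.index, dtype=object)
    reason[extreme.fillna(False)] = "extreme_z"
    reason[constant] = "constant"
    return pd.DataFrame({"include": include.fillna(False), "reason": reason})
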