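"""Negative-binomial differential testing across the dose series.

Counts for feature *f* in sample *j* are modeled as NB with mean
``mu_fj = o_j * m`` (log link with offset ``o_j = library_size_j *
normalization_factor_j``) and variance ``mu + phi * mu^2``. The full
model gives each dose its own mean; the null model a single common mean.
Features are screened with an omnibus likelihood-ratio test on
``n_doses - 1`` degrees of freedom; per-dose contrasts against the
control are available behind a flag. Dispersions are method-of-moments
estimates shrunk toward the common dispersion.

This is a from-scratch NB GLM in the spirit of the count-model fitters
used for sequencing data; it follows the same model family but is not
numerically identical to any particular one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix
from .design import DoseDesign

__all__ = [
    "DispersionEstimate",
    "estimate_dispersions",
    "nb_glm_lrt",
    "bh_adjust",
    "call_differential",
    "compute_fpkm",
]

_EPS = 1e-12


@dataclass(frozen=True)
class DispersionEstimate:
    """Per-feature NB dispersions phi (variance = mu + phi mu^2)."""

    per_feature: pd.Series = field(repr=False)
    common: float = 0.0
    prior_weight: float = 20.0


def _group_indices(design: DoseDesign, sample_ids) -> list[np.ndarray]:
    doses = design.dose_groups().reindex(sample_ids)
    return [np.flatnonzero((doses == lab).to_numpy())
            for lab in pd.unique(doses.to_numpy())]


def estimate_dispersions(
    counts: CountMatrix,
    design: DoseDesign,
    offsets: pd.Series | None = None,
    prior_weight: float = 20.0,
) -> DispersionEstimate:
    """Method-of-moments dispersion per feature, shrunk to the common value.

    Within each dose group the depth-adjusted counts ``z = y / o`` have
    ``E[z] = m_g`` and ``Var[z] = m_g / o + phi m_g^2``; the excess of the
    pooled within-group variance over its Poisson part, scaled by
    ``m_g^2``, estimates phi (clamped at 0). The common dispersion is the
    mean of the per-feature estimates; each feature's estimate is averaged
    with it using ``prior_weight`` pseudo-samples of weight.
    """
    samples = counts.sample_ids
    if len(samples) < 2:
        raise ValueError("dispersion estimation needs >=2 samples")
    y = counts.values
    o = _offsets(counts, offsets)
    groups = _group_indices(design, samples)
    if all(len(g) < 2 for g in groups):
        # no replication: fall back to treating the whole series as one
        # group; dose structure then inflates phi, but there is no
        # replicate information to do better with.
        groups = [np.arange(len(samples))]
    z = y / o[None, :]
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    resid_df = 0
    for g in groups:
        if len(g) < 2:
            continue
        zg = z[:, g]
        m = zg.mean(axis=1)
        resid = zg - m[:, None]
        # unbiased within-group variance of z, minus its Poisson part;
        # denominator corrects E[m_hat^2] = m^2 + Var(m_hat)
        ss = (resid**2).sum(axis=1) / (len(g) - 1)
        poisson = m * np.mean(1.0 / o[g])
        num += (ss - poisson) * len(g)
        den += np.maximum(m**2 - ss / len(g), _EPS) * len(g)
        resid_df += len(g) - 1
    phi = np.clip(num / np.maximum(den, _EPS), 0.0, None)
    common = float(np.mean(phi))
    shrunk = (prior_weight * common + resid_df * phi) / (prior_weight + resid_df)
    per_feature = pd.Series(shrunk, index=counts.counts.index, name="phi")
    return DispersionEstimate(per_feature=per_feature, common=common,
                              prior_weight=prior_weight)


def _offsets(counts: CountMatrix, offsets: pd.Series | None) -> np.ndarray:
    if offsets is None:
        o = counts.library_size.to_numpy(float)
        return o / o.mean()
    o = offsets.reindex(counts.counts.columns).to_numpy(float)
    if np.any(~np.isfinite(o)) or np.any(o <= 0):
        raise ValueError("offsets must be positive and finite for all samples")
    return o / o.mean()  # mean-1 scale keeps fitted means on the count scale


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood (Poisson limit at phi=0)."""
    mu = np.maximum(mu, _EPS)
    phi2 = np.maximum(phi, 0.0)[:, None]
    pois = y * np.log(mu) - mu - special.gammaln(y + 1.0)
    r = 1.0 / np.maximum(phi2, _EPS)
    with np.errstate(invalid="ignore"):
        nb = (
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    return np.where(phi2 > 0, nb, pois).sum(axis=1)


def _fit_common_mean(
    y: np.ndarray, o: np.ndarray, phi: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """MLE of a single mean-per-feature NB model with offsets.

    Newton iterations on eta = log m, vectorized over features. Returns
    (m, converged).
    """
    tot = y.sum(axis=1)
    m = np.maximum(tot / o.sum(), _EPS)
    eta = np.log(m)
    converged = np.zeros(y.shape[0], dtype=bool)
    for _ in range(max_iter):
        mu = o[None, :] * np.exp(eta)[:, None]
        # score d l / d eta = sum_j y - mu (y + r) / (mu + r)
        r = 1.0 / np.maximum(phi, _EPS)
        with np.errstate(over="ignore"):
            score = np.where(
                phi[:, None] > 0,
                y - mu * (y + r[:, None]) / (mu + r[:, None]),
                y - mu,
            ).sum(axis=1)
        info = np.where(
            phi[:, None] > 0, mu / (1.0 + phi[:, None] * mu), mu
        ).sum(axis=1)
        step = score / np.maximum(info, _EPS)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        done = np.abs(step) < tol
        converged |= done
        if done.all():
            break
    return np.exp(eta), converged


def nb_glm_lrt(
    counts: CountMatrix,
    design: DoseDesign,
    dispersions: DispersionEstimate,
    offsets: pd.Series | None = None,
    per_dose: bool = False,
) -> pd.DataFrame:
    """Likelihood-ratio test of any dose effect per feature.

    Full model: one NB mean per dose (log link, offsets); null model: a
    single mean. The LRT statistic ``2 (l_full - l_null)`` is referred to
    a chi-square with ``n_doses - 1`` df. Features whose fits do not
    converge get ``p = NaN``. With ``per_dose=True``, additional columns
    ``p_<dose>`` hold 1-df contrasts of each non-control dose against the
    control.

    Returns a DataFrame with ``stat``, ``df``, ``p``, ``log2fc`` (most
    depleted dose vs control, normalized scale, pseudo-count 0.5) and
    ``converged``.
    """
    samples = counts.sample_ids
    y = counts.values
    o = _offsets(counts, offsets)
    phi = dispersions.per_feature.reindex(counts.counts.index).to_numpy(float)
    if np.any(phi < 0):
        raise ValueError("dispersions must be >= 0")
    groups = _group_indices(design, samples)
    if len(groups) < 2:
        raise ValueError("need >=2 dose groups for a likelihood-ratio test")

    ll_full = np.zeros(y.shape[0])
    converged = np.ones(y.shape[0], dtype=bool)
    group_means = {}
    for g, lab in zip(groups, pd.unique(design.dose_groups().reindex(samples).to_numpy())):
        m, conv = _fit_common_mean(y[:, g], o[g], phi)
        ll_full += _nb_loglik(y[:, g], o[g][None, :] * m[:, None], phi)
        converged &= conv
        group_means[lab] = m
    m0, conv0 = _fit_common_mean(y, o, phi)
    converged &= conv0
    ll_null = _nb_loglik(y, o[None, :] * m0[:, None], phi)

    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    df = len(groups) - 1
    p = stats.chi2.sf(stat, df)
    p = np.where(converged, p, np.nan)

    # fold change at the deepest depletion vs control
    ctrl_lab = design.table.loc[design.table["protein_fraction"] == 1.0, "dose_label"].iloc[0]
    dep_lab = design.most_depleted_label()
    log2fc = np.log2((group_means[dep_lab] + 0.5) / (group_means[ctrl_lab] + 0.5))

    out = pd.DataFrame(
        {"stat": stat, "df": df, "p": p, "log2fc": log2fc, "converged": converged},
        index=counts.counts.index.rename("feature_id"),
    )
    if per_dose:
        labels = pd.unique(design.dose_groups().reindex(samples).to_numpy())
        gc = groups[list(labels).index(ctrl_lab)]
        for lab, g in zip(labels, groups):
            if lab == ctrl_lab:
                continue
            cols = np.concatenate([gc, g])
            ll1 = (
                _nb_loglik(y[:, gc], o[gc][None, :] * group_means[ctrl_lab][:, None], phi)
                + _nb_loglik(y[:, g], o[g][None, :] * group_means[lab][:, None], phi)
            )
            mnull, _ = _fit_common_mean(y[:, cols], o[cols], phi)
            ll0 = _nb_loglik(y[:, cols], o[cols][None, :] * mnull[:, None], phi)
            out[f"p_{lab}"] = stats.chi2.sf(np.maximum(2 * (ll1 - ll0), 0.0), 1)
    return out


def bh_adjust(pvalues) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaNs propagate)."""
    arr = np.asarray(pvalues, dtype=float)
    q = np.full_like(arr, np.nan)
    ok = np.isfinite(arr)
    if ok.sum():
        q[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(q, index=pvalues.index, name="q")
    return q


def call_differential(
    test_results: pd.DataFrame,
    alpha: float = 0.05,
    min_fold: float | None = None,
) -> pd.DataFrame:
    """Gate features into dependency calls.

    DAR mode (``min_fold=None``): dependent iff ``q < alpha``. DEG mode
    (``min_fold=1.5``): additionally requires ``|log2fc| > log2(min_fold)``.
    ``direction`` is the sign of the fold change at the deepest depletion
    for called features, ``none`` otherwise.
    """
    out = test_results.copy()
    out["q"] = bh_adjust(out["p"])
    dependent = out["q"] < alpha
    if min_fold is not None:
        dependent &= out["log2fc"].abs() > np.log2(min_fold)
    out["dependent"] = dependent.fillna(False)
    direction = np.where(
        out["dependent"], np.where(out["log2fc"] < 0, "down", "up"), "none"
    )
    out["direction"] = direction
    return out


def compute_fpkm(
    counts: CountMatrix, control_sample=None, expressed_threshold: float = 1.0
) -> tuple[pd.DataFrame, pd.Series]:
    """FPKM per gene and the expressed-gene mask.

    FPKM = count / (length_kb * library_size_millions). A gene is
    *expressed* iff its control-sample FPKM is strictly greater than the
    threshold (default 1); lower genes are excluded from differential
    analysis. With replicate controls the mean control FPKM is used; with
    ``control_sample=None`` all samples' mean is used.
    """
    if counts.lengths is None:
        raise ValueError("gene lengths required for FPKM")
    if (counts.lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    kb = counts.lengths.to_numpy(float) / 1e3
    millions = counts.library_size.to_numpy(float) / 1e6
    fpkm = counts.counts / millions[None, :]
    fpkm = fpkm.div(kb, axis=0)
    if control_sample is None:
        ref = fpkm.mean(axis=1)
    else:
        controls = [control_sample] if isinstance(control_sample, str) else list(control_sample)
        ref = fpkm[controls].mean(axis=1)
    expressed = (ref > expressed_threshold).rename("expressed")
    return fpkm, expressed
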