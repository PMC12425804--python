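"""The core dosage-sensitivity statistic: two-template dose-response
classification by residual sum of squares.

Each feature's control-relative signal is compared against two fixed
response shapes in the protein fraction ``p`` (control ``p=1``):

* **linear** — retained signal proportional to protein level,
  ``r(p) = p``;
* **buffered** — signal held near control until deep depletion,
  ``r(p) = 1 - (1 - p)^3`` (cubic in the depletion ``d = 1 - p``).

Both templates satisfy ``r(1) = 1`` and ``r(0) = 0``; the buffered curve
dominates the linear one on (0, 1) — at half protein it still retains
87.5% of the signal where the linear template retains 50%.

Each template is fitted by ordinary least squares with a free intercept
and slope (an affine fit), so the comparison depends only on curve
*shape* and is invariant to per-feature scaling or z-scoring of the
response. The statistic is

``delta = RSS_buffered - RSS_linear``

so a positive delta means the feature tracks the linear template more
closely and a negative delta the buffered template. With the free affine
fit, the sign of delta equals the sign of
``r2_linear - r2_buffered`` (squared Pearson correlation against each
template) — an algebraic identity used as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DoseDesign

__all__ = [
    "TEMPLATES",
    "evaluate_template",
    "retained_percent",
    "classify_delta",
    "fit_features",
    "fit_feature",
    "assign_groups",
    "ResponseFit",
]


def _linear(p: np.ndarray) -> np.ndarray:
    return p


def _buffered(p: np.ndarray) -> np.ndarray:
    return 1.0 - (1.0 - p) ** 3


TEMPLATES = {"linear": _linear, "buffered": _buffered}


def evaluate_template(kind: str, p) -> np.ndarray | float:
    """Retained signal fraction predicted by a template at protein fraction p."""
    if kind not in TEMPLATES:
        raise ValueError(f"unknown template {kind!r}; expected one of {sorted(TEMPLATES)}")
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("protein fraction must lie in [0, 1]")
    out = TEMPLATES[kind](arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def retained_percent(kind: str, p: float) -> float:
    """Template-predicted retained signal as a percentage of control."""
    return 100.0 * float(evaluate_template(kind, p))


def classify_delta(delta: float) -> str:
    """delta > 0 -> linear; delta <= 0 -> buffered (ties to buffered)."""
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    return "linear" if delta > 0 else "buffered"


@dataclass(frozen=True)
class ResponseFit:
    """Per-feature two-template fit result."""

    feature_id: str
    rss_linear: float
    rss_buffered: float
    delta: float
    response_class: str
    coef_linear: tuple[float, float]  # (intercept, slope)
    coef_buffered: tuple[float, float]


def _affine_rss(y: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of each row of y on template values t (free intercept).

    Returns (rss, intercept, slope) arrays over features.
    """
    tc = t - t.mean()
    stt = float(tc @ tc)
    ym = y.mean(axis=1)
    yc = y - ym[:, None]
    sty = yc @ tc
    slope = sty / stt
    intercept = ym - slope * t.mean()
    sst = (yc**2).sum(axis=1)
    rss = sst - sty**2 / stt
    return np.maximum(rss, 0.0), intercept, slope


def fit_features(signal: pd.DataFrame, design: DoseDesign) -> pd.DataFrame:
    """Fit the linear and buffered templates to every feature.

    Parameters
    ----------
    signal:
        Features x samples response matrix — control-relative signal (RC)
        by default, but any per-feature affine transform of it (e.g.
        z-scores) yields identical classification.
    design:
        Titration design supplying each sample's protein fraction; needs
        >=3 distinct fractions.

    Returns a DataFrame indexed by feature id with columns ``rss_linear``,
    ``rss_buffered``, ``delta``, ``class`` and the affine coefficients.
    Rows with any non-finite signal are dropped.
    """
    if design.n_distinct_fractions < 3:
        raise ValueError("model fitting needs >=3 distinct protein fractions")
    missing = [s for s in design.sample_ids if s not in signal.columns]
    if missing:
        raise ValueError(f"signal matrix missing design samples: {missing}")
    mat = signal[design.sample_ids]
    finite = np.isfinite(mat.to_numpy()).all(axis=1)
    mat = mat.loc[finite]
    y = mat.to_numpy(float)
    p = design.protein_fractions
    if np.allclose(p, p[0]):
        raise ValueError("rank-deficient design: all protein fractions equal")

    t_lin = _linear(p)
    t_buf = _buffered(p)
    rss_lin, a_lin, b_lin = _affine_rss(y, t_lin)
    rss_buf, a_buf, b_buf = _affine_rss(y, t_buf)
    delta = rss_buf - rss_lin
    cls = np.where(delta > 0, "linear", "buffered")
    return pd.DataFrame(
        {
            "rss_linear": rss_lin,
            "rss_buffered": rss_buf,
            "delta": delta,
            "class": cls,
            "intercept_linear": a_lin,
            "slope_linear": b_lin,
            "intercept_buffered": a_buf,
            "slope_buffered": b_buf,
        },
        index=mat.index.rename("feature_id"),
    )


def fit_feature(rc, design: DoseDesign, feature_id: str = "feature") -> ResponseFit:
    """Single-feature convenience wrapper around :func:`fit_features`."""
    signal = pd.DataFrame([np.asarray(rc, float)], index=[feature_id],
                          columns=design.sample_ids)
    row = fit_features(signal, design).iloc[0]
    return ResponseFit(
        feature_id=feature_id,
        rss_linear=float(row["rss_linear"]),
        rss_buffered=float(row["rss_buffered"]),
        delta=float(row["delta"]),
        response_class=str(row["class"]),
        coef_linear=(float(row["intercept_linear"]), float(row["slope_linear"])),
        coef_buffered=(float(row["intercept_buffered"]), float(row["slope_buffered"])),
    )


def assign_groups(fits: pd.DataFrame, n_groups: int = 5) -> pd.Series:
    """Equal-count sensitivity groups G1..Gk by ascending delta.

    G1 collects the most buffered (most negative delta) features and the
    last group the most linear. Ties in delta break stably by feature id;
    group sizes differ by at most one (larger groups first).
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if len(fits) < n_groups:
        raise ValueError(f"need >= {n_groups} features to form {n_groups} groups")
    order = fits.assign(_id=fits.index.astype(str)).sort_values(
        ["delta", "_id"], kind="mergesort"
    ).index
    labels = np.empty(len(order), dtype=object)
    for g, chunk in enumerate(np.array_split(np.arange(len(order)), n_groups), start=1):
        labels[chunk] = f"G{g}"
    return pd.Series(labels, index=order, name="group").reindex(fits.index)
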