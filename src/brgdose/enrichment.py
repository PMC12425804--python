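"""Fisher-exact enrichment of interval sets against labeled categories,
with shuffled-interval backgrounds and observed/expected ratios."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .intervals import IntervalSet, count_overlaps, shuffle_intervals

__all__ = [
    "fisher_two_by_two",
    "enrichment_vs_shuffled",
    "group_composition",
    "haldane_odds_ratio",
]


def fisher_two_by_two(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The two-sided p sums the hypergeometric probabilities of every table
    with the same margins whose probability does not exceed the observed
    one (the R ``fisher.test`` convention). Returns ``(odds_ratio, p)``
    with the raw sample odds ratio ``ad/bc`` (inf on a zero off-diagonal
    cell).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise ValueError("table entries must be non-negative integers")
        arr = arr.astype(int)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate 2x2 table: zero margin")
    res = stats.fisher_exact(arr, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def haldane_odds_ratio(table) -> float:
    """Odds ratio with the Haldane-Anscombe 0.5 correction (finite with zeros)."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


def _hit_mask(target: IntervalSet, category: IntervalSet) -> np.ndarray:
    counts, _ = count_overlaps(target, category)
    return counts.to_numpy() > 0


def enrichment_vs_shuffled(
    target: IntervalSet,
    categories: dict[str, IntervalSet],
    genome: dict[str, int],
    n_shuffles: int = 10,
    seed: int = 0,
    within_chrom: bool = True,
) -> pd.DataFrame:
    """Category enrichment of a target set against a shuffled background.

    The background pools ``n_shuffles`` length-preserving shuffles of the
    target intervals over the genome. For each category a 2x2 table
    (target in/out of category vs background in/out) is tested with the
    two-sided Fisher exact test; q-values are BH-adjusted across
    categories and ``obs_exp`` is the ratio of the observed category hit
    frequency to the background frequency.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    shuffled = [
        shuffle_intervals(target, genome, seed=int(np.random.default_rng([seed, k]).integers(2**31)),
                          within_chrom=within_chrom)
        for k in range(n_shuffles)
    ]
    background = IntervalSet(
        pd.concat([s.df for s in shuffled], ignore_index=True)
    )
    n_t, n_b = len(target), len(background)
    rows = []
    for label, cat in categories.items():
        a = int(_hit_mask(target, cat).sum())
        c = int(_hit_mask(background, cat).sum())
        table = [[a, n_t - a], [c, n_b - c]]
        obs = a / n_t if n_t else np.nan
        exp = c / n_b if n_b else np.nan
        try:
            oddsr, p = fisher_two_by_two(table)
        except ValueError:
            # zero margin: category hit everywhere or nowhere in both sets
            oddsr, p = np.nan, np.nan
        rows.append(
            {
                "category": label,
                "target_in": a,
                "target_out": n_t - a,
                "background_in": c,
                "background_out": n_b - c,
                "odds_ratio": oddsr,
                "odds_ratio_haldane": haldane_odds_ratio(table),
                "p": p,
                "obs_exp": obs / exp if exp else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("category")
    out["q"] = bh_adjust(out["p"])
    return out


def group_composition(
    groups: pd.Series, flags: pd.Series, category_name: str = "category"
) -> pd.DataFrame:
    """Per-group composition of a boolean or categorical annotation.

    ``groups`` maps feature id -> group label (e.g. G1..G5); ``flags``
    maps feature id -> category (bool or label). Returns per-group counts
    and within-category fractions, plus the 2x2 cells for testing each
    group against the rest (for boolean flags).
    """
    df = pd.DataFrame({"group": groups, "flag": flags}).dropna(subset=["group"])
    rows = []
    if df["flag"].dtype == bool:
        total_in = int(df["flag"].sum())
        for g, sub in df.groupby("group", sort=True):
            a = int(sub["flag"].sum())
            if len(sub) == 0:
                continue
            rows.append(
                {
                    "group": g,
                    "n": len(sub),
                    "n_in_category": a,
                    "fraction_of_category": a / total_in if total_in else np.nan,
                    "in_group_in_cat": a,
                    "in_group_out_cat": len(sub) - a,
                    "out_group_in_cat": total_in - a,
                    "out_group_out_cat": len(df) - len(sub) - (total_in - a),
                }
            )
    else:
        totals = df["flag"].value_counts()
        for (g, f), sub in df.groupby(["group", "flag"], sort=True):
            rows.append(
                {
                    "group": g,
                    category_name: f,
                    "n": len(sub),
                    "fraction_of_category": len(sub) / totals[f],
                }
            )
    return pd.DataFrame(rows)
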