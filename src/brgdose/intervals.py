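"""Genomic intervals: BED I/O, consensus peaks, element annotation,
overlap counting and background shuffling.

All coordinates are 0-based half-open ``[start, end)`` throughout, the
BED convention. Overlap means >=1 bp of intersection; strand is ignored
(the annotation rules implemented here are strand-free).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "IntervalSet",
    "read_bed",
    "read_chrom_sizes",
    "consensus_peaks",
    "annotate_elements",
    "count_overlaps",
    "shuffle_intervals",
]

_COLUMNS = ["chrom", "start", "end", "id", "score"]


@dataclass(frozen=True)
class IntervalSet:
    """A set of named genomic intervals backed by a DataFrame.

    Columns: ``chrom`` (str), ``start``/``end`` (0-based half-open int),
    ``id`` (str), ``score`` (float, NaN when absent).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"interval table missing columns: {sorted(missing)}")
        if len(df):
            if (df["end"] <= df["start"]).any():
                raise ValueError("intervals must satisfy end > start")
            if (df["start"] < 0).any():
                raise ValueError("interval starts must be >= 0")
            if (df["chrom"].astype(str) == "").any():
                raise ValueError("chrom names must be non-empty")

    @classmethod
    def from_records(cls, records) -> "IntervalSet":
        """Build from (chrom, start, end[, id[, score]]) tuples."""
        rows = []
        for i, rec in enumerate(records):
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            iid = str(rec[3]) if len(rec) > 3 else f"iv_{i}"
            score = float(rec[4]) if len(rec) > 4 and rec[4] is not None else np.nan
            rows.append((str(chrom), start, end, iid, score))
        df = pd.DataFrame(rows, columns=_COLUMNS)
        return cls(df)

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(pd.DataFrame(columns=_COLUMNS).astype(
            {"chrom": str, "start": int, "end": int, "id": str, "score": float}
        ))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return list(self.df["id"])

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def sort(self) -> "IntervalSet":
        out = self.df.sort_values(
            ["chrom", "start", "end", "id"], kind="mergesort"
        ).reset_index(drop=True)
        return IntervalSet(out)

    def subset(self, ids) -> "IntervalSet":
        keep = self.df["id"].isin(set(ids))
        return IntervalSet(self.df.loc[keep].reset_index(drop=True))

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees (row index stored as payload)."""
        out: dict[str, IntervalTree] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            out[str(chrom)] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"], sub.index)
            )
        return out

    def to_bed(self, path) -> None:
        """Write sorted BED6 (strand '.', score '.' when NaN)."""
        df = self.sort().df
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for chrom, start, end, iid, score in df.itertuples(index=False):
                s = "." if pd.isna(score) else format(float(score), "g")
                fh.write(f"{chrom}\t{start}\t{end}\t{iid}\t{s}\t.\n")


def read_bed(path) -> IntervalSet:
    """Read BED3/BED6; tolerates ``track``/``browser`` lines and ``#`` comments.

    The BED name field becomes ``id`` (auto-generated when absent) and the
    score field becomes ``score`` ('.' -> NaN).
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for n, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {n + 1}: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            iid = parts[3] if len(parts) > 3 and parts[3] != "" else f"iv_{len(rows)}"
            score = np.nan
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            rows.append((chrom, start, end, iid, score))
    if not rows:
        return IntervalSet.empty()
    return IntervalSet(pd.DataFrame(rows, columns=_COLUMNS))


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV (chrom, length) -> dict."""
    out: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            out[chrom] = int(length)
    return out


def _overlap_counts(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    trees = subject.trees()
    counts = np.zeros(len(query), dtype=int)
    for i, (chrom, start, end) in enumerate(
        query.df[["chrom", "start", "end"]].itertuples(index=False)
    ):
        tree = trees.get(str(chrom))
        if tree is not None:
            counts[i] = len(tree.overlap(start, end))
    return counts


def consensus_peaks(rep1: IntervalSet, rep2: IntervalSet, merge: bool = False) -> IntervalSet:
    """Peaks detected in both biological replicates.

    Default dialect keeps the ``rep1`` intervals that overlap (>=1 bp) any
    ``rep2`` interval, anchoring coordinates on replicate 1. With
    ``merge=True`` each kept rep1 interval is union-merged with the rep2
    intervals it overlaps.
    """
    hits = _overlap_counts(rep1, rep2) > 0
    kept = rep1.df.loc[hits].reset_index(drop=True)
    if not merge or kept.empty:
        return IntervalSet(kept)
    trees = rep2.trees()
    starts, ends = [], []
    for chrom, start, end in kept[["chrom", "start", "end"]].itertuples(index=False):
        ov = trees[str(chrom)].overlap(start, end)
        starts.append(min([start] + [iv.begin for iv in ov]))
        ends.append(max([end] + [iv.end for iv in ov]))
    out = kept.copy()
    out["start"], out["end"] = starts, ends
    return IntervalSet(out)


def annotate_elements(
    peaks: IntervalSet,
    tss: IntervalSet,
    ctcf: IntervalSet,
    promoter_window: int = 1000,
) -> pd.Series:
    """Classify each peak as promoter, insulator or enhancer.

    A peak within ``promoter_window`` bp of a transcription start site is
    a promoter; otherwise, a peak overlapping a CTCF site is an insulator;
    everything else is an enhancer. Priority promoter > insulator >
    enhancer, so the classes are mutually exclusive and exhaustive.

    TSS intervals are taken as 1-bp sites; "near" means the peak intersects
    ``[site - window, site + window + 1)``.

    Returns a Series indexed by peak id.
    """
    tss_win = tss.df.copy()
    if len(tss_win):
        tss_win["start"] = (tss_win["start"] - promoter_window).clip(lower=0)
        tss_win["end"] = tss_win["end"] + promoter_window
    near_tss = _overlap_counts(peaks, IntervalSet(tss_win) if len(tss_win) else tss) > 0
    on_ctcf = _overlap_counts(peaks, ctcf) > 0
    classes = np.where(near_tss, "promoter", np.where(on_ctcf, "insulator", "enhancer"))
    return pd.Series(classes, index=pd.Index(peaks.ids, name="id"), name="element_class")


def count_overlaps(query: IntervalSet, subject: IntervalSet) -> tuple[pd.Series, int]:
    """Per-query counts of overlapping subject intervals (>=1 bp rule).

    Returns ``(counts indexed by query id, number of query intervals with
    at least one hit)``.
    """
    counts = _overlap_counts(query, subject)
    series = pd.Series(counts, index=pd.Index(query.ids, name="id"), name="n_overlaps")
    return series, int((counts > 0).sum())


def shuffle_intervals(
    intervals: IntervalSet,
    genome: dict[str, int],
    seed: int,
    within_chrom: bool = True,
) -> IntervalSet:
    """Randomly relocate intervals on the genome, preserving their lengths.

    Start positions are uniform over the valid placements. With the default
    ``within_chrom=True`` each interval stays on its own chromosome
    (preserving the chromosome composition of the set); otherwise the
    destination chromosome is drawn with probability proportional to its
    number of valid start positions.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    chrom_len = np.array([genome[c] for c in chroms], dtype=np.int64)
    rows = []
    for chrom, start, end, iid, score in intervals.df[_COLUMNS].itertuples(index=False):
        length = end - start
        if within_chrom:
            if chrom not in genome:
                raise ValueError(f"chromosome {chrom!r} missing from genome table")
            space = genome[chrom] - length
            if space < 0:
                raise ValueError(
                    f"interval {iid} ({length} bp) does not fit on {chrom}"
                )
            new_chrom = chrom
            new_start = int(rng.integers(0, space + 1))
        else:
            valid = chrom_len - length + 1
            valid = np.clip(valid, 0, None)
            total = valid.sum()
            if total == 0:
                raise ValueError(
                    f"interval {iid} ({length} bp) longer than every chromosome"
                )
            ci = rng.choice(len(chroms), p=valid / total)
            new_chrom = chroms[ci]
            new_start = int(rng.integers(0, valid[ci]))
        rows.append((new_chrom, new_start, new_start + length, iid, score))
    return IntervalSet(pd.DataFrame(rows, columns=_COLUMNS))
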