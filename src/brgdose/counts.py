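"""Integer count matrices (features x samples) shared by peak and gene data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix"]


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer counts with feature ids and sample ids.

    Parameters
    ----------
    counts:
        DataFrame indexed by feature id with one column per sample.
    lengths:
        Optional per-feature lengths in bp (needed for FPKM).
    library_size:
        Optional per-sample sequencing depth; defaults to column sums.
    """

    counts: pd.DataFrame = field(repr=False)
    lengths: pd.Series | None = field(default=None, repr=False)
    library_size: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if self.counts.index.duplicated().any():
            raise ValueError("feature ids must be unique")
        if self.lengths is not None and not self.lengths.index.equals(self.counts.index):
            object.__setattr__(self, "lengths", self.lengths.reindex(self.counts.index))
        if self.library_size is None:
            object.__setattr__(
                self, "library_size", self.counts.sum(axis=0).astype(float)
            )
        else:
            lib = self.library_size.reindex(self.counts.columns).astype(float)
            if lib.isna().any():
                raise ValueError("library_size missing for some samples")
            object.__setattr__(self, "library_size", lib)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy(float)

    def drop_all_zero(self) -> "CountMatrix":
        """Remove features that are zero in every library."""
        keep = self.counts.sum(axis=1) > 0
        return CountMatrix(
            self.counts.loc[keep],
            None if self.lengths is None else self.lengths.loc[keep],
            self.library_size,
        )

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, lengths=None, library_size=None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, lengths, library_size)
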