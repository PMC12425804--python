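"""Titration design: samples, dose labels and residual protein fractions.

The dose axis of every model in this package is the *protein fraction*
``p``: the abundance of the degraded protein relative to the untreated
control (control ``p = 1``, complete depletion ``p = 0``), as quantified
by western blot. A design holds one row per sequencing sample and maps
each sample to its dose label, protein fraction and biological replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DoseDesign", "make_dose_design", "DEFAULT_PROTEIN_FRACTIONS", "DEFAULT_DOSE_LABELS"]

#: Default six-point titration. The 0.3 nM (0.78) and 10 nM (0.12) anchors are
#: measured values; the intermediate fractions are configurable placeholders
#: spanning the titration, not measurements.
DEFAULT_PROTEIN_FRACTIONS = (1.0, 0.78, 0.55, 0.30, 0.12, 0.05)
DEFAULT_DOSE_LABELS = ("0nM", "0.3nM", "1nM", "3nM", "10nM", "100nM")


@dataclass(frozen=True)
class DoseDesign:
    """Ordered sample sheet for a degron titration.

    Attributes
    ----------
    table:
        One row per sample with columns ``sample_id``, ``dose_label``,
        ``protein_fraction``, ``replicate``. The control dose
        (``protein_fraction == 1``) comes first.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample_id", "dose_label", "protein_fraction", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        frac = self.table["protein_fraction"].to_numpy(float)
        if np.any((frac < 0) | (frac > 1)):
            raise ValueError("protein fractions must lie in [0, 1]")
        if not np.any(frac == 1.0):
            raise ValueError("missing control: no sample has protein_fraction == 1.0")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def protein_fractions(self) -> np.ndarray:
        """Per-sample protein fraction, aligned with :attr:`sample_ids`."""
        return self.table["protein_fraction"].to_numpy(float)

    @property
    def dose_labels(self) -> list[str]:
        return list(self.table["dose_label"])

    @property
    def control_samples(self) -> list[str]:
        mask = self.table["protein_fraction"] == 1.0
        return list(self.table.loc[mask, "sample_id"])

    @property
    def n_distinct_fractions(self) -> int:
        return self.table["protein_fraction"].nunique()

    def dose_groups(self) -> pd.Series:
        """Sample id -> dose label, for grouping replicates."""
        return self.table.set_index("sample_id")["dose_label"]

    def most_depleted_label(self) -> str:
        idx = self.table["protein_fraction"].idxmin()
        return str(self.table.loc[idx, "dose_label"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DoseDesign":
        return cls(pd.read_csv(path, sep="\t"))


def make_dose_design(
    protein_fractions=DEFAULT_PROTEIN_FRACTIONS,
    labels=DEFAULT_DOSE_LABELS,
    n_replicates: int = 2,
) -> DoseDesign:
    """Build a :class:`DoseDesign` from per-dose protein fractions.

    Parameters
    ----------
    protein_fractions:
        One residual protein fraction per dose; exactly one must equal 1.0
        (the control) and at least three distinct values are required so
        the two-template dose-response fit is identifiable.
    labels:
        Dose labels, same length (e.g. ligand concentrations).
    n_replicates:
        Biological replicates per dose; sample ids are
        ``"<label>_rep<k>"``.

    The control dose is placed first. A titration whose fractions
    *increase* along the declared order is suspicious but not illegal
    (real western quantifications are noisy), so it only warns.
    """
    fractions = [float(f) for f in protein_fractions]
    labels = [str(lab) for lab in labels]
    if len(fractions) != len(labels):
        raise ValueError("protein_fractions and labels must have equal length")
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("protein fractions must lie in [0, 1]")
    n_control = sum(f == 1.0 for f in fractions)
    if n_control == 0:
        raise ValueError("missing control: one protein fraction must equal 1.0")
    if n_control > 1:
        raise ValueError("exactly one dose may be the control (fraction 1.0)")
    if len(set(fractions)) < 3:
        raise ValueError(
            "need >=3 distinct protein fractions for model fitting, "
            f"got {len(set(fractions))}"
        )
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    # control first, remaining doses in declared order
    order = sorted(range(len(fractions)), key=lambda i: (fractions[i] != 1.0,))
    fractions = [fractions[i] for i in order]
    labels = [labels[i] for i in order]
    diffs = np.diff(fractions)
    if np.any(diffs > 0):
        warnings.warn(
            "protein fractions increase along the dose order; "
            "check the titration quantification",
            stacklevel=2,
        )

    rows = []
    for lab, frac in zip(labels, fractions):
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{lab}_rep{rep}",
                    "dose_label": lab,
                    "protein_fraction": frac,
                    "replicate": rep,
                }
            )
    return DoseDesign(pd.DataFrame(rows))
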