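import numpy as np
import pandas as pd
import pytest

from brgdose import make_dose_design
from brgdose.counts import CountMatrix
from brgdose.synthetic import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def design():
    """Default six-dose, two-replicate titration design."""
    return make_dose_design()


@pytest.fixture(scope="session")
def unit_library(design):
    """Sample-id-indexed series of ones (no depth differences)."""
    return pd.Series(1.0, index=design.sample_ids)


def simulate_flat_library(design, truth: pd.DataFrame, seed: int, dispersion: float) -> CountMatrix:
    """Counts from the generator with library sizes pinned to 1 so that no
    depth normalization is needed (the generator introduces none)."""
    cm = simulate_counts(design, truth, SimConfig(seed=seed, dispersion=dispersion))
    return CountMatrix(cm.counts, library_size=pd.Series(1.0, index=cm.sample_ids))


def archetype_truth(n_linear: int, n_buffered: int, n_unaffected: int = 0,
                    baseline: float = 500.0) -> pd.DataFrame:
    labels = (
        ["linear"] * n_linear + ["buffered"] * n_buffered + ["unaffected"] * n_unaffected
    )
    return pd.DataFrame(
        {"archetype": labels, "baseline_mean": baseline},
        index=[f"f{i:05d}" for i in range(len(labels))],
    )
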