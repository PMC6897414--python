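from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from refstab.cq_data import CqMatrix


def make_cq(
    values: dict[str, list[float]],
    cell_source: list[str] | None = None,
    loading: list[str] | None = None,
) -> CqMatrix:
    """Build a CqMatrix from a gene -> Cq-list mapping with simple metadata."""
    df = pd.DataFrame(values).T.astype(float)
    n = df.shape[1]
    samples = [f"s{i+1}" for i in range(n)]
    df.columns = samples
    df.index.name = "gene"
    meta = pd.DataFrame(
        {
            "cell_source": cell_source or ["N-SF"] * n,
            "loading": loading or ["control"] * n,
        },
        index=samples,
    )
    return CqMatrix(values=df, metadata=meta)


@pytest.fixture
def toy_cq() -> CqMatrix:
    """Three genes, four samples: A and B constant, C oscillates by 1 cycle."""
    return make_cq({
        "A": [20, 20, 20, 20],
        "B": [22, 22, 22, 22],
        "C": [20, 21, 20, 21],
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_cq_dict(
    rng: np.random.Generator, n_genes: int = 5, n_samples: int = 8
) -> dict[str, list[float]]:
    """Random strictly-positive Cq values for oracle cross-checks."""
    genes = [f"g{i}" for i in range(n_genes)]
    return {
        g: list(rng.uniform(15.0, 30.0, size=n_samples).round(3)) for g in genes
    }
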