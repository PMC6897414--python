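"""Comparative dCq stability.

For every ordered gene pair the per-sample Cq difference is formed and
its sample SD (n-1 denominator) taken across samples; a gene's
stability is the mean of these SDs over all partner genes. Differences
cancel per-sample loading effects, so the statistic is efficiency-free
and computed directly in cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from refstab.cq_data import CqMatrix

logger = logging.getLogger(__name__)


@dataclass
class DeltaCqResult:
    stability: pd.Series      # mean over partners of SD(dCq), cycles
    pairwise_sd: pd.DataFrame # symmetric, zero diagonal
    ranking: list[str]        # ascending stability


def pairwise_sd_matrix(cq: CqMatrix) -> pd.DataFrame:
    """SD across samples of Cq_j - Cq_k for every gene pair (complete-case)."""
    genes = cq.genes
    values = cq.values.to_numpy(dtype=float)
    n = len(genes)
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            diff = values[j] - values[k]
            diff = diff[np.isfinite(diff)]
            if diff.size < 2:
                logger.warning(
                    "gene pair (%s, %s) has < 2 complete samples; excluded",
                    genes[j], genes[k],
                )
                out[j, k] = out[k, j] = np.nan
            else:
                out[j, k] = out[k, j] = np.std(diff, ddof=1)
    return pd.DataFrame(out, index=genes, columns=genes)


def deltacq_stability(cq: CqMatrix) -> DeltaCqResult:
    """Mean pairwise SD of Cq differences per gene; lower = more stable."""
    if cq.n_genes < 3:
        raise ValueError("comparative dCq needs at least 3 genes")
    sd = pairwise_sd_matrix(cq)
    arr = sd.to_numpy(copy=True)
    np.fill_diagonal(arr, np.nan)
    counts = np.sum(~np.isnan(arr), axis=1)
    if np.any(counts == 0):
        logger.warning(
            "gene(s) with no usable partner excluded from stability: %s",
            [g for g, c in zip(cq.genes, counts) if c == 0],
        )
    stability = np.where(
        counts > 0, np.nansum(arr, axis=1) / np.maximum(counts, 1), np.nan
    )
    stab = pd.Series(stability, index=cq.genes, name="stability")
    ranking = list(stab.sort_values(kind="stable").index)
    return DeltaCqResult(stability=stab, pairwise_sd=sd, ranking=ranking)
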