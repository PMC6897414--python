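"""geNorm-style stability analysis on relative quantities.

A gene's stability M is the average, over all other candidates, of the
standard deviation of the pairwise log2 expression ratio across
samples. The stepwise procedure repeatedly drops the least stable gene;
the pairwise-variation series ``V[n/n+1]`` decides how many reference
genes a normalization factor needs (default cutoff 0.15).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from refstab.cq_data import QuantityMatrix

logger = logging.getLogger(__name__)

DEFAULT_V_CUTOFF = 0.15
_TIE_ATOL = 1e-12


@dataclass
class GeNormResult:
    """Bundle of the full geNorm analysis.

    ``m`` holds the one-shot full-panel stability per gene (the
    table-style output); the stepwise exclusion order and its average-M
    curve are reported separately because the two disagree once genes
    are removed.
    """

    m: pd.Series
    ranking: list[str]
    exclusion_order: list[str]
    avg_m_curve: pd.Series  # index: panel size, value: mean M of that panel
    final_pair: tuple[str, str]
    v_series: pd.Series  # index n, value V[n/n+1]
    optimal_n: int
    threshold: float = DEFAULT_V_CUTOFF
    optimal_n_capped: bool = False  # True when no V passed the cutoff
    extra: dict = field(default_factory=dict)


def _log2_matrix(q: QuantityMatrix) -> pd.DataFrame:
    return np.log2(q.values)


def pairwise_variation_matrix(q: QuantityMatrix) -> pd.DataFrame:
    """Symmetric matrix of SD (n-1 denominator) of log2(Q_j / Q_k).

    Complete-case per gene pair; pairs with fewer than two complete
    samples get a missing entry (logged).
    """
    genes = q.genes
    if len(genes) < 2:
        raise ValueError("pairwise variation needs at least 2 genes")
    log_q = _log2_matrix(q).to_numpy()
    n_genes = len(genes)
    v = np.zeros((n_genes, n_genes))
    for j in range(n_genes):
        for k in range(j + 1, n_genes):
            diff = log_q[j] - log_q[k]
            diff = diff[np.isfinite(diff)]
            if diff.size < 2:
                logger.warning(
                    "gene pair (%s, %s) has < 2 complete samples; entry missing",
                    genes[j], genes[k],
                )
                v[j, k] = v[k, j] = np.nan
            else:
                v[j, k] = v[k, j] = np.std(diff, ddof=1)
    return pd.DataFrame(v, index=genes, columns=genes)


def genorm_m(q: QuantityMatrix) -> pd.Series:
    """Per-gene stability M on the full panel: mean over partners of V_jk."""
    if len(q.genes) < 3:
        raise ValueError("geNorm M needs at least 3 genes")
    v = pairwise_variation_matrix(q)
    arr = v.to_numpy(copy=True)
    np.fill_diagonal(arr, np.nan)
    counts = np.sum(~np.isnan(arr), axis=1)
    m = np.where(counts > 0, np.nansum(arr, axis=1) / np.maximum(counts, 1), np.nan)
    return pd.Series(m, index=q.genes, name="M")


def _subset(q: QuantityMatrix, genes: list[str]) -> QuantityMatrix:
    return QuantityMatrix(
        values=q.values.loc[genes],
        metadata=q.metadata,
        efficiencies=None if q.efficiencies is None else q.efficiencies.loc[genes],
    )


def genorm_stepwise(q: QuantityMatrix) -> tuple[list[str], pd.Series]:
    """Stepwise exclusion of the least stable gene.

    Returns ``(exclusion_order, avg_m_curve)``. ``exclusion_order``
    lists genes from least to most stable (the final two appended in
    input order). ``avg_m_curve`` maps each intermediate panel size
    G, G-1, ..., 2 to the mean M of that panel. Ties on the maximal M
    are broken by removing the gene occurring last in input order.
    """
    genes = list(q.genes)
    if len(genes) < 3:
        raise ValueError("stepwise exclusion needs at least 3 genes")
    remaining = list(genes)
    excluded: list[str] = []
    sizes: list[int] = []
    curve: list[float] = []
    while len(remaining) > 2:
        m = genorm_m(_subset(q, remaining))
        sizes.append(len(remaining))
        curve.append(float(m.mean()))
        worst = m.max()
        tied = [g for g in remaining if np.isclose(m[g], worst, rtol=0.0, atol=_TIE_ATOL)]
        if len(tied) > 1:
            logger.info("tie on maximal M among %s; removing last in input order", tied)
        drop = tied[-1]
        excluded.append(drop)
        remaining.remove(drop)
    # final pair: both genes share one pairwise SD as their M
    pair_v = pairwise_variation_matrix(_subset(q, remaining))
    sizes.append(2)
    curve.append(float(pair_v.iloc[0, 1]))
    exclusion_order = excluded + remaining
    return exclusion_order, pd.Series(curve, index=pd.Index(sizes, name="n_genes"), name="mean_M")


def _nan_gmean_columns(values: pd.DataFrame) -> np.ndarray:
    """Per-sample geometric mean over genes, ignoring missing entries."""
    log_q = np.log(values.to_numpy())
    with np.errstate(invalid="ignore"):
        return np.exp(np.nanmean(log_q, axis=0))


def normalization_factors(q: QuantityMatrix, genes: list[str]) -> pd.Series:
    """NF per sample: geometric mean of the given genes' quantities."""
    nf = _nan_gmean_columns(q.values.loc[genes])
    return pd.Series(nf, index=q.samples, name="NF")


def optimal_reference_number(
    q: QuantityMatrix,
    ranking: list[str] | None = None,
    threshold: float = DEFAULT_V_CUTOFF,
) -> tuple[int, pd.Series, bool]:
    """Pairwise-variation rule for the number of reference genes.

    ``V[n/n+1]`` is the SD across samples of
    ``log2(NF_n / NF_{n+1})`` where NF_n is the geometric mean of the n
    most stable genes. Returns ``(optimal_n, v_series, capped)`` with
    ``optimal_n`` the smallest n whose V passes the cutoff; if none
    pass, all genes are required and ``capped`` is True.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if ranking is None:
        ranking = list(genorm_m(q).sort_values(kind="stable").index)
    if len(ranking) < 3:
        raise ValueError("ranking must cover at least 3 genes")
    n_max = len(ranking)
    v_vals: list[float] = []
    ns: list[int] = []
    nf_prev = normalization_factors(q, ranking[:2])
    for n in range(2, n_max):
        nf_next = normalization_factors(q, ranking[: n + 1])
        ratio = np.log2(nf_prev.to_numpy() / nf_next.to_numpy())
        ratio = ratio[np.isfinite(ratio)]
        v_vals.append(float(np.std(ratio, ddof=1)))
        ns.append(n)
        nf_prev = nf_next
    v_series = pd.Series(v_vals, index=pd.Index(ns, name="n"), name="V")
    passing = v_series[v_series <= threshold]
    if len(passing):
        return int(passing.index[0]), v_series, False
    logger.warning("no V[n/n+1] passed the %g cutoff; all %d genes required", threshold, n_max)
    return n_max, v_series, True


def genorm(q: QuantityMatrix, threshold: float = DEFAULT_V_CUTOFF) -> GeNormResult:
    """Run the full geNorm analysis and bundle the outputs."""
    m = genorm_m(q)
    ranking = list(m.sort_values(kind="stable").index)
    exclusion_order, curve = genorm_stepwise(q)
    final_pair = tuple(exclusion_order[-2:])
    optimal_n, v_series, capped = optimal_reference_number(q, ranking, threshold)
    return GeNormResult(
        m=m,
        ranking=ranking,
        exclusion_order=exclusion_order,
        avg_m_curve=curve,
        final_pair=final_pair,  # type: ignore[arg-type]
        v_series=v_series,
        optimal_n=optimal_n,
        threshold=threshold,
        optimal_n_capped=capped,
    )
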