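"""BestKeeper-style descriptive statistics on raw Cq values.

Candidates are scored by their Cq dispersion (the applet's "SD" is the
mean absolute deviation from the arithmetic mean, reported in +/- Cq
cycles) and by the Pearson correlation of their Cq with the BestKeeper
index, the per-sample geometric mean of all candidates' Cq. Everything
here operates on cycles, so the output is independent of amplification
efficiencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from refstab.cq_data import CqMatrix

logger = logging.getLogger(__name__)


@dataclass
class BestKeeperResult:
    table: pd.DataFrame   # per gene: geo_mean, arith_mean, min, max, sd, cv, r, p, rank
    index: pd.Series      # per sample BestKeeper index (geometric mean Cq)
    ranking: list[str]    # descending r; genes with undefined r last
    sd_definition: str    # "mad" (applet convention) or "classic"


def bestkeeper_index(cq: CqMatrix) -> pd.Series:
    """Per-sample geometric mean of all candidate genes' Cq.

    Complete-case per sample: genes missing in a sample are excluded
    from that sample's mean (logged); a sample with no genes at all
    gets a missing index.
    """
    values = cq.values.to_numpy(dtype=float)
    log_cq = np.log(values)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.warning("%d missing Cq value(s) excluded from the index per sample", n_missing)
    with np.errstate(invalid="ignore"):
        idx = np.exp(np.nanmean(log_cq, axis=0))
    return pd.Series(idx, index=cq.samples, name="bestkeeper_index")


def bestkeeper_stats(cq: CqMatrix, sd_definition: str = "mad") -> BestKeeperResult:
    """Descriptive statistics and per-gene correlation with the index.

    ``sd_definition='mad'`` (default) matches the original applet's
    "SD [+/- Cq]": the mean absolute deviation from the arithmetic mean.
    ``'classic'`` substitutes the n-1 standard deviation for sensitivity
    analysis. Genes with zero Cq variance get an undefined r (flagged
    missing) and are ranked last.
    """
    if sd_definition not in {"mad", "classic"}:
        raise ValueError(f"unknown sd_definition {sd_definition!r}")
    if cq.n_genes < 2:
        raise ValueError("BestKeeper needs at least 2 genes")
    index = bestkeeper_index(cq)
    rows = []
    for gene in cq.genes:
        x = cq.values.loc[gene]
        ok = x.notna() & index.notna()
        xv = x[ok].to_numpy(dtype=float)
        iv = index[ok].to_numpy(dtype=float)
        n = xv.size
        if n < 2:
            logger.warning("gene %s has < 2 usable samples; dispersion undefined", gene)
            rows.append(dict(gene=gene, geo_mean=np.nan, arith_mean=np.nan,
                             min=np.nan, max=np.nan, sd=np.nan, cv=np.nan,
                             r=np.nan, p=np.nan, n=n))
            continue
        mean = xv.mean()
        if sd_definition == "mad":
            sd = float(np.abs(xv - mean).mean())
        else:
            sd = float(np.std(xv, ddof=1))
        cv = sd / mean * 100.0
        if n >= 3 and np.std(xv) > 0 and np.std(iv) > 0:
            r, p = stats.pearsonr(xv, iv)
        else:
            if np.std(xv) == 0:
                logger.warning("gene %s has zero Cq variance; r undefined", gene)
            r, p = np.nan, np.nan
        rows.append(dict(
            gene=gene,
            geo_mean=float(stats.gmean(xv)),
            arith_mean=float(mean),
            min=float(xv.min()),
            max=float(xv.max()),
            sd=sd,
            cv=float(cv),
            r=float(r),
            p=float(p),
            n=n,
        ))
    table = pd.DataFrame(rows).set_index("gene")
    # rank: descending r, undefined r last; stable on ties
    order = table["r"].sort_values(ascending=False, kind="stable", na_position="last")
    ranking = list(order.index)
    table["rank"] = pd.Series(
        np.arange(1, len(ranking) + 1), index=ranking
    ).reindex(table.index)
    return BestKeeperResult(
        table=table, index=index, ranking=ranking, sd_definition=sd_definition
    )
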