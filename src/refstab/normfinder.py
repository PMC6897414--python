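"""Model-based stability estimation (NormFinder-style).

Works on log2 relative quantities. Sample means are removed first
(loading effects), then per-gene intragroup variances and shrunken
intergroup differences are combined into a single stability value per
gene; lower values indicate more stable expression. With a single group
the stability reduces to the estimated intragroup SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from refstab.cq_data import QuantityMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormFinderResult:
    stability: pd.Series          # per gene, >= 0, lower = more stable
    se: pd.Series                 # approximate sampling SE of the stability
    ranking: list[str]            # ascending stability, input order on ties
    d: pd.DataFrame | None        # shrunken intergroup differences (gene x group)
    d_raw: pd.DataFrame | None    # unshrunken differences
    sigma2: pd.DataFrame          # intragroup variances (gene x group), clipped >= 0
    gamma2: float                 # intergroup variance, >= 0
    groups: list[str]


def _intragroup_variances(z: np.ndarray) -> np.ndarray:
    """Bias-corrected per-gene variance estimates after gene-centering.

    Centering z across genes makes the naive sample variance biased:
    Var(z_i) = sigma2_i * (1 - 2/I) + mean(sigma2)/I. Solving the moment
    equations gives the correction applied here; negative estimates are
    clipped to zero.
    """
    n_genes = z.shape[0]
    s2 = np.var(z, axis=1, ddof=1)
    u_bar = s2.mean()
    sigma2 = (n_genes / (n_genes - 2)) * (s2 - u_bar / (n_genes - 1))
    return np.clip(sigma2, 0.0, None)


def normfinder_stability(
    q: QuantityMatrix,
    groups: pd.Series | list[str] | None = None,
) -> NormFinderResult:
    """Estimate per-gene stability values.

    Parameters
    ----------
    q
        Relative quantities; log2 values must be finite (no missing
        entries among the analysed samples).
    groups
        Per-sample group labels. ``None`` or a single distinct label
        selects single-group mode.
    """
    genes = q.genes
    n_genes = len(genes)
    if n_genes < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    y = np.log2(q.values.to_numpy(dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("log2 quantities must be finite (remove missing entries first)")

    if groups is None:
        labels = pd.Series(["all"] * len(q.samples), index=q.samples)
    else:
        labels = pd.Series(list(groups), index=q.samples).astype(str)
    group_names = list(pd.unique(labels))
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"group(s) with < 2 samples: {list(small.index)}")

    # (1) remove per-sample (loading) effects
    z = y - y.mean(axis=0, keepdims=True)

    n_groups = len(group_names)
    sigma2 = np.empty((n_genes, n_groups))
    n_g = np.empty(n_groups)
    for gi, g in enumerate(group_names):
        cols = (labels == g).to_numpy()
        n_g[gi] = cols.sum()
        sigma2[:, gi] = _intragroup_variances(z[:, cols])

    sigma2_df = pd.DataFrame(sigma2, index=genes, columns=group_names)

    if n_groups == 1:
        stability = np.sqrt(sigma2[:, 0])
        # delta-method SE of an SD estimate
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.where(
                stability > 0,
                stability / np.sqrt(2.0 * (n_g[0] - 1.0)),
                0.0,
            )
        stab = pd.Series(stability, index=genes, name="stability")
        ranking = list(stab.sort_values(kind="stable").index)
        return NormFinderResult(
            stability=stab,
            se=pd.Series(se, index=genes, name="se"),
            ranking=ranking,
            d=None,
            d_raw=None,
            sigma2=sigma2_df,
            gamma2=0.0,
            groups=group_names,
        )

    # (3) intergroup differences and their shrinkage
    group_means = np.empty((n_genes, n_groups))
    for gi, g in enumerate(group_names):
        cols = (labels == g).to_numpy()
        group_means[:, gi] = z[:, cols].mean(axis=1)
    grand_mean = z.mean(axis=1, keepdims=True)
    d_raw = group_means - grand_mean

    var_terms = sigma2 / n_g[None, :]
    gamma2 = max(0.0, float(np.var(d_raw, ddof=1)) - float(var_terms.mean()))
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = np.where(
            gamma2 + var_terms > 0, gamma2 / (gamma2 + var_terms), 0.0
        )
    d_shrunk = d_raw * shrink

    per_group = np.abs(d_shrunk) + np.sqrt(var_terms * shrink)
    stability = per_group.mean(axis=1)
    if n_groups > 1:
        se = per_group.std(axis=1, ddof=1) / np.sqrt(n_groups)
    else:  # pragma: no cover - handled above
        se = np.zeros(n_genes)

    stab = pd.Series(stability, index=genes, name="stability")
    ties = stab.duplicated(keep=False)
    if ties.any():
        logger.info("stability ties ranked by input order: %s", list(stab.index[ties]))
    ranking = list(stab.sort_values(kind="stable").index)
    return NormFinderResult(
        stability=stab,
        se=pd.Series(se, index=genes, name="se"),
        ranking=ranking,
        d=pd.DataFrame(d_shrunk, index=genes, columns=group_names),
        d_raw=pd.DataFrame(d_raw, index=genes, columns=group_names),
        sigma2=sigma2_df,
        gamma2=gamma2,
        groups=group_names,
    )
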