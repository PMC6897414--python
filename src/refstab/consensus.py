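"""Cross-method ranking, rank-sum consensus and concordance.

The four stability methods produce values on different scales and with
opposite orientations (BestKeeper's correlation r is
descending-is-stable, the rest are ascending). This module ranks each
method's column respecting its orientation, aggregates genes by rank
sum, and quantifies inter-method agreement by Pearson correlation of
the stability values themselves (orientation-aligned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from refstab.bestkeeper import bestkeeper_stats
from refstab.cq_data import CqMatrix, EfficiencyTable, to_quantities
from refstab.deltacq import deltacq_stability
from refstab.genorm import genorm
from refstab.normfinder import normfinder_stability

logger = logging.getLogger(__name__)

Orientation = Literal["asc", "desc"]


@dataclass
class StabilityTable:
    """Gene x method matrix of stability values with declared orientations.

    ``orientation[method]`` is ``"asc"`` when smaller values mean more
    stable (geNorm M, NormFinder, comparative dCq) and ``"desc"`` when
    larger values do (BestKeeper r).
    """

    values: pd.DataFrame
    orientation: dict[str, Orientation]

    def __post_init__(self) -> None:
        missing = [m for m in self.values.columns if m not in self.orientation]
        if missing:
            raise ValueError(f"orientation undeclared for method(s): {missing}")
        bad = {m: o for m, o in self.orientation.items() if o not in ("asc", "desc")}
        if bad:
            raise ValueError(f"invalid orientation(s): {bad}")

    @property
    def methods(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def aligned(self) -> pd.DataFrame:
        """Stability values with descending methods negated so every
        column is smaller-is-stabler."""
        out = self.values.copy()
        for m in self.methods:
            if self.orientation[m] == "desc":
                out[m] = -out[m]
        return out


@dataclass
class ConsensusResult:
    ranks: pd.DataFrame           # gene x method, rank 1 = most stable, ties averaged
    rank_sum: pd.Series           # row sums
    consensus_order: list[str]    # ascending rank sum
    concordance_r: pd.DataFrame | None = None
    concordance_p: pd.DataFrame | None = None
    normality_p: pd.Series | None = None  # Shapiro-Wilk diagnostic per method
    notes: dict = field(default_factory=dict)


def rank_methods(st: StabilityTable) -> pd.DataFrame:
    """Per-method ranks (1 = most stable); ties share the average rank.

    Genes with a missing stability value are flagged and ranked last
    for that method.
    """
    ranks = {}
    for m in st.methods:
        col = st.values[m]
        if col.isna().any():
            logger.warning(
                "method %s: missing stability for %s; ranked last",
                m, list(col.index[col.isna()]),
            )
        ascending = st.orientation[m] == "asc"
        ranks[m] = col.rank(method="average", ascending=ascending, na_option="bottom")
    return pd.DataFrame(ranks, index=st.genes)


def rank_sum_consensus(ranks: pd.DataFrame) -> ConsensusResult:
    """Aggregate per-method ranks by their sum; lower = more stable.

    Rank-sum ties are ordered by the best (smallest) single-method rank,
    then by input order (logged).
    """
    if ranks.shape[1] < 1:
        raise ValueError("at least one method column required")
    rank_sum = ranks.sum(axis=1)
    rank_sum.name = "rank_sum"
    best_single = ranks.min(axis=1)
    order_df = pd.DataFrame({
        "rank_sum": rank_sum,
        "best": best_single,
        "pos": np.arange(len(rank_sum)),
    })
    ties = rank_sum.duplicated(keep=False)
    if ties.any():
        logger.info(
            "rank-sum ties broken by best single-method rank then input order: %s",
            list(rank_sum.index[ties]),
        )
    order = list(order_df.sort_values(["rank_sum", "best", "pos"], kind="stable").index)
    return ConsensusResult(ranks=ranks, rank_sum=rank_sum, consensus_order=order)


def method_concordance(st: StabilityTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation between every pair of methods' stability values.

    Computed on orientation-aligned values (descending methods negated),
    two-sided p-values; zero-variance columns give flagged missing
    entries.
    """
    if len(st.genes) < 3:
        raise ValueError("concordance needs at least 3 genes")
    aligned = st.aligned()
    methods = st.methods
    n = len(methods)
    r = np.ones((n, n))
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = aligned[methods[i]], aligned[methods[j]]
            ok = x.notna() & y.notna()
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            if xv.size < 3 or np.std(xv) == 0 or np.std(yv) == 0:
                logger.warning(
                    "concordance undefined for (%s, %s)", methods[i], methods[j]
                )
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
            else:
                rr, pp = stats.pearsonr(xv, yv)
                r[i, j] = r[j, i] = rr
                p[i, j] = p[j, i] = pp
    idx = pd.Index(methods)
    return pd.DataFrame(r, idx, idx), pd.DataFrame(p, idx, idx)


def normality_screen(st: StabilityTable) -> pd.Series:
    """Shapiro-Wilk p-value per method column — a diagnostic, not a gate."""
    out = {}
    for m in st.methods:
        col = st.values[m].dropna().to_numpy()
        if col.size < 3 or np.ptp(col) == 0:
            out[m] = np.nan
        else:
            out[m] = stats.shapiro(col).pvalue
    return pd.Series(out, name="shapiro_p")


# ---------------------------------------------------------------------------
# whole-panel pipeline
# ---------------------------------------------------------------------------

METHOD_ORIENTATION: dict[str, Orientation] = {
    "genorm": "asc",
    "normfinder": "asc",
    "deltacq": "asc",
    "bestkeeper": "desc",
}


def run_all_methods(
    cq: CqMatrix,
    eff: EfficiencyTable | None = None,
    group_by: str | list[str] | None = None,
) -> StabilityTable:
    """Run all four stability methods on one Cq matrix.

    ``group_by`` names metadata column(s) defining the NormFinder
    groups; ``None`` runs NormFinder in single-group mode.
    """
    q = to_quantities(cq, eff)
    groups = None if group_by is None else cq.groups(group_by)
    values = pd.DataFrame({
        "genorm": genorm(q).m,
        "normfinder": normfinder_stability(q, groups).stability,
        "deltacq": deltacq_stability(cq).stability,
        "bestkeeper": bestkeeper_stats(cq).table["r"],
    })
    return StabilityTable(values=values, orientation=dict(METHOD_ORIENTATION))


def consensus_analysis(st: StabilityTable) -> ConsensusResult:
    """Rank, aggregate and correlate the four methods' outputs."""
    ranks = rank_methods(st)
    result = rank_sum_consensus(ranks)
    r, p = method_concordance(st)
    result.concordance_r = r
    result.concordance_p = p
    result.normality_p = normality_screen(st)
    result.notes["orientation"] = dict(
        (m, st.orientation[m]) for m in st.methods
    )
    result.notes["concordance_sign"] = (
        "descending-oriented methods negated before correlating"
    )
    return result
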