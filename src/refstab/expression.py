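"""Relative target-gene expression (2^-dCq) against reference aggregates.

A normalization factor is built from one or more reference genes (on
the Cq scale the multi-gene aggregate is the arithmetic mean of their
Cq, equivalent to the geometric mean of the linear quantities). Target
expression is 2^-dCq relative to the aggregate, scaled so that the
declared control group's mean fold change is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from refstab.cq_data import CqMatrix

logger = logging.getLogger(__name__)


@dataclass
class ExpressionResult:
    table: pd.DataFrame          # per sample: delta_cq, rel_expr, fold_change
    control_samples: list[str]
    reference_genes: list[str]
    base: float                  # amplification base used for E^-dCq
    group_summary: pd.DataFrame | None = None  # mean/sd fold change per group


def normalization_factor(cq: CqMatrix, reference_genes: list[str]) -> pd.Series:
    """Per-sample reference aggregate Cq.

    A single reference gene contributes its own Cq; several genes are
    aggregated by the arithmetic mean of their Cq per sample. Samples
    with a missing reference Cq are excluded (logged).
    """
    if not reference_genes:
        raise ValueError("at least one reference gene required")
    missing = [g for g in reference_genes if g not in cq.genes]
    if missing:
        raise KeyError(f"reference gene(s) not in matrix: {missing}")
    ref = cq.values.loc[reference_genes]
    ok = ref.notna().all(axis=0)
    if not ok.all():
        logger.warning(
            "sample(s) excluded for missing reference Cq: %s",
            list(ok.index[~ok]),
        )
    agg = ref.loc[:, ok].mean(axis=0)
    agg.name = "reference_cq"
    return agg


def relative_expression(
    target_cq: pd.Series,
    aggregate: pd.Series,
    control_samples: list[str],
    groups: pd.Series | None = None,
    base: float = 2.0,
) -> ExpressionResult:
    """Fold change of a target against a reference aggregate.

    ``rel_expr = base^-(Cq_target - Cq_reference)`` per sample;
    ``fold_change`` divides by the control group's arithmetic mean
    rel_expr, so the control mean fold change is 1 by construction.
    ``groups`` (per-sample labels) adds a mean +/- SD summary table.
    """
    if base <= 1:
        raise ValueError("base must exceed 1")
    samples = [s for s in target_cq.index if s in aggregate.index]
    t = target_cq.loc[samples]
    ok = t.notna()
    if not ok.all():
        logger.warning("sample(s) excluded for missing target Cq: %s", list(t.index[~ok]))
        samples = list(t.index[ok])
    controls = [s for s in control_samples if s in samples]
    if not controls:
        raise ValueError("control group is empty after exclusions")

    delta = target_cq.loc[samples] - aggregate.loc[samples]
    rel = base ** (-delta)
    fold = rel / rel.loc[controls].mean()
    table = pd.DataFrame({
        "delta_cq": delta,
        "rel_expr": rel,
        "fold_change": fold,
    })
    table.index.name = "sample"

    summary = None
    if groups is not None:
        g = pd.Series(list(groups), index=groups.index).loc[samples]
        summary = (
            table.assign(group=g)
            .groupby("group", sort=False)["fold_change"]
            .agg(["mean", "std", "count"])
        )
    return ExpressionResult(
        table=table,
        control_samples=controls,
        reference_genes=[],
        base=base,
        group_summary=summary,
    )


def target_expression(
    cq: CqMatrix,
    target: str,
    reference_genes: list[str],
    control_samples: list[str],
    group_by: str | list[str] | None = None,
    base: float = 2.0,
) -> ExpressionResult:
    """Convenience wrapper: aggregate references, then fold changes."""
    if target not in cq.genes:
        raise KeyError(f"target gene {target!r} not in matrix")
    aggregate = normalization_factor(cq, reference_genes)
    groups = None if group_by is None else cq.groups(group_by)
    result = relative_expression(
        cq.values.loc[target], aggregate, control_samples, groups=groups, base=base
    )
    result.reference_genes = list(reference_genes)
    return result
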