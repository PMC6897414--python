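"""Data model and I/O for quantification-cycle (Cq) matrices.

The central object is :class:`CqMatrix`: a genes x samples matrix of Cq
values with per-sample group metadata. Raw plates with technical
replicates are collapsed to one Cq per (gene, sample) by
:func:`collapse_replicates`; :func:`to_quantities` applies the
efficiency transform ``Q = E**(Cq_min - Cq)`` that puts each gene on a
relative linear scale with its best (lowest-Cq) sample at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default vocabulary for the experimental-design metadata columns.
DEFAULT_GROUP_VOCAB: dict[str, frozenset[str]] = {
    "cell_source": frozenset({"N-SF", "OA-SF"}),
    "loading": frozenset({"control", "pressure"}),
}

#: Cq sanity window in cycles (a 45-cycle run); outside values warn but load.
CQ_SANITY_WINDOW = (1.0, 45.0)

#: Tokens treated as missing when parsing Cq cells.
MISSING_TOKENS = {"", "na", "nan", "n/a", "undetermined", "undet", "-", "none"}


class CqDataError(ValueError):
    """Raised on hard validation failures of Cq inputs."""


@dataclass
class CqMatrix:
    """Genes x samples Cq matrix with per-sample group metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids; ``NaN``
        marks missing measurements. Non-missing entries must be > 0.
    metadata
        DataFrame indexed by sample id; must cover every sample of
        ``values``. Columns listed in ``vocab`` are checked against the
        declared label sets.
    replicates
        Optional long table (columns ``gene, sample, replicate, Cq``)
        retaining the raw technical replicates behind ``values``.
    replicate_n, replicate_sd
        Optional diagnostics from :func:`collapse_replicates`, aligned
        with ``values``.
    vocab
        Declared vocabulary per metadata column; only columns present in
        the mapping are checked.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    replicates: pd.DataFrame | None = None
    replicate_n: pd.DataFrame | None = None
    replicate_sd: pd.DataFrame | None = None
    vocab: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_VOCAB)
    )

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise CqDataError(f"duplicate gene identifiers: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise CqDataError(f"duplicate sample identifiers: {dup}")
        missing_meta = [s for s in self.values.columns if s not in self.metadata.index]
        if missing_meta:
            raise CqDataError(
                f"metadata missing rows for samples: {missing_meta}"
            )
        arr = self.values.to_numpy()
        if np.any(arr[np.isfinite(arr)] <= 0):
            raise CqDataError("non-missing Cq values must be strictly positive")
        lo, hi = CQ_SANITY_WINDOW
        finite = arr[np.isfinite(arr)]
        n_out = int(np.sum((finite < lo) | (finite > hi)))
        if n_out:
            logger.warning(
                "%d Cq value(s) outside the sanity window [%g, %g] cycles",
                n_out, lo, hi,
            )
        for col, allowed in self.vocab.items():
            if col in self.metadata.columns:
                seen = set(self.metadata.loc[self.samples, col].dropna())
                bad = seen - set(allowed)
                if bad:
                    raise CqDataError(
                        f"metadata column {col!r} contains labels outside the "
                        f"declared vocabulary: {sorted(bad)}"
                    )

    def groups(self, by: str | list[str]) -> pd.Series:
        """Per-sample group label built from one or more metadata columns."""
        cols = [by] if isinstance(by, str) else list(by)
        meta = self.metadata.loc[self.samples, cols].astype(str)
        return meta.agg(":".join, axis=1)

    def copy_with(self, values: pd.DataFrame) -> "CqMatrix":
        return CqMatrix(
            values=values,
            metadata=self.metadata.loc[list(values.columns)].copy(),
            vocab=self.vocab,
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the canonical wide layout (first column ``gene``)."""
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


@dataclass
class EfficiencyTable:
    """Per-gene amplification efficiency E in (1, 2].

    Genes absent from the table default to ``default`` (perfect
    doubling, E = 2).
    """

    efficiencies: Mapping[str, float] = field(default_factory=dict)
    default: float = 2.0

    def __post_init__(self) -> None:
        for gene, e in self.efficiencies.items():
            if not (1.0 < e <= 2.0):
                raise CqDataError(
                    f"efficiency for {gene!r} must lie in (1, 2], got {e}"
                )
        if not (1.0 < self.default <= 2.0):
            raise CqDataError(f"default efficiency must lie in (1, 2], got {self.default}")

    def __getitem__(self, gene: str) -> float:
        return float(self.efficiencies.get(gene, self.default))

    def for_genes(self, genes: list[str]) -> pd.Series:
        return pd.Series({g: self[g] for g in genes}, name="E")

    @classmethod
    def read_tsv(cls, path: str | Path, default: float = 2.0) -> "EfficiencyTable":
        df = pd.read_csv(path, sep=None, engine="python")
        if not {"gene", "E"}.issubset(df.columns):
            raise CqDataError("efficiency table needs columns 'gene' and 'E'")
        return cls(dict(zip(df["gene"].astype(str), df["E"].astype(float))), default)


@dataclass
class QuantityMatrix:
    """Efficiency-transformed relative quantities Q in (0, 1].

    Per gene the sample with minimal Cq has Q = 1; missingness is
    propagated from the source :class:`CqMatrix`.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    efficiencies: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if np.any(finite <= 0) or np.any(finite > 1 + 1e-9):
            raise CqDataError("quantities must lie in (0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def groups(self, by: str | list[str]) -> pd.Series:
        cols = [by] if isinstance(by, str) else list(by)
        meta = self.metadata.loc[self.samples, cols].astype(str)
        return meta.agg(":".join, axis=1)

    def log2(self) -> pd.DataFrame:
        """log2 quantities (NaN preserved)."""
        return np.log2(self.values)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _parse_cq_cell(x: object) -> float:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return np.nan
    s = str(x).strip()
    if s.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        logger.warning("unparseable Cq cell %r treated as missing", x)
        return np.nan


def _read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep=None, engine="python", dtype=str)
    if "sample" not in meta.columns:
        raise CqDataError("metadata table needs a 'sample' column")
    if meta["sample"].duplicated().any():
        dup = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise CqDataError(f"duplicate sample identifiers in metadata: {dup}")
    return meta.set_index("sample")


def read_cq_table(
    path: str | Path,
    layout: str = "wide",
    metadata_path: str | Path | None = None,
    metadata: pd.DataFrame | None = None,
    vocab: Mapping[str, frozenset[str]] | None = None,
) -> CqMatrix:
    """Read a Cq table from TSV/CSV.

    ``layout='wide'``: genes in rows (first column ``gene``), samples in
    columns. A transposed file (first column ``sample``) is detected by
    its header keyword and flipped. ``layout='long'``: columns
    ``sample, gene, replicate, Cq``; technical replicates are retained
    in ``CqMatrix.replicates`` and ``values`` holds their arithmetic
    mean per cell.

    Unparseable cells become missing with a logged warning; sample
    order follows the metadata table when provided.
    """
    if layout not in {"wide", "long"}:
        raise CqDataError(f"unknown layout {layout!r}")
    if metadata is None:
        if metadata_path is None:
            raise CqDataError("either metadata_path or metadata is required")
        metadata = _read_metadata(metadata_path)

    kwargs: dict = dict(sep=None, engine="python", dtype=str)
    if layout == "wide":
        raw = pd.read_csv(path, **kwargs)
        first = str(raw.columns[0]).strip().lower()
        if first == "sample":  # transposed wide: samples in rows
            raw = raw.set_index(raw.columns[0]).T.reset_index(names="gene")
        elif first != "gene":
            raise CqDataError(
                "wide layout requires the first column header to be 'gene' "
                f"or 'sample', got {raw.columns[0]!r}"
            )
        if raw["gene"].duplicated().any():
            dup = raw.loc[raw["gene"].duplicated(), "gene"].tolist()
            raise CqDataError(f"duplicate gene identifiers: {dup}")
        values = raw.set_index("gene").map(_parse_cq_cell).astype(float)
        replicates = None
    else:
        raw = pd.read_csv(path, sep=None, engine="python")
        needed = {"sample", "gene", "Cq"}
        if not needed.issubset(raw.columns):
            raise CqDataError(f"long layout requires columns {sorted(needed)}")
        if "replicate" not in raw.columns:
            raw["replicate"] = 1
        replicates = raw[["gene", "sample", "replicate", "Cq"]].copy()
        replicates["Cq"] = replicates["Cq"].map(_parse_cq_cell)
        values = (
            replicates.pivot_table(
                index="gene", columns="sample", values="Cq", aggfunc="mean"
            )
        )
        # preserve first-appearance order of genes and samples
        values = values.reindex(
            index=pd.unique(replicates["gene"]),
            columns=pd.unique(replicates["sample"]),
        )
        values.columns.name = None
        values.index.name = "gene"

    # order samples as in the metadata table where possible
    ordered = [s for s in metadata.index if s in values.columns]
    stray = [s for s in values.columns if s not in metadata.index]
    if stray:
        raise CqDataError(f"metadata missing rows for samples: {stray}")
    values = values[ordered]

    kw = {} if vocab is None else {"vocab": vocab}
    return CqMatrix(values=values, metadata=metadata, replicates=replicates, **kw)


def collapse_replicates(raw: CqMatrix) -> CqMatrix:
    """Collapse technical replicates to one Cq per (gene, sample).

    The collapsed value is the arithmetic mean of the available
    replicates; cells whose replicates are all missing stay missing
    (logged). Replicate count and SD are kept as diagnostics. The
    operation is the identity on already-collapsed matrices.
    """
    if raw.replicates is None:
        return raw
    reps = raw.replicates
    grouped = reps.groupby(["gene", "sample"], sort=False)["Cq"]
    mean = grouped.mean().unstack("sample")
    n = grouped.count().unstack("sample")
    sd = grouped.std(ddof=1).unstack("sample")
    mean = mean.reindex(index=raw.genes, columns=raw.samples)
    n = n.reindex(index=raw.genes, columns=raw.samples).fillna(0).astype(int)
    sd = sd.reindex(index=raw.genes, columns=raw.samples)
    for frame in (mean, n, sd):
        frame.index.name = "gene"
        frame.columns.name = None
    n_empty = int((n.to_numpy() == 0).sum())
    if n_empty:
        logger.warning(
            "%d (gene, sample) cell(s) have no usable replicate; left missing",
            n_empty,
        )
    return CqMatrix(
        values=mean,
        metadata=raw.metadata,
        replicate_n=n,
        replicate_sd=sd,
        vocab=raw.vocab,
    )


def to_quantities(cq: CqMatrix, eff: EfficiencyTable | None = None) -> QuantityMatrix:
    """Efficiency transform to relative quantities.

    ``Q[g, s] = E_g ** (min_s' Cq[g, s'] - Cq[g, s])`` so that per gene
    the minimum-Cq sample maps to Q = 1 and every other sample to a
    value in (0, 1).
    """
    if eff is None:
        eff = EfficiencyTable()
    e = eff.for_genes(cq.genes)
    all_missing = cq.values.isna().all(axis=1)
    if all_missing.any():
        raise CqDataError(
            f"gene(s) with no non-missing Cq: {list(cq.values.index[all_missing])}"
        )
    cq_min = cq.values.min(axis=1)
    exponent = cq.values.rsub(cq_min, axis=0)  # Cq_min - Cq  (<= 0)
    q = pd.DataFrame(
        np.power(e.to_numpy()[:, None], exponent.to_numpy()),
        index=cq.values.index,
        columns=cq.values.columns,
    )
    return QuantityMatrix(values=q, metadata=cq.metadata, efficiencies=e)


def filter_samples(
    cq: CqMatrix, predicate: str | Callable[[pd.Series], bool]
) -> CqMatrix:
    """Subset samples by a metadata predicate.

    ``predicate`` is either a pandas query string over the metadata
    columns (e.g. ``"cell_source == 'N-SF'"``) or a callable applied to
    each metadata row. An empty result is a hard error.
    """
    meta = cq.metadata.loc[cq.samples]
    if callable(predicate):
        keep = meta.apply(predicate, axis=1).astype(bool)
        kept = list(meta.index[keep])
    else:
        kept = list(meta.query(predicate).index)
    if not kept:
        raise CqDataError("sample filter selected no samples")
    return cq.copy_with(cq.values[kept])
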