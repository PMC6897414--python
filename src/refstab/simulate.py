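"""Seeded synthetic Cq data with known ground truth.

Generative model on the cycle scale::

    Cq[i, g, j, r] = B_i + D_ig + S_j + eps_igjr

with per-gene baseline ``B_i``, group regulation effect ``D_ig``, a
common per-sample loading offset ``S_j ~ N(0, lambda^2)`` and technical
noise ``eps ~ N(0, tau_i^2)`` per replicate. Each gene draws from its
own deterministic sub-stream of the master seed, so appending genes to
a spec never perturbs the draws of existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from refstab.cq_data import DEFAULT_GROUP_VOCAB, CqMatrix


@dataclass
class GeneSpec:
    """One simulated gene: baseline Cq, technical noise SD (cycles),
    amplification efficiency and per-group regulation effects (cycles)."""

    name: str
    baseline: float
    noise_sd: float = 0.15
    efficiency: float = 2.0
    regulation: dict[str, float] = field(default_factory=dict)

    @property
    def max_abs_effect(self) -> float:
        return max((abs(v) for v in self.regulation.values()), default=0.0)

    @property
    def regulated(self) -> bool:
        return any(v != 0.0 for v in self.regulation.values())


@dataclass
class SyntheticSpec:
    genes: list[GeneSpec]
    group_sizes: dict[str, int]           # e.g. {"N-SF:control": 5, ...}
    loading_sd: float = 0.0               # common per-sample offset SD (cycles)
    replicates: int = 1
    seed: int = 0
    heavy_tail_df: float | None = None    # Student-t df for contaminated noise

    def validate(self) -> None:
        problems: list[str] = []
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            problems.append("duplicate gene names")
        for g in self.genes:
            if g.noise_sd < 0:
                problems.append(f"{g.name}: noise_sd must be >= 0")
            if not (1.0 < g.efficiency <= 2.0):
                problems.append(f"{g.name}: efficiency must lie in (1, 2]")
            unknown = set(g.regulation) - set(self.group_sizes)
            if unknown:
                problems.append(f"{g.name}: regulation for unknown group(s) {sorted(unknown)}")
        if self.loading_sd < 0:
            problems.append("loading_sd must be >= 0")
        if any(n < 1 for n in self.group_sizes.values()):
            problems.append("group sizes must be >= 1")
        if self.replicates < 1:
            problems.append("replicates must be >= 1")
        if self.heavy_tail_df is not None and self.heavy_tail_df <= 2:
            problems.append("heavy_tail_df must exceed 2")
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "SyntheticSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        genes = [GeneSpec(**g) for g in cfg["genes"]]
        spec = cls(
            genes=genes,
            group_sizes=dict(cfg["group_sizes"]),
            loading_sd=float(cfg.get("loading_sd", 0.0)),
            replicates=int(cfg.get("replicates", 1)),
            seed=int(cfg.get("seed", 0)),
            heavy_tail_df=cfg.get("heavy_tail_df"),
        )
        if seed is not None:
            spec.seed = seed
        return spec


@dataclass
class SyntheticTruth:
    """Ground-truth labels and ordering keys for a simulated matrix."""

    labels: pd.Series          # per gene: "stable" | "regulated"
    max_abs_effect: pd.Series  # cycles
    noise_sd: pd.Series        # cycles
    spec: SyntheticSpec

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels.to_dict(),
            "max_abs_effect": self.max_abs_effect.to_dict(),
            "noise_sd": self.noise_sd.to_dict(),
            "expected_order": truth_ranking(self),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _sample_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Sample metadata; groups named 'cell_source:loading' are split
    into the two canonical metadata columns."""
    rows = []
    for group, n in spec.group_sizes.items():
        for i in range(1, n + 1):
            row = {"sample": f"{group.replace(':', '_')}_{i:02d}", "group": group}
            if ":" in group:
                cell_source, loading = group.split(":", 1)
                row["cell_source"] = cell_source
                row["loading"] = loading
            rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def simulate_cq(spec: SyntheticSpec) -> tuple[CqMatrix, SyntheticTruth]:
    """Draw a replicate-level Cq matrix from the spec.

    Returns a :class:`CqMatrix` whose ``replicates`` table holds the
    raw draws (``values`` is their per-cell mean) together with the
    :class:`SyntheticTruth` labels. Identical spec and seed give
    bitwise-identical output.
    """
    spec.validate()
    meta = _sample_table(spec)
    samples = list(meta.index)
    groups = meta["group"]
    n_samples = len(samples)
    n_rep = spec.replicates

    # stream 0: per-sample loading offsets; streams (1, i): per-gene noise
    root = spec.seed
    offset_rng = np.random.default_rng(np.random.SeedSequence(root, spawn_key=(0,)))
    offsets = offset_rng.normal(0.0, spec.loading_sd, size=n_samples)

    records = []
    for gi, gene in enumerate(spec.genes):
        rng = np.random.default_rng(np.random.SeedSequence(root, spawn_key=(1, gi)))
        if spec.heavy_tail_df is not None:
            df = spec.heavy_tail_df
            scale = gene.noise_sd / np.sqrt(df / (df - 2.0))
            eps = rng.standard_t(df, size=(n_samples, n_rep)) * scale
        else:
            eps = rng.normal(0.0, gene.noise_sd, size=(n_samples, n_rep))
        for sj, sample in enumerate(samples):
            effect = gene.regulation.get(groups.loc[sample], 0.0)
            for r in range(n_rep):
                records.append((
                    gene.name, sample, r + 1,
                    gene.baseline + effect + offsets[sj] + eps[sj, r],
                ))
    replicates = pd.DataFrame(records, columns=["gene", "sample", "replicate", "Cq"])
    values = (
        replicates.pivot_table(index="gene", columns="sample", values="Cq", aggfunc="mean")
        .reindex(index=[g.name for g in spec.genes], columns=samples)
    )
    values.index.name = "gene"
    values.columns.name = None

    vocab = dict(DEFAULT_GROUP_VOCAB)
    vocab["group"] = frozenset(spec.group_sizes)
    cq = CqMatrix(values=values, metadata=meta, replicates=replicates, vocab=vocab)

    names = [g.name for g in spec.genes]
    truth = SyntheticTruth(
        labels=pd.Series(
            ["regulated" if g.regulated else "stable" for g in spec.genes], index=names
        ),
        max_abs_effect=pd.Series([g.max_abs_effect for g in spec.genes], index=names),
        noise_sd=pd.Series([g.noise_sd for g in spec.genes], index=names),
        spec=spec,
    )
    return cq, truth


def truth_ranking(truth: SyntheticTruth) -> list[str]:
    """Expected stability order: ascending by (max |effect|, noise SD);
    ties keep input order."""
    key = pd.DataFrame({
        "effect": truth.max_abs_effect,
        "tau": truth.noise_sd,
        "pos": np.arange(len(truth.labels)),
    })
    return list(key.sort_values(["effect", "tau", "pos"], kind="stable").index)
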