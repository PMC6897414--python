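# refstab

Reference-gene (housekeeping-gene) stability analysis for RT-qPCR
experiments. Implements the four standard candidate-selection
algorithms on a genes × samples Cq matrix:

- **geNorm-style M** — mean pairwise variation of log2 expression
  ratios, stepwise exclusion of the least stable gene, and the
  pairwise-variation rule `V[n/n+1] <= 0.15` for the number of
  reference genes a normalization factor needs;
- **NormFinder-style model-based stability** — separates intragroup
  variance from shrunken intergroup expression differences (multi-group
  and single-group modes);
- **BestKeeper-style descriptives** — per-gene Cq dispersion (the
  applet's "SD" is the mean absolute deviation), CV, and Pearson
  correlation with the per-sample geometric-mean Cq index;
- **comparative ΔCq** — mean over partner genes of the SD of pairwise
  Cq differences.

On top of those: rank-sum consensus across methods with inter-method
concordance correlations, relative target-gene expression (`2^-ΔCq`)
against single- or geometric-mean multi-gene references with
control-group scaling, and a seeded synthetic-data generator with known
ground truth for end-to-end validation.

## CLI

All functionality is exposed through one entry point:

```sh
# synthetic data with known truth
refstab simulate --config examples/sim.yaml --seed 42 \
    --out cq.tsv --metadata-out meta.tsv --truth-out truth.json

# one stability method
refstab stability --cq cq.tsv --metadata meta.tsv \
    --method genorm --v-cutoff 0.15 --outdir out/genorm
refstab stability --cq cq.tsv --metadata meta.tsv \
    --method normfinder --group-by cell_source,loading --outdir out/nf

# all four methods + rank-sum consensus + concordance matrix,
# optionally on a condition subset
refstab run-all --cq cq.tsv --metadata meta.tsv \
    --group-by cell_source,loading \
    --subset "cell_source == 'N-SF'" --outdir out/all

# relative target expression against a reference aggregate
refstab normalize --cq cq.tsv --metadata meta.tsv \
    --targets reg --refs g1,g2 --control "N-SF:control" \
    --group-by cell_source,loading --outdir out/expr
```

Input formats (TSV/CSV, `.` decimal separator):

- wide Cq table: first column `gene`, one column per sample (a
  transposed file whose first column is `sample` is auto-detected);
- long Cq table: columns `sample, gene, replicate, Cq` — technical
  replicates are collapsed by their arithmetic mean;
- metadata: columns `sample, cell_source, loading` (plus free extras);
- efficiencies: columns `gene, E` with `E` in (1, 2]; genes without an
  entry default to `E = 2` (perfect doubling).

## Library use

```python
from refstab import (
    read_cq_table, to_quantities, genorm_m, optimal_reference_number,
    normfinder_stability, bestkeeper_stats, deltacq_stability,
)
from refstab.consensus import run_all_methods, consensus_analysis

cq = read_cq_table("cq.tsv", layout="wide", metadata_path="meta.tsv")
st = run_all_methods(cq, group_by=["cell_source", "loading"])
result = consensus_analysis(st)
print(result.consensus_order)
```
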