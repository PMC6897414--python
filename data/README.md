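# data/

Drop-in location for the source study's raw Cq table (distributed only
as a supplementary word-processor file of the publication; not bundled
and not fetchable offline). Export it as two plain-text files:

## study_cq.tsv

Wide layout, tab-separated. First column `gene`, one column per
biological sample holding the arithmetic triplet-mean Cq:

```
gene	NSF_ctrl_1	NSF_ctrl_2	...
EEF1A1	19.43	19.51	...
GAPDH	20.87	21.02	...
...
```

Expected genes: EEF1A1, GAPDH, POLR2A, PPIB, RNA18S, RPL22, RPLP0,
TBP, YWHAZ (order free). Sample names are free but must match the
metadata file.

## study_metadata.tsv

Tab-separated, one row per sample:

```
sample	cell_source	loading
NSF_ctrl_1	N-SF	control
NSF_press_1	N-SF	pressure
OASF_ctrl_1	OA-SF	control
...
```

`cell_source ∈ {N-SF, OA-SF}`, `loading ∈ {control, pressure}`.

With both files present, the dataset-bound tests in
`tests/test_acceptance.py` run against the real data and
`scripts/acceptance.py` emits all targets.
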