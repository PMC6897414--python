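"""Loader for the study's raw Cq dataset, if deposited.

The raw per-sample mean Cq values live in a supplementary word-processor
table of the source publication and are not redistributable here. To run
the dataset-bound acceptance checks, export them as:

  data/study_cq.tsv       wide layout: first column 'gene', one column
                          per sample, arithmetic triplet-mean Cq values
  data/study_metadata.tsv columns: sample, cell_source (N-SF|OA-SF),
                          loading (control|pressure)

Without these files the dataset-bound checks fail with a clear message.
"""

from __future__ import annotations

from pathlib import Path

REPO_ROOT = Path(__file__).resolve().parents[1]
CQ_PATH = REPO_ROOT / "data" / "study_cq.tsv"
METADATA_PATH = REPO_ROOT / "data" / "study_metadata.tsv"

MISSING_MSG = (
    "study Cq dataset not deposited: expected data/study_cq.tsv and "
    "data/study_metadata.tsv (see tests/_study_data.py for the format). "
    "The raw values are only distributed as a supplementary file of the "
    "source publication and could not be fetched in this offline build; "
    "dataset-bound checks cannot pass without them."
)


def study_dataset_available() -> bool:
    return CQ_PATH.exists() and METADATA_PATH.exists()


def load_study_cq():
    from refstab.cq_data import read_cq_table

    if not study_dataset_available():
        raise FileNotFoundError(MISSING_MSG)
    return read_cq_table(CQ_PATH, layout="wide", metadata_path=METADATA_PATH)
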