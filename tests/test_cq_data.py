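from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab.cq_data import (
    CqDataError,
    CqMatrix,
    EfficiencyTable,
    collapse_replicates,
    filter_samples,
    read_cq_table,
    to_quantities,
)

from conftest import make_cq


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _write_meta(tmp_path, samples, cell_source=None, loading=None):
    meta = pd.DataFrame({
        "sample": samples,
        "cell_source": cell_source or ["N-SF"] * len(samples),
        "loading": loading or ["control"] * len(samples),
    })
    path = tmp_path / "meta.tsv"
    meta.to_csv(path, sep="\t", index=False)
    return path


class TestReadWide:
    def test_basic_wide(self, tmp_path):
        path = tmp_path / "cq.tsv"
        path.write_text("gene\ts1\ts2\nA\t20\t21\nB\t22\t23\n")
        meta = _write_meta(tmp_path, ["s1", "s2"])
        cq = read_cq_table(path, layout="wide", metadata_path=meta)
        assert cq.genes == ["A", "B"]
        assert cq.samples == ["s1", "s2"]
        assert cq.values.loc["A", "s2"] == 21.0

    def test_transposed_wide_detected(self, tmp_path):
        path = tmp_path / "cq.tsv"
        path.write_text("sample\tA\tB\ns1\t20\t22\ns2\t21\t23\n")
        meta = _write_meta(tmp_path, ["s1", "s2"])
        cq = read_cq_table(path, layout="wide", metadata_path=meta)
        assert cq.genes == ["A", "B"]
        assert cq.values.loc["B", "s2"] == 23.0

    def test_undetermined_cell_becomes_missing(self, tmp_path):
        path = tmp_path / "cq.tsv"
        path.write_text("gene\ts1\ts2\nA\tUndetermined\t21\nB\t22\t23\n")
        meta = _write_meta(tmp_path, ["s1", "s2"])
        cq = read_cq_table(path, layout="wide", metadata_path=meta)
        assert np.isnan(cq.values.loc["A", "s1"])
        assert cq.values.loc["A", "s2"] == 21.0

    def test_duplicate_gene_errors(self, tmp_path):
        path = tmp_path / "cq.tsv"
        path.write_text("gene\ts1\nA\t20\nA\t21\n")
        meta = _write_meta(tmp_path, ["s1"])
        with pytest.raises(CqDataError, match="duplicate gene"):
            read_cq_table(path, layout="wide", metadata_path=meta)

    def test_metadata_missing_sample_named(self, tmp_path):
        path = tmp_path / "cq.tsv"
        path.write_text("gene\ts1\tsX\nA\t20\t21\n")
        meta = _write_meta(tmp_path, ["s1"])
        with pytest.raises(CqDataError, match="sX"):
            read_cq_table(path, layout="wide", metadata_path=meta)

    def test_sample_order_follows_metadata(self, tmp_path):
        path = tmp_path / "cq.tsv"
        path.write_text("gene\ts2\ts1\nA\t21\t20\n")
        meta = _write_meta(tmp_path, ["s1", "s2"])
        cq = read_cq_table(path, layout="wide", metadata_path=meta)
        assert cq.samples == ["s1", "s2"]


class TestReadLong:
    def test_single_cell(self, tmp_path):
        path = tmp_path / "cq.csv"
        path.write_text("sample,gene,replicate,Cq\ns1,A,1,20\n")
        meta = _write_meta(tmp_path, ["s1"])
        cq = read_cq_table(path, layout="long", metadata_path=meta)
        assert cq.values.shape == (1, 1)
        assert cq.values.loc["A", "s1"] == 20.0

    def test_replicates_retained(self, tmp_path):
        path = tmp_path / "cq.csv"
        path.write_text(
            "sample,gene,replicate,Cq\n"
            "s1,A,1,20.0\ns1,A,2,20.2\ns1,A,3,20.4\n"
        )
        meta = _write_meta(tmp_path, ["s1"])
        cq = read_cq_table(path, layout="long", metadata_path=meta)
        assert cq.replicates is not None
        assert len(cq.replicates) == 3


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

class TestValidation:
    def test_nonpositive_cq_rejected(self):
        with pytest.raises(CqDataError, match="positive"):
            make_cq({"A": [20, -1]})

    def test_vocab_enforced(self):
        df = pd.DataFrame({"s1": [20.0]}, index=["A"])
        meta = pd.DataFrame({"cell_source": ["Weird"], "loading": ["control"]},
                            index=["s1"])
        with pytest.raises(CqDataError, match="vocabulary"):
            CqMatrix(values=df, metadata=meta)

    def test_out_of_window_warns_but_loads(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            cq = make_cq({"A": [50, 20]})
        assert cq.values.loc["A", "s1"] == 50.0
        assert any("sanity window" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# replicate collapsing
# ---------------------------------------------------------------------------

class TestCollapseReplicates:
    def _raw(self, reps: list[float | None]) -> CqMatrix:
        cq = make_cq({"A": [20.0]})
        cq.replicates = pd.DataFrame({
            "gene": ["A"] * len(reps),
            "sample": ["s1"] * len(reps),
            "replicate": list(range(1, len(reps) + 1)),
            "Cq": [np.nan if r is None else r for r in reps],
        })
        return cq

    def test_triplet_mean(self):
        out = collapse_replicates(self._raw([20.0, 20.2, 20.4]))
        assert out.values.loc["A", "s1"] == pytest.approx(20.2)
        assert out.replicate_n.loc["A", "s1"] == 3

    def test_single_replicate_identity(self):
        out = collapse_replicates(self._raw([19.5]))
        assert out.values.loc["A", "s1"] == 19.5

    def test_missing_replicate_skipped(self):
        out = collapse_replicates(self._raw([20.0, None, 22.0]))
        assert out.values.loc["A", "s1"] == pytest.approx(21.0)
        assert out.replicate_n.loc["A", "s1"] == 2

    def test_all_missing_stays_missing(self):
        out = collapse_replicates(self._raw([None, None]))
        assert np.isnan(out.values.loc["A", "s1"])

    def test_idempotent_on_collapsed(self, toy_cq):
        assert collapse_replicates(toy_cq) is toy_cq
        roundtrip = collapse_replicates(collapse_replicates(toy_cq))
        pd.testing.assert_frame_equal(roundtrip.values, toy_cq.values)


# ---------------------------------------------------------------------------
# efficiency transform
# ---------------------------------------------------------------------------

class TestToQuantities:
    def test_powers_of_two(self):
        cq = make_cq({"A": [20, 21, 23]})
        q = to_quantities(cq)
        np.testing.assert_allclose(q.values.loc["A"], [1, 0.5, 0.125])

    def test_e_19(self):
        cq = make_cq({"A": [20, 21, 23]})
        q = to_quantities(cq, EfficiencyTable({"A": 1.9}))
        np.testing.assert_allclose(
            q.values.loc["A"], [1.0, 1.9 ** -1, 1.9 ** -3], rtol=1e-12
        )
        np.testing.assert_allclose(
            q.values.loc["A"], [1.0, 10 / 19, 1000 / 6859]  # 1.9^0, 1.9^-1, 1.9^-3
        )

    def test_constant_gene(self):
        cq = make_cq({"A": [18, 18, 18]})
        q = to_quantities(cq, EfficiencyTable({"A": 1.7}))
        np.testing.assert_allclose(q.values.loc["A"], [1, 1, 1])

    def test_bad_efficiency_rejected(self):
        with pytest.raises(CqDataError, match=r"\(1, 2\]"):
            EfficiencyTable({"A": 1.0})
        with pytest.raises(CqDataError):
            EfficiencyTable({"A": 2.3})

    def test_all_missing_gene_errors(self):
        cq = make_cq({"A": [20, 21], "B": [20, 21]})
        cq.values.loc["A"] = np.nan
        with pytest.raises(CqDataError, match="A"):
            to_quantities(cq)

    def test_missing_propagated(self):
        cq = make_cq({"A": [20, np.nan, 23]})
        q = to_quantities(cq)
        assert np.isnan(q.values.loc["A", "s2"])

    @given(
        cqs=st.lists(st.floats(min_value=5, max_value=40), min_size=2, max_size=8),
        e=st.floats(min_value=1.01, max_value=2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_log_roundtrip(self, cqs, e):
        # log base E of Q recovers Cq_min - Cq exactly
        cq = make_cq({"A": cqs})
        q = to_quantities(cq, EfficiencyTable({"A": e}))
        recovered = np.log(q.values.loc["A"].to_numpy()) / np.log(e)
        expected = min(cqs) - np.asarray(cqs)
        np.testing.assert_allclose(recovered, expected, atol=1e-12)

    @given(
        cqs=st.lists(st.floats(min_value=5, max_value=40), min_size=3, max_size=8),
        e=st.floats(min_value=1.01, max_value=2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_ratio_structure(self, cqs, e):
        # Q ratios between samples depend only on their Cq difference
        cq = make_cq({"A": cqs})
        q = to_quantities(cq, EfficiencyTable({"A": e})).values.loc["A"].to_numpy()
        ratio = q[0] / q[1]
        np.testing.assert_allclose(ratio, e ** (cqs[1] - cqs[0]), rtol=1e-9)


# ---------------------------------------------------------------------------
# sample filtering
# ---------------------------------------------------------------------------

class TestFilterSamples:
    def _pooled(self) -> CqMatrix:
        return make_cq(
            {"A": [20] * 4, "B": [22] * 4, "C": [20, 21, 20, 21]},
            cell_source=["N-SF", "N-SF", "OA-SF", "OA-SF"],
            loading=["control", "pressure", "control", "pressure"],
        )

    def test_query_subset(self):
        sub = filter_samples(self._pooled(), "cell_source == 'N-SF'")
        assert sub.n_samples == 2
        assert set(sub.metadata.loc[sub.samples, "cell_source"]) == {"N-SF"}

    def test_always_true_identity(self):
        cq = self._pooled()
        sub = filter_samples(cq, lambda row: True)
        pd.testing.assert_frame_equal(sub.values, cq.values)

    def test_empty_result_errors(self):
        cq = make_cq({"A": [20, 21]}, loading=["control", "control"])
        with pytest.raises(CqDataError, match="no samples"):
            filter_samples(cq, "loading == 'pressure'")


def test_wide_tsv_roundtrip(tmp_path, toy_cq):
    path = tmp_path / "out.tsv"
    toy_cq.to_tsv(path)
    meta_path = tmp_path / "meta.tsv"
    toy_cq.metadata.reset_index(names="sample").to_csv(meta_path, sep="\t", index=False)
    back = read_cq_table(path, layout="wide", metadata_path=meta_path)
    pd.testing.assert_frame_equal(back.values, toy_cq.values)
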