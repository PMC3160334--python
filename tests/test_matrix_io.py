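"""Matrix/GMT parsing, probe filtering and collapsing, gene normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromsig import (
    ExpressionMatrix,
    GeneModule,
    ProbeMatrix,
    collapse_probes,
    filter_probes,
    gene_normalize,
    read_matrix,
    read_modules,
    write_matrix,
    write_modules,
)
from chromsig.errors import (
    MatrixFormatError,
    ModuleFormatError,
    NormalizationError,
    ParameterError,
)


def _write(tmp_path, text, name="m.tsv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadMatrix:
    def test_round_trip_expression(self, tmp_path, small_expression_matrix):
        path = tmp_path / "m.tsv"
        write_matrix(small_expression_matrix, path)
        back = read_matrix(path)
        pd.testing.assert_frame_equal(back.values, small_expression_matrix.values)
        pd.testing.assert_series_equal(
            back.sample_groups, small_expression_matrix.sample_groups
        )

    def test_round_trip_probe_matrix(self, tmp_path):
        pm = ProbeMatrix(
            values=pd.DataFrame(
                [[1.0, 2.0], [3.0, np.nan]], index=["p1", "p2"], columns=["s1", "s2"]
            ),
            probe_to_gene=pd.Series(["GA", "GA"], index=["p1", "p2"]),
        )
        path = tmp_path / "pm.tsv"
        write_matrix(pm, path)
        back = read_matrix(path)
        assert isinstance(back, ProbeMatrix)
        pd.testing.assert_frame_equal(back.values, pm.values)
        assert back.probe_to_gene.tolist() == ["GA", "GA"]

    def test_well_formed_2x2(self, tmp_path):
        path = _write(tmp_path, "id\ts1\ts2\nGA\t1\t2\nGB\t3\t4\n")
        em = read_matrix(path)
        assert em.values.shape == (2, 2)

    def test_missing_cells_are_nan_not_zero(self, tmp_path):
        path = _write(tmp_path, "id\ts1\ts2\nGA\t\t2\nGB\tNA\t4\n")
        em = read_matrix(path)
        assert em.values.loc["GA", "s1"] != 0 and np.isnan(em.values.loc["GA", "s1"])
        assert np.isnan(em.values.loc["GB", "s1"])

    def test_ragged_row_names_line(self, tmp_path):
        path = _write(tmp_path, "id\ts1\ts2\nGA\t1\t2\nGB\t3\n")
        with pytest.raises(MatrixFormatError, match=":3"):
            read_matrix(path)

    def test_duplicate_sample_header(self, tmp_path):
        path = _write(tmp_path, "id\ts1\ts1\nGA\t1\t2\n")
        with pytest.raises(MatrixFormatError, match="duplicated sample"):
            read_matrix(path)

    def test_empty_file(self, tmp_path):
        with pytest.raises(MatrixFormatError, match="empty"):
            read_matrix(_write(tmp_path, ""))


class TestFilterProbes:
    def _pm(self, rows, genes, scale="log2"):
        values = pd.DataFrame(
            rows,
            index=[f"p{i}" for i in range(len(rows))],
            columns=[f"s{j}" for j in range(len(rows[0]))],
        )
        return ProbeMatrix(
            values=values,
            probe_to_gene=pd.Series(genes, index=values.index),
            scale=scale,
        )

    def test_probe_at_detection_floor_dropped(self):
        pm = self._pm(
            [[0.0, 0.0, 0.0], [5.0, 6.0, 7.0]], ["GA", "GB"]
        )
        out = filter_probes(pm)
        assert list(out.values.index) == ["p1"]

    def test_singleton_probe_untouched_by_correlation_filter(self):
        pm = self._pm([[5.0, 1.0, 3.0]], ["GA"])
        out = filter_probes(pm, min_interprobe_pcc=0.99)
        assert list(out.values.index) == ["p0"]

    def test_anti_tracking_probe_dropped(self):
        # two probes track each other perfectly; the third anti-tracks both
        base = [1.0, 2.0, 3.0, 4.0]
        pm = self._pm(
            [base, [x + 1 for x in base], [5.0 - x for x in base]],
            ["GA", "GA", "GA"],
        )
        out = filter_probes(pm, min_interprobe_pcc=0.5)
        assert list(out.values.index) == ["p0", "p1"]

    def test_threshold_outside_range_rejected(self):
        pm = self._pm([[1.0, 2.0]], ["GA"])
        with pytest.raises(ParameterError):
            filter_probes(pm, min_interprobe_pcc=1.5)


class TestCollapseProbes:
    def test_mean_of_probe_rows(self):
        pm = ProbeMatrix(
            values=pd.DataFrame(
                [[2.0, 4.0], [4.0, 6.0]], index=["p1", "p2"], columns=["s1", "s2"]
            ),
            probe_to_gene=pd.Series(["GA", "GA"], index=["p1", "p2"]),
        )
        em = collapse_probes(pm)
        assert em.values.loc["GA"].tolist() == [3.0, 5.0]
        assert em.scale == "log2_absolute"

    def test_single_probe_identity(self):
        pm = ProbeMatrix(
            values=pd.DataFrame([[1.5, 2.5]], index=["p1"], columns=["s1", "s2"]),
            probe_to_gene=pd.Series(["GA"], index=["p1"]),
        )
        assert collapse_probes(pm).values.loc["GA"].tolist() == [1.5, 2.5]

    def test_linear_input_log2_before_averaging(self):
        pm = ProbeMatrix(
            values=pd.DataFrame([[8.0, 2.0]], index=["p1"], columns=["s1", "s2"]),
            probe_to_gene=pd.Series(["GA"], index=["p1"]),
            scale="linear",
        )
        assert collapse_probes(pm).values.loc["GA"].tolist() == [3.0, 1.0]


class TestGeneNormalize:
    def test_simple_row(self):
        em = ExpressionMatrix(
            values=pd.DataFrame([[1.0, 2.0, 3.0]], index=["GA"], columns=list("abc")),
            scale="log2_absolute",
        )
        out = gene_normalize(em)
        assert out.values.loc["GA"].tolist() == [-1.0, 0.0, 1.0]
        assert out.scale == "gene_normalized"

    def test_constant_row_flagged_not_divided(self):
        em = ExpressionMatrix(
            values=pd.DataFrame([[5.0, 5.0, 5.0]], index=["GA"], columns=list("abc")),
            scale="log2_absolute",
        )
        out = gene_normalize(em)
        assert out.values.loc["GA"].tolist() == [0.0, 0.0, 0.0]
        assert "GA" in out.constant_genes

    def test_sample_sd_convention(self):
        em = ExpressionMatrix(
            values=pd.DataFrame([[0.0, 0.0, 4.0, 4.0]], index=["GA"], columns=list("abcd")),
            scale="log2_absolute",
        )
        out = gene_normalize(em)
        # sample s.d. (ddof=1) of (0,0,4,4) is 2.3094; normalized ±0.8660
        np.testing.assert_allclose(
            out.values.loc["GA"].to_numpy(), [-0.8660254, -0.8660254, 0.8660254, 0.8660254]
        )

    def test_single_sample_rejected(self):
        em = ExpressionMatrix(
            values=pd.DataFrame([[1.0]], index=["GA"], columns=["s1"]),
            scale="log2_absolute",
        )
        with pytest.raises(NormalizationError):
            gene_normalize(em)

    def test_normalized_rows_mean_zero_unit_sd(self, small_expression_matrix):
        out = gene_normalize(small_expression_matrix)
        vals = out.values
        for g in vals.index:
            if g in out.constant_genes:
                continue
            assert abs(vals.loc[g].mean()) < 1e-9
            assert abs(vals.loc[g].std(ddof=1) - 1.0) < 1e-9

    def test_idempotent(self, small_expression_matrix):
        once = gene_normalize(small_expression_matrix)
        twice = gene_normalize(once)
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), atol=1e-12
        )
        assert twice.constant_genes == once.constant_genes

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(perm=st.permutations([0, 1, 2, 3]))
    def test_collapse_then_normalize_commutes_with_column_permutation(self, perm):
        values = pd.DataFrame(
            np.random.default_rng(2).normal(5.0, 2.0, size=(6, 4)),
            index=[f"G{i}" for i in range(6)],
            columns=["s1", "s2", "s3", "s4"],
        )
        em = ExpressionMatrix(values=values, scale="log2_absolute")
        cols = [em.values.columns[i] for i in perm]
        shuffled = ExpressionMatrix(
            values=em.values[cols], scale=em.scale, sample_groups=em.sample_groups
        )
        a = gene_normalize(em).values[cols]
        b = gene_normalize(shuffled).values
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)


class TestModules:
    def test_gmt_round_trip(self, tmp_path):
        mods = [
            GeneModule("M1", frozenset({"A", "B", "C"}), "src1"),
            GeneModule("M2", frozenset({"D"}), "src2"),
        ]
        path = tmp_path / "m.gmt"
        write_modules(mods, path)
        back = read_modules(path)
        assert {(m.name, m.genes) for m in back} == {(m.name, m.genes) for m in mods}

    def test_gmt_line_parses(self, tmp_path):
        path = _write(tmp_path, "M1\tsrc\tA\tB\tC\n", "m.gmt")
        (m,) = read_modules(path)
        assert m.name == "M1" and m.genes == frozenset({"A", "B", "C"})

    def test_duplicate_gene_counted_once(self, tmp_path, caplog):
        path = _write(tmp_path, "M1\tsrc\tA\tB\tA\n", "m.gmt")
        (m,) = read_modules(path)
        assert m.size == 2

    def test_symbols_uppercased(self, tmp_path):
        path = _write(tmp_path, "M1\tsrc\tkdm5a\tEzh2\n", "m.gmt")
        (m,) = read_modules(path)
        assert m.genes == frozenset({"KDM5A", "EZH2"})

    def test_empty_file_gives_empty_list(self, tmp_path):
        assert read_modules(_write(tmp_path, "", "m.gmt")) == []

    def test_module_without_genes_rejected(self, tmp_path):
        path = _write(tmp_path, "M1\tsrc\n", "m.gmt")
        with pytest.raises(ModuleFormatError):
            read_modules(path)

    def test_empty_module_object_rejected(self):
        with pytest.raises(ModuleFormatError):
            GeneModule("M1", frozenset())
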