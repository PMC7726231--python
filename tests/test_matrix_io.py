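import numpy as np
import pandas as pd
import pytest

from degpath.errors import ConfigurationError, ParseError, ValidationError
from degpath.matrix_io import (
    ExpressionMatrix,
    GeneSetCollection,
    RAW,
    StudyDesign,
    collapse_probes,
    filter_by_quality,
    read_design,
    read_expression_matrix,
    read_gmt,
    write_design,
    write_expression_matrix,
    write_gmt,
    write_results_table,
)


def _write(path, text):
    path.write_text(text)
    return path


class TestReadExpressionMatrix:
    def test_basic_parse(self, tmp_path):
        p = _write(tmp_path / "m.tsv",
                   "gene_id\tS1\tS2\nGA\t1.5\t2.5\nGB\t3\t4\nGC\t5\t6\n")
        m = read_expression_matrix(p)
        assert m.gene_ids == ["GA", "GB", "GC"]
        assert m.sample_ids == ["S1", "S2"]
        assert m.scale == RAW
        assert m.values.loc["GB", "S2"] == 4.0

    def test_case_normalization_makes_duplicates_an_error(self, tmp_path):
        p = _write(tmp_path / "m.tsv",
                   "gene_id\tS1\nrps10\t1\nRPS10\t2\n")
        with pytest.raises(ValidationError, match="RPS10"):
            read_expression_matrix(p)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = _write(tmp_path / "m.tsv",
                   "gene_id\tS1\tS2\nGA\t1\tx\n")
        with pytest.raises(ParseError, match="GA.*S2"):
            read_expression_matrix(p)

    def test_ragged_row_rejected(self, tmp_path):
        p = _write(tmp_path / "m.tsv",
                   "gene_id\tS1\tS2\nGA\t1\n")
        with pytest.raises(ParseError):
            read_expression_matrix(p)

    def test_round_trip_full_precision(self, tmp_path, rng):
        values = pd.DataFrame(rng.lognormal(5, 2, size=(20, 6)),
                              index=[f"G{i}" for i in range(20)],
                              columns=[f"S{i}" for i in range(6)])
        quality = pd.DataFrame(rng.uniform(0, 1, size=(20, 6)),
                               index=values.index, columns=values.columns)
        m = ExpressionMatrix(values, quality, RAW)
        write_expression_matrix(m, tmp_path / "v.tsv", tmp_path / "q.tsv")
        back = read_expression_matrix(tmp_path / "v.tsv", tmp_path / "q.tsv")
        assert np.array_equal(back.values.to_numpy(), values.to_numpy())
        assert np.array_equal(back.quality.to_numpy(), quality.to_numpy())


class TestQualityFilter:
    def _matrix(self, q):
        genes = [f"G{i}" for i in range(q.shape[0])]
        samples = [f"S{i}" for i in range(q.shape[1])]
        values = pd.DataFrame(1.0, index=genes, columns=samples)
        return ExpressionMatrix(values, pd.DataFrame(q, index=genes, columns=samples))

    def test_boundary_score_is_excluded(self):
        # strict inequality: a score exactly at the threshold fails the gene
        q = np.ones((5, 3))
        q[2, 1] = 0.95
        kept = filter_by_quality(self._matrix(q), 0.95)
        assert kept.n_genes == 4
        assert "G2" not in kept.gene_ids

    def test_all_ones_is_identity(self):
        m = self._matrix(np.ones((5, 3)))
        assert filter_by_quality(m, 0.95).gene_ids == m.gene_ids

    def test_threshold_zero_keeps_all_positive_scores(self, rng):
        m = self._matrix(rng.uniform(0.01, 1.0, size=(30, 4)))
        assert filter_by_quality(m, 0.0).n_genes == 30

    def test_matches_exhaustive_scan(self, rng):
        q = rng.uniform(0.8, 1.0, size=(50, 4))
        m = self._matrix(q)
        kept = filter_by_quality(m, 0.95)
        # brute-force oracle: scan every gene/sample score
        expected = [g for i, g in enumerate(m.gene_ids)
                    if all(q[i, j] > 0.95 for j in range(4))]
        assert kept.gene_ids == expected
        assert kept.n_genes <= m.n_genes

    def test_missing_quality_is_configuration_error(self, rng):
        values = pd.DataFrame(rng.uniform(1, 2, size=(3, 2)),
                              index=list("ABC"), columns=["S1", "S2"])
        with pytest.raises(ConfigurationError):
            filter_by_quality(ExpressionMatrix(values), 0.95)


class TestGmt:
    def test_parse_single_set(self, tmp_path):
        p = _write(tmp_path / "s.gmt", "S1\td\tG1\tG2\n")
        c = read_gmt(p)
        assert c.members("S1") == ("G1", "G2")

    def test_duplicate_members_deduplicated(self, tmp_path):
        p = _write(tmp_path / "s.gmt", "S1\td\tG1\tg1\tG2\n")
        assert read_gmt(p).members("S1") == ("G1", "G2")

    def test_short_line_reports_line_number(self, tmp_path):
        p = _write(tmp_path / "s.gmt", "S1\td\tG1\nS2\tonly-two-fields\n")
        with pytest.raises(ParseError, match=":2:"):
            read_gmt(p)

    def test_round_trip_50_random_sets(self, tmp_path, rng):
        genes = [f"G{i:04d}" for i in range(500)]
        sets = {}
        for i in range(50):
            size = int(rng.integers(1, 30))
            members = tuple(sorted(rng.choice(genes, size=size, replace=False)))
            sets[f"SET{i:02d}"] = (f"desc {i}", members)
        c = GeneSetCollection(sets)
        write_gmt(c, tmp_path / "x.gmt")
        back = read_gmt(tmp_path / "x.gmt")
        assert back.names() == c.names()
        for name in c.names():
            assert back.members(name) == c.members(name)


class TestDesign:
    def test_round_trip_and_group_lookup(self, tmp_path, two_group_design):
        write_design(two_group_design, tmp_path / "d.csv")
        d = read_design(tmp_path / "d.csv", control="ctrl")
        assert d.control_samples == ["C1", "C2"]
        assert d.treatment_label == "trt"

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            StudyDesign({"A": "x", "B": "y", "C": "y"}, "x", "y")

    def test_three_groups_rejected(self, tmp_path):
        _write(tmp_path / "d.csv",
               "sample_id,group\nA,x\nB,x\nC,y\nD,y\nE,z\nF,z\n")
        with pytest.raises(ValidationError):
            read_design(tmp_path / "d.csv", control="x")


class TestResultsTable:
    def test_empty_sequence_gives_header_only(self, tmp_path):
        write_results_table([], tmp_path / "r.tsv", columns=["a", "b"])
        assert (tmp_path / "r.tsv").read_text() == "a\tb\n"

    def test_one_row_gives_two_lines(self, tmp_path):
        write_results_table([{"a": 1, "b": 2.5}], tmp_path / "r.tsv")
        lines = (tmp_path / "r.tsv").read_text().splitlines()
        assert lines == ["a\tb", "1\t2.5"]

    def test_reparsed_pvalues_accurate_to_1e6_relative(self, tmp_path, rng):
        rows = [{"gene_id": f"G{i}", "p_value": float(p)}
                for i, p in enumerate(rng.uniform(1e-8, 1, size=200))]
        write_results_table(rows, tmp_path / "r.tsv")
        back = pd.read_csv(tmp_path / "r.tsv", sep="\t")
        orig = np.array([r["p_value"] for r in rows])
        assert np.allclose(back["p_value"], orig, rtol=1e-6, atol=0)


def test_collapse_probes_keeps_max_mean_probe():
    values = pd.DataFrame(
        [[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]],
        index=["P1", "P2", "P3"], columns=["S1", "S2"])
    out = collapse_probes(values, {"P1": "GA", "P2": "GA", "P3": "GB"})
    assert list(out.index) == ["GA", "GB"]
    assert out.loc["GA", "S1"] == 5.0
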