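"""Edge-table, gene-list and report I/O contracts."""

import json

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from leadnet import (GeneList, InteractionNetwork, ParseError, RunConfig,
                     ValidationError, read_annotation_table, read_edge_table,
                     read_gene_list, read_ontology_edges, write_edge_table,
                     write_gene_list, write_report)
from leadnet.io import illustrative_seed_list, read_edge_table_isolated_aware


def _write(tmp_path, text, name="edges.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestEdgeTable:
    def test_symmetric_duplicate_collapses(self, tmp_path):
        p = _write(tmp_path, "A\tB\t900\nB\tA\t900\n")
        net = read_edge_table(p, dialect="string_integer")
        assert net.edges() == [("A", "B", 0.9)]

    def test_self_loop_dropped_with_warning(self, tmp_path, caplog):
        p = _write(tmp_path, "A\tB\t0.95\nA\tA\t0.99\n")
        with caplog.at_level("WARNING", logger="leadnet"):
            net = read_edge_table(p, dialect="unit_float")
        assert net.edges() == [("A", "B", 0.95)]
        assert "A" in net.nodes
        assert any("self-loop" in r.message for r in caplog.records)

    def test_duplicate_pair_keeps_max_score(self, tmp_path):
        p = _write(tmp_path, "A\tB\t850\nA\tB\t900\n")
        net = read_edge_table(p, dialect="string_integer")
        assert net.edges() == [("A", "B", 0.9)]

    def test_header_detected_by_non_numeric_third_column(self, tmp_path):
        p = _write(tmp_path, "gene1\tgene2\tcombined_score\nA\tB\t0.9\n")
        assert read_edge_table(p).edges() == [("A", "B", 0.9)]

    def test_auto_dialect_integer_when_all_scores_exceed_one(self, tmp_path):
        ints = read_edge_table(_write(tmp_path, "A\tB\t900\nB\tC\t950\n"))
        floats = read_edge_table(_write(tmp_path, "A\tB\t0.9\nB\tC\t0.95\n", "f.tsv"))
        assert ints.equals(floats)

    def test_malformed_row_names_line_number(self, tmp_path):
        p = _write(tmp_path, "A\tB\t0.9\nA\tB\n")
        with pytest.raises(ParseError, match="line 2"):
            read_edge_table(p)

    def test_score_out_of_bounds_rejected(self, tmp_path):
        p = _write(tmp_path, "A\tB\t1500\n")
        with pytest.raises(ValidationError, match="outside"):
            read_edge_table(p, dialect="string_integer")

    def test_symbols_case_normalised(self, tmp_path):
        net = read_edge_table(_write(tmp_path, "tp53\tCasp3\t0.9\n"))
        assert net.nodes == {"TP53", "CASP3"}

    @settings(max_examples=30, deadline=None, derandomize=True,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(st.lists(
        st.tuples(st.integers(0, 8), st.integers(0, 8),
                  st.floats(0.001, 1.0, allow_nan=False)),
        min_size=1, max_size=20).filter(lambda es: any(a != b for a, b, _ in es)))
    def test_write_read_round_trip_identity(self, tmp_path, edge_spec):
        net = InteractionNetwork()
        for a, b, s in edge_spec:
            if a != b:
                net.add_edge(f"N{a}", f"N{b}", s)
        path = tmp_path / "rt.tsv"
        write_edge_table(net, path)
        assert read_edge_table_isolated_aware(path).equals(net)


class TestGeneList:
    def test_dedup_and_case_normalisation(self, tmp_path):
        p = _write(tmp_path, "tp53\nHSP90AA1\nTP53\n", "g.txt")
        assert read_gene_list(p).symbols == ["TP53", "HSP90AA1"]

    def test_comment_lines_skipped(self, tmp_path):
        p = _write(tmp_path, "# header\nCASP3\n", "g.txt")
        assert read_gene_list(p).symbols == ["CASP3"]

    def test_empty_file_rejected(self, tmp_path):
        p = _write(tmp_path, "# only a comment\n", "g.txt")
        with pytest.raises(ValidationError):
            read_gene_list(p)

    def test_round_trip(self, tmp_path):
        genes = GeneList(["TP53", "CASP3"])
        p = tmp_path / "g.txt"
        write_gene_list(genes, p)
        assert read_gene_list(p) == genes

    def test_bundled_illustrative_list_has_tp53(self):
        seeds = illustrative_seed_list()
        assert "TP53" in seeds.symbols and len(seeds) == 20


class TestAnnotationOntologyIO:
    def test_annotation_read_with_names(self, tmp_path):
        p = _write(tmp_path, "TP53\tT1\tapoptosis\nCASP3\tT1\nTP53\tT2\n", "a.tsv")
        annot = read_annotation_table(p)
        assert annot.pairs == {("TP53", "T1"), ("CASP3", "T1"), ("TP53", "T2")}
        assert annot.term_names["T1"] == "apoptosis"

    def test_ontology_read(self, tmp_path):
        ont = read_ontology_edges(_write(tmp_path, "T2\tT1\nT3\tT2\n", "o.tsv"))
        assert len(ont) == 2


class TestRunConfig:
    def test_defaults_mirror_published_analysis(self):
        cfg = RunConfig()
        assert (cfg.min_score, cfg.max_score) == (0.9, 0.99)
        assert cfg.expansion_steps == 1 and cfg.alpha == 0.001

    def test_inverted_band_rejected(self):
        with pytest.raises(ValidationError):
            RunConfig(min_score=0.99, max_score=0.9)

    def test_yaml_round_trip_with_override(self, tmp_path):
        p = _write(tmp_path, "min_score: 0.7\nexpansion_steps: 2\n", "c.yaml")
        cfg = RunConfig.from_yaml(p, max_score=0.95)
        assert (cfg.min_score, cfg.max_score, cfg.expansion_steps) == (0.7, 0.95, 2)

    def test_unknown_key_rejected(self, tmp_path):
        p = _write(tmp_path, "bogus: 1\n", "c.yaml")
        with pytest.raises(ValidationError, match="bogus"):
            RunConfig.from_yaml(p)


class TestWriteReport:
    def test_power_law_json_and_empty_enrichment(self, tmp_path):
        import pandas as pd
        manifest = write_report(
            {"power_law": {"exponent": 2.0, "r_squared": 1.0},
             "enrichment": pd.DataFrame(columns=["term", "p_value"])},
            tmp_path)
        fit = json.loads((tmp_path / "power_law.json").read_text())
        assert fit == {"exponent": 2.0, "r_squared": 1.0}
        assert (tmp_path / "enrichment.csv").read_text().startswith("term,p_value")
        assert set(manifest) == {"power_law", "enrichment"}

    def test_score_table_round_trip_exact(self, tmp_path):
        import pandas as pd
        df = pd.DataFrame({"gene": ["A", "B", "C"],
                           "wnl": [1.85, 1.8900000000000001, 1.94],
                           "tis": [1850, 1890, 1940]})
        import numpy as np
        write_report({"gene_scores": df}, tmp_path)
        back = pd.read_csv(tmp_path / "gene_scores.csv")
        assert np.allclose(back["wnl"], df["wnl"], rtol=1e-12, atol=0)
        assert (back["tis"] == df["tis"]).all()
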