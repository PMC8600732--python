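"""File readers/writers: schema enforcement, dedup, round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmmacnet import io


# ---------------------------------------------------------------- interactions

class TestReadInteractions:
    def test_duplicate_pairs_collapsed(self, tmp_path):
        f = tmp_path / "mg.tsv"
        f.write_text("m1\tg1\nm1\tg2\nm1\tg1\n")
        t = io.read_interactions(f, "miRNA", "gene")
        assert len(t) == 2
        assert t.edges == (("m1", "g1"), ("m1", "g2"))

    def test_three_rows_three_edges(self, tmp_path):
        f = tmp_path / "mg.tsv"
        f.write_text("m1\tg1\nm1\tg2\nm2\tg1\n")
        t = io.read_interactions(f, "miRNA", "gene")
        assert len(t) == 3 and t.source_class == "miRNA"

    def test_blank_identifier_names_line(self, tmp_path):
        f = tmp_path / "mg.tsv"
        f.write_text("m1\tg1\n\tg2\n")
        with pytest.raises(io.SchemaError, match=r":2"):
            io.read_interactions(f, "miRNA", "gene")

    def test_wrong_column_count_names_line(self, tmp_path):
        f = tmp_path / "mg.tsv"
        f.write_text("m1\tg1\nm1\tg2\textra\ttoomuch\n")
        with pytest.raises(io.SchemaError, match=r":2"):
            io.read_interactions(f, "miRNA", "gene")

    def test_comma_separated_rejected(self, tmp_path):
        f = tmp_path / "mg.csv"
        f.write_text("m1,g1\nm1,g2\n")
        with pytest.raises(io.SchemaError, match="TSV"):
            io.read_interactions(f, "miRNA", "gene")

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "mg.tsv"
        f.write_text("")
        with pytest.raises(io.SchemaError):
            io.read_interactions(f, "miRNA", "gene")

    def test_header_autodetected(self, tmp_path):
        f = tmp_path / "mg.tsv"
        f.write_text("source\ttarget\nm1\tg1\n")
        t = io.read_interactions(f, "miRNA", "gene")
        assert t.edges == (("m1", "g1"),)

    def test_evidence_whitelist_filters(self, tmp_path):
        f = tmp_path / "mg.tsv"
        f.write_text("m1\tg1\tWestern blot\nm1\tg2\tMicroarray\nm2\tg1\tLuciferase reporter assay\n")
        t = io.read_interactions(f, "miRNA", "gene",
                                 evidence_whitelist=["Western", "reporter"])
        assert set(t.edges) == {("m1", "g1"), ("m2", "g1")}

    def test_reader_deterministic(self, tmp_path):
        f = tmp_path / "mg.tsv"
        f.write_text("m2\tg9\nm1\tg1\nm1\tg4\n")
        assert io.read_interactions(f, "miRNA", "gene") == io.read_interactions(f, "miRNA", "gene")


# ---------------------------------------------------------------- expression

class TestReadExpression:
    def _write(self, tmp_path, rows, n_samples=10):
        f = tmp_path / "expr.tsv"
        header = "t\t" + "\t".join(f"s{i}" for i in range(n_samples))
        f.write_text("\n".join([header] + rows) + "\n")
        return f

    def test_clean_matrix(self, tmp_path):
        rows = [f"t{i}\t" + "\t".join(str(float(j)) for j in range(10)) for i in range(4)]
        m = io.read_expression(self._write(tmp_path, rows))
        assert m.values.shape == (4, 10)
        assert m.transcript_ids == ("t0", "t1", "t2", "t3")

    def test_na_row_dropped(self, tmp_path):
        rows = [f"t{i}\t" + "\t".join(["1.0"] * 10) for i in range(3)]
        rows.append("t3\t" + "\t".join(["1.0"] * 9 + ["NA"]))
        m = io.read_expression(self._write(tmp_path, rows))
        assert m.values.shape == (3, 10)
        assert "t3" not in m

    def test_too_few_samples_rejected(self, tmp_path):
        rows = ["t0\t1.0\t2.0"]
        with pytest.raises(io.SchemaError, match="3 sample"):
            io.read_expression(self._write(tmp_path, rows, n_samples=2))

    def test_duplicate_transcript_rejected(self, tmp_path):
        rows = ["t0\t" + "\t".join(["1"] * 10), "t0\t" + "\t".join(["2"] * 10)]
        with pytest.raises(io.SchemaError, match="duplicate"):
            io.read_expression(self._write(tmp_path, rows))


# ---------------------------------------------------------------- gmt / ids

class TestReadGmt:
    def test_two_sets(self, tmp_path):
        f = tmp_path / "sets.gmt"
        f.write_text("A\tdesc\tg1\tg2\tg3\nB\tdesc\tg4\tg5\n")
        sets = io.read_gmt(f)
        assert {k: len(v) for k, v in sets.items()} == {"A": 3, "B": 2}

    def test_memberless_set_is_empty(self, tmp_path):
        f = tmp_path / "sets.gmt"
        f.write_text("A\tdesc\nB\tdesc\tg1\n")
        assert io.read_gmt(f)["A"] == set()

    def test_duplicate_member_counted_once(self, tmp_path):
        f = tmp_path / "sets.gmt"
        f.write_text("A\tdesc\tg1\tg2\tg1\n")
        assert len(io.read_gmt(f)["A"]) == 2

    def test_duplicate_set_name_rejected(self, tmp_path):
        f = tmp_path / "sets.gmt"
        f.write_text("A\tdesc\tg1\nA\tdesc\tg2\n")
        with pytest.raises(io.SchemaError, match="duplicate"):
            io.read_gmt(f)


def test_id_list_dedup_and_roles(tmp_path):
    f = tmp_path / "ids.txt"
    f.write_text("# comment\ng1\ng2\ng1\n")
    lst = io.read_id_list(f, "risk_gene")
    assert lst.ids == ("g1", "g2")
    with pytest.raises(io.SchemaError):
        io.IdList("nonsense_role", ("a",))
    with pytest.raises(io.SchemaError):
        io.IdList("risk_gene", ())


# ---------------------------------------------------------------- network files

class TestNetworkRoundTrip:
    NODES = [("g1", "gene"), ("m1", "miRNA"), ("l1", "lncRNA")]
    EDGES = [("g1", "m1"), ("m1", "l1")]

    @pytest.mark.parametrize("fmt", ["tsv", "graphml"])
    def test_triplet_round_trip(self, tmp_path, fmt):
        p = tmp_path / f"net.{fmt}"
        io.write_network(self.NODES, self.EDGES, p, format=fmt)
        nodes, edges = io.read_network(p, format=fmt)
        assert nodes == set(self.NODES)
        assert edges == {tuple(sorted(e)) for e in self.EDGES}

    def test_empty_network(self, tmp_path):
        p = tmp_path / "net.tsv"
        io.write_network([("g1", "gene")], [], p)
        nodes, edges = io.read_network(p)
        assert nodes == {("g1", "gene")} and edges == set()

    def test_unknown_node_rejected(self, tmp_path):
        with pytest.raises(io.SchemaError, match="unknown node"):
            io.write_network(self.NODES, [("g1", "ghost")], tmp_path / "x.tsv")

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_random_networks_round_trip(self, tmp_path_factory, data):
        n = data.draw(st.integers(1, 12))
        classes = data.draw(st.lists(st.sampled_from(io.NODE_CLASSES),
                                     min_size=n, max_size=n))
        nodes = [(f"n{i}", c) for i, c in enumerate(classes)]
        possible = [(a[0], b[0]) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        edges = data.draw(st.lists(st.sampled_from(possible), unique=True,
                                   max_size=len(possible))) if possible else []
        p = tmp_path_factory.mktemp("rt") / "net.tsv"
        io.write_network(nodes, edges, p)
        rnodes, redges = io.read_network(p)
        assert rnodes == set(nodes)
        assert redges == {tuple(sorted(e)) for e in edges}


# ---------------------------------------------------------------- config

class TestRunConfig:
    def test_flat_file_round_trip(self, tmp_path):
        cfg = io.RunConfig(pcc_min=0.8, n_permutations=500, rng_seed=9)
        p = tmp_path / "run.cfg"
        cfg.to_flat_file(p)
        assert io.RunConfig.from_flat_file(p) == cfg

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "run.cfg"
        p.write_text("pcc_mim: 0.7\n")
        with pytest.raises(io.SchemaError, match="unknown config key"):
            io.RunConfig.from_flat_file(p)

    @pytest.mark.parametrize("kwargs", [
        {"ppi_min_confidence": 1.5},
        {"rwr_restart": 0.0},
        {"hyper_tail": "sideways"},
        {"mcode_kcore": 1},
        {"n_permutations": 0},
    ])
    def test_bounds_enforced(self, kwargs):
        with pytest.raises(ValueError):
            io.RunConfig(**kwargs)
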