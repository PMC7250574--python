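"""Regulator-table joins and temporal circuit chaining."""

import numpy as np
import pandas as pd
import pytest

from regcircuit.grn import (
    Circuit,
    GRNEdge,
    TFRecord,
    build_regulator_table,
    build_tf_map,
    chain_circuits,
    export_network,
    filter_by_sc_de,
    filter_expressed,
    target_overlap,
)
from regcircuit.intervals import PeakAnnotation
from regcircuit.motifs import PWM

REG_COLS = [
    "peak", "nearest_gene", "distance", "da_direction", "contrast",
    "motif_id", "tf_name", "tf_gene", "hit_score", "da_fdr",
]


def tf_map_for(*tfs):
    return {t: TFRecord(t, t, f"M_{t}") for t in tfs}


def da_frame(rows, contrast=("a", "b")):
    df = pd.DataFrame(rows, columns=["feature", "direction", "fdr"])
    df.attrs["contrast"] = contrast
    return df


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["peak", "motif_id", "tf_name", "offset", "strand", "score"])


def reg_table(rows, stage):
    df = pd.DataFrame(rows, columns=REG_COLS)
    df.attrs["stage"] = stage
    return df


def reg_row(peak, gene, tf, stage="s", score=10.0):
    return (peak, gene, 0, "up_in_2", "a|b", f"M_{tf}", tf, tf, score, 0.01)


class TestBuildRegulatorTable:
    def test_no_da_peaks_gives_empty_table(self):
        da = da_frame([("p1", "ns", 0.9)])
        hits = hits_frame([("p1", "M_tf1", "tf1", 5, "+", 9.0)])
        out = build_regulator_table(da, hits, [PeakAnnotation("p1", "g1", 0)],
                                    tf_map_for("tf1"), "s")
        assert len(out) == 0

    def test_one_peak_two_motifs_gives_two_rows_same_gene(self):
        da = da_frame([("p1", "up_in_2", 0.01)])
        hits = hits_frame(
            [("p1", "M_tf1", "tf1", 5, "+", 9.0), ("p1", "M_tf2", "tf2", 9, "-", 8.0)]
        )
        out = build_regulator_table(da, hits, [PeakAnnotation("p1", "g1", -30)],
                                    tf_map_for("tf1", "tf2"), "s")
        assert len(out) == 2
        assert set(out["nearest_gene"]) == {"g1"}
        assert set(out["tf_name"]) == {"tf1", "tf2"}

    def test_hit_without_annotation_is_an_error(self):
        da = da_frame([("p1", "up_in_2", 0.01)])
        hits = hits_frame([("p1", "M_tf1", "tf1", 5, "+", 9.0)])
        with pytest.raises(ValueError, match="p1"):
            build_regulator_table(da, hits, [], tf_map_for("tf1"), "s")

    def test_matches_nested_loop_join_oracle(self):
        rng = np.random.default_rng(0)
        peaks = [f"p{i}" for i in range(60)]
        dirs = rng.choice(["up_in_2", "up_in_1", "ns"], 60)
        da = da_frame(list(zip(peaks, dirs, rng.uniform(0, 0.05, 60))))
        anns = [PeakAnnotation(p, f"g{i % 7}", int(i)) for i, p in enumerate(peaks)]
        hit_rows = []
        for p in peaks:
            for tf in ("tf1", "tf2"):
                if rng.random() < 0.4:
                    hit_rows.append((p, f"M_{tf}", tf, 3, "+", 8.0))
        hits = hits_frame(hit_rows)
        out = build_regulator_table(da, hits, anns, tf_map_for("tf1", "tf2"), "s")
        got = set(zip(out["peak"], out["motif_id"]))
        up = {p for p, d in zip(peaks, dirs) if d == "up_in_2"}
        want = {(p, m) for p, m, *_ in hit_rows if p in up}
        assert got == want
        ann_of = {a.peak: a.gene_id for a in anns}
        assert all(g == ann_of[p] for p, g in zip(out["peak"], out["nearest_gene"]))


class TestFilterExpressed:
    @staticmethod
    def bulk(**genes):
        return pd.DataFrame({"s": pd.Series(genes, dtype=float)})

    def test_all_below_threshold_gives_empty(self):
        table = reg_table([reg_row("p1", "g1", "tf1")], "s")
        out = filter_expressed(table, self.bulk(tf1=0.1, g1=0.2), "s")
        assert len(out) == 0

    def test_tf_expressed_target_not_drops_row(self):
        table = reg_table([reg_row("p1", "g1", "tf1")], "s")
        out = filter_expressed(table, self.bulk(tf1=5.0, g1=0.2), "s")
        assert len(out) == 0
        out2 = filter_expressed(table, self.bulk(tf1=5.0, g1=2.0), "s")
        assert len(out2) == 1

    def test_missing_gene_treated_as_unexpressed(self):
        table = reg_table([reg_row("p1", "gX", "tf1")], "s")
        out = filter_expressed(table, self.bulk(tf1=5.0), "s")
        assert len(out) == 0

    def test_missing_stage_rejected(self):
        table = reg_table([reg_row("p1", "g1", "tf1")], "s")
        with pytest.raises(ValueError, match="other"):
            filter_expressed(table, self.bulk(tf1=5.0, g1=5.0), "other")

    def test_matches_direct_rule_evaluation(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(30)]
        expr = pd.DataFrame({"s": rng.uniform(0, 3, 31)},
                            index=genes + ["tf1"])
        rows = [reg_row(f"p{i}", g, "tf1") for i, g in enumerate(genes)]
        out = filter_expressed(reg_table(rows, "s"), expr, "s", min_expr=1.0)
        want = {
            g for g in genes
            if expr.loc[g, "s"] >= 1.0 and expr.loc["tf1", "s"] >= 1.0
        }
        assert set(out["nearest_gene"]) == want


class TestChainCircuits:
    def test_empty_tables_give_no_circuits(self):
        tables = {"s1": reg_table([], "s1"), "s2": reg_table([], "s2")}
        assert chain_circuits(tables, tf_map_for("tf1")) == []

    def test_single_stage_pair_raises(self):
        with pytest.raises(ValueError, match="two consecutive"):
            chain_circuits({"s1": reg_table([], "s1")}, {})

    def test_planted_three_stage_chain_recovered_exactly(self):
        # entry linkage: tfA's motif occurs at stage 1; edges at stages 2 and 3
        tables = {
            "s1": reg_table([reg_row("p0", "gL", "tfA", "s1")], "s1"),
            "s2": reg_table([reg_row("p1", "tfB", "tfA", "s2")], "s2"),
            "s3": reg_table([reg_row("p2", "gC", "tfB", "s3")], "s3"),
        }
        circuits = chain_circuits(tables, tf_map_for("tfA", "tfB"))
        assert len(circuits) == 1
        chain = [(e.tf_name, e.target_gene, e.stage) for e in circuits[0].edges]
        assert chain == [("tfA", "tfB", "s2"), ("tfB", "gC", "s3")]

    def test_entry_requires_first_stage_linkage(self):
        tables = {
            "s1": reg_table([], "s1"),  # no linkage evidence
            "s2": reg_table([reg_row("p1", "tfB", "tfA", "s2")], "s2"),
            "s3": reg_table([reg_row("p2", "gC", "tfB", "s3")], "s3"),
        }
        circuits = chain_circuits(tables, tf_map_for("tfA", "tfB"))
        # the s2 edge is inadmissible; the s3 edge stands alone
        assert [
            [(e.tf_name, e.target_gene) for e in c.edges] for c in circuits
        ] == [[("tfB", "gC")]]

    def test_removing_downstream_link_truncates_chain(self):
        tables = {
            "s1": reg_table([reg_row("p0", "gL", "tfA", "s1")], "s1"),
            "s2": reg_table([reg_row("p1", "tfB", "tfA", "s2")], "s2"),
            "s3": reg_table([], "s3"),
        }
        circuits = chain_circuits(tables, tf_map_for("tfA", "tfB"))
        assert len(circuits) == 1 and len(circuits[0]) == 1

    def test_self_loop_flagged_and_not_infinite(self):
        tables = {
            "s1": reg_table([reg_row("p0", "gL", "tfA", "s1")], "s1"),
            "s2": reg_table([reg_row("p1", "tfA", "tfA", "s2")], "s2"),
            "s3": reg_table([reg_row("p2", "gC", "tfA", "s3")], "s3"),
        }
        circuits = chain_circuits(tables, tf_map_for("tfA"))
        assert len(circuits) == 1
        assert circuits[0].edges[0].self_loop
        assert [e.stage for e in circuits[0].edges] == ["s2", "s3"]


class TestFilterBySCDE:
    @staticmethod
    def circuit(*edges):
        return Circuit(
            tuple(
                GRNEdge(tf, tf, tgt, f"p{i}", stage, f"M_{tf}", 9.0, 0.01)
                for i, (tf, tgt, stage) in enumerate(edges)
            )
        )

    @staticmethod
    def de(genes_p):
        return pd.DataFrame(
            {"gene": list(genes_p), "p_adjusted": list(genes_p.values())}
        )

    def test_no_de_gene_drops_everything(self):
        c = self.circuit(("tfA", "g1", "s2"))
        out = filter_by_sc_de([c], self.de({"tfA": 0.9, "g1": 0.8}), ["tfA", "g1"])
        assert out == []

    def test_de_target_retained_with_flag(self):
        c = self.circuit(("tfA", "g1", "s2"))
        out = filter_by_sc_de([c], self.de({"g1": 0.001}), ["tfA", "g1"])
        assert len(out) == 1
        assert out[0].edges[0].sc_de

    def test_alpha_one_is_vacuous(self):
        c = self.circuit(("tfA", "g1", "s2"), ("g1", "g2", "s3"))
        out = filter_by_sc_de(
            [c], self.de({"tfA": 0.9}), ["tfA", "g1", "g2"], alpha=1.0
        )
        assert len(out) == 1

    def test_gene_absent_from_sc_data_drops_circuit(self):
        c = self.circuit(("tfA", "g1", "s2"))
        out = filter_by_sc_de([c], self.de({"g1": 0.001}), ["g1"])  # tfA missing
        assert out == []

    def test_strict_mode_needs_every_node_de(self):
        c = self.circuit(("tfA", "g1", "s2"))
        de = self.de({"tfA": 0.9, "g1": 0.001})
        assert filter_by_sc_de([c], de, ["tfA", "g1"], strict=True) == []
        de2 = self.de({"tfA": 0.001, "g1": 0.001})
        assert len(filter_by_sc_de([c], de2, ["tfA", "g1"], strict=True)) == 1


class TestTargetOverlap:
    def test_forced_counts(self):
        rows = [
            reg_row("r1", "g1", "tfA"),
            reg_row("r2", "g2", "tfA"),
            reg_row("r2", "g2", "tfB"),
            reg_row("r3", "g3", "tfB"),
        ]
        table = reg_table(rows, "s")
        assert target_overlap("tfA", "tfB", [table], tf_map_for("tfA", "tfB")) == (1, 1, 1)

    def test_same_tf_twice(self):
        table = reg_table([reg_row("r1", "g1", "tfA"), reg_row("r2", "g2", "tfA")], "s")
        assert target_overlap("tfA", "tfA", [table], tf_map_for("tfA")) == (0, 2, 0)

    def test_unknown_tf_rejected(self):
        with pytest.raises(ValueError, match="tfZ"):
            target_overlap("tfZ", "tfA", [], tf_map_for("tfA"))

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(2)
        rows = []
        membership = {}
        for i in range(200):
            peak = f"r{i}"
            motifs_here = set()
            for tf in ("tfA", "tfB", "tfC"):
                if rng.random() < 0.35:
                    rows.append(reg_row(peak, f"g{i}", tf))
                    motifs_here.add(tf)
            membership[peak] = motifs_here
        table = reg_table(rows, "s")
        got = target_overlap("tfA", "tfB", [table], tf_map_for("tfA", "tfB", "tfC"))
        a = {p for p, m in membership.items() if "tfA" in m}
        b = {p for p, m in membership.items() if "tfB" in m}
        assert got == (len(a - b), len(a & b), len(b - a))


class TestExportNetwork:
    def test_empty_circuits_give_valid_headers_and_dot(self, tmp_path):
        tsv, dot = tmp_path / "e.tsv", tmp_path / "e.dot"
        df = export_network([], tsv, dot)
        assert len(df) == 0
        assert tsv.read_text().startswith("tf\ttarget\tstage")
        text = dot.read_text()
        assert text.startswith("digraph") and text.rstrip().endswith("}")

    def test_dot_contains_exactly_the_emitted_edges(self, tmp_path):
        c = TestFilterBySCDE.circuit(("tfA", "g1", "s2"), ("g1", "g2", "s3"))
        tsv, dot = tmp_path / "e.tsv", tmp_path / "e.dot"
        export_network([c], tsv, dot)
        text = dot.read_text()
        assert '"tfA" -> "g1" [label="s2"];' in text
        assert '"g1" -> "g2" [label="s3"];' in text
        assert text.count("->") == 2

    def test_repeated_export_is_byte_identical(self, tmp_path):
        c = TestFilterBySCDE.circuit(("tfA", "g1", "s2"))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_network([c], p1, tmp_path / "a.dot")
        export_network([c], p2, tmp_path / "b.dot")
        assert p1.read_bytes() == p2.read_bytes()
        assert (tmp_path / "a.dot").read_bytes() == (tmp_path / "b.dot").read_bytes()


class TestBuildTFMap:
    def test_expression_flags_from_bulk(self):
        pwms = [PWM("M_tfA", "tfA", np.full((4, 4), 0.25))]
        bulk = pd.DataFrame({"s1": [5.0], "s2": [0.1]}, index=["tfA"])
        tf_map = build_tf_map(pwms, {"tfA": "tfA"}, bulk)
        assert tf_map["tfA"].expressed_at == {"s1": True, "s2": False}
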