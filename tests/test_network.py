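import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lncwalk as lw


def _table(block, records):
    return lw.EdgeTable.from_records(block, records)


class TestLoadEdgeList:
    def test_parses_full_row(self, tmp_path):
        path = tmp_path / "gg.tsv"
        path.write_text("g1\tg2\t1.0\texperimental\n")
        table = lw.load_edge_list(path, "gene-gene")
        assert table.records() == [("g1", "g2", 1.0, "experimental")]

    def test_weight_and_evidence_defaults(self, tmp_path):
        path = tmp_path / "gl.tsv"
        path.write_text("# header\ng1\tl1\n\ng2\tl1\t0.4\n")
        table = lw.load_edge_list(path, "gene-lncrna")
        assert table.records() == [
            ("g1", "l1", 1.0, "experimental"),
            ("g2", "l1", 0.4, "predicted"),
        ]

    @pytest.mark.parametrize(
        "line, message",
        [
            ("g1\tg1\t0.5\tpredicted", "self-loop"),
            ("g1\tg2\t1.3", "outside (0, 1]"),
            ("g1\tg2\t0", "outside (0, 1]"),
            ("g1\tg2\tnotanumber", "unparseable weight"),
            ("g1\tg2\t0.5\tguessed", "unknown evidence"),
            ("justone", "expected 2-4 fields"),
        ],
    )
    def test_rejects_bad_rows_naming_line(self, tmp_path, line, message):
        path = tmp_path / "bad.tsv"
        path.write_text("g1\tg2\t0.5\tpredicted\n" + line + "\n")
        with pytest.raises(lw.EdgeListError, match="line 2"):
            lw.load_edge_list(path, "gene-gene")

    def test_round_trip_preserves_records(self, tmp_path):
        table = _table("gene-lncrna", [
            ("g1", "l1", 1.0, "experimental"),
            ("g2", "l1", 0.4375, "predicted"),
            ("g2", "l2", 0.123456789, "predicted"),
        ])
        path = tmp_path / "out.tsv"
        lw.write_edge_list(table, path)
        assert lw.load_edge_list(path, "gene-lncrna").records() == table.records()


class TestMergeEdgeEvidence:
    def test_experimental_beats_predicted(self):
        merged = lw.merge_edge_evidence(
            _table("gene-lncrna", [("g2", "l1", 0.7, "predicted")]),
            _table("gene-lncrna", [("g2", "l1", 1.0, "experimental")]),
        )
        assert merged.records() == [("g2", "l1", 1.0, "experimental")]

    def test_equal_evidence_keeps_max_weight(self):
        merged = lw.merge_edge_evidence(
            _table("gene-lncrna", [("g1", "l1", 0.6, "predicted"),
                                   ("g1", "l1", 0.8, "predicted")])
        )
        assert merged.records() == [("g1", "l1", 0.8, "predicted")]

    def test_intra_layer_orientations_collapse(self):
        merged = lw.merge_edge_evidence(
            _table("gene-gene", [("g2", "g1", 0.3, "predicted"),
                                 ("g1", "g2", 0.5, "predicted")])
        )
        assert merged.records() == [("g1", "g2", 0.5, "predicted")]

    def test_single_table_unchanged_and_idempotent(self):
        table = _table("gene-gene", [("g1", "g2", 0.5, "predicted"),
                                     ("g1", "g3", 1.0, "experimental")])
        once = lw.merge_edge_evidence(table)
        twice = lw.merge_edge_evidence(once)
        assert once.records() == table.records() == twice.records()

    def test_mixed_blocks_rejected(self):
        with pytest.raises(lw.EdgeListError, match="different blocks"):
            lw.merge_edge_evidence(
                _table("gene-gene", [("g1", "g2", 0.5, "predicted")]),
                _table("lncrna-lncrna", [("l1", "l2", 0.5, "predicted")]),
            )

    @given(st.lists(
        st.tuples(
            st.sampled_from(["g1", "g2", "g3", "g4"]),
            st.sampled_from(["g1", "g2", "g3", "g4"]),
            st.floats(0.01, 1.0),
            st.sampled_from(["experimental", "predicted"]),
        ).filter(lambda r: r[0] != r[1]),
        min_size=1, max_size=12,
    ))
    @settings(max_examples=50, deadline=None)
    def test_merge_idempotent_property(self, records):
        merged = lw.merge_edge_evidence(_table("gene-gene", records))
        assert lw.merge_edge_evidence(merged).records() == merged.records()


class TestCoexpressionEdges:
    @staticmethod
    def _expr(profiles, layers):
        ids = sorted(profiles)
        return lw.ExpressionMatrix(
            ids, [f"s{i}" for i in range(len(next(iter(profiles.values()))))],
            np.array([profiles[e] for e in ids], dtype=float), layers,
        )

    def test_perfect_correlation(self):
        expr = self._expr({"a": [1, 2, 3, 4], "b": [2, 4, 6, 8]},
                          {"a": "gene", "b": "gene"})
        table = lw.coexpression_edges(expr, "gene", "gene", threshold=0.6)
        assert table.records() == [("a", "b", 1.0, "predicted")]

    def test_anticorrelation_policies(self):
        expr = self._expr({"a": [1, 2, 3, 4], "c": [4, 3, 2, 1]},
                          {"a": "gene", "c": "gene"})
        signed = lw.coexpression_edges(expr, "gene", "gene", 0.6, "signed_positive")
        assert len(signed) == 0
        absolute = lw.coexpression_edges(expr, "gene", "gene", 0.6, "absolute")
        assert absolute.records() == [("a", "c", 1.0, "predicted")]

    def test_exactly_zero_correlation_excluded(self):
        # a centered is antisymmetric, d centered is symmetric: r = 0 exactly
        expr = self._expr({"a": [1, 2, 3, 4], "d": [1, 2, 2, 1]},
                          {"a": "gene", "d": "gene"})
        assert len(lw.coexpression_edges(expr, "gene", "gene", threshold=0.6)) == 0

    def test_constant_profile_skipped_with_warning(self):
        expr = self._expr({"a": [1, 2, 3, 4], "k": [5, 5, 5, 5]},
                          {"a": "gene", "k": "gene"})
        with pytest.warns(UserWarning, match="constant"):
            table = lw.coexpression_edges(expr, "gene", "gene", threshold=0.0)
        assert len(table) == 0

    def test_threshold_zero_yields_all_variable_pairs(self):
        rng = np.random.default_rng(7)
        profiles = {f"e{i}": rng.random(6).tolist() for i in range(8)}
        expr = self._expr(profiles, {e: "lncrna" for e in profiles})
        table = lw.coexpression_edges(expr, "lncrna", "lncrna", threshold=0.0)
        assert len(table) == 8 * 7 // 2

    def test_cross_layer_routing(self):
        expr = self._expr({"g1": [1, 2, 3, 4], "l1": [2, 4, 6, 8]},
                          {"g1": "gene", "l1": "lncrna"})
        table = lw.coexpression_edges(expr, "gene", "lncrna", threshold=0.6)
        assert table.block == "gene-lncrna"
        assert table.records() == [("g1", "l1", 1.0, "predicted")]

    def test_too_few_samples_rejected(self):
        expr = self._expr({"a": [1, 2], "b": [2, 1]}, {"a": "gene", "b": "gene"})
        with pytest.raises(ValueError, match="3 samples"):
            lw.coexpression_edges(expr, "gene", "gene")


class TestTopKPhenotypeEdges:
    def test_keeps_k_highest_neighbours(self):
        sim = _table("phenotype-phenotype", [
            ("p1", "p2", 0.9, "predicted"),
            ("p1", "p3", 0.5, "predicted"),
            ("p1", "p4", 0.4, "predicted"),
        ])
        kept = lw.top_k_phenotype_edges(sim, 2)
        pairs = {(s, t) for s, t, _, _ in kept.records()}
        # p4's own top-2 includes p1, so the union keeps all three edges minus none
        assert ("p1", "p2") in pairs and ("p1", "p3") in pairs

    def test_large_k_is_identity(self):
        sim = _table("phenotype-phenotype", [
            ("p1", "p2", 0.9, "predicted"), ("p2", "p3", 0.5, "predicted")])
        assert lw.top_k_phenotype_edges(sim, 10).records() == sim.records()

    def test_union_rescues_low_weight_edge(self):
        # p1's top-2 excludes p5, but p5 has no better neighbour than p1
        sim = _table("phenotype-phenotype", [
            ("p1", "p2", 0.9, "predicted"),
            ("p1", "p3", 0.5, "predicted"),
            ("p1", "p5", 0.1, "predicted"),
        ])
        kept = lw.top_k_phenotype_edges(sim, 2)
        assert ("p1", "p5") in {(s, t) for s, t, _, _ in kept.records()}
        # brute-force union of per-node top-2 lists agrees
        expected = set()
        nbrs = {}
        for s, t, w, _ in sim.records():
            nbrs.setdefault(s, []).append((w, t))
            nbrs.setdefault(t, []).append((w, s))
        for node, lst in nbrs.items():
            for _, other in sorted(lst, key=lambda wt: (-wt[0], wt[1]))[:2]:
                expected.add((min(node, other), max(node, other)))
        assert {(s, t) for s, t, _, _ in kept.records()} == expected

    def test_k_below_one_rejected(self):
        sim = _table("phenotype-phenotype", [("p1", "p2", 0.9, "predicted")])
        with pytest.raises(ValueError, match="positive"):
            lw.top_k_phenotype_edges(sim, 0)


class TestBuildComposite:
    def test_worked_example_assembly(self, t1_network):
        net = t1_network
        assert (net.gene_ids, net.phenotype_ids, net.lncrna_ids) == (
            ["g1", "g2"], ["p1"], ["l1"])
        nonzero = sum(
            int(np.count_nonzero(np.triu(W, 1)) if W.shape[0] == W.shape[1] and name in
                ("W_G", "W_P", "W_L") else np.count_nonzero(W))
            for name, W in (("W_G", net.W_G), ("W_P", net.W_P), ("W_L", net.W_L),
                            ("W_GP", net.W_GP), ("W_GL", net.W_GL), ("W_PL", net.W_PL))
        )
        assert nonzero == 4
        net.validate()

    def test_permutation_invariance(self):
        records = [("g2", "g1", 0.5, "predicted"), ("g1", "g3", 0.9, "predicted"),
                   ("g3", "g2", 0.2, "predicted")]
        a = lw.build_composite({"gene-gene": _table("gene-gene", records)})
        b = lw.build_composite({"gene-gene": _table("gene-gene", records[::-1])})
        assert a.gene_ids == b.gene_ids
        assert np.array_equal(a.W_G, b.W_G)

    def test_empty_table_gives_zero_block(self):
        net = lw.build_composite({
            "gene-gene": _table("gene-gene", [("g1", "g2", 1.0, "experimental")]),
            "phenotype-phenotype": _table("phenotype-phenotype", []),
        })
        assert net.n_phenotypes == 0 and net.W_P.shape == (0, 0)

    def test_id_in_two_layers_rejected(self):
        with pytest.raises(lw.NetworkValidationError, match="shared"):
            lw.build_composite({
                "gene-gene": _table("gene-gene", [("shared", "g2", 1.0, "experimental")]),
                "lncrna-lncrna": _table("lncrna-lncrna", [("shared", "l2", 0.5, "predicted")]),
            })

    def test_universe_adds_isolated_nodes(self):
        net = lw.build_composite(
            {"lncrna-lncrna": _table("lncrna-lncrna", [("l1", "l2", 0.5, "predicted")])},
            node_universes={"lncrna": ["l9"], "gene": ["g1"]},
        )
        assert "l9" in net.lncrna_ids and net.gene_ids == ["g1"]


class TestRestrictLayers:
    def test_keep_all_is_identity(self, t1_network):
        kept = lw.restrict_layers(t1_network, ["gene", "phenotype", "lncrna"])
        assert np.array_equal(kept.W_GP, t1_network.W_GP)
        assert kept.node_order == t1_network.node_order

    def test_phenotype_lncrna_only(self, t1_network):
        kept = lw.restrict_layers(t1_network, ["phenotype", "lncrna"])
        assert kept.n_genes == 0
        assert kept.W_PL[0, 0] == 1.0  # the single surviving p1-l1 edge
        assert np.count_nonzero(kept.W_L) == 0

    def test_lncrna_only_degenerate(self, t1_network):
        kept = lw.restrict_layers(t1_network, ["lncrna"])
        assert kept.n_nodes == 1 and np.count_nonzero(kept.W_L) == 0

    def test_dropping_lncrna_layer_rejected(self, t1_network):
        with pytest.raises(ValueError, match="lncrna"):
            lw.restrict_layers(t1_network, ["gene", "phenotype"])


class TestNetworkSerialization:
    def test_round_trip_with_isolated_nodes(self, tmp_path):
        net = lw.build_composite(
            {"gene-lncrna": _table("gene-lncrna", [("g1", "l1", 0.5, "predicted")]),
             "phenotype-lncrna": _table("phenotype-lncrna", [("p1", "l1", 1.0, "experimental")])},
            node_universes={"lncrna": ["l_isolated"]},
        )
        lw.write_network(net, tmp_path / "net")
        loaded = lw.read_network(tmp_path / "net")
        assert loaded.node_order == net.node_order
        for name in ("W_G", "W_P", "W_L", "W_GP", "W_GL", "W_PL"):
            assert np.array_equal(getattr(loaded, name), getattr(net, name))
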