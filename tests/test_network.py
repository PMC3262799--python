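import networkx as nx
import pandas as pd
import pytest

from mircornet.io import CellTypeScheme, TargetPredictionTable
from mircornet.network import (
    build_network,
    collapse_seed_overlaps,
    export_network,
    rank_hubs,
    read_sif,
)
from mircornet.specificity import SpecificityCall
from oracles import brute_force_collapse


def _call(mirna, cell_types=("Neutrophils",)):
    return SpecificityCall(
        transcript=mirna, platform="mirna", direction="up", k=len(cell_types),
        specific_cell_types=tuple(cell_types), boundary_fold_change=8.0,
        boundary_p=1e-4, boundary_p_adj=1e-3,
    )


def _predictions(rows):
    return TargetPredictionTable(
        pd.DataFrame(
            [
                {"mirna_family": m, "gene": g, "site_chrom": g,
                 "site_start": s, "site_end": e,
                 "sources": frozenset({"targetscan", "mirdb"})}
                for m, g, s, e in rows
            ]
        )
    )


class TestCollapseSeedOverlaps:
    def test_overlapping_single_sites_collapse(self):
        kept, groups = collapse_seed_overlaps(
            "g", [("mB", [("g", 100, 107)]), ("mA", [("g", 103, 110)])]
        )
        assert kept == ["mA"]
        assert groups == [["mA", "mB"]]

    def test_adjacent_half_open_kept(self):
        kept, groups = collapse_seed_overlaps(
            "g", [("mA", [("g", 100, 107)]), ("mB", [("g", 107, 114)])]
        )
        assert kept == ["mA", "mB"]
        assert groups == []

    def test_two_overlapping_one_disjoint(self):
        kept, _ = collapse_seed_overlaps(
            "g",
            [
                ("m1", [("g", 100, 107)]),
                ("m2", [("g", 104, 111)]),
                ("m3", [("g", 300, 307)]),
            ],
        )
        assert kept == ["m1", "m3"]

    def test_partial_site_overlap_keeps_both(self):
        # m1 has an extra site m2 does not cover: independent evidence
        kept, groups = collapse_seed_overlaps(
            "g",
            [
                ("m1", [("g", 100, 107), ("g", 200, 207)]),
                ("m2", [("g", 103, 110)]),
            ],
        )
        assert kept == ["m1", "m2"]
        assert groups == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        regs = []
        for i in range(int(rng.integers(2, 6))):
            sites = []
            for _ in range(int(rng.integers(1, 3))):
                start = int(rng.integers(0, 40))
                sites.append(("g", start, start + int(rng.integers(3, 10))))
            regs.append((f"m{i}", sites))
        assert collapse_seed_overlaps("g", regs) == brute_force_collapse(regs)


class TestBuildNetwork:
    def test_single_pair_below_min_degree_empty(self):
        net = build_network(
            [("m1", "g1", -0.7)],
            [_call("m1")],
            _predictions([("m1", "g1", 100, 107)]),
            min_degree=2,
        )
        assert net.edges == []
        assert rank_hubs(net) == []

    def test_planted_five_regulator_hub(self):
        mirnas = [f"m{i}" for i in range(5)]
        preds = _predictions(
            [(m, "hub", 100 + 50 * i, 107 + 50 * i) for i, m in enumerate(mirnas)]
            + [("m0", "solo", 100, 107)]
        )
        edges = [(m, "hub", -0.8) for m in mirnas] + [("m0", "solo", -0.6)]
        net = build_network(edges, [_call(m) for m in mirnas], preds, min_degree=2)
        hubs = rank_hubs(net)
        assert hubs[0] == ("hub", 5)
        assert "solo" not in net.genes  # degree 1 filtered
        # conservation: every input edge to a kept gene survives
        assert set(net.edges) == {(m, "hub") for m in mirnas}

    def test_uncalled_mirnas_dropped(self):
        preds = _predictions([("m1", "g", 100, 107), ("m2", "g", 200, 207)])
        net = build_network(
            [("m1", "g", -0.7), ("m2", "g", -0.7)], [_call("m1")], preds, min_degree=1
        )
        assert net.mirnas == ["m1"]

    def test_seed_similar_regulators_counted_once(self):
        # two miRNAs with fully overlapping sites: gene keeps only one
        preds = _predictions([("m1", "g", 100, 107), ("m2", "g", 103, 110)])
        net = build_network(
            [("m1", "g", -0.7), ("m2", "g", -0.7)],
            [_call("m1"), _call("m2")],
            preds,
            min_degree=2,
        )
        assert net.genes == []  # collapsed to one regulator, below min degree
        assert net.collapse_report == [("g", ["m1", "m2"])]

    def test_bipartite_simple_and_lineage_separation(self):
        scheme = CellTypeScheme.immune_default()
        myeloid = [("mM1", ("Neutrophils",)), ("mM2", ("Monocytes",))]
        lymphoid = [("mL1", ("T", "B", "NK")), ("mL2", ("B",))]
        rows, edges, calls = [], [], []
        for i, (m, cts) in enumerate(myeloid):
            rows.append((m, "gM", 100 + 50 * i, 107 + 50 * i))
            edges.append((m, "gM", -0.8))
            calls.append(_call(m, cts))
        for i, (m, cts) in enumerate(lymphoid):
            rows.append((m, "gL", 100 + 50 * i, 107 + 50 * i))
            edges.append((m, "gL", -0.8))
            calls.append(_call(m, cts))
        net = build_network(edges, calls, _predictions(rows), min_degree=2, scheme=scheme)
        g = net.graph
        assert all(g.nodes[u]["kind"] == "mirna" and g.nodes[v]["kind"] == "gene"
                   for u, v in g.edges)
        for comp in nx.connected_components(g.to_undirected()):
            lineages = {
                g.nodes[n]["lineage"] for n in comp if g.nodes[n]["kind"] == "mirna"
            }
            assert len(lineages) == 1


class TestExport:
    def _demo_net(self):
        mirnas = ["m1", "m2"]
        preds = _predictions(
            [("m1", "g", 100, 107), ("m2", "g", 200, 207)]
        )
        return build_network(
            [("m1", "g", -0.7), ("m2", "g", -0.6)],
            [_call(m) for m in mirnas], preds, min_degree=2,
        )

    def test_empty_sif_body(self, tmp_path):
        net = build_network([], [], _predictions([("m", "g", 0, 7)]), min_degree=2)
        p = tmp_path / "empty.sif"
        export_network(net, p, fmt="sif")
        assert p.read_text() == ""

    def test_sif_roundtrip_topology(self, tmp_path):
        net = self._demo_net()
        p = tmp_path / "net.sif"
        export_network(net, p, fmt="sif")
        back = read_sif(p)
        assert sorted(back.edges()) == net.edges

    def test_graphml_roundtrip(self, tmp_path):
        net = self._demo_net()
        p = tmp_path / "net.graphml"
        export_network(net, p, fmt="graphml")
        back = nx.read_graphml(p)
        assert sorted(back.edges()) == net.edges
        assert back.nodes["m1"]["kind"] == "mirna"
        assert back.nodes["m1"]["lineage"] == "myeloid"

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(self._demo_net(), tmp_path / "x", fmt="dot")
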