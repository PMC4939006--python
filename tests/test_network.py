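"""Pair-file parsing, network typing and subnetwork extraction."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chasnet import (
    ContactNetwork,
    GenomicFragment,
    connected_components,
    read_interactions,
    subnetwork,
    virtual_4c,
)
from chasnet.network import coords_id

from conftest import make_net


def write_bedpe(path, rows):
    path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
    return path


BASE_ROWS = [
    ("chr1", 0, 1000, "chr1", 5000, 6000, "e0", 5.1),
    ("chr1", 0, 1000, "chr1", 10000, 11000, "e1", 4.9),
    ("chr1", 5000, 6000, "chr1", 20000, 21000, "e2", 7.0),
]


class TestReadInteractions:
    def test_score_threshold_is_inclusive_at_boundary(self, tmp_path):
        """Scores (5.1, 4.9, 7.0) at threshold 5 keep exactly two edges."""
        p = write_bedpe(tmp_path / "a.bedpe", BASE_ROWS)
        net = read_interactions(p, score_threshold=5.0)
        assert net.n_edges == 2
        exact = write_bedpe(
            tmp_path / "b.bedpe",
            [("chr1", 0, 1000, "chr1", 5000, 6000, "e", 5.0)],
        )
        assert read_interactions(exact, score_threshold=5.0).n_edges == 1

    def test_duplicate_pair_collapsed_to_max_score(self, tmp_path):
        p = write_bedpe(
            tmp_path / "d.bedpe",
            [
                ("chr1", 0, 1000, "chr1", 5000, 6000, "e0", 6.0),
                ("chr1", 5000, 6000, "chr1", 0, 1000, "e1", 8.0),
            ],
        )
        net = read_interactions(p)
        assert net.n_edges == 1
        (u, v), = net.edges()
        assert net.graph.edges[u, v]["score"] == 8.0

    def test_self_pair_dropped_with_warning(self, tmp_path, caplog):
        p = write_bedpe(
            tmp_path / "s.bedpe",
            [("chr1", 0, 1000, "chr1", 0, 1000, "e0", 9.0)] + BASE_ROWS[:1],
        )
        with caplog.at_level("WARNING"):
            net = read_interactions(p)
        assert net.n_edges == 1
        assert any("self-interaction" in r.message for r in caplog.records)

    def test_malformed_row_names_line_number(self, tmp_path):
        p = write_bedpe(
            tmp_path / "m.bedpe",
            [BASE_ROWS[0], ("chr1", "oops", 1000, "chr1", 5000, 6000, "e", 6)],
        )
        with pytest.raises(ValueError, match="line 2"):
            read_interactions(p)

    def test_inverted_coordinates_rejected(self, tmp_path):
        p = write_bedpe(
            tmp_path / "i.bedpe", [("chr1", 1000, 1000, "chr1", 5000, 6000, "e", 6)]
        )
        with pytest.raises(ValueError, match="line 1"):
            read_interactions(p)

    def test_unknown_chromosome_against_sizes(self, tmp_path):
        p = write_bedpe(tmp_path / "c.bedpe", BASE_ROWS)
        with pytest.raises(ValueError, match="chr1"):
            read_interactions(p, sizes={"chr2": 10_000_000})

    def test_missing_score_column_needs_nonpositive_threshold(self, tmp_path):
        rows = [r[:7] for r in BASE_ROWS]
        p = write_bedpe(tmp_path / "ns.bedpe", rows)
        with pytest.raises(ValueError, match="score"):
            read_interactions(p, score_threshold=5.0)
        assert read_interactions(p, score_threshold=0.0).n_edges == 3

    def test_bait_ids_assign_node_and_edge_classes(self, tmp_path):
        p = write_bedpe(tmp_path / "b.bedpe", BASE_ROWS)
        baits = {coords_id("chr1", 0, 1000), coords_id("chr1", 5000, 6000)}
        net = read_interactions(p, bait_ids=baits)
        classes = {
            net.graph.edges[u, v]["edge_class"] for u, v in net.edges()
        }
        assert classes == {"PP", "PO"}

    def test_chicago_dialect_converts_1based_coordinates(self, tmp_path):
        lines = [
            "baitChr\tbaitStart\tbaitEnd\tbaitID\toeChr\toeStart\toeEnd\toeID\tscore",
            "chr1\t1\t1000\tbait1\tchr1\t5001\t6000\toe1\t6.5",
            "chr1\t1\t1000\tbait1\tchr1\t9001\t9800\toe2\t3.0",
        ]
        p = tmp_path / "t.chicago"
        p.write_text("\n".join(lines) + "\n")
        net = read_interactions(p, fmt="chicago")
        assert net.n_edges == 1  # score 3.0 below threshold
        bait = net.fragment("bait1")
        assert (bait.start, bait.end, bait.node_class) == (0, 1000, "promoter")
        assert net.fragment("oe1").node_class == "other_end"

    def test_threshold_monotonicity(self, tmp_path):
        p = write_bedpe(tmp_path / "mono.bedpe", BASE_ROWS)
        for t1, t2 in [(0, 5), (5, 6), (4.9, 7.0)]:
            loose = set(read_interactions(p, score_threshold=t1).edges())
            strict = set(read_interactions(p, score_threshold=t2).edges())
            assert strict <= loose

    def test_roundtrip_write_read(self, tmp_path, small_dataset):
        net = small_dataset.network
        net.write(tmp_path / "net")
        back = ContactNetwork.read(tmp_path / "net")
        assert back.edges() == net.edges()
        assert {f.node_class for f in back.fragments.values()} == {
            "promoter",
            "other_end",
        }
        for fid, frag in back.fragments.items():
            orig = net.fragment(fid)
            assert (frag.chrom, frag.start, frag.end) == (
                orig.chrom, orig.start, orig.end,
            )
        for u, v in back.edges():
            assert back.graph.edges[u, v]["score"] == pytest.approx(
                net.graph.edges[u, v]["score"]
            )


class TestFragmentInvariants:
    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (10, 2)])
    def test_bad_coordinates_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicFragment("chr1", start, end, "x")

    def test_reused_id_with_other_coords_rejected(self):
        net = ContactNetwork()
        net.add_fragment(GenomicFragment("chr1", 0, 10, "f"))
        with pytest.raises(ValueError, match="re-used"):
            net.add_fragment(GenomicFragment("chr1", 5, 15, "f"))

    def test_bait_seen_as_other_end_stays_promoter(self):
        net = ContactNetwork()
        net.add_fragment(GenomicFragment("chr1", 0, 10, "f", "promoter"))
        net.add_fragment(GenomicFragment("chr1", 0, 10, "f", "other_end"))
        assert net.fragment("f").node_class == "promoter"


class TestSubnetwork:
    def setup_method(self):
        edges = [("p1", "p2"), ("p1", "p3"), ("p2", "p3"),
                 ("p1", "o1"), ("p2", "o2"), ("p3", "o3"), ("p1", "o4")]
        self.net = make_net(edges, promoters=["p1", "p2", "p3"])

    def test_class_filter(self):
        assert subnetwork(self.net, edge_classes={"PP"}).n_edges == 3
        assert subnetwork(self.net, edge_classes={"PO"}).n_edges == 4

    def test_pp_po_partition_edges(self):
        pp = set(subnetwork(self.net, edge_classes={"PP"}).edges())
        po = set(subnetwork(self.net, edge_classes={"PO"}).edges())
        assert pp.isdisjoint(po)
        assert pp | po == set(self.net.edges())

    def test_identity_for_promoter_capture_network(self):
        both = subnetwork(self.net, edge_classes={"PP", "PO"})
        assert both.edges() == self.net.edges()

    def test_min_distance_filter(self):
        net = ContactNetwork()
        net.add_fragment(GenomicFragment("chr1", 0, 1000, "a", "promoter"))
        net.add_fragment(GenomicFragment("chr1", 5000, 6000, "b"))
        net.add_fragment(GenomicFragment("chr1", 50_000, 51_000, "c"))
        net.add_edge("a", "b")
        net.add_edge("a", "c")
        kept = subnetwork(net, min_distance=10_000)
        assert kept.edges() == [("a", "c")]

    def test_cis_only_drops_trans(self):
        net = ContactNetwork()
        net.add_fragment(GenomicFragment("chr1", 0, 1000, "a", "promoter"))
        net.add_fragment(GenomicFragment("chr2", 0, 1000, "b"))
        net.add_fragment(GenomicFragment("chr1", 9000, 9500, "c"))
        net.add_edge("a", "b")
        net.add_edge("a", "c")
        assert subnetwork(net, cis_only=True).edges() == [("a", "c")]
        assert subnetwork(net).n_edges == 2  # trans retained by default

    def test_empty_result_warns_not_raises(self, caplog):
        with caplog.at_level("WARNING"):
            empty = subnetwork(self.net, edge_classes={"OO"})
        assert empty.n_nodes == 0 and empty.n_edges == 0


class TestComponentsAndVirtual4C:
    def test_two_triangles(self):
        net = make_net([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)])
        comps = connected_components(net)
        assert [len(c) for c in comps] == [3, 3]
        assert comps[0] == {"1", "2", "3"}  # tie broken by smallest id

    def test_edgeless_network_gives_singletons(self):
        net = make_net([], nodes=[1, 2, 3, 4, 5])
        comps = connected_components(net)
        assert [len(c) for c in comps] == [1] * 5

    def test_planted_giant_component_fraction_recovered(self, planted_dataset):
        """The generator's 63 % connected group is the observed LCC."""
        net = planted_dataset.network
        comps = connected_components(net)
        assert len(comps[0]) / net.n_nodes == pytest.approx(0.63, abs=0.02)
        assert sum(len(c) for c in comps) == net.n_nodes

    def test_mean_degree_of_emulated_capture_network(self, planted_dataset):
        assert planted_dataset.network.mean_degree == pytest.approx(2.5, rel=0.1)

    def test_virtual_4c_star(self):
        net = make_net([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")])
        star = virtual_4c(net, "a")
        assert star.n_nodes == 4
        assert star.edges() == [("a", "b"), ("a", "c"), ("a", "d")]

    def test_virtual_4c_isolated_anchor_and_unknown(self):
        net = make_net([("a", "b")], nodes=["z"])
        star = virtual_4c(net, "z")
        assert (star.n_nodes, star.n_edges) == (1, 0)
        with pytest.raises(KeyError):
            virtual_4c(net, "missing")

    def test_virtual_4c_neighbors_match_toy_file(self, tmp_path):
        rows = [
            ("chr1", 0, 1000, "chr1", 5000, 6000, "e0", 6.0),
            ("chr1", 0, 1000, "chr1", 9000, 9900, "e1", 6.0),
            ("chr1", 5000, 6000, "chr1", 9000, 9900, "e2", 6.0),
        ]
        p = write_bedpe(tmp_path / "v.bedpe", rows)
        net = read_interactions(p)
        anchor = coords_id("chr1", 0, 1000)
        star = virtual_4c(net, anchor)
        assert set(star.neighbors(anchor)) == {
            coords_id("chr1", 5000, 6000),
            coords_id("chr1", 9000, 9900),
        }
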