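"""Linear<->graph coordinate conversion, feature projection, region extraction."""

import numpy as np
import pytest

from pangview import errors
from pangview.annotio import bind_annotations, read_gff3
from pangview.graphio import FORWARD, REVERSE, path_sequence, reverse_complement
from pangview.projection import (
    extract_region,
    graph_to_linear,
    linear_to_graph,
    parse_region,
    path_span_in_region,
    project_feature,
    projected_sequence,
    region_to_gfa,
)
from pangview.synthpan import random_graph, simulate_pangenome
from tests.conftest import make_graph


class TestLinearToGraph:
    def test_full_path_identity(self, toy_graph):
        segs = linear_to_graph(toy_graph, "P1.chr1", 0, 9)
        assert [(s.node_id, s.start, s.end, s.orientation) for s in segs] == [
            ("n1", 0, 4, "+"), ("n2", 0, 2, "+"), ("n3", 0, 3, "+"),
        ]

    def test_mid_interval(self, toy_graph):
        segs = linear_to_graph(toy_graph, "P1.chr1", 3, 6)
        assert [(s.node_id, s.start, s.end, s.orientation) for s in segs] == [
            ("n1", 3, 4, "+"), ("n2", 0, 2, "+"),
        ]

    def test_reverse_step_forward_offsets(self, toy_graph):
        # Q spells TCC|ACGT; [1,5) covers traversal offsets 1-2 of n3- then 0-1 of n1+
        segs = linear_to_graph(toy_graph, "Q.chr1", 1, 5)
        assert [(s.node_id, s.start, s.end, s.orientation) for s in segs] == [
            ("n3", 0, 2, "-"), ("n1", 0, 2, "+"),
        ]

    def test_out_of_range(self, toy_graph):
        with pytest.raises(errors.RangeError):
            linear_to_graph(toy_graph, "P1.chr1", 0, 10)

    @pytest.mark.parametrize("seed", range(15))
    def test_segments_spell_the_linear_slice(self, seed):
        """Oracle: indexing into the concatenated path string."""
        g = random_graph(seed)
        rng = np.random.default_rng(seed)
        for name in g.paths:
            seq = path_sequence(g, name)
            for _ in range(5):
                a, b = sorted(rng.integers(0, len(seq) + 1, size=2))
                segs = linear_to_graph(g, name, int(a), int(b))
                spelled = "".join(
                    g.nodes[s.node_id].sequence[s.start : s.end]
                    if s.orientation == FORWARD
                    else reverse_complement(g.nodes[s.node_id].sequence[s.start : s.end])
                    for s in segs
                )
                assert spelled == seq[a:b]


class TestGraphToLinear:
    def test_loop_yields_both_positions(self, toy_graph):
        assert graph_to_linear(toy_graph, "R.chr1", "n2", 1) == [1, 3]

    def test_untouched_node_empty(self, toy_graph):
        assert graph_to_linear(toy_graph, "Q.chr1", "n2", 0) == []

    def test_first_node_offset_zero(self, toy_graph):
        assert graph_to_linear(toy_graph, "P1.chr1", "n1", 0) == [0]

    def test_offset_out_of_node_range(self, toy_graph):
        with pytest.raises(errors.RangeError):
            graph_to_linear(toy_graph, "P1.chr1", "n2", 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_round_trip_recovers_position(self, seed):
        """graph_to_linear after linear_to_graph([p, p+1)) always contains p."""
        g = random_graph(seed)
        rng = np.random.default_rng(1000 + seed)
        for name in g.paths:
            total = g.path_length(name)
            for p in rng.integers(0, total, size=8):
                p = int(p)
                (seg,) = linear_to_graph(g, name, p, p + 1)
                assert p in graph_to_linear(g, name, seg.node_id, seg.start)


class TestProjectFeature:
    GFF = (
        "chr1\tx\tgene\t1\t9\t.\t+\t.\tID=g\n"
        "chr1\tx\texon\t4\t6\t.\t+\t.\tID=e1;Parent=g\n"
        "chr1\tx\texon\t2\t2\t.\t+\t.\tID=e2;Parent=g\n"
    )

    def test_exon_across_node_boundary(self, toy_graph):
        annots = bind_annotations(toy_graph, read_gff3(self.GFF, "P1"))
        exon = next(f for f in annots.features if f.id == "e1")
        proj = project_feature(toy_graph, exon)
        assert [(s.node_id, s.start, s.end) for s in proj.segments] == [
            ("n1", 3, 4), ("n2", 0, 2),
        ]
        assert proj.length == 3

    def test_single_base_exon(self, toy_graph):
        annots = bind_annotations(toy_graph, read_gff3(self.GFF, "P1"))
        exon = next(f for f in annots.features if f.id == "e2")
        proj = project_feature(toy_graph, exon)
        assert [(s.node_id, s.start, s.end) for s in proj.segments] == [("n1", 1, 2)]

    def test_projection_is_path_local(self, demo_pan):
        """A feature projects only onto nodes its own path traverses."""
        graph, annots, _ = demo_pan
        s4 = next(a for a in annots if a.genome == "s4")
        exon2 = next(f for f in s4.features if f.id == "g1.t1.exon2")
        proj = project_feature(graph, exon2)
        assert "n08" not in {s.node_id for s in proj.segments}

    @pytest.mark.parametrize("seed", [11, 12])
    def test_partition_property_on_simulated_exons(self, seed):
        """Concatenated projected slices equal the linear feature sequence."""
        graph, annot_sets, _ = simulate_pangenome(
            base_length=4000, n_genomes=5, seed=seed
        )
        checked = 0
        for annots in annot_sets:
            for f in annots.features:
                proj = project_feature(graph, f)
                s0, e0 = f.interval0()
                assert projected_sequence(graph, proj) == path_sequence(
                    graph, f.bound_path
                )[s0:e0]
                assert proj.length == len(f)
                checked += 1
        assert checked > 0


class TestRegionStrings:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("P1.chr1:1-9", ("P1.chr1", 0, 9)),
            ("NATELBORO.chr06:28873554–28874897", ("NATELBORO.chr06", 28873553, 28874897)),
            ("X.chr1:1,000-2,000", ("X.chr1", 999, 2000)),
        ],
    )
    def test_parse_forms(self, text, expected):
        assert parse_region(text) == expected

    @pytest.mark.parametrize("text", ["chr1", "chr1:5", "chr1:9-5", "chr1:0-4"])
    def test_malformed_rejected(self, text):
        with pytest.raises(errors.RegionParseError):
            parse_region(text)


class TestExtractRegion:
    def test_full_chromosome_includes_everything(self, toy_graph):
        sub = extract_region(toy_graph, [], "P1.chr1:1-9")
        assert sub.node_ids == {"n1", "n2", "n3"}
        assert set(sub.clipped_paths) == {"P1.chr1", "Q.chr1", "R.chr1"}

    def test_anchor_clip_is_exact_substring(self, toy_graph):
        seq = path_sequence(toy_graph, "P1.chr1")
        for a, b in [(1, 9), (3, 6), (5, 5), (2, 8)]:
            sub = extract_region(toy_graph, [], f"P1.chr1:{a}-{b}")
            assert sub.anchor_run.sequence(toy_graph) == seq[a - 1 : b]

    def test_private_node_region_has_one_node_one_path(self, demo_pan):
        """A region inside a genome-private segment shows only that node and
        the paths carrying it."""
        graph, annots, _ = demo_pan
        # n04 (the CT substitution node) is private to s2
        pos = graph_to_linear(graph, "s2.chr1", "n04", 0)[0]
        sub = extract_region(graph, annots, f"s2.chr1:{pos + 1}-{pos + 2}")
        assert sub.node_ids == {"n04"}
        assert set(sub.clipped_paths) == {"s2.chr1"}

    def test_monotone_in_interval(self, demo_pan):
        graph, annots, _ = demo_pan
        small = extract_region(graph, annots, "s1.chr1:10-30")
        big = extract_region(graph, annots, "s1.chr1:5-60")
        assert small.node_ids <= big.node_ids

    def test_loop_paths_clip_to_separate_runs(self):
        g = make_graph(
            {"a": "AC", "b": "GT", "c": "AA"},
            {"X.chr1": ["a+", "b+", "a+"], "Y.chr1": ["a+", "c+", "a+"]},
        )
        sub = extract_region(g, [], "X.chr1:1-6")
        # Y enters the node set (a), leaves through private c, re-enters
        assert [r.lin_start for r in sub.clipped_paths["Y.chr1"]] == [0, 4]

    def test_region_export_round_trips_as_gfa(self, demo_pan):
        graph, annots, _ = demo_pan
        sub = extract_region(graph, annots, "s1.chr1:6-58")
        from pangview.graphio import read_gfa

        g2 = read_gfa(region_to_gfa(sub))
        assert set(g2.nodes) == sub.node_ids


class TestPathSpan:
    def test_anchor_span_is_the_request(self, demo_pan):
        graph, annots, _ = demo_pan
        sub = extract_region(graph, annots, "s1.chr1:6-58")
        assert path_span_in_region(sub, "s1.chr1") == (6, 58)

    def test_absent_path_is_none(self, demo_pan):
        graph, annots, _ = demo_pan
        pos = graph_to_linear(graph, "s2.chr1", "n04", 0)[0]
        sub = extract_region(graph, annots, f"s2.chr1:{pos + 1}-{pos + 2}")
        assert path_span_in_region(sub, "s5.chr1") is None

    def test_span_lengths_differ_across_genomes(self, demo_pan):
        """Shared graph coordinates are unevenly distributed along genomes."""
        graph, annots, _ = demo_pan
        sub = extract_region(graph, annots, "s1.chr1:1-77")
        lengths = set()
        for pname in sub.clipped_paths:
            lo, hi = path_span_in_region(sub, pname)
            lengths.add(hi - lo + 1)
        assert len(lengths) > 1

    def test_span_covers_traversed_bases(self, demo_pan):
        graph, annots, _ = demo_pan
        sub = extract_region(graph, annots, "s1.chr1:1-77")
        for pname, runs in sub.clipped_paths.items():
            lo, hi = path_span_in_region(sub, pname)
            traversed = sum(r.lin_end - r.lin_start for r in runs)
            assert hi - lo + 1 >= traversed
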