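"""Coordinate conversion between linear genomes and the variation graph.

The graph is the shared coordinate system: a linear position on one genome
maps to a (node, offset) pair, and a node offset maps back to zero, one or
several linear positions per genome (zero when the genome skips the node,
several when its path loops through it). Gene features projected through
this mapping become ordered lists of node segments — the machinery behind
nucleotide-level comparison of annotations across genomes.

Conventions: linear intervals are 0-based half-open internally; region
strings are 1-based inclusive ``PATH:start-end`` (both hyphen and en-dash
accepted, matching forms like ``NATELBORO.chr06:28873554-28874897``).
Segment offsets are always on the node's FORWARD sequence; a reverse step
traversing offsets ``i`` maps to forward offset ``len - 1 - i``.
"""

from __future__ import annotations

import json
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .annotio import AnnotationSet, GenomeFeature
from .errors import LookupError_, RangeError, RegionParseError
from .graphio import (
    FORWARD,
    REVERSE,
    OrientedStep,
    VariationGraph,
    reverse_complement,
    step_sequence,
)


@dataclass(frozen=True)
class GraphSegment:
    """A contiguous piece of a node covered by a linear interval.

    ``start``/``end`` are 0-based half-open offsets on the node's forward
    sequence; ``orientation`` is the orientation of the path step that
    produced the segment; ``step_index`` its ordinal within the path.
    """

    node_id: str
    start: int
    end: int
    orientation: str
    step_index: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ProjectedFeature:
    """A linear feature re-expressed as ordered graph segments."""

    source: GenomeFeature
    genome: str
    path_name: str
    segments: list[GraphSegment]

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.segments)

    def boundary_coords(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Graph coordinates of the feature's first and last base.

        Offsets are forward-node offsets, so two genomes share a boundary
        exactly when the underlying graph positions coincide regardless of
        traversal orientation.
        """
        first = self.segments[0]
        last = self.segments[-1]
        start_coord = (first.node_id, first.start if first.orientation == FORWARD else first.end - 1)
        end_coord = (last.node_id, last.end - 1 if last.orientation == FORWARD else last.start)
        return start_coord, end_coord


@dataclass
class ClippedRun:
    """A maximal consecutive stretch of one path inside a region's node set."""

    path_name: str
    first_step: int                      # step ordinal of the first step
    steps: list[OrientedStep]
    entry_offset: int                    # traversal offset where the run enters its first step
    exit_offset: int                     # traversal offset (exclusive) where it leaves its last
    lin_start: int                       # 0-based half-open span on the path
    lin_end: int

    def sequence(self, graph: VariationGraph) -> str:
        parts = [step_sequence(graph, s) for s in self.steps]
        if len(parts) == 1:
            return parts[0][self.entry_offset : self.exit_offset]
        parts[0] = parts[0][self.entry_offset :]
        parts[-1] = parts[-1][: self.exit_offset]
        return "".join(parts)


@dataclass
class RegionSubgraph:
    """The node set, clipped paths and clipped features of a region query."""

    graph: VariationGraph
    anchor_path: str
    anchor_interval: tuple[int, int]     # 0-based half-open on the anchor path
    node_ids: set[str]
    clipped_paths: dict[str, list[ClippedRun]]
    clipped_features: list[ProjectedFeature] = field(default_factory=list)

    @property
    def anchor_run(self) -> ClippedRun:
        return self.clipped_paths[self.anchor_path][0]

    def path_names(self) -> list[str]:
        return [p for p, runs in self.clipped_paths.items() if runs]

    def node_order(self) -> list[str]:
        """Nodes ordered by first occurrence on the anchor, then others sorted."""
        order: list[str] = []
        seen: set[str] = set()
        for step in self.anchor_run.steps:
            if step.node_id not in seen:
                seen.add(step.node_id)
                order.append(step.node_id)
        order.extend(sorted(self.node_ids - seen))
        return order


# ---------------------------------------------------------------------------
# Linear <-> graph conversion
# ---------------------------------------------------------------------------


def linear_to_graph(
    graph: VariationGraph, path_name: str, start: int, end: int
) -> list[GraphSegment]:
    """Map a 0-based half-open linear interval to graph segments in path order."""
    starts = graph.cumulative_starts(path_name)
    total = starts[-1]
    if not (0 <= start <= end <= total):
        raise RangeError(
            f"interval [{start}, {end}) outside path {path_name!r} of length {total}"
        )
    if start == end:
        return []
    path = graph.path(path_name)
    segments: list[GraphSegment] = []
    i = bisect_right(starts, start) - 1
    while i < len(path.steps) and starts[i] < end:
        step = path.steps[i]
        node_len = len(graph.node(step.node_id))
        a = max(start, starts[i]) - starts[i]          # traversal offsets
        b = min(end, starts[i] + node_len) - starts[i]
        if step.orientation == FORWARD:
            seg = GraphSegment(step.node_id, a, b, FORWARD, i)
        else:
            seg = GraphSegment(step.node_id, node_len - b, node_len - a, REVERSE, i)
        segments.append(seg)
        i += 1
    return segments


def graph_to_linear(
    graph: VariationGraph, path_name: str, node_id: str, offset: int
) -> list[int]:
    """All linear positions of a node offset on a path (one per traversal).

    Returns an empty list when the path never traverses the node; a looping
    path yields one position per visit, in path order. Reverse traversals
    invert the offset.
    """
    node = graph.node(node_id)
    if not (0 <= offset < len(node)):
        raise RangeError(f"offset {offset} outside node {node_id!r} of length {len(node)}")
    starts = graph.cumulative_starts(path_name)
    path = graph.path(path_name)
    positions: list[int] = []
    for i in graph.node_step_indices(path_name).get(node_id, []):
        step = path.steps[i]
        if step.orientation == FORWARD:
            positions.append(starts[i] + offset)
        else:
            positions.append(starts[i] + (len(node) - 1 - offset))
    return positions


def project_feature(graph: VariationGraph, feature: GenomeFeature) -> ProjectedFeature:
    """Project a bound feature's interval onto the graph."""
    if feature.bound_path is None:
        raise LookupError_(
            f"feature {feature.id!r} is not bound to a path (call bind_annotations)"
        )
    start0, end0 = feature.interval0()
    segments = linear_to_graph(graph, feature.bound_path, start0, end0)
    return ProjectedFeature(
        source=feature, genome=feature.genome, path_name=feature.bound_path,
        segments=segments,
    )


def projected_sequence(graph: VariationGraph, proj: ProjectedFeature) -> str:
    """Spell a projected feature from its node slices (revcomp on reverse)."""
    parts = []
    for seg in proj.segments:
        piece = graph.node(seg.node_id).sequence[seg.start : seg.end]
        parts.append(piece if seg.orientation == FORWARD else reverse_complement(piece))
    return "".join(parts)


# ---------------------------------------------------------------------------
# Region strings
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^(?P<path>.+):(?P<start>[\d,]+)\s*[-–—]\s*(?P<end>[\d,]+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``PATH:start-end`` (1-based inclusive) into (path, start0, end0).

    Hyphen, en-dash and em-dash are accepted as the separator; thousands
    commas in the coordinates are ignored.
    """
    m = _REGION_RE.match(region.strip())
    if not m:
        raise RegionParseError(
            f"cannot parse region {region!r}; expected PATH:start-end (1-based inclusive)"
        )
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if start < 1 or end < start:
        raise RegionParseError(f"invalid coordinates in region {region!r}")
    return m.group("path"), start - 1, end


# ---------------------------------------------------------------------------
# Region subgraph extraction
# ---------------------------------------------------------------------------


def _clip_path_runs(
    graph: VariationGraph, path_name: str, node_ids: set[str]
) -> list[ClippedRun]:
    """Maximal step runs of ``path_name`` whose nodes lie inside ``node_ids``."""
    path = graph.path(path_name)
    starts = graph.cumulative_starts(path_name)
    runs: list[ClippedRun] = []
    i = 0
    n = len(path.steps)
    while i < n:
        if path.steps[i].node_id not in node_ids:
            i += 1
            continue
        j = i
        while j + 1 < n and path.steps[j + 1].node_id in node_ids:
            j += 1
        last_len = len(graph.node(path.steps[j].node_id))
        runs.append(
            ClippedRun(
                path_name=path_name,
                first_step=i,
                steps=list(path.steps[i : j + 1]),
                entry_offset=0,
                exit_offset=last_len,
                lin_start=starts[i],
                lin_end=starts[j] + last_len,
            )
        )
        i = j + 1
    return runs


def extract_region(
    graph: VariationGraph,
    annot_sets: Sequence[AnnotationSet],
    region: str,
    feature_types: Optional[frozenset[str]] = None,
) -> RegionSubgraph:
    """Extract the subgraph of a region anchored on one genome path.

    The node set is every node the anchor path traverses in the interval,
    partial boundary nodes included whole. Every graph path is then clipped
    to its maximal runs inside the node set (membership by node-set
    intersection only — no alignment), and every bound feature of
    ``annot_sets`` with at least one base projecting into the node set is
    projected and clipped to it.

    The anchor path's clipped representation is a single run spanning
    exactly the query interval, via entry/exit offsets on its terminal
    steps, so its clipped sequence reproduces the requested substring.
    """
    path_name, start0, end0 = parse_region(region)
    if path_name not in graph.paths:
        raise LookupError_(f"unknown path {path_name!r} in region {region!r}")
    starts = graph.cumulative_starts(path_name)
    total = starts[-1]
    if end0 > total:
        raise RangeError(
            f"region {region!r} extends beyond path length {total}"
        )

    anchor_segments = linear_to_graph(graph, path_name, start0, end0)
    if not anchor_segments:
        raise RangeError(f"region {region!r} is empty")
    node_ids = {seg.node_id for seg in anchor_segments}

    path = graph.path(path_name)
    i0 = anchor_segments[0].step_index
    i1 = anchor_segments[-1].step_index
    anchor_run = ClippedRun(
        path_name=path_name,
        first_step=i0,
        steps=list(path.steps[i0 : i1 + 1]),
        entry_offset=start0 - starts[i0],
        exit_offset=end0 - starts[i1],
        lin_start=start0,
        lin_end=end0,
    )

    clipped: dict[str, list[ClippedRun]] = {path_name: [anchor_run]}
    for name in graph.paths:
        if name == path_name:
            continue
        runs = _clip_path_runs(graph, name, node_ids)
        if runs:
            clipped[name] = runs

    sub = RegionSubgraph(
        graph=graph,
        anchor_path=path_name,
        anchor_interval=(start0, end0),
        node_ids=node_ids,
        clipped_paths=clipped,
    )
    sub.clipped_features = _clip_features(sub, annot_sets, feature_types)
    return sub


def _clip_features(
    sub: RegionSubgraph,
    annot_sets: Sequence[AnnotationSet],
    feature_types: Optional[frozenset[str]],
) -> list[ProjectedFeature]:
    graph = sub.graph
    by_path: dict[str, AnnotationSet] = {}
    for annots in annot_sets:
        for seqid, pname in annots.seqid_bindings.items():
            by_path[pname] = annots

    projected: list[ProjectedFeature] = []
    for pname, runs in sub.clipped_paths.items():
        annots = by_path.get(pname)
        if annots is None:
            continue
        seqids = [s for s, p in annots.seqid_bindings.items() if p == pname]
        seen: set[str] = set()
        for run in runs:
            # widen the query to the whole-node extent of the run: boundary
            # nodes belong to the subgraph whole, so features touching only
            # their untrimmed part still project into the node set
            last_len = len(graph.node(run.steps[-1].node_id))
            win_start = run.lin_start - run.entry_offset
            win_end = run.lin_end + (last_len - run.exit_offset)
            for seqid in seqids:
                for feat in annots.features_overlapping(seqid, win_start, win_end):
                    if feat.id in seen:
                        continue
                    if feature_types is not None and feat.type not in feature_types:
                        continue
                    seen.add(feat.id)
                    proj = project_feature(graph, feat)
                    kept = [s for s in proj.segments if s.node_id in sub.node_ids]
                    if kept:
                        projected.append(
                            ProjectedFeature(feat, feat.genome, pname, kept)
                        )
    projected.sort(key=lambda p: (p.path_name, p.source.start, p.source.id))
    return projected


def path_span_in_region(sub: RegionSubgraph, path_name: str) -> Optional[tuple[int, int]]:
    """Minimal 1-based inclusive interval of a path covering its clipped runs.

    This is the window a linear browser view of that genome should display
    for the region; ``None`` when the path does not appear. Spans of the same
    subgraph generally differ in length across genomes because indels make
    the shared graph coordinates unevenly distributed along each genome.
    """
    if path_name not in sub.graph.paths:
        raise LookupError_(f"unknown path {path_name!r}")
    runs = sub.clipped_paths.get(path_name)
    if not runs:
        return None
    lo = min(r.lin_start for r in runs)
    hi = max(r.lin_end for r in runs)
    return (lo + 1, hi)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def region_to_gfa(sub: RegionSubgraph) -> bytes:
    """Export a region subgraph as GFA plus implied edges (clipped paths kept whole)."""
    from .graphio import GenomePath, VariationGraph as VG, write_gfa

    g = VG()
    for nid in sorted(sub.node_ids):
        g.nodes[nid] = sub.graph.nodes[nid]
    for edge in sub.graph.edges:
        a, _, b, _ = edge
        if a in sub.node_ids and b in sub.node_ids:
            g.edges.add(edge)
    for pname, runs in sub.clipped_paths.items():
        for k, run in enumerate(runs):
            name = pname if len(runs) == 1 else f"{pname}#run{k}"
            g.paths[name] = GenomePath(name, tuple(run.steps))
    return write_gfa(g)


def region_features_json(sub: RegionSubgraph) -> str:
    """Sidecar JSON describing the clipped features of a region subgraph."""
    payload = []
    for proj in sub.clipped_features:
        payload.append(
            {
                "feature_id": proj.source.id,
                "type": proj.source.type,
                "genome": proj.genome,
                "path": proj.path_name,
                "start": proj.source.start,
                "end": proj.source.end,
                "strand": proj.source.strand,
                "segments": [
                    {
                        "node": s.node_id,
                        "start": s.start,
                        "end": s.end,
                        "orientation": s.orientation,
                        "step_index": s.step_index,
                    }
                    for s in proj.segments
                ],
            }
        )
    return json.dumps(
        {
            "anchor_path": sub.anchor_path,
            "anchor_start": sub.anchor_interval[0] + 1,
            "anchor_end": sub.anchor_interval[1],
            "features": payload,
        },
        indent=2,
        sort_keys=True,
    )
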