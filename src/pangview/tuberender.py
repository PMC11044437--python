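"""Deterministic tube-map layout and static SVG rendering.

A region subgraph is laid out as columns of nodes with one horizontal lane
per genome path; gene features ride on the lanes as gray bars (or colored
bars over gray tracks under the inverted coloration). Two width modes:

* ``full`` — node width proportional to sequence length (``px_per_base``);
* ``compressed`` — width ``max(min_px, log_scale * log10(len + 1))``,
  decoupling width from length for readability. Bar *pixel* widths change
  between modes but the base-pair extent of every bar is invariant; in
  compressed mode a shorter exon can legitimately render wider than a
  longer one, because short nodes are floored at the minimum width.

Rendering is a pure function of (layout, options): the same inputs yield
byte-identical SVG. Crossing minimisation is not attempted — lane order is
input order with the anchor first.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import DomainError, LayoutError
from .graphio import FORWARD
from .projection import ProjectedFeature, RegionSubgraph

FULL = "full"
COMPRESSED = "compressed"

LIGHT_TRACKS = "light-tracks-gray-exons"
GRAY_TRACKS = "gray-tracks-colored-exons"

# nine distinguishable light colors (cycled beyond nine tracks)
DEFAULT_PALETTE = (
    "#a6cee3", "#b2df8a", "#fdbf6f", "#cab2d6", "#fb9a99",
    "#ffff99", "#80cdc1", "#f1b6da", "#c7eae5",
)
EXON_GRAY = "#808080"
TRACK_GRAY = "#cccccc"


@dataclass(frozen=True)
class RenderOptions:
    coloration: str = LIGHT_TRACKS
    show_text: bool = False
    px_per_base: float = 10.0
    compressed_min_px: float = 20.0
    compressed_log_scale: float = 15.0
    palette: tuple[str, ...] = DEFAULT_PALETTE
    lane_height: float = 14.0
    lane_gap: float = 10.0
    node_gap: float = 12.0
    margin: float = 20.0

    def __post_init__(self) -> None:
        if self.px_per_base <= 0:
            raise DomainError("px_per_base must be positive")
        if self.coloration not in (LIGHT_TRACKS, GRAY_TRACKS):
            raise DomainError(f"unknown coloration {self.coloration!r}")


@dataclass(frozen=True)
class FeatureBar:
    path_name: str
    node_id: str
    x0: float
    x1: float
    bar_id: str
    feature_id: str
    length_bp: int


@dataclass
class PathLane:
    path_name: str
    lane_index: int
    y: float
    # one waypoint list per clipped run: (node_id, entry_y, exit_y)
    runs: list[list[tuple[str, float, float]]]


@dataclass
class TubeLayout:
    mode: str
    node_columns: dict[str, float]           # node id -> column rank
    node_x: dict[str, tuple[float, float]]   # node id -> (x0, x1)
    path_lanes: dict[str, PathLane]
    feature_bars: list[FeatureBar]
    width: float
    height: float
    anchor_path: str

    def bars_of_path(self, path_name: str) -> list[FeatureBar]:
        return [b for b in self.feature_bars if b.path_name == path_name]

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "anchor_path": self.anchor_path,
                "node_columns": self.node_columns,
                "node_x": self.node_x,
                "lanes": {
                    p: {"index": l.lane_index, "y": l.y, "runs": l.runs}
                    for p, l in self.path_lanes.items()
                },
                "bars": [
                    {
                        "path": b.path_name, "node": b.node_id, "x0": b.x0,
                        "x1": b.x1, "id": b.bar_id, "feature": b.feature_id,
                        "length_bp": b.length_bp,
                    }
                    for b in self.feature_bars
                ],
                "width": self.width,
                "height": self.height,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------


def _node_width(length: int, mode: str, opts: RenderOptions) -> float:
    if mode == FULL:
        return opts.px_per_base * length
    return max(opts.compressed_min_px, opts.compressed_log_scale * math.log10(length + 1))


def _column_ranks(sub: RegionSubgraph) -> dict[str, float]:
    """Anchor nodes ranked by first occurrence; off-anchor nodes half a
    column after the minimum rank of their within-path predecessors."""
    ranks: dict[str, float] = {}
    r = 0
    for step in sub.anchor_run.steps:
        if step.node_id not in ranks:
            ranks[step.node_id] = float(r)
            r += 1

    pending = set(sub.node_ids) - set(ranks)
    run_lists = [
        [s.node_id for s in run.steps]
        for pname in sub.clipped_paths
        for run in sub.clipped_paths[pname]
    ]
    # forward passes: predecessor rank + 0.5
    changed = True
    while pending and changed:
        changed = False
        for nodes in run_lists:
            for prev, cur in zip(nodes, nodes[1:]):
                if cur in pending and prev in ranks:
                    cand = ranks[prev] + 0.5
                    if cur not in ranks or cand < ranks[cur]:
                        ranks[cur] = cand
                        pending.discard(cur)
                        changed = True
    # backward fallback: successor rank - 0.5 (runs that start off-anchor)
    changed = True
    while pending and changed:
        changed = False
        for nodes in run_lists:
            for prev, cur in zip(nodes, nodes[1:]):
                if prev in pending and cur in ranks:
                    cand = ranks[cur] - 0.5
                    if prev not in ranks or cand > ranks[prev]:
                        ranks[prev] = cand
                        pending.discard(prev)
                        changed = True
    if pending:
        tail = (max(ranks.values()) if ranks else 0.0) + 0.5
        for nid in sorted(pending):
            ranks[nid] = tail
    return ranks


def layout_region(
    sub: RegionSubgraph,
    features: Optional[Sequence[ProjectedFeature]] = None,
    opts: RenderOptions = RenderOptions(),
    mode: str = FULL,
) -> TubeLayout:
    """Compute a deterministic tube-map layout for a region subgraph.

    Columns follow the anchor path's first-occurrence order; lanes follow
    input path order with the anchor first; every projected feature segment
    becomes one bar rectangle positioned inside its node proportionally to
    its forward offsets (rescaled to the compressed width in compressed
    mode). ``features`` defaults to the subgraph's clipped exon features.
    """
    if not sub.node_ids:
        raise LayoutError("cannot lay out an empty subgraph")
    if mode not in (FULL, COMPRESSED):
        raise DomainError(f"unknown mode {mode!r}")
    if features is None:
        features = [p for p in sub.clipped_features if p.source.type == "exon"]

    ranks = _column_ranks(sub)
    ordered = sorted(sub.node_ids, key=lambda n: (ranks[n], n))

    node_x: dict[str, tuple[float, float]] = {}
    cursor = opts.margin
    for nid in ordered:
        w = _node_width(len(sub.graph.node(nid)), mode, opts)
        node_x[nid] = (cursor, cursor + w)
        cursor += w + opts.node_gap
    width = cursor - opts.node_gap + opts.margin

    lane_order = [sub.anchor_path] + [p for p in sub.clipped_paths if p != sub.anchor_path]
    path_lanes: dict[str, PathLane] = {}
    for idx, pname in enumerate(lane_order):
        y = opts.margin + idx * (opts.lane_height + opts.lane_gap)
        runs = [
            [(s.node_id, y, y) for s in run.steps]
            for run in sub.clipped_paths[pname]
        ]
        path_lanes[pname] = PathLane(pname, idx, y, runs)
    height = opts.margin * 2 + len(lane_order) * (opts.lane_height + opts.lane_gap)

    bars: list[FeatureBar] = []
    for proj in features:
        for k, seg in enumerate(proj.segments):
            if seg.node_id not in node_x:
                continue
            nx0, nx1 = node_x[seg.node_id]
            w = nx1 - nx0
            node_len = len(sub.graph.node(seg.node_id))
            bars.append(
                FeatureBar(
                    path_name=proj.path_name,
                    node_id=seg.node_id,
                    x0=nx0 + w * seg.start / node_len,
                    x1=nx0 + w * seg.end / node_len,
                    bar_id=f"{proj.source.id}.seg{k}",
                    feature_id=proj.source.id,
                    length_bp=len(seg),
                )
            )
    bars.sort(key=lambda b: (b.path_name, b.x0, b.bar_id))

    return TubeLayout(
        mode=mode,
        node_columns=ranks,
        node_x=node_x,
        path_lanes=path_lanes,
        feature_bars=bars,
        width=width,
        height=height,
        anchor_path=sub.anchor_path,
    )


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------


def _esc(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;").replace('"', "&quot;")


def render_svg(
    layout: TubeLayout,
    opts: RenderOptions = RenderOptions(),
    sub: Optional[RegionSubgraph] = None,
) -> str:
    """Render a layout to an SVG 1.1 document string, deterministically.

    Track ribbons take palette colors (gray under the inverted coloration,
    which colors the exon bars instead); every feature bar is one rect; a
    track with no projected features carries zero bars, so absence of a
    gray bar on a track reads as absence of the feature. Node sequence text
    is drawn only in full mode when ``show_text`` and ``px_per_base >= 8``
    (the legibility floor). Passing the subgraph enables text rendering.
    """
    parts: list[str] = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{layout.width:.1f}" height="{layout.height:.1f}">',
        f'<rect x="0" y="0" width="{layout.width:.1f}" height="{layout.height:.1f}" fill="#ffffff"/>',
    ]

    # node outlines spanning the lane band
    band_top = opts.margin - 4
    band_bottom = layout.height - opts.margin + 4
    for nid in sorted(layout.node_x):
        x0, x1 = layout.node_x[nid]
        parts.append(
            f'<rect id="node-{_esc(nid)}" x="{x0:.1f}" y="{band_top:.1f}" '
            f'width="{x1 - x0:.1f}" height="{band_bottom - band_top:.1f}" '
            f'fill="none" stroke="#e0e0e0" stroke-width="0.5"/>'
        )

    lanes = sorted(layout.path_lanes.values(), key=lambda l: l.lane_index)
    for lane in lanes:
        if opts.coloration == LIGHT_TRACKS:
            color = opts.palette[lane.lane_index % len(opts.palette)]
        else:
            color = TRACK_GRAY
        h = opts.lane_height
        for ri, run in enumerate(lane.runs):
            prev_x1: Optional[float] = None
            for wi, (nid, _ey, _xy) in enumerate(run):
                x0, x1 = layout.node_x[nid]
                parts.append(
                    f'<rect id="track-{_esc(lane.path_name)}-r{ri}w{wi}" '
                    f'x="{x0:.1f}" y="{lane.y:.1f}" width="{x1 - x0:.1f}" '
                    f'height="{h:.1f}" fill="{color}"/>'
                )
                if prev_x1 is not None:
                    ymid = lane.y + h / 2
                    parts.append(
                        f'<line x1="{prev_x1:.1f}" y1="{ymid:.1f}" '
                        f'x2="{x0:.1f}" y2="{ymid:.1f}" stroke="{color}" stroke-width="2"/>'
                    )
                prev_x1 = x1

    for bar in layout.feature_bars:
        lane = layout.path_lanes[bar.path_name]
        if opts.coloration == LIGHT_TRACKS:
            fill = EXON_GRAY
        else:
            fill = opts.palette[lane.lane_index % len(opts.palette)]
        y0 = lane.y + 2
        h = opts.lane_height - 4
        parts.append(
            f'<rect id="bar-{_esc(bar.path_name)}-{_esc(bar.bar_id)}" class="feature-bar" '
            f'x="{bar.x0:.2f}" y="{y0:.1f}" width="{bar.x1 - bar.x0:.2f}" '
            f'height="{h:.1f}" fill="{fill}"/>'
        )

    if (
        opts.show_text
        and layout.mode == FULL
        and opts.px_per_base >= 8
        and sub is not None
    ):
        for nid in sorted(layout.node_x):
            x0, _x1 = layout.node_x[nid]
            seq = sub.graph.node(nid).sequence
            for i, base in enumerate(seq):
                parts.append(
                    f'<text x="{x0 + (i + 0.5) * opts.px_per_base:.1f}" '
                    f'y="{band_top - 2:.1f}" font-size="7" text-anchor="middle" '
                    f'font-family="monospace">{base}</text>'
                )

    for lane in lanes:
        parts.append(
            f'<text x="2" y="{lane.y + opts.lane_height - 3:.1f}" font-size="8" '
            f'font-family="sans-serif">{_esc(lane.path_name)}</text>'
        )

    parts.append("</svg>")
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# Junction alignment report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionEdge:
    path_name: str
    feature_id: str
    side: str                  # 'start' or 'end'


@dataclass
class JunctionGroup:
    coord: tuple[str, int]     # (node id, forward offset of the boundary base)
    members: list[JunctionEdge]

    @property
    def genomes(self) -> set[str]:
        return {m.path_name for m in self.members}


def exon_edge_alignment_report(
    layout: TubeLayout, features: Sequence[ProjectedFeature]
) -> list[JunctionGroup]:
    """Group feature boundaries landing on identical graph coordinates.

    Each feature contributes its start and end boundary in (node, forward
    offset) coordinates; boundaries from different genomes fall in the same
    group exactly when the splice sites are identical on the graph. Groups
    are returned sorted by node id then offset.
    """
    groups: dict[tuple[str, int], list[JunctionEdge]] = {}
    for proj in features:
        if not proj.segments:
            continue
        start_coord, end_coord = proj.boundary_coords()
        for coord, side in ((start_coord, "start"), (end_coord, "end")):
            if coord[0] not in layout.node_x:
                continue
            groups.setdefault(coord, []).append(
                JunctionEdge(proj.path_name, proj.source.id, side)
            )
    out = [
        JunctionGroup(coord, sorted(members, key=lambda m: (m.path_name, m.feature_id, m.side)))
        for coord, members in groups.items()
    ]
    out.sort(key=lambda g: (g.coord[0], g.coord[1]))
    return out
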