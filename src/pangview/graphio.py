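"""Variation-graph model and GFA v1 I/O.

A pangenome variation graph is a bidirected sequence graph: nodes carry DNA,
edges connect oriented node ends, and each constituent genome (or chromosome)
is a *path* — an ordered, oriented walk whose concatenated node sequences
spell that genome. Paths are named ``GENOME.chr`` so that region strings such
as ``NATELBORO.chr06:28873554-28874897`` resolve directly.

Only blunt-ended GFA v1 graphs are handled (the dialect both PGGB and
Minigraph-Cactus emit after conversion): S/L/P lines plus optional W walk
lines, with 0M or ``*`` overlaps. Graphs are treated as immutable after load;
coordinate indexes built lazily by :mod:`pangview.projection` rely on this.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from .errors import (
    DuplicateSegmentError,
    GFAParseError,
    GraphReferenceError,
    GraphValidationError,
    LookupError_,
)

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"

_ALLOWED_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N self-paired)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Node:
    """A graph node: an id and a non-empty uppercase DNA sequence."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrientedStep:
    """One step of a path: a node id traversed forward (``+``) or reverse (``-``)."""

    node_id: str
    orientation: str  # FORWARD or REVERSE

    def flipped(self) -> "OrientedStep":
        return OrientedStep(self.node_id, REVERSE if self.orientation == FORWARD else FORWARD)


@dataclass
class GenomePath:
    """A named walk through the graph; spells one linear genome sequence."""

    name: str
    steps: tuple[OrientedStep, ...]

    @property
    def genome(self) -> str:
        """Genome part of a ``GENOME.chr`` path name (name itself if undotted)."""
        return self.name.rsplit(".", 1)[0] if "." in self.name else self.name


Edge = tuple[str, str, str, str]  # (from_id, from_orient, to_id, to_orient)


def _edge_flip(edge: Edge) -> Edge:
    a, ao, b, bo = edge
    flip = {FORWARD: REVERSE, REVERSE: FORWARD}
    return (b, flip[bo], a, flip[ao])


@dataclass
class VariationGraph:
    """Nodes, bidirected edges and named genome paths."""

    nodes: dict[str, Node] = field(default_factory=dict)
    edges: set[Edge] = field(default_factory=set)
    paths: dict[str, GenomePath] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # lazy per-path caches; safe because graphs are immutable after load
        self._cumstart_cache: dict[str, list[int]] = {}
        self._node_steps_cache: dict[str, dict[str, list[int]]] = {}
        self._sequence_cache: dict[str, str] = {}

    # -- basic accessors ---------------------------------------------------

    def node(self, node_id: str) -> Node:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise LookupError_(f"unknown node {node_id!r}") from None

    def path(self, name: str) -> GenomePath:
        try:
            return self.paths[name]
        except KeyError:
            raise LookupError_(f"unknown path {name!r}") from None

    def has_edge(self, a: str, ao: str, b: str, bo: str) -> bool:
        e = (a, ao, b, bo)
        return e in self.edges or _edge_flip(e) in self.edges

    def path_length(self, name: str) -> int:
        return sum(len(self.nodes[s.node_id]) for s in self.path(name).steps)

    def genomes(self) -> list[str]:
        """Distinct genome names over all paths, sorted."""
        return sorted({p.genome for p in self.paths.values()})

    def paths_of_genome(self, genome: str) -> list[GenomePath]:
        return [p for p in self.paths.values() if p.genome == genome]

    # -- per-path coordinate caches (used by projection) -------------------

    def cumulative_starts(self, path_name: str) -> list[int]:
        """Linear start offset of every step of ``path_name`` plus total length."""
        if path_name not in self._cumstart_cache:
            starts = [0]
            for step in self.path(path_name).steps:
                starts.append(starts[-1] + len(self.node(step.node_id)))
            self._cumstart_cache[path_name] = starts
        return self._cumstart_cache[path_name]

    def node_step_indices(self, path_name: str) -> dict[str, list[int]]:
        """node id -> ordinals of the steps of ``path_name`` visiting it."""
        if path_name not in self._node_steps_cache:
            index: dict[str, list[int]] = {}
            for i, step in enumerate(self.path(path_name).steps):
                index.setdefault(step.node_id, []).append(i)
            self._node_steps_cache[path_name] = index
        return self._node_steps_cache[path_name]


def step_sequence(graph: VariationGraph, step: OrientedStep) -> str:
    """Sequence contributed by one step, reverse-complemented on reverse steps."""
    seq = graph.node(step.node_id).sequence
    return seq if step.orientation == FORWARD else reverse_complement(seq)


def path_sequence(graph: VariationGraph, path_name: str) -> str:
    """Spell the linear genome sequence of a path."""
    if path_name not in graph._sequence_cache:
        parts = [step_sequence(graph, s) for s in graph.path(path_name).steps]
        graph._sequence_cache[path_name] = "".join(parts)
    return graph._sequence_cache[path_name]


# ---------------------------------------------------------------------------
# GFA v1 reading
# ---------------------------------------------------------------------------

_STEP_RE = re.compile(r"([!-~]+?)([+-])$")
_WALK_RE = re.compile(r"([><])([^><]+)")


def _open_text(source) -> Iterator[str]:
    """Yield text lines from a path, text, bytes or file object; gzip-transparent."""
    if isinstance(source, (str,)) and "\n" not in source and "\t" not in source:
        raw = open(source, "rb")
    elif isinstance(source, str):
        raw = io.BytesIO(source.encode())
    elif isinstance(source, (bytes, bytearray)):
        raw = io.BytesIO(bytes(source))
    else:
        raw = source  # file-like
    data = raw.read()
    if isinstance(data, str):
        data = data.encode()
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    if hasattr(raw, "close"):
        raw.close()
    return iter(data.decode().splitlines())


def _parse_step_token(token: str, lineno: int) -> OrientedStep:
    m = _STEP_RE.fullmatch(token)
    if not m:
        raise GFAParseError(f"malformed path step {token!r}", lineno)
    return OrientedStep(m.group(1), m.group(2))


def _check_sequence(seq: str, segment_id: str, lineno: int) -> str:
    seq = seq.upper()
    if not seq or seq == "*":
        raise GFAParseError(f"segment {segment_id!r} has no sequence", lineno)
    bad = set(seq) - _ALLOWED_BASES
    if bad:
        raise GFAParseError(
            f"segment {segment_id!r} has characters outside ACGTN: {sorted(bad)}", lineno
        )
    return seq


def read_gfa(source, strict: bool = False) -> VariationGraph:
    """Parse GFA v1 text into a :class:`VariationGraph`.

    Two-pass: S lines are collected first, so forward references from L/P/W
    lines are legal. W lines are converted to paths named ``sample.seqid``
    (``sample#hap.seqid`` when the haplotype index is non-zero). Unknown line
    types are ignored with a warning. With ``strict=True`` the parsed graph
    must additionally pass :func:`validate_graph` with strict checks.
    """
    lines = list(_open_text(source))

    graph = VariationGraph()
    deferred: list[tuple[int, list[str]]] = []  # non-S lines for pass 2

    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        tag = fields[0]
        if tag == "S":
            if len(fields) < 3:
                raise GFAParseError("S line needs id and sequence", lineno)
            sid = fields[1]
            if sid in graph.nodes:
                raise DuplicateSegmentError(f"duplicate segment id {sid!r}", lineno)
            graph.nodes[sid] = Node(sid, _check_sequence(fields[2], sid, lineno))
        elif tag in ("L", "P", "W"):
            deferred.append((lineno, fields))
        elif tag == "H":
            continue
        else:
            logger.warning("ignoring unknown GFA line type %r at line %d", tag, lineno)

    for lineno, fields in deferred:
        tag = fields[0]
        if tag == "L":
            if len(fields) < 6:
                raise GFAParseError("L line needs 5 fields", lineno)
            a, ao, b, bo, overlap = fields[1:6]
            if ao not in "+-" or bo not in "+-":
                raise GFAParseError("L line orientations must be + or -", lineno)
            if overlap not in ("*", "0M"):
                raise GFAParseError(
                    f"overlapped link {overlap!r} not supported (blunt-ended graphs only)",
                    lineno,
                )
            for sid in (a, b):
                if sid not in graph.nodes:
                    raise GraphReferenceError(
                        f"L line {lineno} refers to missing segment {sid!r}"
                    )
            graph.edges.add((a, ao, b, bo))
        elif tag == "P":
            if len(fields) < 3:
                raise GFAParseError("P line needs name and steps", lineno)
            name = fields[1]
            steps = tuple(
                _parse_step_token(tok, lineno) for tok in fields[2].split(",") if tok
            )
            if not steps:
                raise GFAParseError(f"path {name!r} has no steps", lineno)
            for s in steps:
                if s.node_id not in graph.nodes:
                    raise GraphReferenceError(
                        f"P line {lineno}: step refers to missing segment {s.node_id!r}"
                    )
            graph.paths[name] = GenomePath(name, steps)
        elif tag == "W":
            if len(fields) < 7:
                raise GFAParseError("W line needs 6 fields", lineno)
            sample, hap, seqid, _start, _end, walk = fields[1:7]
            name = f"{sample}.{seqid}" if hap in ("0", "*") else f"{sample}#{hap}.{seqid}"
            steps = tuple(
                OrientedStep(nid, FORWARD if sign == ">" else REVERSE)
                for sign, nid in _WALK_RE.findall(walk)
            )
            if not steps:
                raise GFAParseError(f"walk {name!r} has no steps", lineno)
            for s in steps:
                if s.node_id not in graph.nodes:
                    raise GraphReferenceError(
                        f"W line {lineno}: walk refers to missing segment {s.node_id!r}"
                    )
            graph.paths[name] = GenomePath(name, steps)

    if strict:
        findings = validate_graph(graph, strict=True)
        if findings:
            raise GraphValidationError(
                "; ".join(f"{f.kind}: {f.message}" for f in findings)
            )
    return graph


# ---------------------------------------------------------------------------
# GFA v1 writing
# ---------------------------------------------------------------------------


def write_gfa(graph: VariationGraph) -> bytes:
    """Serialize to GFA v1 bytes, deterministically.

    Nodes are emitted lexicographically by id, paths by name. Edges implied
    by path adjacency but absent from the edge set are added as L lines so
    the output is a valid strict graph; repeated calls are byte-identical.
    """
    out = ["H\tVN:Z:1.0"]
    for sid in sorted(graph.nodes):
        out.append(f"S\t{sid}\t{graph.nodes[sid].sequence}")

    edges = set(graph.edges)
    for path in graph.paths.values():
        for a, b in zip(path.steps, path.steps[1:]):
            e = (a.node_id, a.orientation, b.node_id, b.orientation)
            if e not in edges and _edge_flip(e) not in edges:
                edges.add(e)
    for a, ao, b, bo in sorted(edges):
        out.append(f"L\t{a}\t{ao}\t{b}\t{bo}\t0M")

    for name in sorted(graph.paths):
        steps = ",".join(f"{s.node_id}{s.orientation}" for s in graph.paths[name].steps)
        out.append(f"P\t{name}\t{steps}\t*")
    return ("\n".join(out) + "\n").encode()


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Finding:
    kind: str  # missing-node | empty-sequence | bad-character | missing-edge
    message: str


def validate_graph(graph: VariationGraph, strict: bool = False) -> list[Finding]:
    """Check graph invariants; returns findings instead of raising.

    Strict mode additionally requires every consecutive step pair of every
    path to be backed by an edge (in either writing of the bidirected link).
    """
    findings: list[Finding] = []
    for node in graph.nodes.values():
        if not node.sequence:
            findings.append(Finding("empty-sequence", f"node {node.id} has empty sequence"))
        elif set(node.sequence) - _ALLOWED_BASES:
            findings.append(Finding("bad-character", f"node {node.id} has non-ACGTN bases"))
    for a, ao, b, bo in graph.edges:
        for sid in (a, b):
            if sid not in graph.nodes:
                findings.append(
                    Finding("missing-node", f"edge endpoint {sid!r} is not a node")
                )
    for path in graph.paths.values():
        for step in path.steps:
            if step.node_id not in graph.nodes:
                findings.append(
                    Finding(
                        "missing-node",
                        f"path {path.name} step refers to missing node {step.node_id!r}",
                    )
                )
        if strict:
            for a, b in zip(path.steps, path.steps[1:]):
                if a.node_id not in graph.nodes or b.node_id not in graph.nodes:
                    continue
                if not graph.has_edge(a.node_id, a.orientation, b.node_id, b.orientation):
                    findings.append(
                        Finding(
                            "missing-edge",
                            f"path {path.name}: adjacency {a.node_id}{a.orientation}"
                            f"->{b.node_id}{b.orientation} has no L line",
                        )
                    )
    return findings
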