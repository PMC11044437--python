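"""Presence/absence variation calling, gene comparison and association.

This module turns the shared graph coordinates into population-level calls:

* a *presence matrix* counts how often each genome's path traverses each
  node of a region — the basis for grouping accessions by a skipped node
  (the classic case being a single long deletion node whose skippers lack
  the gene);
* *gene comparison* projects a reference gene's exons onto the graph and
  classifies every other genome by splice-site identity in (node, offset)
  coordinates: identical structure, shifted boundaries, element-level
  presence/absence, or loss of the annotation / the underlying sequence;
* *coding indel scan* walks two genomes through a gene region and reports
  the indel bubbles overlapping coding sequence, split into frame-preserving
  (length divisible by three) and frame-breaking;
* an exact-sequence *locator* finds a query in every genome path (both
  strands) by k-mer seeding and verification;
* a Wilcoxon *rank-sum test* associates presence groups with a quantitative
  phenotype.
"""

from __future__ import annotations

import difflib
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotio import AnnotationSet, GeneModel, find_gene
from .errors import (
    AbsenceError,
    DegenerateGroupingError,
    DomainError,
    LookupError_,
)
from .graphio import FORWARD, VariationGraph, path_sequence, reverse_complement
from .projection import (
    GraphSegment,
    ProjectedFeature,
    RegionSubgraph,
    extract_region,
    project_feature,
)

logger = logging.getLogger(__name__)

FRAME_PRESERVING = "frame_preserving"
FRAME_BREAKING = "frame_breaking"

IDENTICAL_STRUCTURE = "identical_structure"
BOUNDARY_SHIFT = "boundary_shift"
ELEMENT_PAV = "element_pav"
ABSENT_ANNOTATION = "absent_annotation"
ABSENT_SEQUENCE = "absent_sequence"

DEFAULT_PRESENCE_THRESHOLD = 0.8
DEFAULT_EXACT_CUTOFF = 10
DEFAULT_LOCATOR_K = 16


# ---------------------------------------------------------------------------
# Presence matrix and grouping
# ---------------------------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Genome-by-node traversal counts for a region subgraph."""

    counts: pd.DataFrame           # index: genome names, columns: node ids
    anchor_genome: str
    all_genomes: list[str]         # every genome with a path in the graph

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def node_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self) -> str:
        return self.counts.to_csv(sep="\t", index_label="genome")


def presence_matrix(sub: RegionSubgraph) -> PresenceMatrix:
    """Count node traversals per genome across the clipped runs of a region.

    A genome appears as a row iff it traverses at least one region node;
    counts exceed one when a path loops. Multiple paths of the same genome
    (e.g. several chromosomes touching the region) are summed.
    """
    node_order = sub.node_order()
    genome_order: list[str] = []
    rows: dict[str, dict[str, int]] = {}
    for pname, runs in sub.clipped_paths.items():
        genome = sub.graph.path(pname).genome
        if genome not in rows:
            rows[genome] = {n: 0 for n in node_order}
            genome_order.append(genome)
        for run in runs:
            for step in run.steps:
                rows[genome][step.node_id] += 1
    counts = pd.DataFrame(
        [[rows[g][n] for n in node_order] for g in genome_order],
        index=genome_order,
        columns=node_order,
        dtype=int,
    )
    return PresenceMatrix(
        counts=counts,
        anchor_genome=sub.graph.path(sub.anchor_path).genome,
        all_genomes=sub.graph.genomes(),
    )


@dataclass
class NodeGrouping:
    node_id: str
    traversing: list[str]
    skipping: list[str]
    unplaced: list[str]            # genomes absent from the region entirely


def group_by_node(m: PresenceMatrix, node_id: str) -> NodeGrouping:
    """Split region genomes by whether they traverse (>=1) or skip a node.

    Genomes with no path in the region are reported separately as unplaced,
    not as skippers.
    """
    if node_id not in m.counts.columns:
        raise LookupError_(f"node {node_id!r} not in presence matrix")
    col = m.counts[node_id]
    traversing = sorted(col.index[col >= 1])
    skipping = sorted(col.index[col == 0])
    unplaced = sorted(set(m.all_genomes) - set(m.genomes))
    return NodeGrouping(node_id, traversing, skipping, unplaced)


# ---------------------------------------------------------------------------
# Gene comparison
# ---------------------------------------------------------------------------


@dataclass
class GenomeCall:
    genome: str
    status: str
    coverage: float
    splice_diffs: list[tuple[str, int]] = field(default_factory=list)
    matched_gene: Optional[str] = None


@dataclass
class GeneComparison:
    gene_id: str
    reference_genome: str
    calls: dict[str, GenomeCall]

    def status_of(self, genome: str) -> str:
        return self.calls[genome].status

    def to_tsv(self) -> str:
        lines = ["genome\tstatus\tcoverage\tmatched_gene\tsplice_diffs"]
        for g in sorted(self.calls):
            c = self.calls[g]
            diffs = ",".join(f"{n}:{o}" for n, o in c.splice_diffs) or "."
            lines.append(
                f"{g}\t{c.status}\t{c.coverage:.4f}\t{c.matched_gene or '.'}\t{diffs}"
            )
        return "\n".join(lines) + "\n"


def _gene_model(annots: AnnotationSet, gene_id: str) -> GeneModel:
    if gene_id in annots.genes:
        return annots.genes[gene_id]
    for model in annots.genes.values():
        if model.gene.attributes.get("Name") == gene_id:
            return model
    raise LookupError_(f"gene {gene_id!r} not found in genome {annots.genome!r}")


def _exon_projections(
    graph: VariationGraph, model: GeneModel, use_cds: bool
) -> list[ProjectedFeature]:
    elems = model.structure_elements(use_cds=use_cds)
    if not elems:
        raise LookupError_(f"gene {model.gene.id!r} has no exon/CDS elements")
    return [project_feature(graph, e) for e in elems]


def _boundary_list(projs: Sequence[ProjectedFeature]) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    return [p.boundary_coords() for p in projs]


def _genome_node_set(graph: VariationGraph, genome: str) -> set[str]:
    nodes: set[str] = set()
    for path in graph.paths_of_genome(genome):
        nodes.update(s.node_id for s in path.steps)
    return nodes


def _offsets_by_node(projs: Sequence[ProjectedFeature]) -> dict[str, list[tuple[int, int]]]:
    by_node: dict[str, list[tuple[int, int]]] = {}
    for proj in projs:
        for seg in proj.segments:
            by_node.setdefault(seg.node_id, []).append((seg.start, seg.end))
    return by_node


def _intervals_overlap(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> bool:
    return any(s1 < e2 and s2 < e1 for s1, e1 in a for s2, e2 in b)


def compare_gene(
    graph: VariationGraph,
    annot_sets: Sequence[AnnotationSet],
    gene_id: str,
    reference_genome: str,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    use_cds: bool = False,
) -> GeneComparison:
    """Classify every other genome against a reference gene's exon structure.

    The reference gene's exons are projected to graph coordinates. For each
    other genome: the *coverage* fraction is the share of the reference
    exonic graph positions lying on nodes that genome traverses (absence of
    sequence is graph-topological, independent of annotation). If the genome
    annotates a gene whose projected exons overlap the reference projection,
    splice sites are compared as exact (node, forward-offset) equality of
    exon boundaries: all equal -> identical_structure; equal exon count with
    a differing boundary -> boundary_shift; differing exon count ->
    element_pav. Without an overlapping annotation the call is
    absent_annotation when coverage >= ``presence_threshold`` and
    absent_sequence below it.
    """
    by_genome = {a.genome: a for a in annot_sets}
    if reference_genome not in by_genome:
        raise LookupError_(f"no annotations for reference genome {reference_genome!r}")
    if not graph.paths_of_genome(reference_genome):
        raise LookupError_(f"reference genome {reference_genome!r} has no path in graph")

    ref_model = _gene_model(by_genome[reference_genome], gene_id)
    ref_projs = _exon_projections(graph, ref_model, use_cds)
    ref_boundaries = _boundary_list(ref_projs)
    ref_offsets = _offsets_by_node(ref_projs)
    exonic_total = sum(p.length for p in ref_projs)

    calls: dict[str, GenomeCall] = {}
    for genome in graph.genomes():
        if genome == reference_genome:
            continue
        traversed = _genome_node_set(graph, genome)
        covered = sum(
            e - s
            for node, spans in ref_offsets.items()
            if node in traversed
            for s, e in spans
        )
        coverage = covered / exonic_total if exonic_total else 0.0

        match = _find_overlapping_gene(
            graph, by_genome.get(genome), ref_offsets, use_cds
        )
        if match is not None:
            model, projs = match
            boundaries = _boundary_list(projs)
            if boundaries == ref_boundaries:
                status, diffs = IDENTICAL_STRUCTURE, []
            else:
                flat_ref = {c for pair in ref_boundaries for c in pair}
                flat_other = {c for pair in boundaries for c in pair}
                diffs = sorted(flat_ref.symmetric_difference(flat_other))
                status = (
                    BOUNDARY_SHIFT if len(boundaries) == len(ref_boundaries) else ELEMENT_PAV
                )
            calls[genome] = GenomeCall(
                genome, status, coverage, diffs, matched_gene=model.gene.id
            )
        elif coverage >= presence_threshold:
            calls[genome] = GenomeCall(genome, ABSENT_ANNOTATION, coverage)
        else:
            calls[genome] = GenomeCall(genome, ABSENT_SEQUENCE, coverage)

    return GeneComparison(gene_id=gene_id, reference_genome=reference_genome, calls=calls)


def _find_overlapping_gene(
    graph: VariationGraph,
    annots: Optional[AnnotationSet],
    ref_offsets: dict[str, list[tuple[int, int]]],
    use_cds: bool,
) -> Optional[tuple[GeneModel, list[ProjectedFeature]]]:
    """Best gene of ``annots`` whose projected exons share graph positions
    with the reference exon projection (largest shared base count wins,
    gene id as tie-break)."""
    if annots is None:
        return None
    best: Optional[tuple[int, str, GeneModel, list[ProjectedFeature]]] = None
    for gid in sorted(annots.genes):
        model = annots.genes[gid]
        elems = model.structure_elements(use_cds=use_cds)
        if not elems or any(e.bound_path is None for e in elems):
            continue
        projs = [project_feature(graph, e) for e in elems]
        offsets = _offsets_by_node(projs)
        shared = 0
        for node, spans in offsets.items():
            for s, e in spans:
                for rs, re_ in ref_offsets.get(node, []):
                    lo, hi = max(s, rs), min(e, re_)
                    if hi > lo:
                        shared += hi - lo
        if shared > 0 and (best is None or shared > best[0]):
            best = (shared, gid, model, projs)
    if best is None:
        return None
    return best[2], best[3]


# ---------------------------------------------------------------------------
# Frame classification and coding indel scan
# ---------------------------------------------------------------------------


def classify_indel_frame(indel_length: int) -> str:
    """Frame-preserving iff the indel length is a multiple of three (0 included)."""
    if indel_length < 0:
        raise DomainError(f"indel length must be non-negative, got {indel_length}")
    return FRAME_PRESERVING if indel_length % 3 == 0 else FRAME_BREAKING


@dataclass(frozen=True)
class IndelCall:
    kind: str                  # insertion | deletion (relative to the reference path)
    length: int
    frame: str
    ref_position: int          # 1-based position on the reference path (left-anchored)
    node_ids: tuple[str, ...]


def coding_indel_scan(
    graph: VariationGraph,
    annot_sets: Sequence[AnnotationSet],
    gene_id: str,
    reference_genome: str,
    other_genome: str,
) -> list[IndelCall]:
    """Report indel bubbles between two genomes inside a gene's coding regions.

    Both genomes' clipped walks through the reference gene region are
    compared node-by-node; every maximal node run present in exactly one of
    the two walks and overlapping the reference CDS (exons when no CDS is
    annotated) is reported with its total length and frame classification.
    Balanced replacement bubbles (equal lengths on both sides, e.g. SNPs)
    are substitutions, not indels, and are skipped; unbalanced replacements
    contribute their net length difference.
    """
    by_genome = {a.genome: a for a in annot_sets}
    ref_model = _gene_model(by_genome[reference_genome], gene_id)
    gene = ref_model.gene
    if gene.bound_path is None:
        raise LookupError_(f"gene {gene_id!r} is not bound to a path")
    region = f"{gene.bound_path}:{gene.start}-{gene.end}"
    sub = extract_region(graph, [], region)

    other_paths = [
        p.name for p in graph.paths_of_genome(other_genome) if p.name in sub.clipped_paths
    ]
    if not other_paths:
        raise AbsenceError(
            f"genome {other_genome!r} does not traverse the region of gene {gene_id!r}"
        )

    ref_nodes = [s.node_id for s in sub.anchor_run.steps]
    # slice the other genome's raw walk between its first and last visit of
    # region nodes: clipped runs would drop the private bubble nodes (SNP
    # alternates, insertions) that the scan exists to find
    other_nodes: list[str] = []
    for pname in other_paths:
        steps = graph.path(pname).steps
        idxs = [i for i, s in enumerate(steps) if s.node_id in sub.node_ids]
        if idxs:
            other_nodes.extend(
                s.node_id for s in steps[min(idxs) : max(idxs) + 1]
            )

    cds_elems = ref_model.structure_elements(use_cds=True)
    cds_intervals = [e.interval0() for e in cds_elems]

    # linear start of each reference-run node on the reference path
    starts = graph.cumulative_starts(gene.bound_path)
    ref_node_pos = [starts[sub.anchor_run.first_step + k] for k in range(len(ref_nodes))]

    def node_len(nid: str) -> int:
        return len(graph.node(nid))

    calls: list[IndelCall] = []
    matcher = difflib.SequenceMatcher(a=ref_nodes, b=other_nodes, autojunk=False)
    for op, i1, i2, j1, j2 in matcher.get_opcodes():
        if op == "equal":
            continue
        del_nodes = tuple(ref_nodes[i1:i2])
        ins_nodes = tuple(other_nodes[j1:j2])
        del_len = sum(node_len(n) for n in del_nodes)
        ins_len = sum(node_len(n) for n in ins_nodes)
        if del_len == ins_len:
            continue  # balanced replacement: substitution bubble
        # left-anchored reference position of the event
        if i1 < len(ref_node_pos):
            pos0 = ref_node_pos[i1]
        else:
            pos0 = ref_node_pos[-1] + node_len(ref_nodes[-1])
        if del_len > ins_len:
            kind, length, nodes = "deletion", del_len - ins_len, del_nodes
            span = (pos0, pos0 + del_len)
            in_cds = any(s < span[1] and span[0] < e for s, e in cds_intervals)
        else:
            kind, length, nodes = "insertion", ins_len - del_len, ins_nodes
            in_cds = any(s < pos0 < e for s, e in cds_intervals)
        if in_cds:
            calls.append(
                IndelCall(kind, length, classify_indel_frame(length), pos0 + 1, nodes)
            )
    return calls


# ---------------------------------------------------------------------------
# Exact sequence locating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocateHit:
    path_name: str
    start: int                 # 1-based inclusive
    end: int
    strand: str                # '+' or '-'
    matches: int
    gaps: int = 0              # always 0: exact locator

    def to_bed_line(self) -> str:
        return f"{self.path_name}\t{self.start - 1}\t{self.end}\t{self.strand}\t{self.matches}"


@dataclass
class LocateResult:
    hits: list[LocateHit]
    truncated: bool

    def __iter__(self):
        return iter(self.hits)

    def __len__(self):
        return len(self.hits)


def locate_sequence(
    graph: VariationGraph,
    query: str,
    max_hits: int = 100,
    k: int = DEFAULT_LOCATOR_K,
) -> LocateResult:
    """Exact occurrences of a query (or its reverse complement) in every path.

    The first k bases seed candidate positions which are then verified in
    full, per path sequence; hits are sorted by path name then start and
    truncated at ``max_hits`` with a truncation flag. Every hit spans exactly
    the query length with zero gaps (the ``gaps`` field exists for schema
    compatibility with gapped-alignment reports).
    """
    query = query.upper()
    if not query or set(query) - set("ACGT"):
        raise DomainError("query must be a non-empty string over ACGT")
    if len(query) < k:
        raise DomainError(f"query shorter than seed length k={k}")

    rc = reverse_complement(query)
    hits: list[LocateHit] = []
    for name in sorted(graph.paths):
        seq = path_sequence(graph, name)
        for target, strand in ((query, "+"), (rc, "-")):
            if strand == "-" and rc == query:
                continue  # palindromic query: avoid double-reporting
            seed = target[:k]
            pos = seq.find(seed)
            while pos != -1:
                if seq[pos : pos + len(target)] == target:
                    hits.append(
                        LocateHit(name, pos + 1, pos + len(target), strand, len(target))
                    )
                pos = seq.find(seed, pos + 1)
    hits.sort(key=lambda h: (h.path_name, h.start, h.strand))
    truncated = len(hits) > max_hits
    return LocateResult(hits=hits[:max_hits], truncated=truncated)


def locate_hits_tsv(result: LocateResult) -> str:
    lines = ["#path\tstart0\tend\tstrand\tmatches"]
    lines += [h.to_bed_line() for h in result.hits]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test and phenotype association
# ---------------------------------------------------------------------------


@dataclass
class RankSumResult:
    u_statistic: float
    n1: int
    n2: int
    p_value: float
    alternative: str
    method: str                # 'exact' or 'normal-approximation'


def rank_sum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test between two samples.

    Midranks handle ties; U is the statistic of the first group,
    U = R1 - n1(n1+1)/2. The exact null distribution is used when
    ``min(n1, n2) <= exact_cutoff`` and the data are tie-free; otherwise the
    normal approximation with tie-corrected variance and 0.5 continuity
    correction applies (ties always force the approximation). A fully
    constant pooled sample is exchangeable by symmetry and returns p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise DomainError(f"unknown alternative {alternative!r}")

    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.all(pooled == pooled[0]):
        return RankSumResult(
            u_statistic=a.size * b.size / 2.0,
            n1=a.size, n2=b.size, p_value=1.0,
            alternative=alternative, method="normal-approximation",
        )

    use_exact = (min(a.size, b.size) <= exact_cutoff) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    return RankSumResult(
        u_statistic=float(res.statistic),
        n1=int(a.size),
        n2=int(b.size),
        p_value=float(min(1.0, res.pvalue)),
        alternative=alternative,
        method="exact" if use_exact else "normal-approximation",
    )


@dataclass
class GroupSummary:
    label: str
    n: int
    median: float


@dataclass
class AssociationResult:
    node_id: str
    test: RankSumResult
    traversing: GroupSummary
    skipping: GroupSummary
    dropped: int               # genomes without phenotype

    def to_tsv(self) -> str:
        lines = [
            "node\tgroup\tn\tmedian\tU\tp_value\tmethod",
            f"{self.node_id}\ttraversing\t{self.traversing.n}\t{self.traversing.median:.4g}"
            f"\t{self.test.u_statistic:.4g}\t{self.test.p_value:.6g}\t{self.test.method}",
            f"{self.node_id}\tskipping\t{self.skipping.n}\t{self.skipping.median:.4g}"
            f"\t{self.test.u_statistic:.4g}\t{self.test.p_value:.6g}\t{self.test.method}",
        ]
        return "\n".join(lines) + "\n"


def associate_phenotype(
    m: PresenceMatrix,
    node_id: str,
    phenotype: dict[str, float],
    alternative: str = "two-sided",
) -> AssociationResult:
    """Test a quantitative phenotype against the traverse/skip split of a node.

    Genomes lacking a phenotype value are dropped (with a logged count);
    an empty group after dropping raises :class:`DegenerateGroupingError`.
    """
    grouping = group_by_node(m, node_id)
    trav = [phenotype[g] for g in grouping.traversing if g in phenotype]
    skip = [phenotype[g] for g in grouping.skipping if g in phenotype]
    dropped = (len(grouping.traversing) - len(trav)) + (len(grouping.skipping) - len(skip))
    if dropped:
        logger.info("association at node %s: dropped %d genome(s) without phenotype",
                    node_id, dropped)
    if not trav or not skip:
        raise DegenerateGroupingError(
            f"node {node_id!r}: a group is empty after phenotype matching "
            f"(traversing n={len(trav)}, skipping n={len(skip)})"
        )
    test = rank_sum_test(trav, skip, alternative=alternative)
    return AssociationResult(
        node_id=node_id,
        test=test,
        traversing=GroupSummary("traversing", len(trav), float(np.median(trav))),
        skipping=GroupSummary("skipping", len(skip), float(np.median(skip))),
        dropped=dropped,
    )
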