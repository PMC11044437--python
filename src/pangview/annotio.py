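"""Per-genome GFF3 annotations and their binding to graph paths.

Each genome contributes one GFF3 file. Features keep GFF3 semantics —
1-based inclusive coordinates on the forward strand of their seqid — and are
organised into gene -> transcript -> exon/CDS hierarchies via ID/Parent
attributes. *Binding* resolves each feature's seqid to a graph path (by the
``genome.seqid`` naming convention or an explicit rename map) without
touching coordinates; the projection module then converts bound features to
graph (node, offset) coordinates.

Parsing is delegated to :mod:`gffutils` (in-memory database); hierarchy
resolution, binding and writing live here.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import gffutils
from intervaltree import IntervalTree

from .errors import BindingError, FeatureRangeError, GFF3ParseError
from .graphio import VariationGraph

logger = logging.getLogger(__name__)

GENE_TYPES = frozenset({"gene", "pseudogene"})
TRANSCRIPT_TYPES = frozenset({"mRNA", "transcript"})
EXON_TYPES = frozenset({"exon"})
CDS_TYPES = frozenset({"CDS"})


@dataclass
class GenomeFeature:
    """One GFF3 record (1-based inclusive coordinates, forward-strand)."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    id: str
    parent_id: Optional[str] = None
    attributes: dict[str, str] = field(default_factory=dict)
    genome: str = ""
    orphan: bool = False       # had an unresolvable or missing Parent
    bound_path: Optional[str] = None  # set by bind_annotations

    def __len__(self) -> int:
        return self.end - self.start + 1

    def interval0(self) -> tuple[int, int]:
        """0-based half-open interval (internal convention)."""
        return self.start - 1, self.end


@dataclass
class GeneModel:
    """A gene with its transcripts and their exon/CDS children."""

    gene: GenomeFeature
    transcripts: dict[str, GenomeFeature] = field(default_factory=dict)
    exons: dict[str, list[GenomeFeature]] = field(default_factory=dict)  # per transcript
    cds: dict[str, list[GenomeFeature]] = field(default_factory=dict)

    def primary_transcript(self) -> Optional[str]:
        """First transcript id lexicographically (deterministic representative)."""
        return min(self.transcripts) if self.transcripts else None

    def structure_elements(self, use_cds: bool = False) -> list[GenomeFeature]:
        """Sorted exon (or CDS) features defining this gene's structure.

        Uses the primary transcript; falls back to exons attached directly
        to the gene (single-exon synthetic containers included).
        """
        tid = self.primary_transcript()
        pools = (self.cds, self.exons) if use_cds else (self.exons, self.cds)
        keys = [tid] if tid is not None else []
        keys.append(self.gene.id)  # direct children fallback
        for pool in pools:
            for key in keys:
                elems = pool.get(key, [])
                if elems:
                    return sorted(elems, key=lambda f: (f.start, f.end))
        return []


@dataclass
class AnnotationSet:
    """All features of one genome plus the resolved gene hierarchy."""

    genome: str
    features: list[GenomeFeature]
    genes: dict[str, GeneModel] = field(default_factory=dict)
    seqid_bindings: dict[str, str] = field(default_factory=dict)  # seqid -> path name

    def __post_init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def seqids(self) -> list[str]:
        return sorted({f.seqid for f in self.features})

    def features_overlapping(self, seqid: str, start0: int, end0: int) -> list[GenomeFeature]:
        """Features intersecting the 0-based half-open interval on ``seqid``."""
        if seqid not in self._trees:
            tree = IntervalTree()
            for f in self.features:
                if f.seqid == seqid:
                    s, e = f.interval0()
                    tree.addi(s, e, f)
            self._trees[seqid] = tree
        if end0 <= start0:
            return []
        hits = [iv.data for iv in self._trees[seqid].overlap(start0, end0)]
        return sorted(hits, key=lambda f: (f.start, f.end, f.id))

    def path_of(self, feature: GenomeFeature) -> Optional[str]:
        return feature.bound_path


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _read_source_text(source) -> str:
    if isinstance(source, str) and "\n" not in source and "\t" not in source:
        with open(source, "rb") as fh:
            data = fh.read()
    elif isinstance(source, str):
        data = source.encode()
    elif isinstance(source, (bytes, bytearray)):
        data = bytes(source)
    else:
        data = source.read()
        if isinstance(data, str):
            data = data.encode()
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return data.decode()


def read_gff3(source, genome: str) -> AnnotationSet:
    """Parse GFF3 into an :class:`AnnotationSet` for one genome.

    Hierarchy is resolved via ID/Parent. Exon/CDS features with a missing or
    unresolvable Parent are flagged as orphans and attached to a synthetic
    single-exon gene container so downstream comparison still sees them.
    """
    text = _read_source_text(source)
    has_records = any(
        line.strip() and not line.startswith("#") for line in text.splitlines()
    )
    if not has_records:
        return AnnotationSet(genome=genome, features=[])
    db = gffutils.create_db(
        text,
        ":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )

    features: list[GenomeFeature] = []
    by_id: dict[str, GenomeFeature] = {}
    for f in db.all_features(order_by=("seqid", "start", "end")):
        if f.end < f.start:
            raise GFF3ParseError(
                f"feature {f.id!r}: end {f.end} < start {f.start}"
            )
        attrs = {k: ",".join(v) for k, v in f.attributes.items()}
        parents = f.attributes.get("Parent", [])
        gf = GenomeFeature(
            seqid=f.seqid,
            type=f.featuretype,
            start=f.start,
            end=f.end,
            strand=f.strand or ".",
            id=f.id,
            parent_id=parents[0] if parents else None,
            attributes=attrs,
            genome=genome,
        )
        features.append(gf)
        by_id[gf.id] = gf

    annots = AnnotationSet(genome=genome, features=features)
    _build_hierarchy(annots, by_id)
    return annots


def _build_hierarchy(annots: AnnotationSet, by_id: dict[str, GenomeFeature]) -> None:
    genes = {f.id: GeneModel(gene=f) for f in annots.features if f.type in GENE_TYPES}

    for f in annots.features:
        if f.type in TRANSCRIPT_TYPES:
            if f.parent_id in genes:
                genes[f.parent_id].transcripts[f.id] = f
            else:
                # transcript without a gene container: promote it
                model = GeneModel(gene=f)
                model.transcripts[f.id] = f
                genes[f.id] = model

    tid_to_gene: dict[str, str] = {}
    for gid, model in genes.items():
        for tid in model.transcripts:
            tid_to_gene[tid] = gid

    synthetic_count = 0
    for f in annots.features:
        if f.type not in EXON_TYPES and f.type not in CDS_TYPES:
            continue
        pool = "exons" if f.type in EXON_TYPES else "cds"
        parent = f.parent_id
        if parent in tid_to_gene:
            getattr(genes[tid_to_gene[parent]], pool).setdefault(parent, []).append(f)
        elif parent in genes:
            getattr(genes[parent], pool).setdefault(parent, []).append(f)
        else:
            # orphan: fabricate a single-exon gene container
            f.orphan = True
            synthetic_count += 1
            if parent is not None:
                logger.warning(
                    "genome %s: feature %s has unresolvable Parent %r; kept as orphan",
                    annots.genome, f.id, parent,
                )
            container_id = f"synthetic-gene-{f.id}"
            container = GenomeFeature(
                seqid=f.seqid, type="gene", start=f.start, end=f.end,
                strand=f.strand, id=container_id, attributes={"ID": container_id},
                genome=annots.genome, orphan=True,
            )
            model = GeneModel(gene=container)
            getattr(model, pool).setdefault(container_id, []).append(f)
            genes[container_id] = model
    if synthetic_count:
        logger.info(
            "genome %s: %d orphan feature(s) wrapped in synthetic gene containers",
            annots.genome, synthetic_count,
        )
    annots.genes = genes


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_gff3(annots: AnnotationSet) -> bytes:
    """Serialize an AnnotationSet back to GFF3 bytes, deterministically.

    Features are ordered (seqid, start, end, type rank, id) with genes before
    their children at equal coordinates; ID/Parent always lead the attributes.
    """
    rank = {"gene": 0, "pseudogene": 0, "mRNA": 1, "transcript": 1, "exon": 2, "CDS": 3}
    out = ["##gff-version 3"]
    real = [f for f in annots.features]
    for f in sorted(real, key=lambda f: (f.seqid, f.start, rank.get(f.type, 9), f.end, f.id)):
        attrs = dict(f.attributes)
        attrs.setdefault("ID", f.id)
        if f.parent_id is not None:
            attrs["Parent"] = f.parent_id
        keys = ["ID"] + (["Parent"] if "Parent" in attrs else [])
        keys += sorted(k for k in attrs if k not in ("ID", "Parent"))
        attr_str = ";".join(f"{k}={attrs[k]}" for k in keys)
        out.append(
            f"{f.seqid}\tpangview\t{f.type}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attr_str}"
        )
    return ("\n".join(out) + "\n").encode()


# ---------------------------------------------------------------------------
# Binding and lookup
# ---------------------------------------------------------------------------


def bind_annotations(
    graph: VariationGraph,
    annots: AnnotationSet,
    seqid_map: Optional[dict[str, str]] = None,
) -> AnnotationSet:
    """Resolve every feature's seqid to a graph path; idempotent.

    The default rule maps seqid ``chr`` of genome ``G`` to path ``G.chr``;
    ``seqid_map`` overrides per seqid. Coordinates are never modified.
    Features ending beyond their path's length are rejected.
    """
    seqid_map = seqid_map or {}
    bindings: dict[str, str] = {}
    unresolved: list[str] = []
    for seqid in annots.seqids():
        candidate = seqid_map.get(seqid, f"{annots.genome}.{seqid}")
        if candidate in graph.paths:
            bindings[seqid] = candidate
        elif seqid in graph.paths:  # seqid already a full path name
            bindings[seqid] = seqid
        else:
            unresolved.append(seqid)
    if unresolved:
        raise BindingError(
            f"genome {annots.genome}: cannot resolve seqids {unresolved} to graph paths"
        )

    lengths = {p: graph.path_length(p) for p in set(bindings.values())}
    for f in annots.features:
        path = bindings[f.seqid]
        if f.end > lengths[path]:
            raise FeatureRangeError(
                f"feature {f.id!r} ends at {f.end} beyond path {path!r} "
                f"length {lengths[path]}"
            )
        f.bound_path = path
    annots.seqid_bindings = bindings
    return annots


def find_gene(
    annot_sets: Iterable[AnnotationSet], gene_id: str
) -> list[tuple[str, GenomeFeature]]:
    """Case-sensitive gene lookup by ID, then by Name attribute.

    Returns ``(genome, gene feature)`` pairs ordered by genome name; an
    unknown id yields an empty list.
    """
    hits: list[tuple[str, GenomeFeature]] = []
    for annots in annot_sets:
        if gene_id in annots.genes:
            hits.append((annots.genome, annots.genes[gene_id].gene))
            continue
        for model in annots.genes.values():
            if model.gene.attributes.get("Name") == gene_id:
                hits.append((annots.genome, model.gene))
                break
    return sorted(hits, key=lambda t: t[0])
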