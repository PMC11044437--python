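"""Synthetic pangenome generation with ground truth.

The generator builds a multi-genome pangenome from a base sequence plus a
set of non-overlapping variants (SNPs, insertions, deletions), each carried
by a subset of genomes. Because variants never overlap, the graph can be
constructed directly by splitting the base sequence at variant breakpoints
— reference and alternate nodes with shared flanks — with one path per
genome and no alignment step. Gene models planted on the base sequence are
coordinate-lifted through each genome's variants into per-genome GFF3
annotations, truncating or dropping exons erased by deletions, and the
resulting per-genome gene fate (present with identical structure,
structurally variant, or absent) is recorded as ground truth.

Scenario builders reproduce the canonical study situations: a fixed
five-genome demo with a substitution, an exon-deleting indel, a shortened
exon and a whole-gene deletion (:func:`demo_pangenome`); a long deletion node
splitting a population in half with an associated phenotype
(:func:`sd1_scenario`); and a long insertion private to a minority of
genomes (:func:`xa7_scenario`).

All randomness flows through one :class:`numpy.random.Generator` seeded by
the mandatory ``seed`` argument; outputs are byte-identical across runs
with the same seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .annotio import AnnotationSet, GenomeFeature, read_gff3, write_gff3, bind_annotations
from .errors import ConfigurationError, DomainError, PlacementError
from .graphio import (
    FORWARD,
    REVERSE,
    GenomePath,
    Node,
    OrientedStep,
    VariationGraph,
    write_gfa,
)

PRESENT_IDENTICAL = "present_identical"
STRUCTURALLY_VARIANT = "structurally_variant"
ABSENT = "absent"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class VariantSpec:
    """One variant on the base sequence, carried by a subset of genomes.

    ``position`` is 0-based on the base sequence. For SNPs ``length`` is 1
    and ``alt`` the substituted base(s); insertions insert ``alt`` *before*
    the base at ``position``; deletions remove ``length`` bases starting at
    ``position``.
    """

    kind: str                      # 'snp' | 'insertion' | 'deletion'
    position: int
    length: int
    alt: str = ""
    carriers: frozenset[str] = frozenset()

    def span(self) -> tuple[int, int]:
        """Occupied interval on the base sequence (insertions occupy a point)."""
        if self.kind == "insertion":
            return (self.position, self.position)
        return (self.position, self.position + self.length)


@dataclass(frozen=True)
class ExonSpec:
    start: int                     # 0-based half-open on the base sequence
    end: int


@dataclass(frozen=True)
class GeneSpec:
    id: str
    exons: tuple[ExonSpec, ...]
    strand: str = "+"

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    def exonic_length(self) -> int:
        return sum(e.end - e.start for e in self.exons)


@dataclass
class PhenotypeModel:
    """Causal target for phenotype simulation: carriers shift by the effect."""

    carriers: frozenset[str]
    target_node: Optional[str] = None
    baseline: float = 100.0


@dataclass
class SyntheticTruth:
    base_sequence: str
    variants: list[VariantSpec]
    genes: list[GeneSpec]
    gene_fates: dict[str, dict[str, str]]       # genome -> gene id -> fate
    phenotype_model: Optional[PhenotypeModel] = None
    deletion_nodes: dict[tuple[int, int], str] = field(default_factory=dict)
    insertion_nodes: dict[int, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "base_length": len(self.base_sequence),
                "variants": [
                    {
                        "kind": v.kind, "position": v.position, "length": v.length,
                        "alt": v.alt, "carriers": sorted(v.carriers),
                    }
                    for v in self.variants
                ],
                "genes": [
                    {"id": g.id, "exons": [[e.start, e.end] for e in g.exons]}
                    for g in self.genes
                ],
                "gene_fates": self.gene_fates,
                "phenotype_model": (
                    None
                    if self.phenotype_model is None
                    else {
                        "carriers": sorted(self.phenotype_model.carriers),
                        "target_node": self.phenotype_model.target_node,
                        "baseline": self.phenotype_model.baseline,
                    }
                ),
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Deterministic graph construction from base + variants
# ---------------------------------------------------------------------------


def _check_nonoverlapping(variants: Sequence[VariantSpec], base_len: int) -> None:
    spans = sorted((v.span(), v.kind) for v in variants)
    prev_end = -1
    for (s, e), kind in spans:
        if not (0 <= s <= e <= base_len):
            raise DomainError(f"variant span ({s}, {e}) outside base sequence")
        if s < prev_end:
            raise DomainError("variants overlap on the base sequence")
        prev_end = max(prev_end, e)
    # two insertions at the same point would be order-ambiguous
    points = [v.position for v in variants if v.kind == "insertion"]
    if len(points) != len(set(points)):
        raise DomainError("two insertions share the same position")


def build_pangenome(
    base_sequence: str,
    genome_names: Sequence[str],
    variants: Sequence[VariantSpec],
    genes: Sequence[GeneSpec] = (),
    chrom: str = "chr1",
    presence_threshold: float = 0.8,
) -> tuple[VariationGraph, list[AnnotationSet], SyntheticTruth]:
    """Build graph, bound per-genome annotations and truth from explicit specs.

    The base sequence is cut at every variant breakpoint; each deletion span
    therefore becomes exactly one node (skipped by its carriers), each SNP a
    two-node bubble, each insertion a private node between shared flanks.
    """
    base = base_sequence.upper()
    _check_nonoverlapping(variants, len(base))
    for v in variants:
        if v.kind not in ("snp", "insertion", "deletion"):
            raise DomainError(f"unknown variant kind {v.kind!r}")
        if v.kind != "snp" and v.length < 1:
            raise DomainError(f"{v.kind} length must be >= 1")
        if v.kind == "snp" and (v.length != len(v.alt) or v.length < 1):
            raise DomainError("snp length must equal alt length and be >= 1")

    cuts = {0, len(base)}
    for v in variants:
        s, e = v.span()
        cuts.add(s)
        cuts.add(e)
    bounds = sorted(cuts)

    # node events in base order: insertions before the ref segment at the
    # same position, SNP alternates right after their ref node
    events: list[tuple[int, int, str, object]] = []  # (pos, rank, seq, meta)
    ref_segments: list[tuple[int, int]] = [
        (s, e) for s, e in zip(bounds, bounds[1:]) if e > s
    ]
    snp_at: dict[int, VariantSpec] = {}
    ins_at: dict[int, VariantSpec] = {}
    del_spans: list[tuple[int, int, VariantSpec]] = []
    for v in variants:
        if v.kind == "snp":
            snp_at[v.position] = v
        elif v.kind == "insertion":
            ins_at[v.position] = v
        else:
            del_spans.append((v.position, v.position + v.length, v))

    for pos, v in ins_at.items():
        events.append((pos, 0, v.alt.upper(), ("ins", v)))
    for s, e in ref_segments:
        events.append((s, 1, base[s:e], ("ref", (s, e))))
    for pos, v in snp_at.items():
        events.append((pos, 2, v.alt.upper(), ("alt", v)))
    events.sort(key=lambda t: (t[0], t[1]))

    graph = VariationGraph()
    width = max(4, len(str(len(events))))
    ref_node_of: dict[tuple[int, int], str] = {}
    alt_node_of: dict[int, str] = {}
    ins_node_of: dict[int, str] = {}
    for i, (pos, rank, seq, meta) in enumerate(events, start=1):
        nid = f"n{i:0{width}d}"
        graph.nodes[nid] = Node(nid, seq)
        tag, payload = meta
        if tag == "ref":
            ref_node_of[payload] = nid
        elif tag == "alt":
            alt_node_of[payload.position] = nid
        else:
            ins_node_of[payload.position] = nid

    def deleted_by(genome: str) -> list[tuple[int, int]]:
        return [(s, e) for s, e, v in del_spans if genome in v.carriers]

    for genome in genome_names:
        dels = deleted_by(genome)
        steps: list[OrientedStep] = []

        def maybe_insert(pos: int) -> None:
            v = ins_at.get(pos)
            if v is not None and genome in v.carriers:
                steps.append(OrientedStep(ins_node_of[pos], FORWARD))

        for s, e in ref_segments:
            maybe_insert(s)
            if any(ds <= s and e <= de for ds, de in dels):
                continue
            snp = snp_at.get(s)
            if snp is not None and genome in snp.carriers and (e - s) == snp.length:
                steps.append(OrientedStep(alt_node_of[s], FORWARD))
            else:
                steps.append(OrientedStep(ref_node_of[(s, e)], FORWARD))
        maybe_insert(len(base))

        name = f"{genome}.{chrom}"
        graph.paths[name] = GenomePath(name, tuple(steps))

    for path in graph.paths.values():
        for a, b in zip(path.steps, path.steps[1:]):
            graph.edges.add((a.node_id, a.orientation, b.node_id, b.orientation))

    annot_sets, fates = _lift_annotations(
        base, list(genome_names), variants, genes, chrom, graph
    )
    deletion_nodes = {
        (s, e): ref_node_of.get((s, e)) for s, e, _v in del_spans
    }
    truth = SyntheticTruth(
        base_sequence=base,
        variants=list(variants),
        genes=list(genes),
        gene_fates=fates,
    )
    truth.deletion_nodes = deletion_nodes  # span -> node id (single-node deletions)
    truth.insertion_nodes = dict(ins_node_of)
    return graph, annot_sets, truth


# ---------------------------------------------------------------------------
# Annotation lifting and gene fates
# ---------------------------------------------------------------------------


def _lift_annotations(
    base: str,
    genomes: list[str],
    variants: Sequence[VariantSpec],
    genes: Sequence[GeneSpec],
    chrom: str,
    graph: VariationGraph,
) -> tuple[list[AnnotationSet], dict[str, dict[str, str]]]:
    annot_sets: list[AnnotationSet] = []
    fates: dict[str, dict[str, str]] = {}

    for genome in genomes:
        dels = sorted(
            (v.position, v.position + v.length)
            for v in variants
            if v.kind == "deletion" and genome in v.carriers
        )
        inss = sorted(
            (v.position, len(v.alt))
            for v in variants
            if v.kind == "insertion" and genome in v.carriers
        )

        def deleted(p: int) -> bool:
            return any(s <= p < e for s, e in dels)

        def lift(p: int) -> int:
            shift = sum(l for q, l in inss if q <= p)
            removed = sum(min(e, p) - s for s, e in dels if s < p)
            return p + shift - removed

        features: list[GenomeFeature] = []
        fates[genome] = {}
        for gene in genes:
            lifted_exons: list[tuple[int, int]] = []
            variant_structure = False
            for exon in gene.exons:
                first = next((p for p in range(exon.start, exon.end) if not deleted(p)), None)
                if first is None:
                    variant_structure = True  # exon dropped
                    continue
                last = next(
                    p for p in range(exon.end - 1, exon.start - 1, -1) if not deleted(p)
                )
                if first != exon.start or last != exon.end - 1:
                    variant_structure = True  # boundary base removed
                lifted_exons.append((lift(first), lift(last) + 1))

            if not lifted_exons:
                fates[genome][gene.id] = ABSENT
                continue
            fates[genome][gene.id] = (
                STRUCTURALLY_VARIANT if variant_structure else PRESENT_IDENTICAL
            )

            g_start = min(s for s, _ in lifted_exons)
            g_end = max(e for _, e in lifted_exons)
            gene_feat = GenomeFeature(
                seqid=chrom, type="gene", start=g_start + 1, end=g_end,
                strand=gene.strand, id=gene.id, attributes={"ID": gene.id},
                genome=genome,
            )
            tid = f"{gene.id}.t1"
            mrna = GenomeFeature(
                seqid=chrom, type="mRNA", start=g_start + 1, end=g_end,
                strand=gene.strand, id=tid, parent_id=gene.id,
                attributes={"ID": tid, "Parent": gene.id}, genome=genome,
            )
            features.extend([gene_feat, mrna])
            for k, (s, e) in enumerate(sorted(lifted_exons), start=1):
                eid = f"{tid}.exon{k}"
                features.append(
                    GenomeFeature(
                        seqid=chrom, type="exon", start=s + 1, end=e,
                        strand=gene.strand, id=eid, parent_id=tid,
                        attributes={"ID": eid, "Parent": tid}, genome=genome,
                    )
                )

        # round-trip through the GFF3 writer/reader so the hierarchy index is
        # built exactly as it would be from files on disk
        annots = read_gff3(
            write_gff3(AnnotationSet(genome=genome, features=features)), genome
        )
        bind_annotations(graph, annots)
        annot_sets.append(annots)

    return annot_sets, fates


# ---------------------------------------------------------------------------
# Random simulation
# ---------------------------------------------------------------------------

DEFAULT_RATES = {"snp": 2e-3, "insertion": 2e-4, "deletion": 2e-4}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _plant_genes(rng: np.random.Generator, base_length: int, n_genes: int) -> list[GeneSpec]:
    genes: list[GeneSpec] = []
    cursor = int(rng.integers(100, 400))
    for gi in range(n_genes):
        n_exons = int(rng.integers(1, 6))
        exons: list[ExonSpec] = []
        pos = cursor
        for _ in range(n_exons):
            elen = int(rng.integers(60, 301))
            if pos + elen > base_length - 100:
                break
            exons.append(ExonSpec(pos, pos + elen))
            pos += elen + int(rng.integers(60, 401))
        if exons:
            genes.append(GeneSpec(id=f"gene{gi + 1:03d}", exons=tuple(exons)))
        cursor = pos + int(rng.integers(200, 801))
        if cursor > base_length - 300:
            break
    return genes


def simulate_pangenome(
    base_length: int = 10_000,
    n_genomes: int = 10,
    rates: Optional[dict[str, float]] = None,
    seed: int = 0,
    n_genes: Optional[int] = None,
    presence_threshold: float = 0.8,
    max_indel: int = 30,
) -> tuple[VariationGraph, list[AnnotationSet], SyntheticTruth]:
    """Sample a random pangenome with planted genes and known gene fates.

    Per-kind ``rates`` are expected events per base (defaults: SNPs 2e-3,
    insertions and deletions 2e-4 each — a polymorphism density that gives a
    bubble every few hundred bases). Variants are placed without overlap;
    insertions are kept off exact exon boundaries so lifted annotations are
    unambiguous. Raises :class:`PlacementError` when the requested density
    cannot be placed within a bounded number of retries.
    """
    if base_length < 100:
        raise DomainError("base_length must be >= 100")
    if n_genomes < 2:
        raise DomainError("n_genomes must be >= 2")
    rates = dict(DEFAULT_RATES if rates is None else rates)
    if any(r < 0 for r in rates.values()):
        raise DomainError("rates must be non-negative")

    rng = np.random.default_rng(seed)
    base = _random_sequence(rng, base_length)
    genomes = [f"G{i + 1:03d}" for i in range(n_genomes)]
    if n_genes is None:
        n_genes = max(1, base_length // 2500)
    genes = _plant_genes(rng, base_length, n_genes)
    exon_bounds = {b for g in genes for e in g.exons for b in (e.start, e.end)}

    occupied: list[tuple[int, int]] = []

    def free(s: int, e: int) -> bool:
        return all(e <= os_ or oe <= s for os_, oe in occupied)

    def sample_carriers() -> frozenset[str]:
        for _ in range(100):
            p = rng.uniform(0.1, 0.9)
            mask = rng.random(n_genomes) < p
            if 0 < mask.sum() < n_genomes:
                return frozenset(g for g, m in zip(genomes, mask) if m)
        raise PlacementError("could not sample a proper carrier subset")

    variants: list[VariantSpec] = []
    for kind in ("snp", "insertion", "deletion"):
        count = int(rng.poisson(rates.get(kind, 0.0) * base_length))
        for _ in range(count):
            placed = False
            for _try in range(200):
                if kind == "snp":
                    p = int(rng.integers(0, base_length))
                    if not free(p, p + 1):
                        continue
                    ref = base[p]
                    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                    variants.append(
                        VariantSpec("snp", p, 1, alt, sample_carriers())
                    )
                    occupied.append((p, p + 1))
                elif kind == "insertion":
                    p = int(rng.integers(1, base_length))
                    length = int(rng.integers(1, max_indel + 1))
                    if p in exon_bounds or not free(p, p):
                        continue
                    if any(os_ < p < oe for os_, oe in occupied):
                        continue
                    variants.append(
                        VariantSpec(
                            "insertion", p, length,
                            _random_sequence(rng, length), sample_carriers(),
                        )
                    )
                    occupied.append((p, p))
                else:
                    length = int(rng.integers(1, max_indel + 1))
                    p = int(rng.integers(0, base_length - length))
                    if not free(p, p + length):
                        continue
                    variants.append(
                        VariantSpec("deletion", p, length, "", sample_carriers())
                    )
                    occupied.append((p, p + length))
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place all {kind} variants without overlap "
                    f"(rate too high for base length {base_length})"
                )

    variants.sort(key=lambda v: (v.position, v.kind))
    return build_pangenome(
        base, genomes, variants, genes, presence_threshold=presence_threshold
    )


# ---------------------------------------------------------------------------
# Fixed scenarios
# ---------------------------------------------------------------------------


def demo_pangenome() -> tuple[VariationGraph, list[AnnotationSet], SyntheticTruth]:
    """Fixed five-genome demo: one two-exon gene under four variant scenarios.

    * s1 — reference;
    * s2 — a GA->CT substitution inside exon 1 (structure identical);
    * s3 — a deletion removing exon 1 only (element-level PAV);
    * s4 — a long internal node missing, shortening exon 2 (its bar renders
      *wider* than the longer exon 2 of the others in compressed mode);
    * s5 — a large deletion removing both exons (no bars at all).
    """
    nodes = {
        "n01": "TTACG",
        "n02": "CCA",
        "n03": "GA",
        "n04": "CT",
        "n05": "TGGC",
        "n06": "GTAAGTTTCAG",
        "n07": "AGT",
        "n08": "ATGCCTAGGATCAGTCCATGGCATTACGGATCCAGTGGTA",  # the 'ATG...TA' node
        "n09": "GTCA",
        "n10": "CGTAA",
    }
    walks = {
        "s1": ["n01", "n02", "n03", "n05", "n06", "n07", "n08", "n09", "n10"],
        "s2": ["n01", "n02", "n04", "n05", "n06", "n07", "n08", "n09", "n10"],
        "s3": ["n01", "n06", "n07", "n08", "n09", "n10"],
        "s4": ["n01", "n02", "n03", "n05", "n06", "n07", "n09", "n10"],
        "s5": ["n01", "n10"],
    }
    graph = VariationGraph()
    for nid, seq in nodes.items():
        graph.nodes[nid] = Node(nid, seq)
    for genome, walk in walks.items():
        name = f"{genome}.chr1"
        steps = tuple(OrientedStep(n, FORWARD) for n in walk)
        graph.paths[name] = GenomePath(name, steps)
        for a, b in zip(steps, steps[1:]):
            graph.edges.add((a.node_id, a.orientation, b.node_id, b.orientation))

    # (genome, exon intervals 1-based inclusive)
    exon_tables = {
        "s1": [(6, 14), (26, 58)],
        "s2": [(6, 14), (26, 58)],
        "s3": [(17, 49)],
        "s4": [(6, 14), (26, 32)],
        "s5": [],
    }
    annot_sets: list[AnnotationSet] = []
    for genome, exons in exon_tables.items():
        features: list[GenomeFeature] = []
        if exons:
            g_start = min(s for s, _ in exons)
            g_end = max(e for _, e in exons)
            features.append(GenomeFeature("chr1", "gene", g_start, g_end, "+", "g1",
                                          attributes={"ID": "g1"}, genome=genome))
            features.append(GenomeFeature("chr1", "mRNA", g_start, g_end, "+", "g1.t1",
                                          parent_id="g1",
                                          attributes={"ID": "g1.t1", "Parent": "g1"},
                                          genome=genome))
            for k, (s, e) in enumerate(exons, start=1):
                eid = f"g1.t1.exon{k}"
                features.append(GenomeFeature("chr1", "exon", s, e, "+", eid,
                                              parent_id="g1.t1",
                                              attributes={"ID": eid, "Parent": "g1.t1"},
                                              genome=genome))
        annots = read_gff3(write_gff3(AnnotationSet(genome=genome, features=features)),
                           genome)
        bind_annotations(graph, annots)
        annot_sets.append(annots)

    fates = {
        "s2": {"g1": PRESENT_IDENTICAL},
        "s3": {"g1": STRUCTURALLY_VARIANT},
        "s4": {"g1": STRUCTURALLY_VARIANT},
        "s5": {"g1": ABSENT},
    }
    truth = SyntheticTruth(
        base_sequence="".join(nodes[n] for n in walks["s1"]),
        variants=[
            VariantSpec("snp", 6, 2, "CT", frozenset({"s2"})),
            VariantSpec("deletion", 5, 9, "", frozenset({"s3"})),
            VariantSpec("deletion", 25, 40, "", frozenset({"s4"})),
            VariantSpec("deletion", 5, 67, "", frozenset({"s5"})),
        ],
        genes=[GeneSpec("g1", (ExonSpec(5, 14), ExonSpec(25, 58)))],
        gene_fates=fates,
    )
    return graph, annot_sets, truth


def sd1_scenario(
    n_genomes: int = 40,
    deletion_length: int = 382,
    base_length: int = 6_000,
    n_snps: int = 12,
    seed: int = 0,
) -> tuple[VariationGraph, list[AnnotationSet], SyntheticTruth]:
    """A long deletion node splitting the population into two gene groups.

    A two-exon gene sits entirely inside a ``deletion_length``-base deletion
    (exons 1-2 plus the intron) carried by the designated first half of the
    genomes, so the graph contains one skipped node of exactly that length
    and the traverse/skip split at that node reproduces the carrier split.
    The truth carries a phenotype model whose causal carriers are the
    deletion carriers (the gene-absent group).
    """
    rng = np.random.default_rng(seed)
    base = _random_sequence(rng, base_length)
    genomes = [f"G{i + 1:03d}" for i in range(n_genomes)]
    carriers = frozenset(genomes[: n_genomes // 2])

    del_start = 1000
    del_end = del_start + deletion_length
    gene = GeneSpec(
        "sd1like",
        (ExonSpec(del_start + 40, del_start + 160), ExonSpec(del_start + 260, del_start + 360)),
    )
    assert gene.end <= del_end

    variants = [VariantSpec("deletion", del_start, deletion_length, "", carriers)]
    placed: list[int] = []
    while len(placed) < n_snps:
        p = int(rng.integers(0, base_length))
        if del_start - 1 <= p <= del_end or p in placed:
            continue
        ref = base[p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        variants.append(VariantSpec("snp", p, 1, alt, frozenset(
            g for g, m in zip(genomes, rng.random(n_genomes) < 0.5) if m
        ) or frozenset(genomes[:1])))
        placed.append(p)
    variants.sort(key=lambda v: v.position)

    graph, annots, truth = build_pangenome(base, genomes, variants, [gene])
    deletion_node = truth.deletion_nodes[(del_start, del_end)]
    truth.phenotype_model = PhenotypeModel(carriers=carriers, target_node=deletion_node)
    return graph, annots, truth


def xa7_scenario(
    n_genomes: int = 113,
    n_carriers: int = 16,
    insert_length: int = 1_345,
    base_length: int = 4_000,
    seed: int = 0,
) -> tuple[VariationGraph, list[AnnotationSet], SyntheticTruth]:
    """A long insertion private to a minority of genomes.

    The inserted sequence exists only on the carrier paths; locating it
    yields one hit per carrier, and a region anchored inside the insertion
    on a carrier genome contains exactly the carrier paths.
    """
    rng = np.random.default_rng(seed)
    base = _random_sequence(rng, base_length)
    genomes = [f"G{i + 1:03d}" for i in range(n_genomes)]
    carriers = frozenset(
        genomes[i] for i in sorted(rng.choice(n_genomes, size=n_carriers, replace=False))
    )
    insert_seq = _random_sequence(rng, insert_length)
    variants = [VariantSpec("insertion", base_length // 2, insert_length, insert_seq, carriers)]
    graph, annots, truth = build_pangenome(base, genomes, variants, [])
    truth.phenotype_model = PhenotypeModel(
        carriers=carriers, target_node=truth.insertion_nodes[base_length // 2]
    )
    return graph, annots, truth


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------


def simulate_phenotype(
    truth: SyntheticTruth,
    genomes: Sequence[str],
    effect: float,
    noise_sd: float,
    seed: int,
) -> dict[str, float]:
    """Gaussian phenotype with the causal carriers' mean shifted by ``effect``.

    The carrier set comes from the truth's phenotype model; a truth without
    one raises :class:`ConfigurationError`. Deterministic given the seed.
    """
    if truth.phenotype_model is None:
        raise ConfigurationError("truth carries no phenotype model target")
    model = truth.phenotype_model
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(genomes))
    return {
        g: model.baseline + (effect if g in model.carriers else 0.0) + float(n)
        for g, n in zip(genomes, noise)
    }


# ---------------------------------------------------------------------------
# Random graphs for property testing
# ---------------------------------------------------------------------------


def random_graph(
    seed: int,
    max_nodes: int = 8,
    max_paths: int = 4,
    max_steps: int = 12,
    max_node_len: int = 6,
) -> VariationGraph:
    """A small random graph with reverse steps and loops.

    Paths are unconstrained random oriented walks (repeats allowed), and the
    edge set is exactly the walk-implied adjacencies, so GFA round trips are
    the identity. Intended for property tests of coordinate conversion.
    """
    rng = np.random.default_rng(seed)
    n_nodes = int(rng.integers(1, max_nodes + 1))
    graph = VariationGraph()
    for i in range(1, n_nodes + 1):
        nid = f"n{i}"
        graph.nodes[nid] = Node(nid, _random_sequence(rng, int(rng.integers(1, max_node_len + 1))))
    node_ids = list(graph.nodes)
    n_paths = int(rng.integers(1, max_paths + 1))
    for p in range(1, n_paths + 1):
        length = int(rng.integers(1, max_steps + 1))
        steps = tuple(
            OrientedStep(
                node_ids[int(rng.integers(0, n_nodes))],
                FORWARD if rng.random() < 0.7 else REVERSE,
            )
            for _ in range(length)
        )
        name = f"G{p}.chr1"
        graph.paths[name] = GenomePath(name, steps)
        for a, b in zip(steps, steps[1:]):
            e = (a.node_id, a.orientation, b.node_id, b.orientation)
            flip = (b.node_id, {"+": "-", "-": "+"}[b.orientation],
                    a.node_id, {"+": "-", "-": "+"}[a.orientation])
            if flip not in graph.edges:
                graph.edges.add(e)
    return graph


# ---------------------------------------------------------------------------
# Fixture output
# ---------------------------------------------------------------------------


def write_fixture(
    outdir: str,
    graph: VariationGraph,
    annot_sets: Sequence[AnnotationSet],
    truth: SyntheticTruth,
    phenotype: Optional[dict[str, float]] = None,
) -> list[str]:
    """Write GFA + per-genome GFF3 + truth JSON (+ phenotype TSV) to a directory."""
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []

    def emit(name: str, data: bytes) -> None:
        path = os.path.join(outdir, name)
        with open(path, "wb") as fh:
            fh.write(data)
        written.append(name)

    emit("graph.gfa", write_gfa(graph))
    for annots in sorted(annot_sets, key=lambda a: a.genome):
        emit(f"{annots.genome}.gff3", write_gff3(annots))
    emit("truth.json", truth.to_json().encode())
    if phenotype is not None:
        lines = ["genome\tvalue"]
        lines += [f"{g}\t{phenotype[g]:.6f}" for g in sorted(phenotype)]
        emit("phenotype.tsv", ("\n".join(lines) + "\n").encode())
    return written
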