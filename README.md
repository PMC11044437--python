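# pangview

Nucleotide-level pangenome browsing on variation graphs: project per-genome
gene annotations onto a graph pangenome, extract and render region views
(tube-map SVG with gene-feature bars over genome tracks), and call
presence/absence variations (PAVs), gene structural variations (gSVs) and
presence-group phenotype associations directly from the graph.

## Who this is for

A pangenome built from many individual genomes of one species (e.g. a rice
population) can be represented as a *variation graph*: nodes carry DNA
sequence, and each genome is a named *path* — an ordered, oriented walk
whose concatenated node sequences spell that genome. Shared sequence lives
on shared nodes; substitutions and indels form bubbles. Because every
genome's linear coordinates map onto the same node set, the graph is a
common coordinate system in which gene annotations from *different*
genomes can be compared base by base: identical splice sites land on
identical (node, offset) positions, a deleted gene shows up as a skipped
node, and a gene private to a few genomes lives on nodes only their paths
traverse. `pangview` is the computational core of such a browser, for
anyone who has a GFA pangenome plus per-genome GFF3 annotations and wants
those comparisons as data, pictures, and statistics rather than by eye.

## The model

* **Coordinates.** A linear position `p` on path `P` maps to a unique
  `(node, offset)` pair; a node offset maps back to zero, one, or several
  positions per path (zero when the path skips the node, several when it
  loops). A feature interval projects to an ordered list of node segments;
  concatenating the segment slices (reverse-complemented on reverse steps)
  reproduces the feature's sequence exactly.
* **Regions.** A query `PATH:start-end` (1-based inclusive, e.g.
  `NATELBORO.chr06:28873554-28874897`) anchors a subgraph: the node set is
  what the anchor traverses in the interval (boundary nodes whole); every
  other path is clipped to its maximal runs inside that node set.
* **PAV/gSV calls.** A genome × node matrix of traversal counts groups
  accessions by any node (traverse vs skip). A reference gene's exons,
  projected to graph coordinates, classify every other genome:
  `identical_structure` (all exon boundaries at identical graph
  coordinates), `boundary_shift` (same exon count, a boundary moved),
  `element_pav` (exon count differs), `absent_annotation` / `absent_sequence`
  (no overlapping gene; the exonic coverage fraction against a threshold,
  default 0.8, separates the two). Coding indel bubbles between two genomes
  are classified frame-preserving iff their length is a multiple of three.
* **Association.** A quantitative phenotype is tested between the
  traverse/skip groups of a node with the Wilcoxon rank-sum test (exact
  null distribution for small tie-free samples, tie-corrected normal
  approximation with continuity correction otherwise).

## Worked example

`pangview` ships a fixed five-genome demo: one two-exon gene under a
substitution (s2), an exon-1-deleting indel (s3), a missing internal node
that shortens exon 2 (s4), and a whole-gene deletion (s5).

```sh
pangview simulate --out demo/fixture --seed 1 --demo five-genome
pangview view --graph demo/fixture/graph.gfa --annotations demo/fixture \
              --region "s1.chr1:1-77" --out demo/view --compress
pangview pav  --graph demo/fixture/graph.gfa --annotations demo/fixture \
              --region "s1.chr1:1-77" --out demo/pav
```

`demo/pav/presence_matrix.tsv` — each row is a genome, each column a node
of the region; `0` means the path skips that node:

```
genome	n01	n02	n03	n05	n06	n07	n08	n09	n10
s1	1	1	1	1	1	1	1	1	1
s2	1	1	0	1	1	1	1	1	1
s3	1	0	0	0	1	1	1	1	1
s4	1	1	1	1	1	1	0	1	1
s5	1	0	0	0	0	0	0	0	1
```

s2 skips only the reference allele of the substitution site (n03), s3
skips the exon-1 block, s4 skips the 40 bp internal node n08, and s5 keeps
only the flanks. `demo/pav/gene_comparison.tsv` turns this into gene calls
against the s1 annotation:

```
gene	reference	genome	status	coverage	matched_gene
g1	s1	s2	identical_structure	0.9524	g1
g1	s1	s3	element_pav	0.7857	g1
g1	s1	s4	boundary_shift	0.2857	g1
g1	s1	s5	absent_sequence	0.0000	.
```

The substitution leaves every splice site identical (s2); losing exon 1
changes the exon count (s3); the missing node moves an exon-2 boundary
(s4); and s5 has no gene sequence left — its track in
`demo/view/region.svg` carries zero gray bars. In the compressed view
(`demo/view/region.compressed.svg`) the 7 bp exon 2 of s4 renders *wider*
than the 33 bp exon 2 of the other genomes, because short nodes are floored
at a minimum pixel width — bar pixel width is decoupled from base-pair
length in compressed mode, never in full mode.

The library surface mirrors the CLI: `read_gfa`, `read_gff3`,
`bind_annotations`, `extract_region`, `compare_gene`, `locate_sequence`,
`associate_phenotype`, `layout_region`, `render_svg`, and the generators
`simulate_pangenome`, `demo_pangenome`, `sd1_scenario`, `xa7_scenario`.

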