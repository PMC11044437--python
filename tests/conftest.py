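"""Shared fixtures: tiny hand-built graphs and the fixed demo pangenome."""

import pytest

from pangview.graphio import (
    FORWARD,
    REVERSE,
    GenomePath,
    Node,
    OrientedStep,
    VariationGraph,
)
from pangview.synthpan import demo_pangenome


def make_graph(nodes: dict[str, str], walks: dict[str, list[str]]) -> VariationGraph:
    """Build a graph from node sequences and walks like ``["n1+", "n3-"]``."""
    g = VariationGraph()
    for nid, seq in nodes.items():
        g.nodes[nid] = Node(nid, seq)
    for name, walk in walks.items():
        steps = tuple(OrientedStep(tok[:-1], tok[-1]) for tok in walk)
        g.paths[name] = GenomePath(name, steps)
        for a, b in zip(steps, steps[1:]):
            flip = (
                b.node_id, {"+": "-", "-": "+"}[b.orientation],
                a.node_id, {"+": "-", "-": "+"}[a.orientation],
            )
            if flip not in g.edges:
                g.edges.add((a.node_id, a.orientation, b.node_id, b.orientation))
    return g


@pytest.fixture
def toy_graph() -> VariationGraph:
    """Three nodes; a forward path, a reverse-containing path and a loop path."""
    return make_graph(
        {"n1": "ACGT", "n2": "TT", "n3": "GGA"},
        {
            "P1.chr1": ["n1+", "n2+", "n3+"],
            "Q.chr1": ["n3-", "n1+"],
            "R.chr1": ["n2+", "n2+"],
        },
    )


@pytest.fixture(scope="session")
def demo_pan():
    """The fixed five-genome demo: (graph, annotation sets, truth)."""
    return demo_pangenome()


def apply_variants(base: str, variants, genome: str) -> str:
    """Independent string oracle: the base sequence with a genome's variants applied."""
    out = []
    i = 0
    carried = sorted(
        (v for v in variants if genome in v.carriers), key=lambda v: v.position
    )
    for v in carried:
        out.append(base[i : v.position])
        if v.kind == "snp":
            out.append(v.alt)
            i = v.position + v.length
        elif v.kind == "deletion":
            i = v.position + v.length
        else:  # insertion: alt goes before the base at v.position
            out.append(v.alt)
            i = v.position
    out.append(base[i:])
    return "".join(out)
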