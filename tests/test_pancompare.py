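"""Presence matrices, gene comparison, indel scanning, locating, rank-sum."""

import itertools

import numpy as np
import pytest

from pangview import errors
from pangview.pancompare import (
    ABSENT_ANNOTATION,
    ABSENT_SEQUENCE,
    BOUNDARY_SHIFT,
    ELEMENT_PAV,
    FRAME_BREAKING,
    FRAME_PRESERVING,
    IDENTICAL_STRUCTURE,
    associate_phenotype,
    classify_indel_frame,
    coding_indel_scan,
    compare_gene,
    group_by_node,
    locate_sequence,
    presence_matrix,
    rank_sum_test,
)
from pangview.projection import extract_region
from pangview.synthpan import (
    ExonSpec,
    GeneSpec,
    VariantSpec,
    build_pangenome,
    sd1_scenario,
    simulate_phenotype,
    simulate_pangenome,
    xa7_scenario,
    _random_sequence,
)
from tests.conftest import make_graph


def exact_rank_sum_oracle(a, b):
    """Brute-force two-sided p: enumerate every assignment of ranks to group A."""
    n1, n = len(a), len(a) + len(b)
    pooled = sorted(a + b)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in a) - n1 * (n1 + 1) / 2
    us = [
        sum(c + 1 for c in comb) - n1 * (n1 + 1) / 2
        for comb in itertools.combinations(range(n), n1)
    ]
    us = np.array(us)
    lo = (us <= u_obs).mean()
    hi = (us >= u_obs).mean()
    return min(1.0, 2 * min(lo, hi))


class TestPresenceMatrix:
    def test_counts_by_enumeration(self):
        g = make_graph(
            {"n1": "AC", "n2": "GT", "n3": "AA"},
            {"A.chr1": ["n1+", "n2+", "n3+"], "B.chr1": ["n1+", "n3+"]},
        )
        sub = extract_region(g, [], "A.chr1:1-6")
        m = presence_matrix(sub)
        assert m.counts.loc["A"].tolist() == [1, 1, 1]
        assert m.counts.loc["B"].tolist() == [1, 0, 1]

    def test_loop_counts_twice(self, toy_graph):
        sub = extract_region(toy_graph, [], "R.chr1:1-4")
        m = presence_matrix(sub)
        assert m.counts.loc["R", "n2"] == 2

    def test_anchor_row_everywhere_positive(self, demo_pan):
        graph, annots, _ = demo_pan
        sub = extract_region(graph, annots, "s1.chr1:1-77")
        m = presence_matrix(sub)
        assert (m.counts.loc["s1"] >= 1).all()

    def test_single_path_region(self, demo_pan):
        graph, annots, _ = demo_pan
        from pangview.projection import graph_to_linear

        pos = graph_to_linear(graph, "s2.chr1", "n04", 0)[0]
        sub = extract_region(graph, annots, f"s2.chr1:{pos + 1}-{pos + 2}")
        m = presence_matrix(sub)
        assert m.genomes == ["s2"]
        assert (m.counts.values >= 1).all()


class TestGroupByNode:
    def test_split_and_unplaced(self, demo_pan):
        graph, annots, _ = demo_pan
        sub = extract_region(graph, annots, "s1.chr1:26-58")
        m = presence_matrix(sub)
        grp = group_by_node(m, "n08")
        assert grp.traversing == ["s1", "s2", "s3"]
        assert grp.skipping == ["s4"]
        assert grp.unplaced == ["s5"]

    def test_all_traverse(self, demo_pan):
        graph, annots, _ = demo_pan
        sub = extract_region(graph, annots, "s1.chr1:1-5")
        grp = group_by_node(presence_matrix(sub), "n01")
        assert grp.skipping == []

    def test_unknown_node(self, demo_pan):
        graph, annots, _ = demo_pan
        sub = extract_region(graph, annots, "s1.chr1:1-5")
        with pytest.raises(errors.LookupError_):
            group_by_node(presence_matrix(sub), "n99")


class TestCompareGene:
    def test_demo_fixture_statuses(self, demo_pan):
        graph, annots, _ = demo_pan
        cmp_ = compare_gene(graph, annots, "g1", "s1")
        assert cmp_.status_of("s2") == IDENTICAL_STRUCTURE
        assert cmp_.calls["s2"].coverage < 1.0  # substitution node not traversed
        assert cmp_.status_of("s3") == ELEMENT_PAV
        assert cmp_.status_of("s4") == BOUNDARY_SHIFT
        assert cmp_.status_of("s5") == ABSENT_SEQUENCE
        assert cmp_.calls["s5"].coverage == 0.0

    def test_identical_sequence_and_annotation(self):
        base = _random_sequence(np.random.default_rng(0), 800)
        gene = GeneSpec("g", (ExonSpec(100, 220), ExonSpec(300, 420)))
        graph, annots, _ = build_pangenome(base, ["A", "B"], [], [gene])
        cmp_ = compare_gene(graph, annots, "g", "A")
        assert cmp_.status_of("B") == IDENTICAL_STRUCTURE
        assert cmp_.calls["B"].coverage == 1.0

    def test_substitutions_inside_exons_keep_structure(self):
        base = _random_sequence(np.random.default_rng(1), 800)
        gene = GeneSpec("g", (ExonSpec(100, 220), ExonSpec(300, 420)))
        snps = [
            VariantSpec("snp", p, 1, "A" if base[p] != "A" else "C", frozenset({"B"}))
            for p in (150, 160, 350)
        ]
        graph, annots, _ = build_pangenome(base, ["A", "B"], snps, [gene])
        cmp_ = compare_gene(graph, annots, "g", "A")
        assert cmp_.status_of("B") == IDENTICAL_STRUCTURE

    def test_whole_gene_deletion_is_absent_sequence(self):
        base = _random_sequence(np.random.default_rng(2), 800)
        gene = GeneSpec("g", (ExonSpec(100, 220), ExonSpec(300, 420)))
        dele = VariantSpec("deletion", 80, 360, "", frozenset({"B"}))
        graph, annots, _ = build_pangenome(base, ["A", "B"], [dele], [gene])
        cmp_ = compare_gene(graph, annots, "g", "A")
        assert cmp_.status_of("B") == ABSENT_SEQUENCE
        assert cmp_.calls["B"].coverage == 0.0

    def test_missing_annotation_with_intact_sequence(self):
        base = _random_sequence(np.random.default_rng(3), 800)
        gene = GeneSpec("g", (ExonSpec(100, 220),))
        graph, annots, _ = build_pangenome(base, ["A", "B"], [], [gene])
        b = next(a for a in annots if a.genome == "B")
        b.features = []
        b.genes = {}
        cmp_ = compare_gene(graph, annots, "g", "A")
        assert cmp_.status_of("B") == ABSENT_ANNOTATION
        assert cmp_.calls["B"].coverage == 1.0

    def test_identical_structure_is_reference_symmetric(self, demo_pan):
        graph, annots, _ = demo_pan
        assert compare_gene(graph, annots, "g1", "s1").status_of("s2") == IDENTICAL_STRUCTURE
        assert compare_gene(graph, annots, "g1", "s2").status_of("s1") == IDENTICAL_STRUCTURE

    def test_unknown_gene_raises(self, demo_pan):
        graph, annots, _ = demo_pan
        with pytest.raises(errors.LookupError_):
            compare_gene(graph, annots, "nope", "s1")

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_truth_recovery_on_simulated_pangenomes(self, seed):
        """Comparison statuses reproduce the generator's gene-fate truth."""
        graph, annots, truth = simulate_pangenome(
            base_length=6000, n_genomes=8, seed=seed,
            rates={"snp": 2e-3, "insertion": 4e-4, "deletion": 6e-4},
        )
        to_fate = {
            IDENTICAL_STRUCTURE: "present_identical",
            BOUNDARY_SHIFT: "structurally_variant",
            ELEMENT_PAV: "structurally_variant",
            ABSENT_ANNOTATION: "absent",
            ABSENT_SEQUENCE: "absent",
        }
        checked = 0
        for gene in truth.genes:
            ref = next(
                (g for g in graph.genomes()
                 if truth.gene_fates[g][gene.id] == "present_identical"),
                None,
            )
            if ref is None:
                continue
            cmp_ = compare_gene(graph, annots, gene.id, ref)
            for g, call in cmp_.calls.items():
                assert to_fate[call.status] == truth.gene_fates[g][gene.id], (
                    gene.id, g, call.status,
                )
                checked += 1
        assert checked > 0


class TestFrameClassification:
    @pytest.mark.parametrize("length,expected", [(0, FRAME_PRESERVING),
                                                 (1, FRAME_BREAKING),
                                                 (3, FRAME_PRESERVING)])
    def test_known_cases(self, length, expected):
        assert classify_indel_frame(length) == expected

    def test_negative_rejected(self):
        with pytest.raises(errors.DomainError):
            classify_indel_frame(-1)

    def test_preserving_closed_under_addition(self):
        preserving = [n for n in range(0, 60) if classify_indel_frame(n) == FRAME_PRESERVING]
        for a in preserving:
            for b in preserving:
                assert classify_indel_frame(a + b) == FRAME_PRESERVING


class TestCodingIndelScan:
    @pytest.fixture
    def bubble_fixture(self):
        base = _random_sequence(np.random.default_rng(7), 1200)
        gene = GeneSpec("g", (ExonSpec(100, 400), ExonSpec(500, 900)))
        variants = [
            VariantSpec("deletion", 200, 3, "", frozenset({"B"})),       # exon, in-frame
            VariantSpec("insertion", 600, 1, "T", frozenset({"B"})),     # exon, frame-breaking
            VariantSpec("snp", 300, 1, "A" if base[300] != "A" else "C", frozenset({"B"})),
            VariantSpec("deletion", 430, 6, "", frozenset({"B"})),       # intron: excluded
        ]
        return build_pangenome(base, ["A", "B"], variants, [gene])

    def test_reports_only_coding_indels_with_frames(self, bubble_fixture):
        graph, annots, _ = bubble_fixture
        calls = coding_indel_scan(graph, annots, "g", "A", "B")
        assert [(c.kind, c.length, c.frame) for c in calls] == [
            ("deletion", 3, FRAME_PRESERVING),
            ("insertion", 1, FRAME_BREAKING),
        ]

    def test_identical_paths_empty(self, bubble_fixture):
        graph, annots, _ = bubble_fixture
        assert coding_indel_scan(graph, annots, "g", "A", "A") == []

    def test_absent_genome_raises(self, demo_pan):
        graph, annots, _ = demo_pan
        with pytest.raises(errors.AbsenceError):
            coding_indel_scan(graph, annots, "g1", "s1", "s5")


class TestLocate:
    def test_planted_match(self, demo_pan):
        graph, _, _ = demo_pan
        from pangview.graphio import path_sequence

        query = path_sequence(graph, "s1.chr1")[10:40]
        res = locate_sequence(graph, query)
        s1_hits = [h for h in res.hits if h.path_name == "s1.chr1"]
        assert s1_hits[0].start == 11 and s1_hits[0].end == 40
        assert all(h.matches == 30 and h.gaps == 0 for h in res.hits)

    def test_absent_query_empty(self, demo_pan):
        graph, _, _ = demo_pan
        assert locate_sequence(graph, "A" * 40).hits == []

    def test_reverse_strand_hit(self, demo_pan):
        graph, _, _ = demo_pan
        from pangview.graphio import path_sequence, reverse_complement

        query = reverse_complement(path_sequence(graph, "s1.chr1")[5:35])
        hits = [h for h in locate_sequence(graph, query) if h.path_name == "s1.chr1"]
        assert hits and hits[0].strand == "-"

    def test_minority_insertion_found_in_exactly_the_carriers(self):
        graph, _, truth = xa7_scenario(
            n_genomes=30, n_carriers=7, insert_length=200, base_length=1500, seed=4
        )
        res = locate_sequence(graph, truth.variants[0].alt)
        genomes = {h.path_name.split(".")[0] for h in res.hits}
        assert genomes == set(truth.phenotype_model.carriers)
        assert len(res.hits) == 7

    def test_short_or_invalid_query_rejected(self, demo_pan):
        graph, _, _ = demo_pan
        with pytest.raises(errors.DomainError):
            locate_sequence(graph, "ACGT")
        with pytest.raises(errors.DomainError):
            locate_sequence(graph, "N" * 30)

    def test_truncation_flag(self):
        g = make_graph({"n1": "ACGTACGTACGTACGTACGT"}, {
            f"G{i}.chr1": ["n1+"] for i in range(5)
        })
        res = locate_sequence(g, "ACGTACGTACGTACGT", max_hits=3)
        assert len(res.hits) == 3 and res.truncated


class TestRankSum:
    def test_separated_groups_exact(self):
        r = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert r.u_statistic == 0.0
        assert r.p_value == pytest.approx(0.1)
        assert r.method == "exact"

    def test_constant_data_exchangeable(self):
        assert rank_sum_test([5, 5], [5, 5]).p_value == 1.0

    def test_ties_force_normal_approximation(self):
        r = rank_sum_test([1, 2, 2], [2, 3, 4])
        assert r.method == "normal-approximation"

    def test_empty_group_rejected(self):
        with pytest.raises(errors.DomainError):
            rank_sum_test([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 7) for n2 in range(n1, 7)])
    def test_exact_p_matches_enumeration(self, n1, n2):
        """Exhaustive: exact p equals the brute-force oracle for n1, n2 <= 6."""
        rng = np.random.default_rng(n1 * 10 + n2)
        a = list(rng.permutation(n1 + n2)[:n1].astype(float))
        b = [float(v) for v in range(n1 + n2) if float(v) not in a]
        r = rank_sum_test(a, b)
        assert r.method == "exact"
        assert r.p_value == pytest.approx(exact_rank_sum_oracle(a, b))

    def test_normal_approx_close_to_exact_at_n8(self):
        """Away from the deep tail (exact p >= 0.05) the continuity-corrected
        normal approximation stays within 10% relative error of the exact p
        for n1 = n2 = 8 random data."""
        rng = np.random.default_rng(8)
        compared = 0
        for _ in range(100):
            a = list(rng.normal(size=8))
            b = list(rng.normal(size=8))
            exact = rank_sum_test(a, b, exact_cutoff=10)
            approx = rank_sum_test(a, b, exact_cutoff=0)
            assert approx.method == "normal-approximation"
            if exact.p_value >= 0.05:
                assert abs(approx.p_value - exact.p_value) / exact.p_value < 0.10
                compared += 1
        assert compared > 50

    def test_type_one_error_calibration(self):
        """Under the null the normal-approximation test rejects ~5% at alpha=0.05."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_reps = 10_000
        for _ in range(n_reps):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            if rank_sum_test(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_reps <= 0.07


class TestAssociatePhenotype:
    def test_planted_effect_detected(self):
        graph, annots, truth = sd1_scenario(seed=2)
        node = truth.phenotype_model.target_node
        sub = extract_region(graph, annots, "G021.chr1:900-1500")
        m = presence_matrix(sub)
        phen = simulate_phenotype(truth, graph.genomes(), effect=-10.0, noise_sd=5.0, seed=3)
        assoc = associate_phenotype(m, node, phen)
        assert assoc.test.p_value < 0.01
        assert assoc.traversing.n == 20 and assoc.skipping.n == 20
        assert assoc.traversing.median > assoc.skipping.median

    def test_missing_phenotypes_dropped(self):
        graph, annots, truth = sd1_scenario(seed=2)
        node = truth.phenotype_model.target_node
        sub = extract_region(graph, annots, "G021.chr1:900-1500")
        m = presence_matrix(sub)
        phen = simulate_phenotype(truth, graph.genomes(), effect=-10.0, noise_sd=5.0, seed=3)
        del phen["G001"], phen["G040"]
        assoc = associate_phenotype(m, node, phen)
        assert assoc.dropped == 2
        assert assoc.traversing.n + assoc.skipping.n == 38

    def test_group_without_phenotype_is_degenerate(self):
        graph, annots, truth = sd1_scenario(seed=2)
        node = truth.phenotype_model.target_node
        sub = extract_region(graph, annots, "G021.chr1:900-1500")
        m = presence_matrix(sub)
        phen = {g: 1.0 for g in truth.phenotype_model.carriers}  # skip group only
        with pytest.raises(errors.DegenerateGroupingError):
            associate_phenotype(m, node, phen)
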