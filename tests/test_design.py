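import numpy as np
import pytest

from teguide.annotation import ElementAnnotation, TEAnnotation, TECopy
from teguide.design import (Candidate, CombinationResult, DesignConfig,
                            OffTargetCounts, combination_score,
                            greedy_combination, greedy_select,
                            offtarget_counts, single_copy_design,
                            subfamily_coverage)
from teguide.index import build_index
from teguide.scan import scan_genome
from teguide.simulate import (GeneModelSpec, SimulationParams, SubfamilySpec,
                              simulate_genome)

from oracles import combo_score, exhaustive_best_trace, naive_scan, \
    reference_greedy


class TestCombinationScore:
    def test_penalty_free_score_is_coverage(self):
        assert combination_score(0.80, OffTargetCounts()) == 0.80

    def test_te_offtarget_penalty(self):
        counts = OffTargetCounts(w1=100)
        assert combination_score(0.50, counts) == pytest.approx(0.40, abs=1e-15)

    def test_element_class_penalties(self):
        counts = OffTargetCounts(w2=10, w3=10, w4=10, w5=10)
        assert combination_score(0.70, counts) == pytest.approx(0.6986, abs=1e-15)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            OffTargetCounts(w1=-1)

    def test_score_may_go_negative(self):
        assert combination_score(0.0, OffTargetCounts(w1=10)) < 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DesignConfig(lambda1=-0.1)
        with pytest.raises(ValueError):
            DesignConfig(k_max=4)
        with pytest.raises(ValueError):
            DesignConfig(coverage_mismatch=2, k_max=1)


def abstract_candidate(gid, proto, covered, offsites=()):
    return Candidate(gid, proto, frozenset(covered), tuple(offsites), 1)


def random_instance(rng, n_cands, n_copies):
    """Seeded abstract design instance: random coverage subsets and
    random planted off-target sites per candidate."""
    protos = set()
    while len(protos) < n_cands:
        protos.add("".join(rng.choice(list("ACGT"), size=20)))
    cands = []
    site_pool = [("c", int(i * 50), "+") for i in range(40)]
    for gid, proto in enumerate(sorted(protos)):
        n_cov = int(rng.integers(0, n_copies + 1))
        covered = rng.choice(n_copies, size=n_cov, replace=False)
        n_off = int(rng.integers(0, 6))
        sites = rng.choice(len(site_pool), size=n_off, replace=False)
        offsites = tuple(sorted((site_pool[s], int(rng.integers(1, 6)))
                                for s in sites))
        cands.append(abstract_candidate(gid, proto,
                                        {f"cp{c}" for c in covered}, offsites))
    return cands


class TestGreedySelect:
    def test_dominant_candidate_selected_first(self):
        copies = {f"cp{i}" for i in range(10)}
        dominant = abstract_candidate(0, "A" * 20, copies)
        weak = abstract_candidate(1, "C" * 20, {"cp0", "cp1"},
                                  [(("c", 0, "+"), 1)])
        results = greedy_select([weak, dominant], 10, DesignConfig())
        assert results[0][0][0].gid == 0
        assert results[0][1] == pytest.approx(1.0)

    def test_greedy_is_greedy_not_optimal_aware(self):
        """With copies 1..10: A covers 1-5, B covers 6-10, C covers 1-6.
        Greedy seeded at C adds B (coverage 1.0); A adds nothing after C+B."""
        A = abstract_candidate(0, "A" * 20, {f"cp{i}" for i in range(1, 6)})
        B = abstract_candidate(1, "C" * 20, {f"cp{i}" for i in range(6, 11)})
        C = abstract_candidate(2, "G" * 20, {f"cp{i}" for i in range(1, 7)})
        results = greedy_select([A, B, C], 10, DesignConfig())
        top_gids = [c.gid for c in results[0][0]]
        assert top_gids == [2, 1]  # C then B; A gives zero increment
        assert results[0][1] == pytest.approx(1.0)

    def test_stops_on_non_positive_increment(self):
        a = abstract_candidate(0, "A" * 20, {"cp0"})
        b = abstract_candidate(1, "C" * 20, {"cp0"})  # redundant
        results = greedy_select([a, b], 1, DesignConfig())
        assert len(results[0][0]) == 1

    def test_empty_candidates(self):
        assert greedy_select([], 5, DesignConfig()) == []

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(17)
        cfg = DesignConfig()
        for _ in range(20):
            cands = random_instance(rng, int(rng.integers(3, 31)),
                                    int(rng.integers(3, 51)))
            n_total = 50
            got = [([c.gid for c in combo], score)
                   for combo, score in greedy_select(cands, n_total, cfg)]
            want = reference_greedy(cands, n_total, cfg)
            assert [g for g, _ in got] == [g for g, _ in want]
            for (_, s1), (_, s2) in zip(got, want):
                assert s1 == pytest.approx(s2, abs=1e-12)

    def test_exhaustive_trace_confirms_top_seed(self):
        rng = np.random.default_rng(29)
        cfg = DesignConfig()
        for _ in range(10):
            cands = random_instance(rng, int(rng.integers(3, 16)), 12)
            trace, score = exhaustive_best_trace(cands, 12, cfg)
            results = greedy_select(cands, 12, cfg)
            seed_trace = next(([c.gid for c in combo], s)
                              for combo, s in results
                              if combo[0].gid == trace[0])
            assert seed_trace[0] == trace
            assert seed_trace[1] == pytest.approx(score, abs=1e-12)

    def test_final_score_bounds_and_monotone_coverage(self):
        rng = np.random.default_rng(31)
        cfg = DesignConfig()
        for _ in range(10):
            cands = random_instance(rng, 20, 30)
            results = greedy_select(cands, 30, cfg)
            best_single = max(combo_score([c], 30, cfg) for c in cands)
            assert results[0][1] >= best_single - 1e-12
            combo, _ = results[0]
            covs = [len(frozenset().union(*(c.covered for c in combo[:i + 1])))
                    for i in range(len(combo))]
            assert covs == sorted(covs)


@pytest.fixture(scope="module")
def planted_genome():
    """Hand-built genome: one FOC copy and one identical-sequence AluY
    decoy copy that lies inside an intron."""
    guide = "ACGTTGCATCAGGTACGAGT"
    site = guide + "TGG"
    pad = "TTTTT"
    pre = "ATATATATTA"
    mid = "ATCTTATCAATTACCAATTATTATCATTAGCATTTACCAAATATATCATCATTAC"
    post = "ATTATTATCACTATTATCATCAACCTATTTTACTATTACCATCATTAAT"
    foc_start = len(pre)
    foc_end = foc_start + len(pad) + len(site) + len(pad)
    alu_start = foc_end + len(mid)
    alu_end = alu_start + len(pad) + len(site) + len(pad)
    chrom = pre + pad + site + pad + mid + pad + site + pad + post
    seqs = {"c": chrom}
    foc = TECopy("c", foc_start, foc_end, "+", "FOC", "ERVK", "LTR", "FOC_dup1")
    alu = TECopy("c", alu_start, alu_end, "+", "AluY", "Alu", "SINE", "AluY_dup1")
    tes = TEAnnotation([foc, alu])
    # the decoy copy sits inside an intron: transcript spans it, exons do not
    elements = ElementAnnotation(promoters=[],
                                 exons=[("c", foc_end, foc_end + 20)],
                                 transcripts=[("c", foc_end, len(chrom))])
    index = build_index(scan_genome(seqs))
    return guide, seqs, index, tes, elements


class TestOffTargetCounting:
    def test_te_membership_outranks_element_class(self, planted_genome):
        guide, seqs, index, tes, elements = planted_genome
        gid = index.gid_of(guide)
        counts = offtarget_counts([gid], "FOC", index, tes, elements)
        assert counts.w1 == 1 and counts.w4 == 0

    def test_on_subfamily_sites_never_counted(self, planted_genome):
        guide, seqs, index, tes, elements = planted_genome
        gid = index.gid_of(guide)
        counts = offtarget_counts([gid], "AluY", index, tes, elements)
        # queried as AluY: the FOC site becomes the off-target TE site
        assert counts.w1 == 1

    def test_sites_deduplicated_across_guides(self, planted_genome):
        guide, seqs, index, tes, elements = planted_genome
        gid = index.gid_of(guide)
        single = offtarget_counts([gid], "FOC", index, tes, elements)
        doubled = offtarget_counts([gid, gid], "FOC", index, tes, elements)
        assert single == doubled

    def test_unknown_subfamily_names_near_misses(self, planted_genome):
        guide, seqs, index, tes, elements = planted_genome
        with pytest.raises(ValueError, match="FOC"):
            offtarget_counts([0], "FOX", index, tes, elements)


class TestSubfamilyCoverage:
    def test_coverage_matches_substring_oracle(self, tiny_pipeline):
        sim, index, tes, elements = tiny_pipeline
        copies = tes.copies_of("FOC")
        # brute per-copy protospacer sets via naive both-strand scan
        per_copy = {}
        for c in copies:
            seq = sim.sequences[c.chrom]
            protos = {p for (_, s, e, _, p, _) in naive_scan(c.chrom, seq)
                      if c.start <= s and e <= c.end}
            per_copy[c.copy_id] = protos
        rng = np.random.default_rng(4)
        gids = [int(g) for g in rng.integers(0, len(index), size=12)]
        frac, covered = subfamily_coverage(gids, "FOC", index, tes)
        protos = {index.record(g).protospacer for g in gids}
        expected = {cid for cid, pool in per_copy.items() if pool & protos}
        assert covered == expected
        assert frac == pytest.approx(len(expected) / len(copies))

    def test_union_over_guides(self, planted_genome):
        guide, seqs, index, tes, elements = planted_genome
        gid = index.gid_of(guide)
        frac, covered = subfamily_coverage([gid], "FOC", index, tes)
        assert frac == 1.0 and covered == {"FOC_dup1"}


@pytest.fixture(scope="module")
def identical_pair_genome():
    """Simulated subfamily with zero divergence: two byte-identical copies."""
    params = SimulationParams(
        seed=5, n_chroms=1, chrom_length=4000,
        subfamilies=[SubfamilySpec("TWIN", consensus_length=150, n_copies=2,
                                   divergence=0.0)],
        genes=GeneModelSpec(n_genes=1, exons_per_gene=2, exon_length=100,
                            intron_length=150))
    sim = simulate_genome(params)
    index = build_index(scan_genome(sim.sequences))
    return sim, index, sim.to_te_annotation(), sim.to_element_annotation()


class TestSingleCopyDesign:
    def test_sibling_copy_forces_mm0(self, identical_pair_genome):
        sim, index, tes, elements = identical_pair_genome
        rows = single_copy_design("TWIN_dup1", index, tes)
        assert rows
        assert all(r.mm_counts[0] >= 1 for r in rows)

    def test_unique_guide_ranks_first_with_zero_counts(self, tiny_pipeline):
        sim, index, tes, elements = tiny_pipeline
        rows = single_copy_design("FOC_dup1", index, tes)
        assert rows
        unique = [r for r in rows if r.mm_counts == (0, 0, 0, 0)]
        if unique:
            assert rows[0].mm_counts == (0, 0, 0, 0)
        assert [r.mm_counts for r in rows] == sorted(r.mm_counts for r in rows)

    def test_counts_match_bruteforce_recount(self, tiny_pipeline):
        from oracles import hamming
        sim, index, tes, elements = tiny_pipeline
        copy = tes.by_id["FOC_dup2"]
        rows = single_copy_design("FOC_dup2", index, tes)
        all_sites = [(rec.protospacer, s) for rec in index.records
                     for s in rec.sites]
        for r in rows[:5]:
            bins = [0, 0, 0, 0]
            for proto, s in all_sites:
                d = hamming(proto, r.protospacer)
                if d <= 3 and not copy.contains(s.chrom, s.start, s.end):
                    bins[d] += 1
            assert r.mm_counts == tuple(bins)

    def test_unknown_copy_id(self, tiny_pipeline):
        sim, index, tes, elements = tiny_pipeline
        with pytest.raises(ValueError, match="unknown TE copy"):
            single_copy_design("FOC_dup99", index, tes)


class TestGreedyOnGenome:
    def test_zero_divergence_full_coverage(self, identical_pair_genome):
        sim, index, tes, elements = identical_pair_genome
        results = greedy_combination("TWIN", index, tes, elements)
        assert results[0].coverage == 1.0

    def test_score_reproducible_from_components(self, tiny_pipeline):
        sim, index, tes, elements = tiny_pipeline
        cfg = DesignConfig()
        for r in greedy_combination("FOC", index, tes, elements, cfg):
            assert r.score == pytest.approx(
                combination_score(r.coverage, r.counts, cfg), abs=1e-12)
            assert r.coverage == pytest.approx(
                len(r.covered_copies) / len(tes.copies_of("FOC")))

    def test_results_sorted_by_score(self, tiny_pipeline):
        sim, index, tes, elements = tiny_pipeline
        scores = [r.score for r in greedy_combination("FOC", index, tes,
                                                      elements)]
        assert scores == sorted(scores, reverse=True)
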