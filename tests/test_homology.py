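"""Word length, candidate filtering, best hits and paralog inference."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from pandict.homology import (
    PangenomeConfig,
    best_hits,
    bidirectional_best_hits,
    candidate_pairs,
    infer_paralogs,
    optimal_k,
    run_pangenome,
)
from pandict.index import accumulate_stats, build_index

from conftest import make_genesets, naive_jaccard, naive_kmer_counts


def geneset_of_length(total: int):
    """Gene sets whose genetic lengths sum to ``total``."""
    return make_genesets({"G": {"g": "A" * total}})


class TestOptimalK:
    @pytest.mark.parametrize(
        "total,expect",
        [(20**5, 5), (8000, 3), (10_000_000, 5), (20, 1), (50, 1)],
    )
    def test_log_alphabet_rounded_half_up(self, total, expect):
        assert optimal_k(geneset_of_length(total)) == expect

    def test_alternate_alphabet_size(self):
        assert optimal_k(geneset_of_length(4**6), alphabet_size=4) == 6

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            optimal_k([])


class TestCandidatePairs:
    def test_threshold_is_two_over_k_both_directions(self):
        # k=5: coverage must reach 2/5 = 0.4 in BOTH directions
        lengths = np.array([104, 104])  # len-k+1 = 100
        stats_keep = type("S", (), {"stats": {(0, 1): (40, 40, 40)}, "k": 5})()
        stats_drop = type("S", (), {"stats": {(0, 1): (39, 39, 41)}, "k": 5})()
        assert (0, 1) in candidate_pairs(stats_keep, lengths, 5)
        assert candidate_pairs(stats_drop, lengths, 5) == {}

    def test_worked_pair_fails_at_k2(self, two_gene_pair):
        # coverages 0.8 and 1.0 against threshold 2/2 = 1.0 -> discarded
        idx = build_index(two_gene_pair)
        stats = accumulate_stats(idx, 2)
        assert candidate_pairs(stats, idx.gene_lengths, 2) == {}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        genomes = {
            f"G{g}": {
                f"g{g}_{i}": "".join(rng.choice(list("ACDEFG"), size=30))
                for i in range(5)
            }
            for g in range(3)
        }
        idx = build_index(make_genesets(genomes))
        stats = accumulate_stats(idx, 2)
        sizes = []
        for thr in (0.2, 0.5, 0.8, 1.0):
            ch = candidate_pairs(stats, idx.gene_lengths, 2, Fraction(thr).limit_denominator())
            sizes.append(set(ch))
        for smaller, larger in zip(sizes[1:], sizes):
            assert smaller <= larger


class TestBestHits:
    def _ch(self, entries):
        """entries: {(i, j): Fraction} -> candidate map with exact fractions."""
        return {
            pair: (f.numerator, f.denominator) for pair, f in entries.items()
        }

    def test_single_maximum(self):
        ch = self._ch({(0, 1): Fraction(8, 10), (0, 2): Fraction(5, 10)})
        genome = np.array([0, 1, 1])
        bh = best_hits(ch, genome)
        assert bh[(0, 1)][2] == {1}

    def test_ties_keep_all_maximizers(self):
        ch = self._ch({(0, 1): Fraction(4, 5), (0, 2): Fraction(8, 10)})
        genome = np.array([0, 1, 1])
        bh = best_hits(ch, genome)
        assert bh[(0, 1)][2] == {1, 2}

    def test_no_candidates_no_best_hit(self):
        bh = best_hits({}, np.array([0, 1]))
        assert bh == {}

    def test_bbh_requires_reciprocity(self):
        # s0's best in genome 1 is t1, but t1's best in genome 0 is s2
        ch = self._ch(
            {(0, 3): Fraction(7, 10), (2, 3): Fraction(9, 10), (1, 3): Fraction(2, 10)}
        )
        genome = np.array([0, 0, 0, 1])
        bbh = bidirectional_best_hits(ch, genome)
        assert (2, 3) in bbh and (0, 3) not in bbh

    def test_bbh_matches_brute_force_on_random_instances(self):
        """Reciprocal-max by double loop over dictionaries, 5 genomes x genes."""
        rng = np.random.default_rng(42)
        bases = [
            "".join(rng.choice(list("ACDEFGHIKL"), size=int(rng.integers(25, 45))))
            for _ in range(4)
        ]
        genomes = {}
        for g in range(5):
            genes = {}
            for i in range(int(rng.integers(3, 8))):
                s = list(bases[int(rng.integers(len(bases)))])
                for _ in range(int(rng.integers(0, 4))):
                    s[int(rng.integers(len(s)))] = "W"
                genes[f"g{g}_{i}"] = "".join(s)
            genomes[f"G{g}"] = genes
        idx = build_index(make_genesets(genomes))
        k = 3
        stats = accumulate_stats(idx, k)
        ch = candidate_pairs(stats, idx.gene_lengths, k)
        got = bidirectional_best_hits(ch, idx.genome_index)

        # brute force from scratch: naive J on CH pairs, double loop max
        seqs = {}
        for gi, (gname, genes) in enumerate(genomes.items()):
            for gene_id in genes:
                key = (gname, gene_id)
                seqs[idx.gene_ids.index(key)] = genes[gene_id]
        sim = {
            pair: naive_jaccard(seqs[pair[0]], seqs[pair[1]], k) for pair in ch
        }
        expect = set()
        for (i, j), s in sim.items():
            gi, gj = int(idx.genome_index[i]), int(idx.genome_index[j])
            best_fwd = max(
                v for p, v in sim.items()
                if (p[0] == i and idx.genome_index[p[1]] == gj)
                or (p[1] == i and idx.genome_index[p[0]] == gj)
            )
            best_rev = max(
                v for p, v in sim.items()
                if (p[0] == j and idx.genome_index[p[1]] == gi)
                or (p[1] == j and idx.genome_index[p[0]] == gi)
            )
            if s == best_fwd and s == best_rev:
                expect.add((i, j))
        assert set(got) == expect
        assert len(got) > 0


class TestParalogInference:
    def test_threshold_is_min_inter_genome_bbh(self):
        genome = np.array([0, 0, 0, 0, 1])
        bbh = {
            (0, 4): (6, 10),   # inter edge: tau_0 = 0.6
            (0, 1): (7, 10),   # intra, 0.7 >= 0.6 -> paralog
            (2, 3): (59, 100), # intra, 0.59 < 0.6 -> rejected
        }
        ortho, para = infer_paralogs(bbh, genome)
        assert set(ortho) == {(0, 4)}
        assert set(para) == {(0, 1)}

    def test_score_exactly_tau_is_paralog(self):
        genome = np.array([0, 0, 1])
        bbh = {(0, 2): (3, 5), (0, 1): (6, 10)}  # 6/10 == 3/5 exactly
        _, para = infer_paralogs(bbh, genome)
        assert set(para) == {(0, 1)}

    def test_no_inter_bbh_means_no_paralogs(self):
        genome = np.array([0, 0])
        _, para = infer_paralogs({(0, 1): (9, 10)}, genome)
        assert para == {}

    def test_paralog_scores_respect_tau_invariant(self):
        rng = np.random.default_rng(3)
        genome = np.array([0] * 6 + [1] * 6)
        bbh = {}
        for i, j in itertools.combinations(range(12), 2):
            if rng.random() < 0.3:
                bbh[(i, j)] = (int(rng.integers(1, 100)), 100)
        ortho, para = infer_paralogs(bbh, genome)
        tau = {}
        for (i, j), (n, d) in ortho.items():
            for g in (int(genome[i]), int(genome[j])):
                f = Fraction(n, d)
                tau[g] = min(tau.get(g, Fraction(2)), f)
        for (i, j), (n, d) in para.items():
            assert Fraction(n, d) >= tau[int(genome[i])]


class TestRunPangenome:
    def test_two_identical_single_gene_genomes(self):
        seq = "WLLPPPKKAALM" * 3
        sets = make_genesets({"G1": {"a": seq}, "G2": {"b": seq}})
        res = run_pangenome(sets, PangenomeConfig(k_override=3))
        assert len(res.families) == 1
        fam = res.families[0]
        assert fam.category == "core" and len(fam.members) == 2
        (edge,) = res.edges
        assert edge.weight == 1.0

    def test_disjoint_genomes_all_singletons(self):
        sets = make_genesets({"G1": {"a": "AAAAAAAA"}, "G2": {"b": "CCCCCCCC"}})
        res = run_pangenome(sets, PangenomeConfig(k_override=2))
        assert all(f.category == "singleton" for f in res.families)
        assert len(res.families) == 2

    def test_short_genes_become_forced_singletons(self):
        sets = make_genesets(
            {"G1": {"a": "WLLPPPKKAA", "tiny": "WL"}, "G2": {"b": "WLLPPPKKAA"}}
        )
        res = run_pangenome(sets, PangenomeConfig(k_override=3))
        cats = {sorted(f.members)[0][1] if len(f.members) == 1 else "fam": f.category
                for f in res.families}
        assert cats.get("tiny") == "singleton"
        assert res.report["n_short_genes"] == 1

    def test_emitted_edges_satisfy_coverage_threshold_post_hoc(self):
        """Every final edge re-checks the 2/k rule from raw dictionaries."""
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACDEFGHIKL"), size=40))
        genomes = {}
        for g in range(3):
            variants = {}
            for i in range(4):
                s = list(base)
                for _ in range(rng.integers(0, 4)):
                    s[int(rng.integers(len(s)))] = "M"
                variants[f"g{i}"] = "".join(s)
            genomes[f"G{g}"] = variants
        sets = make_genesets(genomes)
        res = run_pangenome(sets, PangenomeConfig(k_override=3))
        seq_of = {g.key: g.sequence for gs in sets for g in gs}
        k = res.k
        for e in res.edges:
            s = seq_of[res.gene_ids[e.gene_i]]
            t = seq_of[res.gene_ids[e.gene_j]]
            cs, ct = naive_kmer_counts(s, k), naive_kmer_counts(t, k)
            shared = set(cs) & set(ct)
            p_st = sum(cs[w] for w in shared) / (len(s) - k + 1)
            p_ts = sum(ct[w] for w in shared) / (len(t) - k + 1)
            assert p_st >= 2 / k - 1e-12 and p_ts >= 2 / k - 1e-12

    def test_requires_two_genes(self):
        with pytest.raises(ValueError):
            run_pangenome(make_genesets({"G": {"a": "WLLPPP"}}))
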