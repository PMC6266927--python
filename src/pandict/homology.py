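"""Homology candidate selection and bidirectional best hits.

The pipeline is parameter-free: the word length k is derived from the total
genetic length of the input, the candidate filter threshold is the fixed
ratio 2/k motivated by sequence reconstructibility, and the paralogy
threshold per genome is the minimum similarity among its trusted inter-genome
orthologs.  All similarity comparisons (maxima, thresholds) are carried out
on exact integer fractions so tie behavior is platform independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from .families import build_graph, extract_families, refine_graph
from .index import (
    ConcatenatedIndex,
    PairStats,
    accumulate_stats,
    build_index,
    jaccard_fraction,
)
from .io import FamilyAssignment, GeneSet

logger = logging.getLogger(__name__)


def optimal_k(genesets: Sequence[GeneSet], alphabet_size: int = 20) -> int:
    """Word length k = log_|Γ|(Σ ⟨G^i⟩), rounded half-up, at least 1.

    The summed genetic length of all input genomes sets the resolution at
    which k-mer dictionaries maximally separate real sequences from random
    ones of the same length.
    """
    total = sum(gs.genetic_length for gs in genesets)
    if total <= 0:
        raise ValueError("total genetic length is zero")
    k = math.floor(math.log(total, alphabet_size) + 0.5)
    return max(k, 1)


@dataclass(frozen=True)
class HomologyEdge:
    """A candidate homology relation between two distinct genes."""

    gene_i: int
    gene_j: int
    weight: float
    num: int
    den: int
    relation: str  # ortholog_candidate | paralog_candidate


@dataclass
class PangenomeConfig:
    alphabet_size: int = 20
    k_override: int | None = None
    min_coverage_override: float | None = None  # replaces 2/k when set


@dataclass
class PangenomeResult:
    families: list[FamilyAssignment]
    graph: "object"  # networkx.Graph of the refined homology network
    report: dict = field(default_factory=dict)
    k: int = 0
    edges: list[HomologyEdge] = field(default_factory=list)
    gene_ids: list[tuple[str, str]] = field(default_factory=list)


def candidate_pairs(
    stats: PairStats,
    gene_lengths,
    k: int,
    min_coverage: Fraction | None = None,
) -> dict[tuple[int, int], tuple[int, int]]:
    """Filter gene pairs by two-sided dictionary coverage >= 2/k.

    Returns the candidate set CH as a map pair -> exact Jaccard fraction
    (numerator, denominator).  The comparison cov/(len-k+1) >= 2/k is done by
    integer cross multiplication.
    """
    if min_coverage is None:
        thr_num, thr_den = 2, k
    else:
        thr = Fraction(min_coverage).limit_denominator(10**9)
        thr_num, thr_den = thr.numerator, thr.denominator
    ch: dict[tuple[int, int], tuple[int, int]] = {}
    for (i, j), (a, cov_i, cov_j) in stats.stats.items():
        li = int(gene_lengths[i])
        lj = int(gene_lengths[j])
        if cov_i * thr_den < thr_num * (li - k + 1):
            continue
        if cov_j * thr_den < thr_num * (lj - k + 1):
            continue
        ch[(i, j)] = jaccard_fraction(a, li, lj, k)
    return ch


def _frac_cmp(n1: int, d1: int, n2: int, d2: int) -> int:
    """Compare n1/d1 with n2/d2 exactly (positive denominators)."""
    lhs = n1 * d2
    rhs = n2 * d1
    return (lhs > rhs) - (lhs < rhs)


def best_hits(
    ch: dict[tuple[int, int], tuple[int, int]],
    genome_index,
) -> dict[tuple[int, int], tuple[int, int, set[int]]]:
    """Per (query gene, target genome): the best-hit set BH.

    Maps (gene, genome) -> (num, den, set of genes attaining the maximum
    similarity).  Ties keep all maximizers; intra-genome queries never list
    the query itself (candidate pairs are between distinct genes already).
    """
    bh: dict[tuple[int, int], tuple[int, int, set[int]]] = {}

    def update(query: int, target: int, n: int, d: int) -> None:
        tg = int(genome_index[target])
        key = (query, tg)
        cur = bh.get(key)
        if cur is None:
            bh[key] = (n, d, {target})
            return
        c = _frac_cmp(n, d, cur[0], cur[1])
        if c > 0:
            bh[key] = (n, d, {target})
        elif c == 0:
            cur[2].add(target)

    for (i, j), (n, d) in ch.items():
        update(i, j, n, d)
        update(j, i, n, d)
    return bh


def bidirectional_best_hits(
    ch: dict[tuple[int, int], tuple[int, int]],
    genome_index,
) -> dict[tuple[int, int], tuple[int, int]]:
    """All reciprocal best-hit pairs over the candidate set.

    Covers every genome pair including self-comparisons (the paralog search).
    Returns pair (i < j) -> exact similarity fraction.
    """
    bh = best_hits(ch, genome_index)
    bbh: dict[tuple[int, int], tuple[int, int]] = {}
    for (i, j), (n, d) in ch.items():
        gi = int(genome_index[i])
        gj = int(genome_index[j])
        fwd = bh.get((i, gj))
        rev = bh.get((j, gi))
        if fwd and rev and j in fwd[2] and i in rev[2]:
            bbh[(i, j)] = (n, d)
    return bbh


def infer_paralogs(
    bbh: dict[tuple[int, int], tuple[int, int]],
    genome_index,
) -> tuple[dict[tuple[int, int], tuple[int, int]], dict[tuple[int, int], tuple[int, int]]]:
    """Split BBH pairs into orthologs (CH_O) and accepted paralogs (CH_P).

    For each genome the orthology score τ is the minimum similarity over its
    inter-genome BBH edges; an intra-genome BBH is accepted as paralogous
    when its score is >= τ ("equal to or greater than").  A genome with no
    inter-genome BBH infers no paralogs.
    """
    tau: dict[int, tuple[int, int]] = {}
    ortho: dict[tuple[int, int], tuple[int, int]] = {}
    intra: dict[tuple[int, int], tuple[int, int]] = {}
    for (i, j), (n, d) in bbh.items():
        gi = int(genome_index[i])
        gj = int(genome_index[j])
        if gi == gj:
            intra[(i, j)] = (n, d)
            continue
        ortho[(i, j)] = (n, d)
        for g in (gi, gj):
            cur = tau.get(g)
            if cur is None or _frac_cmp(n, d, cur[0], cur[1]) < 0:
                tau[g] = (n, d)
    para: dict[tuple[int, int], tuple[int, int]] = {}
    for (i, j), (n, d) in intra.items():
        g = int(genome_index[i])
        t = tau.get(g)
        if t is not None and _frac_cmp(n, d, t[0], t[1]) >= 0:
            para[(i, j)] = (n, d)
    return ortho, para


def homology_edges(
    ortho: dict[tuple[int, int], tuple[int, int]],
    para: dict[tuple[int, int], tuple[int, int]],
) -> list[HomologyEdge]:
    edges = []
    for relation, pairs in (("ortholog_candidate", ortho), ("paralog_candidate", para)):
        for (i, j), (n, d) in pairs.items():
            edges.append(
                HomologyEdge(
                    gene_i=i, gene_j=j, weight=n / d, num=n, den=d, relation=relation
                )
            )
    return edges


def run_pangenome(
    genesets: Sequence[GeneSet],
    config: PangenomeConfig | None = None,
) -> PangenomeResult:
    """Full pipeline: k selection, index sweep, CH filter, BBH, paralog
    inference, network refinement, family classification."""
    config = config or PangenomeConfig()
    n_genes_total = sum(len(gs) for gs in genesets)
    if n_genes_total < 2:
        raise ValueError("need at least two genes")
    k = config.k_override or optimal_k(genesets, config.alphabet_size)

    # genes shorter than k cannot carry a full k-mer; they are excluded from
    # the index and reported as forced singleton families
    indexed: list[GeneSet] = []
    short_genes: list[tuple[str, str]] = []
    for gs in genesets:
        kept = [g for g in gs if g.length >= k]
        dropped = [g for g in gs if g.length < k]
        short_genes.extend(g.key for g in dropped)
        indexed.append(GeneSet(genome_id=gs.genome_id, genes=kept))
    if short_genes:
        logger.warning(
            "%d genes shorter than k=%d excluded from indexing (forced singletons)",
            len(short_genes),
            k,
        )

    index = build_index(indexed)
    stats = accumulate_stats(index, k)
    min_cov = (
        Fraction(config.min_coverage_override).limit_denominator(10**9)
        if config.min_coverage_override is not None
        else None
    )
    ch = candidate_pairs(stats, index.gene_lengths, k, min_cov)
    bbh = bidirectional_best_hits(ch, index.genome_index)
    ortho, para = infer_paralogs(bbh, index.genome_index)
    edges = homology_edges(ortho, para)

    key_of = index.gene_ids
    graph = build_graph(
        [
            (key_of[e.gene_i], key_of[e.gene_j], e.weight, e.relation)
            for e in edges
        ]
    )
    refined = refine_graph(graph)
    all_keys = [g.key for gs in genesets for g in gs]
    n_genomes = len(genesets)
    families = extract_families(refined, all_keys, n_genomes)

    report = {
        "k": k,
        "n_genomes": n_genomes,
        "n_genes": n_genes_total,
        "n_short_genes": len(short_genes),
        "n_pairs_sharing_kmers": len(stats),
        "n_candidate_pairs": len(ch),
        "n_bbh": len(bbh),
        "n_ortholog_edges": len(ortho),
        "n_paralog_edges": len(para),
        "n_families": len(families),
        "n_core": sum(1 for f in families if f.category == "core"),
        "n_dispensable": sum(1 for f in families if f.category == "dispensable"),
        "n_singleton": sum(1 for f in families if f.category == "singleton"),
    }
    for key, value in report.items():
        logger.info("%s = %s", key, value)
    return PangenomeResult(
        families=families,
        graph=refined,
        report=report,
        k=k,
        edges=edges,
        gene_ids=key_of,
    )
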