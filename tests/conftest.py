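"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the suffix-array machinery: k-mer statistics
are recomputed by direct substring hashing, betweenness by exhaustive
shortest-path enumeration, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
from collections import Counter
from fractions import Fraction

import pytest

from pandict.io import Gene, GeneSet


def make_genesets(spec: dict[str, dict[str, str]]) -> list[GeneSet]:
    """Build gene sets from {genome_id: {gene_id: sequence}}."""
    return [
        GeneSet(genome_id=gid, genes=[Gene(g, gid, s) for g, s in genes.items()])
        for gid, genes in spec.items()
    ]


def naive_kmer_counts(seq: str, k: int) -> Counter:
    """Multiplicity of every k-mer of one sequence, skipping masked 'X'."""
    counts: Counter = Counter()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "X" not in w:
            counts[w] += 1
    return counts


def naive_pair_stats(seq_i: str, seq_j: str, k: int) -> tuple[int, int, int] | None:
    """(a, cov_i, cov_j) over shared k-mers by direct hashing; None if disjoint."""
    ci = naive_kmer_counts(seq_i, k)
    cj = naive_kmer_counts(seq_j, k)
    shared = set(ci) & set(cj)
    if not shared:
        return None
    a = sum(min(ci[w], cj[w]) for w in shared)
    return a, sum(ci[w] for w in shared), sum(cj[w] for w in shared)


def naive_jaccard(seq_i: str, seq_j: str, k: int) -> Fraction:
    """Σmin / Σmax over the union of the two k-dictionaries."""
    ci = naive_kmer_counts(seq_i, k)
    cj = naive_kmer_counts(seq_j, k)
    num = sum(min(ci[w], cj[w]) for w in set(ci) | set(cj))
    den = sum(max(ci[w], cj[w]) for w in set(ci) | set(cj))
    return Fraction(num, den)


def oracle_edge_betweenness(graph) -> dict[tuple, float]:
    """Edge betweenness by exhaustive simple-path enumeration (tiny graphs).

    For every unordered vertex pair, all simple paths are enumerated, the
    shortest total 'distance' kept, and each minimal path contributes
    1/#minimal-paths to every edge it uses.
    """
    nodes = list(graph.nodes)
    bc: dict[tuple, float] = {tuple(sorted(e)): 0.0 for e in graph.edges}

    def all_simple_paths(s, t):
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                yield path
                continue
            for nb in graph[node]:
                if nb not in path:
                    stack.append((nb, path + [nb]))

    for s, t in itertools.combinations(nodes, 2):
        paths = list(all_simple_paths(s, t))
        if not paths:
            continue
        lengths = [
            sum(graph[u][v]["distance"] for u, v in zip(p, p[1:])) for p in paths
        ]
        best = min(lengths)
        minimal = [p for p, l in zip(paths, lengths) if l <= best + 1e-9]
        for p in minimal:
            for u, v in zip(p, p[1:]):
                bc[tuple(sorted((u, v)))] += 1.0 / len(minimal)
    return bc


@pytest.fixture
def two_gene_pair() -> list[GeneSet]:
    """The worked example pair: WLLPPP vs LLPP in two genomes."""
    return make_genesets({"GA": {"s": "WLLPPP"}, "GB": {"t": "LLPP"}})
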