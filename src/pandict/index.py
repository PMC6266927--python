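"""ESA-based k-mer indexing of many genes at once.

All genes are concatenated into one global string with a separator symbol at
every joint; an enhanced suffix array (suffix array + LCP array) over the
concatenation, augmented with a next-invalid-symbol distance array (NDIST)
and a per-suffix sequence identifier array (SID), recovers every k-mer of
every gene — with exact per-gene multiplicities — in a single linear sweep
over LCP intervals.  The separator (and the ambiguity placeholder 'X')
guarantees that no enumerated k-mer crosses a gene boundary: any suffix whose
first k symbols touch an invalid position has NDIST < k and is skipped.

From the sweep the module accumulates, per gene pair sharing at least one
k-mer, the sum of minimum multiplicities ``a`` and the two one-sided coverage
sums; these yield the generalized Jaccard similarity

    J_k(s, t) = a / (|s| + |t| - 2k + 2 - a)

and the directional dictionary-coverage fractions

    p_k(s -> t) = cov_s / (|s| - k + 1)

without ever comparing two sequences directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from numba import njit

from .io import STANDARD_AA, GeneSet

# integer codes: 0 = separator / invalid symbol, residues are 1..20 in
# alphabetical order so suffix order matches residue alphabetical order.
_CODE = np.zeros(128, dtype=np.int64)
for _i, _aa in enumerate(sorted(STANDARD_AA), start=1):
    _CODE[ord(_aa)] = _i
_DECODE = {i: aa for i, aa in enumerate(sorted(STANDARD_AA), start=1)}

SEPARATOR_CODE = 0


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), vectorized)."""
    n = codes.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    sa = np.argsort(codes, kind="stable")
    sorted_codes = codes[sa]
    dense = np.zeros(n, dtype=np.int64)
    if n > 1:
        dense[1:] = np.cumsum(sorted_codes[1:] != sorted_codes[:-1])
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = dense
    step = 1
    while dense[-1] != n - 1:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - step] = rank[step:]
        sa = np.lexsort((second, rank))
        r1, r2 = rank[sa], second[sa]
        changed = np.zeros(n, dtype=np.int64)
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        dense = np.cumsum(changed)
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = dense
        step *= 2
    return sa


@njit(cache=True)
def _kasai_lcp(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:  # pragma: no cover
    n = sa.size
    rank = np.empty(n, dtype=np.int64)
    for i in range(n):
        rank[sa[i]] = i
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def _ndist(codes: np.ndarray) -> np.ndarray:
    """Per position, the run length of valid symbols starting there.

    0 exactly at separator / invalid positions; the end of the string acts
    like a separator.
    """
    n = codes.size
    invalid = np.flatnonzero(codes == SEPARATOR_CODE)
    boundaries = np.append(invalid, n)
    nxt = boundaries[np.searchsorted(boundaries, np.arange(n))]
    return nxt - np.arange(n)


@dataclass
class ConcatenatedIndex:
    """Suffix array, LCP, NDIST and SID over all genes joined by separators."""

    codes: np.ndarray          # int64 global sequence (0 = separator/invalid)
    sa: np.ndarray             # suffix start positions, lexicographic order
    lcp: np.ndarray            # lcp[i] = LCP(suffix sa[i-1], suffix sa[i]); lcp[0]=0
    ndist: np.ndarray          # valid-run length per text position
    sid: np.ndarray            # gene index per text position (-1 at separators)
    gene_ids: list[tuple[str, str]]   # (genome_id, gene_id) per gene index
    gene_lengths: np.ndarray   # residues per gene index
    genome_index: np.ndarray   # genome index per gene index
    genome_ids: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def build_index(genesets: Sequence[GeneSet]) -> ConcatenatedIndex:
    """Index the concatenation s1·N·s2·N·…·N·sM of every gene of every genome."""
    genome_ids = [gs.genome_id for gs in genesets]
    gene_ids: list[tuple[str, str]] = []
    lengths: list[int] = []
    genome_index: list[int] = []
    chunks: list[np.ndarray] = []
    sids: list[np.ndarray] = []
    for gi, gs in enumerate(genesets):
        for gene in gs:
            idx = len(gene_ids)
            gene_ids.append(gene.key)
            lengths.append(gene.length)
            genome_index.append(gi)
            arr = _CODE[np.frombuffer(gene.sequence.encode("ascii"), dtype=np.uint8)]
            chunks.append(arr)
            sids.append(np.full(gene.length, idx, dtype=np.int64))
            chunks.append(np.array([SEPARATOR_CODE], dtype=np.int64))
            sids.append(np.array([-1], dtype=np.int64))
    if not gene_ids:
        raise ValueError("no genes to index")
    # drop the trailing separator
    codes = np.concatenate(chunks)[:-1]
    sid = np.concatenate(sids)[:-1]
    sa = _suffix_array(codes)
    lcp = _kasai_lcp(codes, sa)
    ndist = _ndist(codes)
    return ConcatenatedIndex(
        codes=codes,
        sa=sa,
        lcp=lcp,
        ndist=ndist,
        sid=sid,
        gene_ids=gene_ids,
        gene_lengths=np.asarray(lengths, dtype=np.int64),
        genome_index=np.asarray(genome_index, dtype=np.int64),
        genome_ids=genome_ids,
    )


@dataclass
class KmerInterval:
    """One distinct k-mer with its per-gene multiplicities."""

    kmer: str
    occurrences: dict[int, int]  # gene index -> multiplicity


def _interval_rows(index: ConcatenatedIndex, k: int):
    """(interval id, gene index) per valid suffix, in suffix-array order.

    Interval ids increase whenever the LCP with the previous suffix drops
    below k, so equal ids mean an identical leading k-mer; suffixes whose
    first k symbols touch a separator or 'X' (NDIST < k) are dropped.
    """
    group = np.cumsum(index.lcp < k)
    valid = index.ndist[index.sa] >= k
    return group[valid], index.sid[index.sa[valid]], index.sa[valid]


def enumerate_kmer_intervals(index: ConcatenatedIndex, k: int) -> Iterator[KmerInterval]:
    """Yield every distinct k-mer of the concatenation, lexicographically.

    Each k-mer is reported once with exact per-gene multiplicities; k-mers
    crossing gene boundaries or covering masked symbols never appear.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    groups, sids, positions = _interval_rows(index, k)
    i = 0
    n = groups.size
    while i < n:
        j = i
        occ: dict[int, int] = {}
        while j < n and groups[j] == groups[i]:
            occ[int(sids[j])] = occ.get(int(sids[j]), 0) + 1
            j += 1
        start = int(positions[i])
        kmer = "".join(_DECODE[int(c)] for c in index.codes[start : start + k])
        yield KmerInterval(kmer=kmer, occurrences=occ)
        i = j


@njit(cache=True)
def _pair_sweep(group: np.ndarray, sid: np.ndarray):  # pragma: no cover
    """Aggregate pair statistics over (interval, gene, count) runs.

    Input rows are sorted by (interval id, gene index).  For every unordered
    gene pair co-occurring in an interval the minimum multiplicity and both
    multiplicities are accumulated into hash maps keyed by i * n_genes + j.
    """
    n = group.size
    a_acc = {}
    ci_acc = {}
    cj_acc = {}
    # scale for the pair key: one more than the largest gene index
    base = np.int64(0)
    for i in range(n):
        if sid[i] > base:
            base = sid[i]
    base += 1
    i = 0
    # run-length encode (group, sid) into per-interval gene/count buffers
    genes = np.empty(64, dtype=np.int64)
    counts = np.empty(64, dtype=np.int64)
    while i < n:
        g = group[i]
        m = 0
        while i < n and group[i] == g:
            s = sid[i]
            c = 0
            while i < n and group[i] == g and sid[i] == s:
                c += 1
                i += 1
            if m == genes.size:
                genes = np.concatenate((genes, np.empty(genes.size, dtype=np.int64)))
                counts = np.concatenate((counts, np.empty(counts.size, dtype=np.int64)))
            genes[m] = s
            counts[m] = c
            m += 1
        for p in range(m):
            for q in range(p + 1, m):
                key = genes[p] * base + genes[q]
                mn = counts[p] if counts[p] < counts[q] else counts[q]
                if key in a_acc:
                    a_acc[key] += mn
                    ci_acc[key] += counts[p]
                    cj_acc[key] += counts[q]
                else:
                    a_acc[key] = mn
                    ci_acc[key] = counts[p]
                    cj_acc[key] = counts[q]
    out_keys = np.empty(len(a_acc), dtype=np.int64)
    out_a = np.empty(len(a_acc), dtype=np.int64)
    out_ci = np.empty(len(a_acc), dtype=np.int64)
    out_cj = np.empty(len(a_acc), dtype=np.int64)
    t = 0
    for key in a_acc:
        out_keys[t] = key
        out_a[t] = a_acc[key]
        out_ci[t] = ci_acc[key]
        out_cj[t] = cj_acc[key]
        t += 1
    return out_keys, out_a, out_ci, out_cj, base


@dataclass
class PairStats:
    """Sparse per-pair statistics at a fixed k.

    ``stats[(i, j)] = (a, cov_i, cov_j)`` with i < j: the sum of minimum
    multiplicities over shared k-mers, and each gene's total multiplicity
    over those same shared k-mers.  Pairs sharing no k-mer are absent.
    """

    k: int
    stats: dict[tuple[int, int], tuple[int, int, int]]

    def __len__(self) -> int:
        return len(self.stats)


def accumulate_stats(index: ConcatenatedIndex, k: int) -> PairStats:
    """One sweep over all k-mer intervals, filling the sparse M/P1/P2 maps."""
    if k < 1:
        raise ValueError("k must be >= 1")
    groups, sids, _ = _interval_rows(index, k)
    if groups.size == 0:
        return PairStats(k=k, stats={})
    # sort genes within each interval so runs are contiguous; interval order
    # is already non-decreasing in suffix-array order
    order = np.lexsort((sids, groups))
    keys, a, ci, cj, base = _pair_sweep(groups[order], sids[order])
    stats: dict[tuple[int, int], tuple[int, int, int]] = {}
    gi = keys // base
    gj = keys % base
    for t in range(keys.size):
        stats[(int(gi[t]), int(gj[t]))] = (int(a[t]), int(ci[t]), int(cj[t]))
    return PairStats(k=k, stats=stats)


def jaccard_from_stats(a: int, len_i: int, len_j: int, k: int) -> float:
    """Generalized Jaccard similarity from the sum of minima ``a``.

    Equals sum(min multiplicities) / sum(max multiplicities) over the union
    of the two k-dictionaries, because the total k-mer occurrences of the two
    sequences sum to |s| + |t| - 2k + 2.
    """
    num, den = jaccard_fraction(a, len_i, len_j, k)
    return num / den if num else 0.0


def jaccard_fraction(a: int, len_i: int, len_j: int, k: int) -> tuple[int, int]:
    """Exact (numerator, denominator) of the generalized Jaccard similarity."""
    if len_i < k or len_j < k:
        raise ValueError("sequence shorter than k")
    if not 0 <= a <= min(len_i, len_j) - k + 1:
        raise ValueError(f"a={a} outside [0, min(|s|,|t|)-k+1]")
    den = len_i + len_j - 2 * k + 2 - a
    return a, den


def coverage_from_stats(cov: int, length: int, k: int) -> float:
    """Fraction of a gene's k-mer occurrences that fall in the shared dictionary."""
    if length < k:
        raise ValueError("sequence shorter than k")
    total = length - k + 1
    if not 0 <= cov <= total:
        raise ValueError(f"coverage sum {cov} outside [0, {total}]")
    return cov / total


def dump_index(index: ConcatenatedIndex) -> str:
    """Debug TSV of the structure: i, SA, LCP, NDIST, SID, suffix head."""
    lines = ["i\tSA\tLCP\tNDIST\tSID\tsuffix"]
    for i in range(index.sa.size):
        p = int(index.sa[i])
        head = "".join(
            _DECODE.get(int(c), "N") for c in index.codes[p : p + 12]
        )
        lines.append(
            f"{i}\t{p}\t{int(index.lcp[i])}\t{int(index.ndist[p])}"
            f"\t{int(index.sid[p])}\t{head}"
        )
    return "\n".join(lines) + "\n"
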