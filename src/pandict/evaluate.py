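"""Scoring predicted gene families against a golden truth.

Families are compared as partitions of the gene universe through their sets
of within-family gene pairs (TP/FP/FN/TN and the F1 f-measure), and through
CDiff — the count of truth families split across several predictions plus
predicted families merging several truth families.  A composition-vector
cosine distance between proteomes provides an alignment-free phylogenetic
distance in [0, 1].
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .io import FamilyAssignment, GeneSet

GeneKey = tuple[str, str]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class PartitionDiff:
    split_count: int
    merge_count: int

    @property
    def cdiff(self) -> int:
        return self.split_count + self.merge_count


def pairwise_relations(
    families: Sequence[FamilyAssignment],
) -> set[frozenset[GeneKey]]:
    """All unordered within-family gene pairs; singletons contribute none."""
    seen: dict[GeneKey, int] = {}
    pairs: set[frozenset[GeneKey]] = set()
    for fam in families:
        members = sorted(fam.members)
        for m in members:
            if m in seen and seen[m] != fam.family_id:
                raise ValueError(f"gene {m} appears in more than one family")
            seen[m] = fam.family_id
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add(frozenset((members[i], members[j])))
    return pairs


def confusion_counts(
    predicted: Sequence[FamilyAssignment],
    golden: Sequence[FamilyAssignment],
    gene_universe: Sequence[GeneKey],
) -> ConfusionCounts:
    """Pairwise confusion over all C(G, 2) distinct gene pairs.

    The negative universe includes intra-genome pairs; TN is derived from
    the closed-form total rather than enumerated.
    """
    universe = set(gene_universe)
    for fams, name in ((predicted, "predicted"), (golden, "golden")):
        covered = {m for f in fams for m in f.members}
        if covered - universe:
            raise ValueError(f"{name} families mention genes outside the universe")
    p = pairwise_relations(predicted)
    g = pairwise_relations(golden)
    tp = len(p & g)
    fp = len(p - g)
    fn = len(g - p)
    total = len(universe) * (len(universe) - 1) // 2
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=total - tp - fp - fn)


def f_measure(counts: ConfusionCounts) -> float:
    """F1: harmonic mean of pairwise precision and recall, in [0, 1]."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        raise ValueError("f-measure undefined: no positive pairs predicted or true")
    return 2 * counts.tp / denom


def cdiff(
    predicted: Sequence[FamilyAssignment],
    golden: Sequence[FamilyAssignment],
    weighted: bool = False,
) -> PartitionDiff:
    """Count golden families split by the prediction and predicted families
    merging several golden ones.

    With ``weighted`` False (default) each offending family counts once; the
    alternative counts golden families not recovered exactly.
    """
    pred_of: dict[GeneKey, int] = {}
    for fam in predicted:
        for m in fam.members:
            pred_of[m] = fam.family_id
    gold_of: dict[GeneKey, int] = {}
    for fam in golden:
        for m in fam.members:
            gold_of[m] = fam.family_id
    if set(pred_of) != set(gold_of):
        raise ValueError("predicted and golden families cover different gene sets")

    if weighted:
        pred_sets = {frozenset(f.members) for f in predicted}
        missed = sum(1 for f in golden if frozenset(f.members) not in pred_sets)
        return PartitionDiff(split_count=missed, merge_count=0)

    split = sum(
        1 for fam in golden if len({pred_of[m] for m in fam.members}) >= 2
    )
    merge = sum(
        1 for fam in predicted if len({gold_of[m] for m in fam.members}) >= 2
    )
    return PartitionDiff(split_count=split, merge_count=merge)


def composition_vector(gs: GeneSet, k: int) -> Counter:
    """Aggregated k-mer counts over every gene of the genome."""
    counts: Counter = Counter()
    for gene in gs:
        seq = gene.sequence
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "X" not in w:
                counts[w] += 1
    return counts


def composition_distance(gs_a: GeneSet, gs_b: GeneSet, k: int) -> float:
    """1 − cosine similarity between k-mer composition vectors; in [0, 1]."""
    if k < 1:
        raise ValueError("k must be >= 1")
    va = composition_vector(gs_a, k)
    vb = composition_vector(gs_b, k)
    if not va or not vb:
        raise ValueError("empty k-mer dictionary")
    dot = sum(c * vb[w] for w, c in va.items())
    na = math.sqrt(sum(c * c for c in va.values()))
    nb = math.sqrt(sum(c * c for c in vb.values()))
    return 1.0 - dot / (na * nb)


def mean_composition_distance(genesets: Sequence[GeneSet], k: int) -> tuple[float, float]:
    """Mean and standard deviation of pairwise composition distances."""
    ds = []
    for i in range(len(genesets)):
        for j in range(i + 1, len(genesets)):
            ds.append(composition_distance(genesets[i], genesets[j], k))
    if not ds:
        raise ValueError("need at least two genomes")
    mean = sum(ds) / len(ds)
    var = sum((d - mean) ** 2 for d in ds) / len(ds)
    return mean, math.sqrt(var)
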