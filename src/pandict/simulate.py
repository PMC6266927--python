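"""Synthetic bacterial population evolution with truth-tracked gene families.

A population grows as an n-ary tree from a single ancestor genome.  Each
child genome is produced from its parent by vertical transmission with
per-gene loss, gain of entirely new genes (emulating horizontal acquisition),
per-residue variation of most transmitted genes, and rare duplication.
Every gene instance carries the identifier of its ancestral family, so the
true homology partition of any extracted sub-population is known exactly —
a golden truth for benchmarking family-detection methods.

Default rates per generation: 0.1% of genes lost, 1% new genes gained,
80% of transmitted genes varied at a configurable per-residue percentage
(typically 0.5% or 1%), and 0.01% of genes duplicated.  Event counts follow
per-gene Bernoulli draws (binomial in aggregate), so small genomes still
experience rare events at the right expected rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import STANDARD_AA, FamilyAssignment, Gene, GeneSet

_RESIDUES = sorted(STANDARD_AA)


@dataclass
class EvolutionParams:
    """Per-generation evolution rates.

    loss_rate, gain_rate, duplication_rate are per-gene probabilities;
    variation_fraction is the probability a transmitted gene is varied at
    all; locus_variation_pct is the fraction of its residues edited when it
    is (each edit a uniform choice of substitution, insertion or deletion).
    """

    loss_rate: float = 0.001
    gain_rate: float = 0.01
    variation_fraction: float = 0.8
    locus_variation_pct: float = 0.005
    duplication_rate: float = 0.0001
    min_offspring: int = 1
    max_offspring: int = 4
    min_gene_length: int = 13  # deletions never shrink a gene below this

    def __post_init__(self) -> None:
        for name in ("loss_rate", "gain_rate", "variation_fraction",
                     "locus_variation_pct", "duplication_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class TruthTable:
    """Ancestral family id per gene instance.

    New genes found new families; transmitted, varied and duplicated genes
    inherit the family of the gene they descend from.  Two genes are true
    homologs iff their family ids match.
    """

    family_of: dict[tuple[str, str], int] = field(default_factory=dict)
    next_family: int = 1

    def new_family(self) -> int:
        fid = self.next_family
        self.next_family += 1
        return fid

    def assign(self, genome_id: str, gene_id: str, family: int) -> None:
        self.family_of[(genome_id, gene_id)] = family


@dataclass
class PopulationTree:
    """The simulated population: genomes arranged as an n-ary lineage tree."""

    root: str
    genomes: dict[str, GeneSet]
    children: dict[str, list[str]]
    depth: dict[str, int]
    order: list[str]  # breadth-first generation order

    def leaves(self) -> list[str]:
        return [g for g in self.order if not self.children.get(g)]

    def newick(self) -> str:
        """Newick string with unit branch lengths per generation."""

        def rec(node: str) -> str:
            kids = self.children.get(node, [])
            if not kids:
                return f"{node}:1"
            inner = ",".join(rec(c) for c in kids)
            return f"({inner}){node}:1"

        kids = self.children.get(self.root, [])
        if not kids:
            return f"{self.root};"
        inner = ",".join(rec(c) for c in kids)
        return f"({inner}){self.root};"


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_RESIDUES, size=length))


def default_length_sampler(rng: np.random.Generator) -> int:
    """Log-normal gene length, clipped to 100–1500 residues.

    Median ~330 residues with heavy right tail, echoing the wide length
    variability of real bacterial gene sets.
    """
    return int(np.clip(round(rng.lognormal(math.log(330.0), 0.45)), 100, 1500))


def generate_ancestor(
    n_genes: int,
    seed: int | np.random.Generator = 0,
    length_sampler=default_length_sampler,
    genome_id: str = "ancestor",
    truth: TruthTable | None = None,
) -> tuple[GeneSet, TruthTable]:
    """Random ancestor gene set: i.i.d. residues, sampled lengths.

    Each ancestral gene founds its own truth family.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = truth or TruthTable()
    genes = []
    for i in range(1, n_genes + 1):
        gid = f"g{i:05d}"
        genes.append(
            Gene(gene_id=gid, genome_id=genome_id,
                 sequence=_random_sequence(rng, length_sampler(rng)))
        )
        truth.assign(genome_id, gid, truth.new_family())
    return GeneSet(genome_id=genome_id, genes=genes), truth


def _vary(seq: str, pct: float, rng: np.random.Generator, min_len: int) -> str:
    """Edit round(pct * len) positions, each a uniform sub/insert/delete."""
    n_edits = round(pct * len(seq))
    chars = list(seq)
    for _ in range(n_edits):
        op = rng.integers(3)
        if op == 0 or (op == 2 and len(chars) <= min_len):  # substitution
            pos = int(rng.integers(len(chars)))
            chars[pos] = _RESIDUES[int(rng.integers(20))]
        elif op == 1:  # insertion
            pos = int(rng.integers(len(chars) + 1))
            chars.insert(pos, _RESIDUES[int(rng.integers(20))])
        else:  # deletion
            pos = int(rng.integers(len(chars)))
            del chars[pos]
    return "".join(chars)


def evolve_child(
    parent: GeneSet,
    params: EvolutionParams,
    rng: np.random.Generator,
    truth: TruthTable,
    child_id: str,
    length_sampler=default_length_sampler,
) -> GeneSet:
    """One generation: transmit, lose, vary, duplicate, gain."""
    if len(parent) == 0:
        raise ValueError("parent genome is empty")
    genes: list[Gene] = []
    counter = 0

    def add(sequence: str, family: int) -> None:
        nonlocal counter
        counter += 1
        gid = f"g{counter:05d}"
        genes.append(Gene(gene_id=gid, genome_id=child_id, sequence=sequence))
        truth.assign(child_id, gid, family)

    for gene in parent:
        if rng.random() < params.loss_rate:
            continue
        family = truth.family_of[gene.key]
        seq = gene.sequence
        if params.variation_fraction > 0 and rng.random() < params.variation_fraction:
            seq = _vary(seq, params.locus_variation_pct, rng, params.min_gene_length)
        add(seq, family)
        if rng.random() < params.duplication_rate:
            add(seq, family)
    n_gain = rng.binomial(len(parent), params.gain_rate)
    for _ in range(n_gain):
        add(_random_sequence(rng, length_sampler(rng)), truth.new_family())
    return GeneSet(genome_id=child_id, genes=genes)


def generate_population(
    ancestor: GeneSet,
    size: int,
    params: EvolutionParams,
    truth: TruthTable,
    seed: int | np.random.Generator = 0,
    length_sampler=default_length_sampler,
) -> tuple[PopulationTree, TruthTable]:
    """Grow the population breadth-first to ``size`` genomes (ancestor included).

    Each node receives a uniform number of offspring in
    [min_offspring, max_offspring] until the target size is reached.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genomes = {ancestor.genome_id: ancestor}
    children: dict[str, list[str]] = {ancestor.genome_id: []}
    depth = {ancestor.genome_id: 0}
    order = [ancestor.genome_id]
    queue = [ancestor.genome_id]
    serial = 0
    while len(genomes) < size and queue:
        node = queue.pop(0)
        n_off = int(rng.integers(params.min_offspring, params.max_offspring + 1))
        for _ in range(n_off):
            if len(genomes) >= size:
                break
            serial += 1
            cid = f"N{serial:05d}"
            child = evolve_child(genomes[node], params, rng, truth, cid, length_sampler)
            genomes[cid] = child
            children[node].append(cid)
            children[cid] = []
            depth[cid] = depth[node] + 1
            order.append(cid)
            queue.append(cid)
    tree = PopulationTree(
        root=ancestor.genome_id, genomes=genomes, children=children,
        depth=depth, order=order,
    )
    return tree, truth


def extract_subpopulation(
    tree: PopulationTree, mode: str, count: int
) -> list[GeneSet]:
    """Pick the ``roots`` (minimal tree depth) or ``leaves`` (childless,
    deepest first) individuals; ties broken by generation order."""
    bfs_pos = {g: i for i, g in enumerate(tree.order)}
    if mode == "roots":
        ranked = sorted(tree.order, key=lambda g: (tree.depth[g], bfs_pos[g]))
    elif mode == "leaves":
        ranked = sorted(tree.leaves(), key=lambda g: (-tree.depth[g], bfs_pos[g]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if count > len(ranked):
        raise ValueError(f"requested {count} {mode}, only {len(ranked)} available")
    return [tree.genomes[g] for g in ranked[:count]]


def export_truth_families(
    truth: TruthTable, selected: Sequence[GeneSet]
) -> list[FamilyAssignment]:
    """Golden-truth families restricted to the selected genomes."""
    if not selected:
        raise ValueError("empty genome selection")
    per_family: dict[int, set[tuple[str, str]]] = {}
    for gs in selected:
        for gene in gs:
            fid = truth.family_of[gene.key]
            per_family.setdefault(fid, set()).add(gene.key)
    out = [
        FamilyAssignment.from_members(new_id, members, len(selected))
        for new_id, (_, members) in enumerate(sorted(per_family.items()), start=1)
    ]
    return out


def benchmark_population(
    n_genes: int = 500,
    size: int = 200,
    locus_variation_pct: float = 0.01,
    seed: int = 0,
    params: EvolutionParams | None = None,
) -> tuple[PopulationTree, TruthTable]:
    """Convenience constructor for the standard benchmark conditions."""
    params = params or EvolutionParams()
    params = replace(params, locus_variation_pct=locus_variation_pct)
    rng = np.random.default_rng(seed)
    ancestor, truth = generate_ancestor(n_genes, rng)
    return generate_population(ancestor, size, params, truth, rng)
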