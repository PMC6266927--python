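"""Gene family extraction by homology-network coherence refinement.

Candidate homology edges form an undirected weighted network whose connected
components are the starting families.  A component is *inconsistent* when it
holds two genes of the same genome that are not directly linked as paralogs;
such components are split by repeatedly removing the edge of highest
shortest-path betweenness (Girvan–Newman) until every part is consistent.
Edge weights (Jaccard similarities) are normalized by the component maximum
and converted to path distances as 1/weight, so strong similarity means a
short path.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Sequence

import networkx as nx

from .io import FamilyAssignment

_TIE_EPS = 1e-12


def build_graph(
    edges: Iterable[tuple[Hashable, Hashable, float, str]],
) -> nx.Graph:
    """Build the homology network from (u, v, weight, relation) records.

    Self loops are rejected; a duplicated edge is kept once but its weights
    must agree.
    """
    g = nx.Graph()
    for u, v, w, relation in edges:
        if u == v:
            raise ValueError(f"self loop on {u!r}")
        if not 0.0 < w <= 1.0:
            raise ValueError(f"edge weight {w} outside (0, 1]")
        if g.has_edge(u, v):
            if abs(g[u][v]["weight"] - w) > 1e-12:
                raise ValueError(f"conflicting weights for edge {u!r}-{v!r}")
            continue
        g.add_edge(u, v, weight=w, relation=relation)
    return g


def is_consistent(graph: nx.Graph, nodes: Iterable[Hashable]) -> bool:
    """True iff every same-genome gene pair among ``nodes`` shares an edge.

    Vertices are (genome_id, gene_id) pairs; two genes of one genome sitting
    in the same component without a direct paralog edge make it inconsistent.
    """
    per_genome: dict[str, list] = {}
    for node in nodes:
        per_genome.setdefault(node[0], []).append(node)
    for members in per_genome.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if not graph.has_edge(members[i], members[j]):
                    return False
    return True


def normalize_weights(graph: nx.Graph, nodes: Iterable[Hashable] | None = None) -> None:
    """Divide edge weights in the (sub)graph by their maximum, in place.

    Stores the result as ``norm_weight`` and the betweenness distance
    ``1/norm_weight`` as ``distance``; the strongest edge of the component
    gets norm_weight 1.
    """
    if nodes is None:
        nodes = list(graph.nodes)
    sub = graph.subgraph(nodes)
    if sub.number_of_edges() == 0:
        return
    wmax = max(d["weight"] for _, _, d in sub.edges(data=True))
    for u, v, d in sub.edges(data=True):
        nw = d["weight"] / wmax
        graph[u][v]["norm_weight"] = nw
        graph[u][v]["distance"] = 1.0 / nw


def _pick_edge_to_remove(sub: nx.Graph) -> tuple[Hashable, Hashable]:
    """Highest-betweenness edge; ties broken by lexicographic endpoint pair."""
    bc = nx.edge_betweenness_centrality(sub, weight="distance", normalized=False)
    best = max(bc.values())
    candidates = [
        tuple(sorted(e)) for e, b in bc.items() if b >= best - _TIE_EPS
    ]
    return min(candidates)


def refine_component(
    graph: nx.Graph, nodes: Iterable[Hashable] | None = None
) -> tuple[list[set[Hashable]], list[tuple[Hashable, Hashable]]]:
    """Split one component into consistent subgroups by Girvan–Newman.

    One edge is removed per iteration; after each removal the (possibly
    split) parts are re-normalized and re-checked.  Returns the consistent
    vertex sets and the removal sequence.  Terminates because the edge count
    strictly decreases and edgeless parts are always consistent.
    """
    if nodes is None:
        nodes = set(graph.nodes)
    work = graph.subgraph(nodes).copy()
    removed: list[tuple[Hashable, Hashable]] = []
    done: list[set[Hashable]] = []
    stack: list[set[Hashable]] = [set(work.nodes)]
    while stack:
        comp = stack.pop()
        if is_consistent(work, comp):
            done.append(comp)
            continue
        # two same-genome genes in a size-2 component are necessarily joined
        # by the one edge connecting them, hence consistent
        assert len(comp) > 2, "inconsistent two-vertex component is impossible"
        normalize_weights(work, comp)
        sub = work.subgraph(comp)
        u, v = _pick_edge_to_remove(sub)
        work.remove_edge(u, v)
        removed.append((u, v))
        for part in nx.connected_components(work.subgraph(comp)):
            stack.append(set(part))
    return done, removed


def refine_graph(graph: nx.Graph) -> nx.Graph:
    """Refine every inconsistent component; returns the refined network."""
    work = graph.copy()
    normalize_weights(work)
    for comp in list(nx.connected_components(graph)):
        parts, removed = refine_component(work, comp)
        for u, v in removed:
            work.remove_edge(u, v)
    return work


def extract_families(
    graph: nx.Graph,
    all_genes: Sequence[tuple[str, str]],
    n_genomes: int,
) -> list[FamilyAssignment]:
    """Families = consistent components plus singleton genes.

    Genes of the input universe that carry no surviving edge become
    singleton families; a family present in all genomes is core, otherwise
    dispensable (or singleton when it has a single member).
    """
    families: list[frozenset[tuple[str, str]]] = []
    in_graph: set[tuple[str, str]] = set()
    for comp in nx.connected_components(graph):
        members = frozenset(comp)
        in_graph.update(members)
        families.append(members)
    for key in all_genes:
        if key not in in_graph:
            families.append(frozenset([key]))
    families.sort(key=lambda m: sorted(m)[0])
    out = []
    for fid, members in enumerate(families, start=1):
        fam = FamilyAssignment.from_members(fid, members, n_genomes)
        if not is_consistent(graph, members):
            raise AssertionError(f"family {fid} is not consistent")
        out.append(fam)
    return out


def export_edge_list(graph: nx.Graph) -> list[tuple[str, str, str, str, float, str]]:
    """Edge list rows (genome_i, gene_i, genome_j, gene_j, weight, relation)."""
    rows = []
    for u, v, d in graph.edges(data=True):
        a, b = sorted((u, v))
        rows.append((a[0], a[1], b[0], b[1], d["weight"], d.get("relation", "")))
    rows.sort()
    return rows
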