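"""Overlapping link communities and dietary-network assembly.

Communities are detected on *edges* rather than nodes, so a food group can
belong to several communities at once (butter can sit both with animal fats
and with breakfast items). Adjacent edges (i,k) and (j,k) are scored by the
Jaccard similarity of the inclusive neighborhoods of their unshared
endpoints, n+(x) = {x} + neighbors(x); non-adjacent edges have similarity 0.
Single-linkage agglomeration of edges produces a dendrogram, which is cut
where the partition density

    D = (2/M) * sum_c m_c (m_c - n_c + 1) / ((n_c - 2)(n_c - 1))

is maximal (m_c edges, n_c nodes per community; two-node communities
contribute 0). Connected unions of communities with at least three food
groups form dietary networks; the food belonging to the most communities is
the network's central food.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import networkx as nx

from .ggm import PartialCorrelationNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeDendrogram",
    "LinkCommunitySet",
    "DietaryNetwork",
    "edge_similarity",
    "cluster_edges",
    "partition_density",
    "cut_at_max_density",
    "community_centrality",
    "assemble_networks",
]

Edge = tuple


def _as_edge_list(network) -> list[Edge]:
    if isinstance(network, PartialCorrelationNetwork):
        edges = network.edge_tuples()
    else:
        edges = [tuple(sorted(e)) for e in network]
    if len(set(edges)) != len(edges):
        raise ValueError("duplicate edges in network")
    return sorted(edges)


def _adjacency(edges: list[Edge]) -> dict:
    nbrs: dict = {}
    for u, v in edges:
        nbrs.setdefault(u, set()).add(v)
        nbrs.setdefault(v, set()).add(u)
    return nbrs


@dataclasses.dataclass
class EdgeDendrogram:
    """Single-linkage merge sequence over the edges of a network.

    ``merges`` lists (edge_a, edge_b, similarity) in agglomeration order:
    merging the clusters currently containing edge_a and edge_b at that
    similarity. Similarities are non-increasing along the sequence.
    """

    leaves: list
    merges: list

    def __post_init__(self):
        sims = [s for _, _, s in self.merges]
        if any(b > a + 1e-12 for a, b in zip(sims, sims[1:])):
            raise ValueError("merge similarities must be non-increasing")


@dataclasses.dataclass
class LinkCommunitySet:
    """Edge partition at the chosen dendrogram cut."""

    communities: list  # list of frozensets of edges
    nodes: list
    cut_similarity: float
    density: float

    @property
    def node_membership(self) -> dict:
        member: dict = {n: set() for n in self.nodes}
        for cid, comm in enumerate(self.communities):
            for u, v in comm:
                member[u].add(cid)
                member[v].add(cid)
        return member


@dataclasses.dataclass
class DietaryNetwork:
    """A connected assembly of link communities with >= 3 food groups."""

    name: str
    community_ids: list
    nodes: list
    edges: list
    central: list  # central food(s): max community membership
    centrality: dict  # node -> membership count
    loadings: dict | None = None  # filled by network scoring


def edge_similarity(network, e1: Edge, e2: Edge) -> float:
    """Jaccard similarity of two edges' inclusive endpoint neighborhoods.

    Edges sharing node k compare n+(i) and n+(j) of the unshared endpoints;
    edges with no shared node score 0.
    """
    edges = _as_edge_list(network)
    e1, e2 = tuple(sorted(e1)), tuple(sorted(e2))
    if e1 == e2:
        raise ValueError("edges must differ")
    for e in (e1, e2):
        if e not in edges:
            raise ValueError(f"edge {e} not in network")
    shared = set(e1) & set(e2)
    if not shared:
        return 0.0
    nbrs = _adjacency(edges)
    (i,) = set(e1) - shared
    (j,) = set(e2) - shared
    ni = nbrs[i] | {i}
    nj = nbrs[j] | {j}
    return len(ni & nj) / len(ni | nj)


def _adjacent_pair_similarities(edges: list[Edge]) -> list[tuple[float, Edge, Edge]]:
    """Similarity of every adjacent edge pair, sorted for deterministic merging."""
    nbrs = _adjacency(edges)
    incl = {x: nbrs[x] | {x} for x in nbrs}
    incident: dict = {}
    for e in edges:
        for x in e:
            incident.setdefault(x, []).append(e)
    pairs = set()
    for k, inc in incident.items():
        for e1, e2 in itertools.combinations(sorted(inc), 2):
            pairs.add((e1, e2, k))
    sims = []
    for e1, e2, k in pairs:
        (i,) = set(e1) - {k}
        (j,) = set(e2) - {k}
        if i == j:  # parallel edges cannot occur in a simple graph
            continue
        sim = len(incl[i] & incl[j]) / len(incl[i] | incl[j])
        sims.append((sim, e1, e2))
    # Descending similarity; lexicographic edge order breaks ties.
    sims.sort(key=lambda t: (-t[0], t[1], t[2]))
    return sims


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def cluster_edges(network) -> EdgeDendrogram:
    """Single-linkage agglomerative clustering of edges by similarity.

    Non-adjacent edge pairs have similarity 0, so disconnected pieces merge
    only at the final zero-similarity level. Deterministic: ties are merged
    in lexicographic edge order.
    """
    edges = _as_edge_list(network)
    if len(edges) < 2:
        logger.warning("fewer than 2 edges: trivial dendrogram")
        return EdgeDendrogram(leaves=edges, merges=[])
    merges = []
    uf = _UnionFind(edges)
    n_clusters = len(edges)
    for sim, e1, e2 in _adjacent_pair_similarities(edges):
        if uf.union(e1, e2):
            merges.append((e1, e2, sim))
            n_clusters -= 1
    # Remaining clusters (disconnected components) merge at similarity 0.
    if n_clusters > 1:
        reps = sorted({uf.find(e) for e in edges})
        for other in reps[1:]:
            merges.append((reps[0], other, 0.0))
    return EdgeDendrogram(leaves=edges, merges=merges)


def partition_density(communities, total_edges: int) -> float:
    """Average within-community link density over an edge partition.

    Each community is normalized between a tree (D_c = 0) and a clique
    (D_c = 1) on its node set; single-edge communities contribute 0.
    """
    seen: set = set()
    m_total = 0
    acc = 0.0
    for comm in communities:
        comm = set(tuple(sorted(e)) for e in comm)
        if comm & seen:
            raise ValueError("communities overlap in edges; must partition the edge set")
        seen |= comm
        m_c = len(comm)
        m_total += m_c
        nodes = set(itertools.chain.from_iterable(comm))
        n_c = len(nodes)
        if n_c <= 2:
            continue
        acc += m_c * (m_c - n_c + 1) / ((n_c - 2) * (n_c - 1))
    if m_total != total_edges:
        raise ValueError(f"communities cover {m_total} edges, expected {total_edges}")
    if total_edges == 0:
        return 0.0
    return 2.0 * acc / total_edges


def cut_at_max_density(dendrogram: EdgeDendrogram, total_edges: int | None = None) -> LinkCommunitySet:
    """Cut the edge dendrogram at the partition-density maximum.

    Every distinct merge similarity defines a candidate partition (all
    merges at or above that similarity applied); the all-singletons
    partition (D = 0) is the baseline. Ties go to the higher similarity,
    i.e. more and smaller communities.
    """
    edges = list(dendrogram.leaves)
    m = len(edges) if total_edges is None else total_edges
    if m != len(edges):
        raise ValueError("total_edges does not match dendrogram leaves")
    nodes = sorted(set(itertools.chain.from_iterable(edges)))
    if m == 0:
        return LinkCommunitySet([], nodes, 1.0, 0.0)

    uf = _UnionFind(edges)

    def current_partition():
        groups: dict = {}
        for e in edges:
            groups.setdefault(uf.find(e), set()).add(e)
        return [frozenset(g) for g in groups.values()]

    best = (0.0, 1.0, current_partition())  # (density, cut similarity, partition)
    i = 0
    merges = dendrogram.merges
    while i < len(merges):
        sim = merges[i][2]
        while i < len(merges) and merges[i][2] == sim:
            uf.union(merges[i][0], merges[i][1])
            i += 1
        part = current_partition()
        d = partition_density(part, m)
        if d > best[0] + 1e-12:
            best = (d, sim, part)
    density, cut_sim, part = best
    part = sorted(part, key=lambda c: sorted(c))
    return LinkCommunitySet(communities=part, nodes=nodes, cut_similarity=cut_sim, density=density)


def community_centrality(communities: LinkCommunitySet, node) -> int:
    """Number of communities containing an edge incident to ``node``."""
    if node not in communities.nodes:
        raise KeyError(f"unknown node: {node!r}")
    return len(communities.node_membership[node])


def assemble_networks(
    communities: LinkCommunitySet,
    partials: PartialCorrelationNetwork | None = None,
    *,
    min_nodes: int = 3,
) -> list[DietaryNetwork]:
    """Assemble dietary networks from the detected link communities.

    Networks are the connected components of the union of all community
    edges; components with fewer than ``min_nodes`` food groups are dropped
    (a lone conditional dependence is not a dietary pattern). Within each
    network the central food maximizes community membership; ties break by
    the largest total |partial correlation| over incident edges. Networks
    are named by size rank and may be renamed by the analyst (e.g.
    "healthy", "unhealthy", "saturated fats").
    """
    if not communities.communities:
        logger.warning("empty community set: no dietary networks")
        return []
    union = nx.Graph()
    edge_comms: dict = {}
    for cid, comm in enumerate(communities.communities):
        for e in comm:
            union.add_edge(*e)
            edge_comms[tuple(sorted(e))] = cid
    membership = communities.node_membership

    components = sorted(nx.connected_components(union), key=lambda c: (-len(c), sorted(c)))
    networks = []
    rank = 0
    for comp in components:
        if len(comp) < min_nodes:
            logger.info("dropping %d-node component %s (< %d nodes)", len(comp), sorted(comp), min_nodes)
            continue
        rank += 1
        sub = union.subgraph(comp)
        edges = sorted(tuple(sorted(e)) for e in sub.edges())
        cids = sorted({edge_comms[e] for e in edges})
        centrality = {n: len(membership[n]) for n in sorted(comp)}
        top = max(centrality.values())

        def weight_degree(n):
            if partials is None:
                return sub.degree(n)
            return sum(abs(partials.edge_weight(n, v)) for v in sub.neighbors(n))

        candidates = [n for n, c in centrality.items() if c == top]
        best_w = max(weight_degree(n) for n in candidates)
        central = sorted(n for n in candidates if weight_degree(n) >= best_w - 1e-12)
        networks.append(
            DietaryNetwork(
                name=f"network_{rank}",
                community_ids=cids,
                nodes=sorted(comp),
                edges=edges,
                central=central,
                centrality=centrality,
            )
        )
    return networks
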