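"""Interactome computations: minimum-order subnetwork extraction and clustering.

Minimum-order subnetwork
------------------------
Given seed proteins on an interactome, the goal is the smallest connected
subnetwork containing all seeds, with non-seed "connector" proteins added
only where needed to bridge seeds — a node-weighted Steiner problem on an
unweighted graph. Seeds falling in different graph components are handled
per component; a seed sharing no component with another seed is reported
isolated. Within a component, small instances (at most
``EXACT_CANDIDATE_LIMIT`` candidate connectors) are solved exactly by
enumerating connector subsets in increasing size; larger instances use the
Takahashi-Matsuyama shortest-path heuristic started from every seed, followed
by removal of redundant connectors. All tie-breaks are by symbol order, so
the result is deterministic. Finally every graph edge among the selected
nodes is included, so the subnetwork is the induced subgraph.

Clustering
----------
``graph_kmeans`` embeds proteins by classical multidimensional scaling of
their pairwise shortest-path distances (unreachable pairs get the finite
penalty ``graph diameter + 1``) and partitions the embedding with Lloyd's
k-means (multiple restarts, fixed seed). Cluster labels are canonicalized by
each cluster's alphabetically smallest member.
"""

from __future__ import annotations

import itertools
import warnings
from collections import deque
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans

from ._utils import normalize_symbols, substream
from .errors import ValidationError
from .enrichment import EnrichmentRecord, run_ora
from .io import GeneSetCollection, InteractionGraph

#: exact Steiner search is used when a component has at most this many
#: candidate connector nodes (2^15 subsets worst case, with early exit)
EXACT_CANDIDATE_LIMIT = 14


@dataclass(frozen=True)
class MinimumOrderNetwork:
    """Seeds plus bridging connectors forming a connected PPI subnetwork."""

    seeds: tuple[str, ...]            # input proteins found in the graph
    connectors: tuple[str, ...]       # added bridging proteins
    edges: tuple[tuple[str, str], ...]
    dropped_seeds: tuple[str, ...]    # inputs absent from the graph
    isolated_seeds: tuple[str, ...]   # in-graph seeds with no co-component seed

    @property
    def nodes(self) -> set[str]:
        return (set(self.seeds) - set(self.isolated_seeds)) | set(self.connectors)


@dataclass(frozen=True)
class ClusterAssignment:
    """k-means partition of proteins on the interactome."""

    labels: dict[str, int]
    k: int
    inertia: float
    seed: int


@dataclass(frozen=True)
class NetworkEnrichment:
    """ORA of a subnetwork's node set, with seed/connector roles per record."""

    records: tuple[EnrichmentRecord, ...]
    seed_members: dict[str, tuple[str, ...]]       # set_id -> overlapping seeds
    connector_members: dict[str, tuple[str, ...]]  # set_id -> overlapping connectors


# ---------------------------------------------------------------------------
# minimum-order subnetwork
# ---------------------------------------------------------------------------

def _induced_connected(g: nx.Graph, nodes: set[str]) -> bool:
    """Is the subgraph induced by ``nodes`` connected (nodes assumed non-empty)?"""
    start = next(iter(nodes))
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in g.adj[u]:
            if v in nodes and v not in seen:
                seen.add(v)
                queue.append(v)
    return len(seen) == len(nodes)


def _exact_minimum(g: nx.Graph, seeds: set[str], candidates: list[str]) -> set[str]:
    """Smallest seed-connecting node set by subset enumeration (size order,
    lexicographic within a size)."""
    for size in range(len(candidates) + 1):
        for extra in itertools.combinations(candidates, size):
            nodes = seeds | set(extra)
            if _induced_connected(g, nodes):
                return nodes
    raise AssertionError("component is connected; full candidate set must work")


def _multi_source_bfs(g: nx.Graph, sources: set[str]):
    """BFS from a node set with deterministic (sorted) expansion order."""
    dist = {s: 0 for s in sorted(sources)}
    parent: dict[str, str] = {}
    queue = deque(sorted(sources))
    while queue:
        u = queue.popleft()
        for v in sorted(g.adj[u]):
            if v not in dist:
                dist[v] = dist[u] + 1
                parent[v] = u
                queue.append(v)
    return dist, parent


def _takahashi_matsuyama(g: nx.Graph, seeds: set[str]) -> set[str]:
    """Grow a Steiner tree by repeatedly attaching the nearest unconnected
    seed via its shortest path; best result over every start seed."""
    best: set[str] | None = None
    for start in sorted(seeds):
        tree = {start}
        remaining = set(seeds) - {start}
        while remaining:
            dist, parent = _multi_source_bfs(g, tree)
            target = min(remaining, key=lambda s: (dist[s], s))
            node = target
            while node not in tree:
                tree.add(node)
                node = parent[node]
            remaining -= tree
        if best is None or (len(tree), sorted(tree)) < (len(best), sorted(best)):
            best = tree
    assert best is not None
    return best


def _prune_connectors(g: nx.Graph, seeds: set[str], selected: set[str]) -> set[str]:
    """Drop connectors whose removal keeps the induced subnetwork connected."""
    selected = set(selected)
    changed = True
    while changed:
        changed = False
        for c in sorted(selected - seeds):
            trial = selected - {c}
            if _induced_connected(g, trial):
                selected = trial
                changed = True
                break
    return selected


def minimum_order(graph: InteractionGraph, seeds: Iterable[str]) -> MinimumOrderNetwork:
    """Extract the minimum-order connected subnetwork spanning the seeds.

    Raises if fewer than two seeds are present in the graph. Returns the
    in-graph seeds, the bridging connectors, all induced edges among the
    selected nodes, the seeds absent from the graph, and the seeds isolated
    in their own component.
    """
    g = graph.graph
    requested = normalize_symbols(seeds)
    present = sorted(s for s in requested if s in g)
    dropped = tuple(sorted(requested - set(present)))
    if dropped:
        warnings.warn(f"minimum_order: {len(dropped)} seed(s) absent from graph")
    if len(present) < 2:
        raise ValidationError("minimum_order: need at least 2 seeds present in graph")

    comp_of: dict[str, int] = {}
    components: list[set[str]] = []
    for ci, comp in enumerate(nx.connected_components(g)):
        components.append(set(comp))
        for node in comp:
            comp_of[node] = ci

    seeds_by_comp: dict[int, set[str]] = {}
    for s in present:
        seeds_by_comp.setdefault(comp_of[s], set()).add(s)

    selected: set[str] = set()
    isolated: list[str] = []
    for ci in sorted(seeds_by_comp):
        comp_seeds = seeds_by_comp[ci]
        if len(comp_seeds) == 1:
            isolated.extend(comp_seeds)
            continue
        comp_nodes = components[ci]
        candidates = sorted(comp_nodes - comp_seeds)
        if len(candidates) <= EXACT_CANDIDATE_LIMIT:
            chosen = _exact_minimum(g, comp_seeds, candidates)
        else:
            chosen = _prune_connectors(
                g, comp_seeds, _takahashi_matsuyama(g, comp_seeds)
            )
        selected |= chosen

    edges = tuple(sorted(tuple(sorted(e)) for e in g.subgraph(selected).edges()))
    connectors = tuple(sorted(selected - set(present)))
    return MinimumOrderNetwork(
        seeds=tuple(present),
        connectors=connectors,
        edges=edges,
        dropped_seeds=dropped,
        isolated_seeds=tuple(sorted(isolated)),
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _classical_mds(D: np.ndarray) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix; keeps positive modes."""
    m = len(D)
    J = np.eye(m) - np.full((m, m), 1.0 / m)
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > max(eigvals[0], 0.0) * 1e-9
    if not keep.any():
        return np.zeros((m, 1))
    return eigvecs[:, keep] * np.sqrt(eigvals[keep])


def _graph_penalty_distance(g: nx.Graph) -> int:
    """Finite stand-in distance for unreachable pairs: graph diameter + 1."""
    diam = 0
    for comp in nx.connected_components(g):
        if len(comp) > 1:
            diam = max(diam, nx.diameter(g.subgraph(comp)))
    return diam + 1


def graph_kmeans(graph: InteractionGraph, proteins: Iterable[str], k: int = 4,
                 seed: int = 0) -> ClusterAssignment:
    """Partition proteins into ``k`` clusters from shortest-path geometry.

    Proteins are embedded by classical MDS of their pairwise shortest-path
    distances on the graph (unreachable pairs get the penalty distance
    ``diameter + 1``), then clustered with Lloyd's k-means using 10 random
    restarts from the given seed. Deterministic for fixed
    ``(graph, proteins, k, seed)``.
    """
    g = graph.graph
    prots = sorted(normalize_symbols(proteins))
    missing = [p for p in prots if p not in g]
    if missing:
        raise ValidationError(
            f"graph_kmeans: protein(s) absent from graph: {missing[:5]}"
        )
    m = len(prots)
    if not 1 <= k <= m:
        raise ValidationError("k: must lie between 1 and the number of proteins")

    D = np.full((m, m), np.nan)
    index = {p: i for i, p in enumerate(prots)}
    for i, p in enumerate(prots):
        lengths = nx.single_source_shortest_path_length(g, p)
        for q, d in lengths.items():
            j = index.get(q)
            if j is not None:
                D[i, j] = d
    if np.isnan(D).any():
        D = np.where(np.isnan(D), float(_graph_penalty_distance(g)), D)

    if k == m:
        labels = {p: i for i, p in enumerate(prots)}
        return ClusterAssignment(labels, k, 0.0, seed)

    X = _classical_mds(D)
    km_seed = int(substream(seed, "graph_kmeans").integers(2 ** 31))
    km = KMeans(n_clusters=k, n_init=10, random_state=km_seed).fit(X)

    # canonicalize: cluster containing the smallest symbol becomes label 0, etc.
    first_member: dict[int, str] = {}
    for p, lab in zip(prots, km.labels_):
        first_member.setdefault(int(lab), p)
    remap = {
        old: new
        for new, old in enumerate(sorted(first_member, key=first_member.get))
    }
    labels = {p: remap[int(lab)] for p, lab in zip(prots, km.labels_)}
    return ClusterAssignment(labels, k, float(km.inertia_), seed)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_network(net: MinimumOrderNetwork, coll: GeneSetCollection,
                     universe: Iterable[str], **ora_kwargs) -> NetworkEnrichment:
    """ORA of the subnetwork node set (seeds plus connectors).

    Delegates entirely to :func:`anchorsig.enrichment.run_ora`; per record the
    overlapping genes are split into seed and connector members.
    """
    seeds = set(net.seeds)
    connectors = set(net.connectors)
    query = seeds | connectors
    records = run_ora(query, coll, universe, **ora_kwargs)
    seed_members = {
        r.set_id: tuple(g for g in r.overlap_genes if g in seeds) for r in records
    }
    connector_members = {
        r.set_id: tuple(g for g in r.overlap_genes if g in connectors)
        for r in records
    }
    return NetworkEnrichment(tuple(records), seed_members, connector_members)
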