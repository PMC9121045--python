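"""Module detection on ego nets, with and without dimension-layer expansion.

Modules (communities) are detected on the *alter–alter* subgraph only: the
ego, being linked to every alter, belongs to every module and is excluded
from clustering, then re-attached for reporting.  Alters without
alter–alter links each form a singleton module of their own.

Detection is a greedy Louvain-style modularity maximization written for
reproducibility: node sweeps run in ascending node order with deterministic
tie-breaking, plus a fixed number of seeded random-order restarts, and the
best-Q partition is returned.  Identical input and seed always give an
identical assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import EgoNet, EgotrophError, TrophicLink
from . import descriptors


@dataclass(frozen=True)
class ModulePartition:
    """A non-overlapping assignment of alters to modules.

    ``n_multi`` counts modules with at least two alters, ``n_singleton``
    the one-alter modules (alters with no alter–alter links, which pair
    only with the ego); ``n_modules = n_multi + n_singleton`` is N_m.
    ``q`` is the modularity of the partition on the alter–alter subgraph
    (0 by convention when that subgraph has no links).
    """

    assignment: dict
    n_multi: int
    n_singleton: int
    n_modules: int
    q: float
    alter_ids: frozenset

    def modules(self) -> dict:
        out: dict = {}
        for node, label in self.assignment.items():
            out.setdefault(label, set()).add(node)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.assignment.items())
        return pd.DataFrame(rows, columns=["node", "module"])


# ---------------------------------------------------------------------------
# greedy modularity maximization (Louvain)


def _one_level(adj, self_w, degree, m2, order, resolution, rng=None):
    """One Louvain local-moving phase; returns node -> community."""
    comm = {u: u for u in order}
    tot = {u: degree[u] for u in order}
    improved = True
    while improved:
        improved = False
        if rng is not None:
            order = [order[i] for i in rng.permutation(len(order))]
        for u in order:
            cu = comm[u]
            w2c: dict = {}
            for v, w in adj[u].items():
                w2c[comm[v]] = w2c.get(comm[v], 0.0) + w
            tot[cu] -= degree[u]
            best_c, best_gain = cu, w2c.get(cu, 0.0) - resolution * tot[cu] * degree[u] / m2
            for c in sorted(w2c):
                if c == cu:
                    continue
                gain = w2c[c] - resolution * tot[c] * degree[u] / m2
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            tot[best_c] += degree[u]
            if best_c != cu:
                comm[u] = best_c
                improved = True
    return comm


def _aggregate(adj, self_w, comm):
    """Collapse communities into super-nodes; returns (adj, self_w)."""
    new_adj: dict = {}
    new_self: dict = {}
    for u, neighbors in adj.items():
        cu = comm[u]
        new_adj.setdefault(cu, {})
        new_self[cu] = new_self.get(cu, 0.0) + self_w.get(u, 0.0)
        for v, w in neighbors.items():
            cv = comm[v]
            if cu == cv:
                if u < v:  # each internal edge once
                    new_self[cu] = new_self.get(cu, 0.0) + w
            else:
                new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
    return new_adj, new_self


def _louvain_once(graph: nx.Graph, resolution: float, rng=None) -> dict:
    """Full multi-level Louvain pass.

    Without ``rng`` every sweep runs in ascending node order (the
    deterministic reference pass); with it, the node order is reshuffled
    at each aggregation level.
    """
    adj = {u: {v: 1.0 for v in graph[u]} for u in graph}
    self_w = {u: 0.0 for u in graph}
    membership = {u: u for u in graph}
    while True:
        degree = {
            u: 2.0 * self_w[u] + sum(adj[u].values()) for u in adj
        }
        m2 = sum(degree.values())
        if m2 <= 0:
            break
        level_order = sorted(adj)
        comm = _one_level(adj, self_w, degree, m2, level_order, resolution, rng=rng)
        labels = sorted(set(comm.values()))
        if len(labels) == len(adj):  # no merge happened; converged
            break
        membership = {node: comm[membership[node]] for node in membership}
        adj, self_w = _aggregate(adj, self_w, comm)
    return membership


def _louvain(graph: nx.Graph, seed: int, resolution: float, n_restarts: int) -> list:
    """Best-of-restarts Louvain; returns a list of frozensets (communities)."""
    rng = np.random.default_rng(seed)
    best_partition, best_q = None, -np.inf
    for restart in range(max(1, n_restarts)):
        membership = _louvain_once(graph, resolution,
                                   rng=None if restart == 0 else rng)
        groups: dict = {}
        for node, label in membership.items():
            groups.setdefault(label, set()).add(node)
        partition = [frozenset(g) for g in groups.values()]
        q = nx.community.modularity(graph, partition, resolution=resolution)
        if q > best_q + 1e-12:  # strict improvement; earliest restart wins ties
            best_partition, best_q = partition, q
    return best_partition


def detect_modules(
    net: EgoNet,
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 16,
) -> ModulePartition:
    """Detect modules on the undirected alter–alter subgraph of an ego net.

    Alters with no alter–alter links are singleton modules by definition
    (each forms a module with the ego alone); the remaining alters are
    partitioned by greedy modularity maximization at the given
    ``resolution`` (1 = classic modularity).  Module labels are ``M1``,
    ``M2``, … in order of each module's smallest member id.
    """
    sub = net.alter_subgraph()
    isolated = sorted(n for n in sub if sub.degree(n) == 0)
    core = sub.subgraph(n for n in sub if sub.degree(n) > 0)
    if core.number_of_edges() == 0:
        warnings.warn(
            "alter-alter subgraph has no links; modularity Q set to 0 by convention",
            stacklevel=2,
        )
        groups = []
        q = 0.0
    else:
        groups = _louvain(core, seed=seed, resolution=resolution,
                          n_restarts=n_restarts)
        q = nx.community.modularity(
            sub, groups + [{n} for n in isolated], resolution=resolution
        )
    groups = groups + [frozenset((n,)) for n in isolated]
    groups.sort(key=lambda g: min(g))
    assignment = {
        node: f"M{i + 1}" for i, group in enumerate(groups) for node in group
    }
    sizes = [len(g) for g in groups]
    n_multi = sum(1 for s in sizes if s >= 2)
    n_singleton = sum(1 for s in sizes if s == 1)
    return ModulePartition(
        assignment=assignment,
        n_multi=n_multi,
        n_singleton=n_singleton,
        n_modules=n_multi + n_singleton,
        q=q,
        alter_ids=net.alter_ids,
    )


def module_census(partition: ModulePartition, n_alters: int) -> tuple:
    """(N_m, M_ratio) for a partition; M_ratio uses the original alter count."""
    return partition.n_modules, descriptors.module_ratio(partition.n_modules, n_alters)


# ---------------------------------------------------------------------------
# dimension-layer expansion


@dataclass(frozen=True)
class LayeredEgoNet:
    """An ego net expanded along the habitat × interaction-type dimensions.

    Each taxon is replicated into one copy per (habitat, interaction-type)
    context in which it has at least one link; each original link maps to
    exactly one link between copies.  Copies of the same taxon are *not*
    linked to each other.  Copy ids read ``taxon@habitat@type``.
    """

    layered_nodes: frozenset
    layered_links: tuple
    back_map: dict
    ego_id: str

    @property
    def n_layered_alters(self) -> int:
        return sum(1 for copy, taxon in self.back_map.items() if taxon != self.ego_id)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for copy in sorted(self.layered_nodes):
            g.add_node(copy, taxon=self.back_map[copy])
        for src, dst, habitat, itype in self.layered_links:
            g.add_edge(src, dst, habitat=habitat, interaction_type=itype)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)


def _copy_id(taxon: str, link: TrophicLink) -> str:
    return f"{taxon}@{link.habitat}@{link.interaction_type}"


def expand_layers(net: EgoNet) -> LayeredEgoNet:
    """Replicate taxa into per-(habitat, interaction-type) node copies.

    A taxon eaten as carrion on land, preyed upon on land, and hunting at
    sea gets three copies.  The number of layered links always equals the
    original E; no links are invented between copies of one taxon.
    """
    nodes = set()
    links = []
    back_map = {}
    for link in net.links:
        src = _copy_id(link.consumer_id, link)
        dst = _copy_id(link.resource_id, link)
        nodes.update((src, dst))
        back_map[src] = link.consumer_id
        back_map[dst] = link.resource_id
        links.append((src, dst, link.habitat, link.interaction_type))
    return LayeredEgoNet(
        layered_nodes=frozenset(nodes),
        layered_links=tuple(links),
        back_map=back_map,
        ego_id=net.ego_id,
    )
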