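"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths they check: betweenness is
counted by enumerating every shortest path, fragmentation by building an
explicit pairwise-reachability matrix, and modularity optima by exhaustive
set-partition search.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import egotroph as et
from egotroph.synthetic import EGO_ID, GeneratorParams


@pytest.fixture(scope="session")
def toy_tables():
    return et.make_toy_net()


@pytest.fixture(scope="session")
def toy_net(toy_tables):
    nodes, links = toy_tables
    return et.build_ego_net(nodes, links, EGO_ID)


def star_tables(k: int, direction: str = "ego_consumes"):
    """Pure star: ego plus k alters, no alter-alter links."""
    node_rows = [{"id": EGO_ID, "name": "", "is_consumer": 1, "is_resource": 1,
                  "habitats": "land", "origin": "native",
                  "arrival": "", "departure": "", "scenarios": ""}]
    link_rows = []
    for i in range(k):
        a = f"s{i + 1:02d}"
        node_rows.append({"id": a, "name": "", "is_consumer": 1, "is_resource": 1,
                          "habitats": "land", "origin": "native",
                          "arrival": "", "departure": "", "scenarios": ""})
        consumer, resource = ((EGO_ID, a) if direction == "ego_consumes"
                              else (a, EGO_ID))
        link_rows.append({"consumer_id": consumer, "resource_id": resource,
                          "habitat": "land", "interaction_type": "predation",
                          "first_observed": ""})
    return pd.DataFrame(node_rows), pd.DataFrame(link_rows)


@pytest.fixture
def star_net():
    nodes, links = star_tables(5)
    return et.build_ego_net(nodes, links, EGO_ID)


def random_net(seed: int, n_alters: int = 10, alter_link_prob: float = 0.25):
    """A random generated ego net with all-dual-role alters."""
    params = GeneratorParams(
        n_alters=n_alters, frac_consumer=0.0, frac_resource=0.0, frac_both=1.0,
        alter_link_prob=alter_link_prob, seed=seed,
    )
    nodes, links = et.generate_ego_dataset(params)
    return et.build_ego_net(nodes, links, EGO_ID)


# ---------------------------------------------------------------------------
# oracles


def brute_ego_betweenness(net) -> float:
    """Exhaustive fractional shortest-path count through the ego."""
    g = net.to_undirected(include_ego=True)
    ego = net.ego_id
    alters = sorted(net.alters)
    total = 0.0
    for a, b in itertools.combinations(alters, 2):
        paths = list(nx.all_shortest_paths(g, a, b))
        through = sum(1 for p in paths if ego in p[1:-1])
        total += through / len(paths)
    n = len(alters)
    return total / (n * (n - 1) / 2)


def reachability_fragmentation(net) -> float:
    """F from an explicit N x N reachability matrix, pairwise traversal."""
    sub = net.alter_subgraph()
    alters = sorted(net.alters)
    n = len(alters)
    reach = np.zeros((n, n), dtype=int)
    for i, a in enumerate(alters):
        for j, b in enumerate(alters):
            if i != j and nx.has_path(sub, a, b):
                reach[i, j] = 1
    return 1.0 - reach.sum() / (n * (n - 1))


def set_partitions(items):
    """All partitions of a sequence into non-empty blocks."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [block + [first]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_modularity(graph: nx.Graph, resolution: float = 1.0) -> float:
    """Globally optimal Q by trying every partition (graphs up to ~9 nodes)."""
    return max(
        nx.community.modularity(graph, [set(b) for b in part], resolution=resolution)
        for part in set_partitions(sorted(graph))
    )
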