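"""The ten structural descriptors of a trophic ego net.

Size descriptors
    N (alter count), E (link count), total link density d1, bipartite
    alter link density d2, and effective size N_eff with its normalization
    *efficiency*.

Heterogeneity descriptors
    normalized ego betweenness b_ego, module ratio M_ratio, fragmentation
    index F, and Blau layer diversity H (with its Index of Qualitative
    Variation, IQV) along the habitat and interaction-type dimensions.

Each descriptor is a pure function of the ego net (or of the pre-computed
counts that enter its formula, so worked examples are checkable in
isolation).  Densities are reported on the 0–100 percent scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .core import (
    HABITATS,
    INTERACTION_TYPES,
    EgoNet,
    EgotrophError,
    RoleCensus,
    UndefinedDescriptorError,
    role_census,
)

#: Layer vocabulary per dimension; IQV always normalizes by the number of
#: *possible* layers, not the number of occupied ones.
DIMENSIONS = {"habitat": HABITATS, "interaction_type": INTERACTION_TYPES}


def total_density(n_alters: int, n_links: int) -> float:
    """Total link density d1 = 100·E / [N·(N+1)], in percent.

    The net is treated as 1-modal: all N+1 nodes (ego included) may
    interact in either direction, loops excluded, giving N(N+1) possible
    directed links.
    """
    if n_alters < 1:
        raise UndefinedDescriptorError("empty ego net: d1 undefined for N = 0")
    return 100.0 * n_links / (n_alters * (n_alters + 1))


def alter_density(n_alters: int, n_links: int, census: RoleCensus) -> float:
    """Bipartite alter link density d2, in percent.

    d2 = 100·(E − N) / (n_consumers·n_resources − n_both).  The E − N
    alter–alter links are measured against the trophically allowed
    consumer→resource pairs only; the n_both taxa acting as both consumer
    and resource contribute their own forbidden loop, which the
    denominator removes.
    """
    denom = census.n_consumers * census.n_resources - census.n_both
    if denom <= 0:
        raise UndefinedDescriptorError(
            "undefined bipartite density: no trophically allowed alter pair"
        )
    return 100.0 * (n_links - n_alters) / denom


def effective_size_from_counts(
    n_alters: int, n_alter_links: int, mode: str = "link_count"
) -> tuple:
    """Effective size N_eff and efficiency from N and the alter–alter link count.

    ``mode='link_count'`` (default) counts each alter–alter link once:
    N_eff = N − A/N with A = E − N.  ``mode='degree_sum'`` is the
    conventional redundancy variant summing alter degrees, where each
    alter–alter link contributes twice: N_eff = N − 2A/N.
    """
    if n_alters < 1:
        raise UndefinedDescriptorError("empty ego net: effective size undefined")
    if mode == "link_count":
        redundancy = n_alter_links / n_alters
    elif mode == "degree_sum":
        redundancy = 2.0 * n_alter_links / n_alters
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_eff = n_alters - redundancy
    return n_eff, n_eff / n_alters


def effective_size(net: EgoNet, mode: str = "link_count") -> tuple:
    """(N_eff, efficiency) of an ego net; see :func:`effective_size_from_counts`."""
    return effective_size_from_counts(net.n_alters, len(net.alter_alter_links), mode)


def ego_betweenness(net: EgoNet) -> float:
    """Normalized ego betweenness b_ego in [0, 1].

    Over all unordered alter pairs, the fraction of shortest undirected
    paths between the pair that pass through the ego (a pair whose
    shortest paths split between ego and non-ego routes contributes
    fractionally, e.g. 1/2).  Normalized by the star-net maximum
    N(N−1)/2, so a pure star scores 1.  Link direction is ignored and
    path length counts links.
    """
    n = net.n_alters
    if n < 2:
        raise UndefinedDescriptorError("betweenness undefined for fewer than 2 alters")
    graph = net.to_undirected(include_ego=True)
    raw = nx.betweenness_centrality(graph, normalized=False)[net.ego_id]
    return raw / (n * (n - 1) / 2.0)


def fragmentation_from_component_sizes(sizes, n_alters: int) -> float:
    """F = 1 − Σ s(s−1) / [N(N−1)] over alter–alter component sizes s."""
    if n_alters < 2:
        raise UndefinedDescriptorError("fragmentation undefined for fewer than 2 alters")
    reachable = sum(s * (s - 1) for s in sizes)
    return 1.0 - reachable / (n_alters * (n_alters - 1))


def fragmentation_index(net: EgoNet) -> float:
    """Fragmentation index F in [0, 1].

    The proportion of ordered alter pairs that cannot reach each other
    along any path avoiding the ego.  Computed from the connected
    components of the undirected alter–alter subgraph: with component
    sizes s, F = 1 − Σ s(s−1) / [N(N−1)].  A star (no alter–alter links)
    scores 1; a connected alter–alter subgraph scores 0.
    """
    sub = net.alter_subgraph()
    sizes = [len(c) for c in nx.connected_components(sub)]
    return fragmentation_from_component_sizes(sizes, net.n_alters)


def module_ratio(n_modules: int, n_alters: int) -> float:
    """Module ratio M_ratio = (N_m − 1)/(N − 1), a normalized module count."""
    if n_alters < 2:
        raise UndefinedDescriptorError("module ratio undefined for N < 2")
    if not 1 <= n_modules <= n_alters:
        raise EgotrophError(
            f"module count {n_modules} outside [1, {n_alters}]"
        )
    return (n_modules - 1) / (n_alters - 1)


def blau_index(counts) -> float:
    """Blau heterogeneity H = 1 − Σ p_k² (the Gini–Simpson index)."""
    total = sum(counts)
    if total <= 0:
        raise UndefinedDescriptorError("layer diversity undefined without links")
    return 1.0 - sum((c / total) ** 2 for c in counts)


def iqv(h: float, n_layers: int) -> float:
    """Index of Qualitative Variation: H normalized by its maximum 1 − 1/n."""
    if n_layers < 2:
        raise UndefinedDescriptorError(
            "IQV undefined for a single-layer dimension (maximum H is 0)"
        )
    return h / (1.0 - 1.0 / n_layers)


def layer_diversity(
    net: EgoNet, dimension: str, proportions: str = "links"
) -> tuple:
    """(H, IQV, per-layer counts) of an ego net along one link dimension.

    ``dimension`` is ``'habitat'`` (3 layers) or ``'interaction_type'``
    (4 layers).  By default p_k is the proportion of the net's links (ego–
    alter and alter–alter alike) recorded in layer k; ``proportions=
    'alters'`` instead counts, per layer, the alters with at least one
    link in that layer (an alter active in several layers counts in each).
    IQV divides H by 1 − 1/n with n the number of layers defined for the
    dimension, occupied or not.
    """
    try:
        layers = DIMENSIONS[dimension]
    except KeyError:
        raise EgotrophError(
            f"unknown dimension {dimension!r} (expected one of {sorted(DIMENSIONS)})"
        ) from None
    counts = dict.fromkeys(layers, 0)
    if proportions == "links":
        for link in net.links:
            counts[getattr(link, dimension)] += 1
    elif proportions == "alters":
        for layer in layers:
            counts[layer] = sum(
                1
                for a in net.alters
                if any(
                    getattr(l, dimension) == layer
                    and a in (l.consumer_id, l.resource_id)
                    for l in net.links
                )
            )
    else:
        raise ValueError(f"unknown proportions mode {proportions!r}")
    h = blau_index(list(counts.values()))
    return h, iqv(h, len(layers)), counts


_NAN = float("nan")


@dataclass
class DescriptorRecord:
    """All descriptor values for one ego net (one summary-table column).

    Fields that are undefined on a given net (e.g. d2 when no trophically
    allowed alter pair exists) hold NaN and are listed in ``notes`` —
    undefined is reported explicitly, never as 0.
    """

    n_alters: int
    n_links: int
    d1: float = _NAN
    d2: float = _NAN
    b_ego: float = _NAN
    n_eff: float = _NAN
    efficiency: float = _NAN
    n_modules: int | float = _NAN
    m_ratio: float = _NAN
    fragmentation: float = _NAN
    h_habitat: float = _NAN
    iqv_habitat: float = _NAN
    h_interaction: float = _NAN
    iqv_interaction: float = _NAN
    habitat_counts: dict = field(default_factory=dict)
    interaction_counts: dict = field(default_factory=dict)
    notes: tuple = ()

    #: serialization order for trajectory tables (summary-table row order)
    TABLE_FIELDS = (
        "n_alters", "n_links", "d1", "d2", "b_ego", "n_eff", "efficiency",
        "m_ratio", "n_modules", "fragmentation",
        "h_habitat", "iqv_habitat", "h_interaction", "iqv_interaction",
    )

    def to_series(self) -> pd.Series:
        return pd.Series({f: getattr(self, f) for f in self.TABLE_FIELDS})

    def to_dict(self, include_counts: bool = True) -> dict:
        out = {f: getattr(self, f) for f in self.TABLE_FIELDS}
        out = {k: (None if isinstance(v, float) and math.isnan(v) else v)
               for k, v in out.items()}
        if include_counts:
            out["habitat_counts"] = dict(self.habitat_counts)
            out["interaction_counts"] = dict(self.interaction_counts)
        if self.notes:
            out["notes"] = list(self.notes)
        return out


def descriptor_suite(net: EgoNet, partition=None, seed: int | None = None) -> DescriptorRecord:
    """Evaluate every descriptor on one ego net.

    ``partition`` is a ModulePartition computed on this net (checked; a
    partition from another net raises ``'stale partition'``).  If omitted,
    module detection is run here with ``seed``.
    """
    from .community import detect_modules  # deferred to avoid import cycle

    if partition is None:
        partition = detect_modules(net, seed=seed if seed is not None else 0)
    if partition.alter_ids != net.alter_ids:
        raise EgotrophError("stale partition: computed on a different alter set")

    record = DescriptorRecord(n_alters=net.n_alters, n_links=net.n_links)
    notes = []

    def attempt(fieldnames, fn):
        try:
            values = fn()
        except UndefinedDescriptorError as err:
            notes.append(f"{'/'.join(fieldnames)} undefined: {err}")
            return
        if len(fieldnames) == 1:
            values = (values,)
        for name, value in zip(fieldnames, values):
            setattr(record, name, value)

    census = role_census(net)
    attempt(("d1",), lambda: total_density(net.n_alters, net.n_links))
    attempt(("d2",), lambda: alter_density(net.n_alters, net.n_links, census))
    attempt(("b_ego",), lambda: ego_betweenness(net))
    attempt(("n_eff", "efficiency"), lambda: effective_size(net))
    attempt(("m_ratio",), lambda: module_ratio(partition.n_modules, net.n_alters))
    record.n_modules = partition.n_modules
    attempt(("fragmentation",), lambda: fragmentation_index(net))

    def diversity(dimension, h_field, iqv_field, counts_field):
        try:
            h, q, counts = layer_diversity(net, dimension)
        except UndefinedDescriptorError as err:
            notes.append(f"{h_field}/{iqv_field} undefined: {err}")
            return
        setattr(record, h_field, h)
        setattr(record, iqv_field, q)
        setattr(record, counts_field, counts)

    diversity("habitat", "h_habitat", "iqv_habitat", "habitat_counts")
    diversity("interaction_type", "h_interaction", "iqv_interaction",
              "interaction_counts")
    record.notes = tuple(notes)
    return record
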