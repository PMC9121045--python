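"""Domain types and construction of ego networks from trophic interaction records.

An ego net is a focal species (the *ego*) together with every taxon it
directly interacts with (the *alters*), the ego–alter links, and the
alter–alter links among those alters.  Taxa that interact only with alters
lie outside the ego net and are dropped during construction.

Input is a pair of delimited text tables:

* a **node table** with columns
  ``id,name,is_consumer,is_resource,habitats,origin,arrival,departure,scenarios``
  (``habitats`` and ``scenarios`` are semicolon-separated; a taxon with
  several presence intervals repeats its row, one interval per row);
* a **link table** with columns
  ``consumer_id,resource_id,habitat,interaction_type,first_observed``.

Links are directed consumer → resource.  Loops (cannibalism) are rejected,
and duplicate link rows are collapsed with a warning so that the link count
E always counts distinct records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import pandas as pd

#: Ordinal habitat layers, from inland to open water.
HABITATS = ("land", "tidal", "sea")

#: Nominal interaction-type layers.
INTERACTION_TYPES = ("detritivory", "herbivory", "predation", "parasitism")

#: Sentinel for links/presences recorded before the study window opens.
BASELINE = "baseline"

NODE_COLUMNS = (
    "id", "name", "is_consumer", "is_resource", "habitats",
    "origin", "arrival", "departure", "scenarios",
)
LINK_COLUMNS = (
    "consumer_id", "resource_id", "habitat", "interaction_type", "first_observed",
)


class EgotrophError(Exception):
    """Base class for all package errors."""


class ValidationError(EgotrophError):
    """Malformed or inconsistent input tables."""


class UndefinedDescriptorError(EgotrophError):
    """A descriptor has no defined value on this input (never silently 0)."""


@dataclass(frozen=True)
class PresenceInterval:
    """Presence of a taxon over ``[start, end)`` years, optionally scenario-tagged.

    ``start is None`` means present from the earliest slice (pre-baseline
    records carry no arrival year); ``end is None`` means open-ended.  The
    interval is closed on the arrival year and open after the departure
    year, so a taxon removed in 1991 is absent from a 1995 slice.
    """

    start: int | None = None
    end: int | None = None
    scenario: str | None = None

    def covers(self, year: int, scenario: str | None = None) -> bool:
        if self.scenario is not None and scenario != self.scenario:
            return False
        if self.start is not None and year < self.start:
            return False
        if self.end is not None and year >= self.end:
            return False
        return True


@dataclass(frozen=True)
class TaxonNode:
    """A species or species aggregate appearing in the interaction tables."""

    id: str
    name: str = ""
    is_consumer: bool = False
    is_resource: bool = False
    habitats: frozenset = frozenset()
    origin: str = "native"
    presence: tuple = (PresenceInterval(),)

    def __post_init__(self):
        if not self.id:
            raise ValidationError("taxon id must be a non-empty token")
        if self.origin not in ("native", "exotic"):
            raise ValidationError(
                f"node {self.id!r}: origin must be 'native' or 'exotic', got {self.origin!r}"
            )
        bad = set(self.habitats) - set(HABITATS)
        if bad:
            raise ValidationError(f"node {self.id!r}: unknown habitats {sorted(bad)}")
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        # presence intervals must not overlap within one scenario tag
        by_tag: dict = {}
        for iv in self.presence:
            by_tag.setdefault(iv.scenario, []).append(iv)
        for tag, ivs in by_tag.items():
            lo = lambda iv: float("-inf") if iv.start is None else iv.start
            hi = lambda iv: float("inf") if iv.end is None else iv.end
            ivs = sorted(ivs, key=lambda iv: (lo(iv), hi(iv)))
            for a, b in zip(ivs, ivs[1:]):
                if hi(a) > lo(b):
                    raise ValidationError(
                        f"node {self.id!r}: overlapping presence intervals "
                        f"for scenario {tag!r}"
                    )

    def present(self, year: int, scenario: str | None = None) -> bool:
        return any(iv.covers(year, scenario) for iv in self.presence)


@dataclass(frozen=True)
class TrophicLink:
    """One directed consumer → resource interaction record."""

    consumer_id: str
    resource_id: str
    habitat: str
    interaction_type: str
    first_observed: int | None = None  # None = baseline record

    def __post_init__(self):
        if self.consumer_id == self.resource_id:
            raise ValidationError(
                f"loop link {self.consumer_id!r} -> itself: cannibalism/intra-node "
                "links are excluded"
            )
        if self.habitat not in HABITATS:
            raise ValidationError(
                f"link {self.consumer_id!r}->{self.resource_id!r}: unknown habitat "
                f"{self.habitat!r} (expected one of {HABITATS})"
            )
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValidationError(
                f"link {self.consumer_id!r}->{self.resource_id!r}: unknown interaction "
                f"type {self.interaction_type!r} (expected one of {INTERACTION_TYPES})"
            )

    @property
    def key(self) -> tuple:
        return (self.consumer_id, self.resource_id, self.habitat, self.interaction_type)


class RoleCensus(NamedTuple):
    """Counts of alters acting as consumer, as resource, and as both."""

    n_consumers: int
    n_resources: int
    n_both: int


@dataclass(frozen=True)
class EgoNet:
    """The ego, its alters, and all links among them.

    N = number of alters; E = total number of links (ego–alter plus
    alter–alter).  Every alter is guaranteed to share at least one link
    with the ego.
    """

    ego: TaxonNode
    alters: Mapping[str, TaxonNode]
    ego_alter_links: tuple
    alter_alter_links: tuple
    metadata: dict = field(default_factory=dict)

    @property
    def ego_id(self) -> str:
        return self.ego.id

    @property
    def n_alters(self) -> int:
        """N — degree centrality of the ego."""
        return len(self.alters)

    @property
    def n_links(self) -> int:
        """E — total number of distinct links in the net."""
        return len(self.ego_alter_links) + len(self.alter_alter_links)

    @property
    def links(self) -> tuple:
        return self.ego_alter_links + self.alter_alter_links

    @property
    def alter_ids(self) -> frozenset:
        return frozenset(self.alters)

    def roles(self) -> dict:
        """Role of each alter ('consumer' / 'resource' / 'both'), from in-net links."""
        consumers, resources = set(), set()
        for link in self.links:
            if link.consumer_id in self.alters:
                consumers.add(link.consumer_id)
            if link.resource_id in self.alters:
                resources.add(link.resource_id)
        out = {}
        for a in self.alters:
            if a in consumers and a in resources:
                out[a] = "both"
            elif a in consumers:
                out[a] = "consumer"
            elif a in resources:
                out[a] = "resource"
            else:  # unreachable by construction; fall back on declared flags
                node = self.alters[a]
                out[a] = "consumer" if node.is_consumer else "resource"
        return out

    def to_undirected(self, include_ego: bool = True) -> nx.Graph:
        """Simple undirected graph view (parallel layer links collapse)."""
        g = nx.Graph()
        if include_ego:
            g.add_node(self.ego_id)
        g.add_nodes_from(self.alters)
        for link in self.links:
            if not include_ego and self.ego_id in (link.consumer_id, link.resource_id):
                continue
            g.add_edge(link.consumer_id, link.resource_id)
        return g

    def alter_subgraph(self) -> nx.Graph:
        """Undirected alter–alter subgraph (ego and its links removed)."""
        return self.to_undirected(include_ego=False)

    def to_digraph(self) -> nx.MultiDiGraph:
        """Directed multigraph with node/edge attributes, for export."""
        g = nx.MultiDiGraph()
        roles = self.roles()
        for node in [self.ego, *self.alters.values()]:
            g.add_node(
                node.id,
                name=node.name,
                role="ego" if node.id == self.ego_id else roles[node.id],
                is_consumer=bool(node.is_consumer),
                is_resource=bool(node.is_resource),
                habitats=";".join(sorted(node.habitats)),
                origin=node.origin,
            )
        for link in self.links:
            g.add_edge(
                link.consumer_id,
                link.resource_id,
                habitat=link.habitat,
                interaction_type=link.interaction_type,
            )
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_digraph(), path)


# ---------------------------------------------------------------------------
# table parsing


def _parse_bool(value, context: str) -> bool:
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in ("1", "true", "yes", "y"):
        return True
    if token in ("0", "false", "no", "n", ""):
        return False
    raise ValidationError(f"{context}: cannot interpret {value!r} as a flag")


def _parse_year(value, context: str) -> int | None:
    if value is None:
        return None
    token = str(value).strip()
    if token in ("", BASELINE, "nan", "None"):
        return None
    try:
        return int(float(token))
    except ValueError:
        raise ValidationError(f"{context}: expected a year or 'baseline', got {value!r}")


def _split_tokens(value) -> list:
    if value is None:
        return []
    token = str(value).strip()
    if token in ("", "nan", "None"):
        return []
    return [t.strip() for t in token.split(";") if t.strip()]


def _as_frame(source, columns: Sequence[str], what: str) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        frame = source.copy()
    else:
        frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = set(columns) - set(frame.columns)
    if missing:
        raise ValidationError(f"{what} table is missing columns {sorted(missing)}")
    return frame


def read_node_table(source) -> dict:
    """Parse a node table (path, file or DataFrame) into ``{id: TaxonNode}``.

    Repeated rows for the same id contribute extra presence intervals; the
    remaining fields must agree across those rows.
    """
    frame = _as_frame(source, NODE_COLUMNS, "node")
    rows_by_id: dict = {}
    for idx, row in frame.iterrows():
        context = f"node table row {idx}"
        node_id = str(row["id"]).strip()
        if not node_id:
            raise ValidationError(f"{context}: empty id")
        arrival = _parse_year(row["arrival"], context)
        departure = _parse_year(row["departure"], context)
        tags = _split_tokens(row["scenarios"]) or [None]
        intervals = [PresenceInterval(arrival, departure, tag) for tag in tags]
        static = (
            str(row["name"]).strip(),
            _parse_bool(row["is_consumer"], context),
            _parse_bool(row["is_resource"], context),
            frozenset(_split_tokens(row["habitats"])),
            (str(row["origin"]).strip() or "native"),
        )
        if node_id in rows_by_id:
            prev_static, prev_intervals = rows_by_id[node_id]
            if prev_static != static:
                raise ValidationError(
                    f"{context}: repeated id {node_id!r} with conflicting attributes"
                )
            rows_by_id[node_id] = (static, prev_intervals + intervals)
        else:
            rows_by_id[node_id] = (static, intervals)
    nodes = {}
    for node_id, (static, intervals) in rows_by_id.items():
        name, is_consumer, is_resource, habitats, origin = static
        nodes[node_id] = TaxonNode(
            id=node_id,
            name=name,
            is_consumer=is_consumer,
            is_resource=is_resource,
            habitats=habitats,
            origin=origin,
            presence=tuple(intervals),
        )
    return nodes


def read_link_table(source) -> list:
    """Parse a link table (path, file or DataFrame) into a list of TrophicLink."""
    frame = _as_frame(source, LINK_COLUMNS, "link")
    links = []
    for idx, row in frame.iterrows():
        context = f"link table row {idx}"
        habitat = str(row["habitat"]).strip()
        itype = str(row["interaction_type"]).strip()
        if not habitat or not itype:
            raise ValidationError(f"{context}: unlayered link (missing habitat or "
                                  "interaction_type)")
        try:
            links.append(
                TrophicLink(
                    consumer_id=str(row["consumer_id"]).strip(),
                    resource_id=str(row["resource_id"]).strip(),
                    habitat=habitat,
                    interaction_type=itype,
                    first_observed=_parse_year(row["first_observed"], context),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{context}: {err}") from None
    return links


def nodes_to_frame(nodes: Mapping[str, TaxonNode]) -> pd.DataFrame:
    """Serialize nodes back to the delimited table layout (one row per interval)."""
    rows = []
    for node in nodes.values():
        for iv in node.presence:
            rows.append({
                "id": node.id,
                "name": node.name,
                "is_consumer": int(node.is_consumer),
                "is_resource": int(node.is_resource),
                "habitats": ";".join(sorted(node.habitats)),
                "origin": node.origin,
                "arrival": "" if iv.start is None else iv.start,
                "departure": "" if iv.end is None else iv.end,
                "scenarios": iv.scenario or "",
            })
    return pd.DataFrame(rows, columns=list(NODE_COLUMNS))


def links_to_frame(links: Iterable[TrophicLink]) -> pd.DataFrame:
    rows = [
        {
            "consumer_id": l.consumer_id,
            "resource_id": l.resource_id,
            "habitat": l.habitat,
            "interaction_type": l.interaction_type,
            "first_observed": "" if l.first_observed is None else l.first_observed,
        }
        for l in links
    ]
    return pd.DataFrame(rows, columns=list(LINK_COLUMNS))


# ---------------------------------------------------------------------------
# construction


def _ensure_nodes(nodes) -> dict:
    if isinstance(nodes, Mapping) and all(isinstance(v, TaxonNode) for v in nodes.values()):
        return dict(nodes)
    return read_node_table(nodes)


def _ensure_links(links) -> list:
    if not isinstance(links, (pd.DataFrame, str, Path)) and all(
        isinstance(l, TrophicLink) for l in links
    ):
        return list(links)
    return read_link_table(links)


def validate_tables(nodes, links) -> tuple:
    """Validate a node/link table pair; returns (nodes, deduplicated links).

    Raises :class:`ValidationError` on dangling links (a link row naming an
    undeclared taxon), role-less or habitat-less linked taxa; collapses
    duplicate link rows with a warning.
    """
    nodes = _ensure_nodes(nodes)
    links = _ensure_links(links)
    seen: dict = {}
    for link in links:
        for endpoint in (link.consumer_id, link.resource_id):
            if endpoint not in nodes:
                raise ValidationError(
                    f"dangling link {link.key}: node {endpoint!r} is not declared"
                )
        if link.key in seen:
            warnings.warn(
                f"duplicate link row {link.key} collapsed", stacklevel=2
            )
        else:
            seen[link.key] = link
    deduped = list(seen.values())
    linked = {l.consumer_id for l in deduped} | {l.resource_id for l in deduped}
    for node_id in sorted(linked):
        node = nodes[node_id]
        if not (node.is_consumer or node.is_resource):
            raise ValidationError(
                f"node {node_id!r} appears in links but declares no trophic role"
            )
        if not node.habitats:
            raise ValidationError(
                f"node {node_id!r} appears in links but has an empty habitat set"
            )
    return nodes, deduped


def build_ego_net(nodes, links, ego_id: str, metadata: dict | None = None) -> EgoNet:
    """Construct the ego net of ``ego_id`` from node and link tables.

    Alters are exactly the taxa sharing a link with the ego; links among
    alters are kept, and any link touching a taxon outside the closed
    neighborhood is dropped (such taxa are outside the ego net by
    definition).

    Raises ``EgotrophError('ego not found')`` if ``ego_id`` is undeclared or
    occurs in no link.
    """
    nodes, links = validate_tables(nodes, links)
    if ego_id not in nodes:
        raise EgotrophError(f"ego not found: {ego_id!r} is not declared in the node table")
    ego_links = [l for l in links if ego_id in (l.consumer_id, l.resource_id)]
    if not ego_links:
        raise EgotrophError(f"ego not found in any link: {ego_id!r}")
    alter_ids = {
        l.consumer_id if l.resource_id == ego_id else l.resource_id for l in ego_links
    }
    alter_links = [
        l
        for l in links
        if l.consumer_id in alter_ids
        and l.resource_id in alter_ids
        and ego_id not in (l.consumer_id, l.resource_id)
    ]
    return EgoNet(
        ego=nodes[ego_id],
        alters={a: nodes[a] for a in sorted(alter_ids)},
        ego_alter_links=tuple(ego_links),
        alter_alter_links=tuple(alter_links),
        metadata=dict(metadata or {}),
    )


def role_census(net: EgoNet) -> RoleCensus:
    """Sort alters into consumers and resources from their in-net links.

    An alter is a consumer if it is the consumer end of any link inside the
    net (ego–alter or alter–alter), a resource analogously; taxa acting as
    both are counted in both tallies and once more in ``n_both``, so that
    ``n_consumers + n_resources - n_both == N``.  The ego itself is
    excluded from the census.
    """
    roles = net.roles()
    n_cons = sum(1 for r in roles.values() if r in ("consumer", "both"))
    n_res = sum(1 for r in roles.values() if r in ("resource", "both"))
    n_both = sum(1 for r in roles.values() if r == "both")
    return RoleCensus(n_cons, n_res, n_both)
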