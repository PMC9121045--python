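"""Synthetic interaction datasets emulating an island trophic ego net.

The generator produces node/link tables in the same delimited layout the
package reads, so every stage — construction, descriptors, module
detection, temporal slicing — is testable without field data.  The
default parameters emulate the statistical shape of a sub-Antarctic
seabird-island ego net baseline: ~50 alters with a consumer-only /
resource-only / dual role split of 0.08 / 0.50 / 0.42 (census 25, 46, 21),
an alter–alter link probability of 0.048 over the trophically allowed
consumer→resource pairs (≈54 links), habitat link weights 39:32:33 over
land/tidal/sea, and interaction-type link weights 16:6:78:4 over
detritivory/herbivory/predation/parasitism.

The timeline generator layers scripted invasion/extinction waves on top of
a generated baseline, ending in two terminal scenario branches that differ
by one keystone exotic and its cascade of dependent natives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .core import HABITATS, INTERACTION_TYPES, ValidationError
from .temporal import ScenarioTimeline

EGO_ID = "ego"

#: Default terminal branch tags (a future with / without the keystone exotic).
BRANCH_WITH = "2100_with_mouse"
BRANCH_WITHOUT = "2100_no_mouse"

DEFAULT_SLICES = (
    ("1800", 1800), ("1820", 1820), ("1930", 1930), ("1975", 1975),
    ("1995", 1995), ("2020", 2020), ("2100", 2100),
)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic ego-net generator.

    ``frac_consumer`` / ``frac_resource`` / ``frac_both`` are the
    proportions of alters that are consumer-only, resource-only, and both
    (summing to 1).  ``alter_link_prob`` is the Bernoulli probability of
    each trophically allowed consumer→resource alter pair.  Optional
    planted groups (``planted_sizes`` with ``within_prob``/``between_prob``
    link probabilities) override the background Bernoulli links to create
    recoverable module structure; ``n_bridge_links`` isolated alters
    additionally get a single link into the first planted group.
    """

    n_alters: int = 50
    frac_consumer: float = 0.08
    frac_resource: float = 0.50
    frac_both: float = 0.42
    alter_link_prob: float = 0.048
    habitat_weights: tuple = (39 / 104, 32 / 104, 33 / 104)
    type_weights: tuple = (16 / 104, 6 / 104, 78 / 104, 4 / 104)
    planted_sizes: tuple = ()
    within_prob: float = 0.9
    between_prob: float = 0.0
    n_bridge_links: int = 0
    timeline_events: tuple | None = None  # None = default script; () = no events
    seed: int = 0

    def __post_init__(self):
        fracs = (self.frac_consumer, self.frac_resource, self.frac_both)
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValidationError(f"role fractions must sum to 1, got {fracs}")
        for name in ("alter_link_prob", "within_prob", "between_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        for name, weights, k in (
            ("habitat_weights", self.habitat_weights, len(HABITATS)),
            ("type_weights", self.type_weights, len(INTERACTION_TYPES)),
        ):
            if len(weights) != k or abs(sum(weights) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must be {k} proportions summing to 1")
        if sum(self.planted_sizes) > self.n_alters:
            raise ValidationError("planted group sizes exceed n_alters")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorParams":
        with open(path) as fh:
            config = yaml.safe_load(fh) or {}
        for key, value in list(config.items()):
            if isinstance(value, list):
                config[key] = tuple(value)
        return cls(**config)


# ---------------------------------------------------------------------------
# fixed toy fixture


def _toy_rows():
    # ego consumes alters 3, 5, 6, 7 and is consumed by alters 2 and 4;
    # the four named alter-alter links (5>3, 5>6, 2>5, 7>5) plus four more,
    # frozen once, complete the printed totals: 14 in-net links and an
    # alter role census of 5 consumers, 4 resources, 3 dual-role.
    in_net = [
        (EGO_ID, "a3", "land", "herbivory"),
        (EGO_ID, "a5", "tidal", "predation"),
        (EGO_ID, "a6", "land", "detritivory"),
        (EGO_ID, "a7", "sea", "predation"),
        ("a2", EGO_ID, "land", "predation"),
        ("a4", EGO_ID, "land", "parasitism"),
        ("a5", "a3", "tidal", "herbivory"),
        ("a5", "a6", "tidal", "predation"),
        ("a2", "a5", "sea", "predation"),
        ("a7", "a5", "sea", "predation"),
        ("a6", "a3", "land", "herbivory"),
        ("a4", "a3", "land", "herbivory"),
        ("a2", "a6", "land", "predation"),
        ("a7", "a6", "tidal", "predation"),
    ]
    # links of the three outside taxa: linked to alters but never to ego,
    # so construction must drop them (and the outside taxa with them)
    outside = [
        ("xA", "a5", "sea", "predation"),
        ("xB", "a3", "land", "herbivory"),
        ("a6", "xC", "land", "detritivory"),
        ("xA", "xB", "sea", "predation"),
    ]
    return in_net, outside


def make_toy_net() -> tuple:
    """The fixed seven-node teaching fixture (plus three outside taxa).

    Returns (node table, link table) DataFrames for an ego with six
    alters, 14 in-net links, and alter role census (5, 4, 3); three
    further taxa link only to alters and fall outside the ego net.
    """
    in_net, outside = _toy_rows()
    links = in_net + outside
    consumers = {c for c, _, _, _ in links}
    resources = {r for _, r, _, _ in links}
    habitats: dict = {}
    for c, r, h, _ in links:
        habitats.setdefault(c, set()).add(h)
        habitats.setdefault(r, set()).add(h)
    node_rows = []
    for node_id in sorted(habitats):
        node_rows.append({
            "id": node_id,
            "name": node_id,
            "is_consumer": int(node_id in consumers),
            "is_resource": int(node_id in resources),
            "habitats": ";".join(sorted(habitats[node_id])),
            "origin": "native",
            "arrival": "",
            "departure": "",
            "scenarios": "",
        })
    link_rows = [
        {"consumer_id": c, "resource_id": r, "habitat": h,
         "interaction_type": t, "first_observed": ""}
        for c, r, h, t in links
    ]
    return pd.DataFrame(node_rows), pd.DataFrame(link_rows)


# ---------------------------------------------------------------------------
# random generator


def _role_classes(params: GeneratorParams, rng) -> dict:
    n = params.n_alters
    n_both = round(params.frac_both * n)
    n_cons = round(params.frac_consumer * n)
    n_res = n - n_both - n_cons
    if n_res < 0:
        raise ValidationError("role fractions infeasible for this n_alters")
    classes = (["both"] * n_both + ["consumer"] * n_cons + ["resource"] * n_res)
    rng.shuffle(classes)
    ids = [f"a{i + 1:02d}" for i in range(n)]
    return dict(zip(ids, classes))


def _sample_layer(rng, weights, values):
    return values[int(rng.choice(len(values), p=np.asarray(weights)))]


def _feasible_direction(u, v, classes, rng):
    """Pick a consumer→resource orientation for an undirected pair, or None."""
    u_cons = classes[u] in ("consumer", "both")
    u_res = classes[u] in ("resource", "both")
    v_cons = classes[v] in ("consumer", "both")
    v_res = classes[v] in ("resource", "both")
    options = []
    if u_cons and v_res:
        options.append((u, v))
    if v_cons and u_res:
        options.append((v, u))
    if not options:
        return None
    return options[int(rng.integers(len(options)))] if len(options) > 1 else options[0]


def generate_ego_dataset(params: GeneratorParams | None = None, seed: int | None = None):
    """Generate a star-plus-alter-links ego dataset.

    Every alter carries exactly one link to the ego (consumer-only alters
    consume the ego, all others are consumed by it), then alter–alter
    links are drawn as independent Bernoulli trials over the trophically
    allowed consumer→resource pairs — or, when planted groups are
    configured, with high within-group and low between-group probability.
    Link habitat and interaction-type layers are sampled from the weight
    vectors.  Returns (node table, link table) DataFrames; identical
    parameters and seed give identical tables.
    """
    params = params or GeneratorParams()
    if seed is not None:
        params = replace(params, seed=seed)
    rng = np.random.default_rng(params.seed)
    classes = _role_classes(params, rng)
    ids = list(classes)

    consumers = [a for a in ids if classes[a] in ("consumer", "both")]
    resources = [a for a in ids if classes[a] in ("resource", "both")]
    if params.alter_link_prob > 0 and (not consumers or not resources):
        raise ValidationError(
            "infeasible role fractions: alter links requested but no "
            "consumer/resource pair exists"
        )

    link_rows = []

    def add_link(consumer, resource, first_observed=""):
        link_rows.append({
            "consumer_id": consumer,
            "resource_id": resource,
            "habitat": _sample_layer(rng, params.habitat_weights, HABITATS),
            "interaction_type": _sample_layer(rng, params.type_weights,
                                              INTERACTION_TYPES),
            "first_observed": first_observed,
        })

    for a in ids:  # star skeleton
        if classes[a] == "consumer":
            add_link(a, EGO_ID)
        else:
            add_link(EGO_ID, a)

    if params.planted_sizes:
        groups, cursor = [], 0
        for size in params.planted_sizes:
            groups.append(ids[cursor:cursor + size])
            cursor += size
        leftover = ids[cursor:]
        member_group = {a: gi for gi, g in enumerate(groups) for a in g}
        for i, u in enumerate(ids):
            for v in ids[i + 1:]:
                same = (u in member_group and v in member_group
                        and member_group[u] == member_group[v])
                p = params.within_prob if same else params.between_prob
                if p > 0 and rng.random() < p:
                    oriented = _feasible_direction(u, v, classes, rng)
                    if oriented:
                        add_link(*oriented)
        bridges = leftover[: params.n_bridge_links]
        for u in bridges:
            v = groups[0][int(rng.integers(len(groups[0])))]
            oriented = _feasible_direction(u, v, classes, rng)
            if oriented:
                add_link(*oriented)
    else:
        for c in consumers:
            for r in resources:
                if c != r and rng.random() < params.alter_link_prob:
                    add_link(c, r)

    links = pd.DataFrame(
        link_rows,
        columns=["consumer_id", "resource_id", "habitat", "interaction_type",
                 "first_observed"],
    ).drop_duplicates(
        subset=["consumer_id", "resource_id", "habitat", "interaction_type"]
    ).reset_index(drop=True)

    node_habitats: dict = {}
    for row in links.itertuples(index=False):
        node_habitats.setdefault(row.consumer_id, set()).add(row.habitat)
        node_habitats.setdefault(row.resource_id, set()).add(row.habitat)
    node_rows = [{
        "id": EGO_ID, "name": "focal species", "is_consumer": 1, "is_resource": 1,
        "habitats": ";".join(sorted(node_habitats.get(EGO_ID, {"land"}))),
        "origin": "native", "arrival": "", "departure": "", "scenarios": "",
    }]
    for a in ids:
        cls = classes[a]
        node_rows.append({
            "id": a,
            "name": a,
            "is_consumer": int(cls in ("consumer", "both")),
            "is_resource": int(cls in ("resource", "both")),
            "habitats": ";".join(sorted(node_habitats.get(a, {"land"}))),
            "origin": "native",
            "arrival": "",
            "departure": "",
            "scenarios": "",
        })
    return pd.DataFrame(node_rows), links


# ---------------------------------------------------------------------------
# timeline generator

#: Default invasion/extinction script, emulating two reversible historical
#: disturbances (a resource-exploitation wave and a four-decade predator
#: presence) and a terminal branch on one keystone exotic whose persistence
#: drags four dependent natives out of the net.
DEFAULT_TIMELINE_EVENTS = (
    {"kind": "gap", "id": "a04", "start": 1805, "end": 1930},
    {"kind": "gap", "id": "a05", "start": 1805, "end": 1930},
    {"kind": "gap", "id": "a06", "start": 1810, "end": 1930},
    {"kind": "arrival", "id": "inv1", "year": 1810, "origin": "exotic",
     "extra_links": 2},
    {"kind": "arrival", "id": "inv2", "year": 1905, "origin": "exotic",
     "extra_links": 1},
    {"kind": "arrival", "id": "cat", "year": 1949, "origin": "exotic",
     "departure": 1991, "extra_links": 1},
    {"kind": "departure", "id": "a07", "year": 1960},
    {"kind": "departure", "id": "a08", "year": 1985},
    {"kind": "arrival", "id": "mouse", "year": 1820, "origin": "exotic",
     "extra_links": 2, "keystone": True},
    {"kind": "cascade", "id": "a09"},
    {"kind": "cascade", "id": "a10"},
    {"kind": "cascade", "id": "a11"},
    {"kind": "cascade", "id": "a12"},
)


def generate_timeline_dataset(
    params: GeneratorParams | None = None, seed: int | None = None
) -> tuple:
    """Generate (node table, link table, timeline) with scripted dynamics.

    Scripted events are applied to a generated baseline: presence gaps and
    departures of natives, arrivals of exotics (each new arrival gets an
    ego link and a few alter links first observed in its arrival year),
    one keystone exotic that persists only in the ``with`` terminal
    branch, and cascade natives that persist only in the ``without``
    branch.  Events referencing an alter id absent from the baseline raise
    a validation error.
    """
    params = params or GeneratorParams()
    if seed is not None:
        params = replace(params, seed=seed)
    nodes, links = generate_ego_dataset(params)
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 421)))
    timeline = ScenarioTimeline(
        slices=DEFAULT_SLICES, scenarios=(BRANCH_WITHOUT, BRANCH_WITH)
    )
    cut = timeline.slices[-2][1] + 1  # first year after the last shared slice
    events = (DEFAULT_TIMELINE_EVENTS if params.timeline_events is None
              else params.timeline_events)

    nodes = nodes.set_index("id", drop=False)
    known = set(nodes["id"])
    extra_node_rows, extra_link_rows = [], []

    def require(node_id):
        if node_id not in known:
            raise ValidationError(f"timeline event references unknown node {node_id!r}")

    def random_alter_link(new_id, year):
        partner = f"a{int(rng.integers(params.n_alters)) + 1:02d}"
        consumer, resource = (new_id, partner) if rng.random() < 0.7 else (partner, new_id)
        extra_link_rows.append({
            "consumer_id": consumer, "resource_id": resource,
            "habitat": HABITATS[int(rng.integers(len(HABITATS)))],
            "interaction_type": INTERACTION_TYPES[int(rng.integers(len(INTERACTION_TYPES)))],
            "first_observed": year,
        })

    for event in events:
        kind = event["kind"]
        if kind == "gap":
            require(event["id"])
            i = nodes.index.get_loc(event["id"])
            nodes.iloc[i, nodes.columns.get_loc("departure")] = event["start"]
            row = nodes.iloc[i].copy()
            row["arrival"], row["departure"] = event["end"], ""
            extra_node_rows.append(row.to_dict())
        elif kind == "departure":
            require(event["id"])
            i = nodes.index.get_loc(event["id"])
            nodes.iloc[i, nodes.columns.get_loc("departure")] = event["year"]
        elif kind == "cascade":
            # persists beyond the branch point only if the keystone is gone
            require(event["id"])
            i = nodes.index.get_loc(event["id"])
            nodes.iloc[i, nodes.columns.get_loc("departure")] = cut
            row = nodes.iloc[i].copy()
            row["arrival"], row["departure"], row["scenarios"] = cut, "", BRANCH_WITHOUT
            extra_node_rows.append(row.to_dict())
        elif kind == "arrival":
            new_id, year = event["id"], event["year"]
            if new_id in known:
                raise ValidationError(f"arrival event id {new_id!r} already exists")
            known.add(new_id)
            base_row = {
                "id": new_id, "name": new_id, "is_consumer": 1, "is_resource": 1,
                "habitats": "land;tidal", "origin": event.get("origin", "exotic"),
                "arrival": year, "departure": event.get("departure", ""),
                "scenarios": "",
            }
            if event.get("keystone"):
                base_row["departure"] = cut
                extra_node_rows.append({**base_row, "arrival": cut, "departure": "",
                                        "scenarios": BRANCH_WITH})
            extra_node_rows.append(base_row)
            extra_link_rows.append({
                "consumer_id": new_id, "resource_id": EGO_ID, "habitat": "land",
                "interaction_type": "predation", "first_observed": year,
            })
            for _ in range(event.get("extra_links", 0)):
                random_alter_link(new_id, year)
        else:
            raise ValidationError(f"unknown timeline event kind {kind!r}")

    nodes = pd.concat(
        [nodes.reset_index(drop=True), pd.DataFrame(extra_node_rows)],
        ignore_index=True,
    )
    links = pd.concat([links, pd.DataFrame(extra_link_rows)], ignore_index=True)
    links = links.drop_duplicates(
        subset=["consumer_id", "resource_id", "habitat", "interaction_type"]
    ).reset_index(drop=True)
    return nodes, links, timeline
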