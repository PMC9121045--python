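"""Time-sliced ego nets: trajectories, turnover, and descriptor correlations.

A timeline is an ordered series of labelled year snapshots, optionally
branching into alternative scenarios at the final slice (e.g. a future
with or without an invading keystone exotic).  Slicing follows a
persistence rule: a link, once first observed, stays in the network for as
long as both of its species are present.  Species presence is driven by
arrival/departure intervals on the node table, closed on the arrival year
and open after the departure year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import (
    EgoNet,
    EgotrophError,
    ValidationError,
    build_ego_net,
    validate_tables,
)
from .descriptors import DescriptorRecord, descriptor_suite

#: The ten descriptors entering the pairwise correlation analysis
#: (efficiency and the IQVs are normalizations of other rows and excluded).
CORRELATION_FIELDS = (
    "n_alters", "n_links", "d1", "d2", "b_ego", "n_eff",
    "m_ratio", "fragmentation", "h_habitat", "h_interaction",
)


@dataclass(frozen=True)
class ScenarioTimeline:
    """Ordered time slices plus the branch tags of the final slice."""

    slices: tuple  # ((label, year), ...)
    scenarios: tuple = ()  # branch tags, final slice only

    def __post_init__(self):
        years = [year for _, year in self.slices]
        if not years:
            raise ValidationError("timeline needs at least one slice")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValidationError("timeline years must be strictly increasing")

    @property
    def years(self) -> tuple:
        return tuple(year for _, year in self.slices)

    def slice_plan(self) -> list:
        """[(label, year, scenario)] — final slice fans out over branches."""
        plan = []
        for i, (label, year) in enumerate(self.slices):
            final = i == len(self.slices) - 1
            if final and self.scenarios:
                for tag in self.scenarios:
                    plan.append((f"{label} {tag}", year, tag))
            else:
                plan.append((label, year, None))
        return plan

    @classmethod
    def from_dict(cls, config: dict) -> "ScenarioTimeline":
        slices = tuple((str(s["label"]), int(s["year"])) for s in config["slices"])
        return cls(slices=slices, scenarios=tuple(config.get("scenarios", ())))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioTimeline":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "slices": [{"label": l, "year": y} for l, y in self.slices],
            "scenarios": list(self.scenarios),
        }


@dataclass(frozen=True)
class TurnoverRecord:
    """Alters entering/leaving the ego net since the previous slice, by origin."""

    slice_label: str
    native_in: int
    native_out: int
    exotic_in: int
    exotic_out: int
    n_alters: int

    @property
    def net_change(self) -> int:
        return self.native_in + self.exotic_in - self.native_out - self.exotic_out


def _known_scenarios(nodes) -> set:
    tags = set()
    for node in nodes.values():
        for iv in node.presence:
            if iv.scenario is not None:
                tags.add(iv.scenario)
    return tags


def slice_network(
    nodes,
    links,
    ego_id: str,
    year: int,
    scenario: str | None = None,
    known_scenarios: Iterable[str] | None = None,
) -> EgoNet:
    """Ego net at one year under one scenario branch.

    A taxon is present iff one of its presence intervals (untagged, or
    tagged with this scenario) covers the year; a link is present iff both
    endpoints are present and its first observation is not later than the
    year (baseline links count as always observed).
    """
    nodes, links = validate_tables(nodes, links)
    known = set(known_scenarios) if known_scenarios is not None else _known_scenarios(nodes)
    if scenario is not None and known and scenario not in known:
        raise EgotrophError(
            f"unknown scenario {scenario!r}; known tags: {sorted(known)}"
        )
    present = {
        node_id for node_id, node in nodes.items() if node.present(year, scenario)
    }
    live_links = [
        l
        for l in links
        if l.consumer_id in present
        and l.resource_id in present
        and (l.first_observed is None or l.first_observed <= year)
    ]
    return build_ego_net(
        {n: nodes[n] for n in present},
        live_links,
        ego_id,
        metadata={"year": year, "scenario": scenario},
    )


def trajectory(
    nodes, links, ego_id: str, timeline: ScenarioTimeline, seed: int = 0
) -> pd.DataFrame:
    """Descriptor records for every (slice, scenario branch) of a timeline.

    Returns one row per slice (branch slices fan out), columns in summary-
    table order plus ``slice``/``year``/``scenario``.  A slice at which the
    ego has no links yields a row of NaN markers, never zeros.  Module
    detection is re-run per slice with the single supplied seed.
    """
    nodes, links = validate_tables(nodes, links)
    known = _known_scenarios(nodes) | set(timeline.scenarios)
    rows = []
    for label, year, scenario in timeline.slice_plan():
        meta = {"slice": label, "year": year, "scenario": scenario or ""}
        try:
            net = slice_network(nodes, links, ego_id, year, scenario,
                                known_scenarios=known)
        except EgotrophError:
            rows.append(meta)  # descriptor columns stay NaN
            continue
        record = descriptor_suite(net, seed=seed)
        rows.append({**meta, **{f: getattr(record, f)
                                for f in DescriptorRecord.TABLE_FIELDS}})
    columns = ["slice", "year", "scenario", *DescriptorRecord.TABLE_FIELDS]
    return pd.DataFrame(rows, columns=columns)


def trajectory_table(traj: pd.DataFrame) -> pd.DataFrame:
    """Pivot a trajectory into summary-table orientation.

    Rows are descriptors (summary-table order), columns are the slice
    labels — one column per (slice, scenario branch).
    """
    wide = traj.set_index("slice")[list(DescriptorRecord.TABLE_FIELDS)].T
    wide.index.name = "descriptor"
    return wide


def turnover(
    nodes, links, ego_id: str, timeline: ScenarioTimeline,
    scenario: str | None = None,
) -> list:
    """Per-slice counts of alters entering/leaving the ego net, by origin.

    Records cover consecutive slice pairs only (no record for the opening
    slice), so a ``k``-slice timeline yields ``k − 1`` records.  The
    ledger identity N(t) = N(t−1) + in − out holds at every record.
    """
    nodes, links = validate_tables(nodes, links)
    known = _known_scenarios(nodes) | set(timeline.scenarios)

    def alters_at(year):
        try:
            net = slice_network(nodes, links, ego_id, year, scenario,
                                known_scenarios=known)
        except EgotrophError:
            return frozenset()
        return net.alter_ids

    records = []
    previous = alters_at(timeline.slices[0][1])
    for label, year in timeline.slices[1:]:
        current = alters_at(year)
        entering = current - previous
        leaving = previous - current
        records.append(
            TurnoverRecord(
                slice_label=label,
                native_in=sum(1 for a in entering if nodes[a].origin == "native"),
                native_out=sum(1 for a in leaving if nodes[a].origin == "native"),
                exotic_in=sum(1 for a in entering if nodes[a].origin == "exotic"),
                exotic_out=sum(1 for a in leaving if nodes[a].origin == "exotic"),
                n_alters=len(current),
            )
        )
        previous = current
    return records


def turnover_frame(records: Sequence[TurnoverRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "slice": r.slice_label,
                "native_in": r.native_in,
                "native_out": r.native_out,
                "exotic_in": r.exotic_in,
                "exotic_out": r.exotic_out,
                "n_alters": r.n_alters,
            }
            for r in records
        ]
    )


def descriptor_correlations(
    traj: pd.DataFrame, method: str = "pearson"
) -> tuple:
    """Pairwise correlations between descriptor trajectories.

    Returns two symmetric 10×10 DataFrames (coefficients, p-values) over
    the ten descriptors, diagonal NaN.  Needs at least three slices.
    Constant columns give NaN markers (the coefficient is undefined), and
    slices where a descriptor is undefined are dropped pairwise.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    data = traj[list(CORRELATION_FIELDS)].astype(float)
    if len(data) < 3:
        raise EgotrophError(
            f"insufficient points: correlation needs >= 3 slices, got {len(data)}"
        )
    k = len(CORRELATION_FIELDS)
    coef = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(k):
        for j in range(i + 1, k):
            pair = data.iloc[:, [i, j]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # undefined: stays NaN
            result = fn(x, y)
            coef[i, j] = coef[j, i] = result.statistic
            pval[i, j] = pval[j, i] = result.pvalue
    index = list(CORRELATION_FIELDS)
    return (
        pd.DataFrame(coef, index=index, columns=index),
        pd.DataFrame(pval, index=index, columns=index),
    )
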