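"""Time slicing, trajectories, turnover accounting, and correlations."""

import math

import numpy as np
import pandas as pd
import pytest

import egotroph as et
from egotroph.core import ValidationError
from egotroph.synthetic import BRANCH_WITH, BRANCH_WITHOUT, EGO_ID
from egotroph.temporal import CORRELATION_FIELDS

from conftest import star_tables


def node_row(node_id, arrival="", departure="", scenarios="", origin="native"):
    return {"id": node_id, "name": node_id, "is_consumer": 1, "is_resource": 1,
            "habitats": "land", "origin": origin, "arrival": arrival,
            "departure": departure, "scenarios": scenarios}


def link_row(consumer, resource, first=""):
    return {"consumer_id": consumer, "resource_id": resource, "habitat": "land",
            "interaction_type": "predation", "first_observed": first}


@pytest.fixture
def scripted_tables():
    """Ego + three permanent alters, one 1949-1991 invader, one 1900 arrival."""
    nodes = pd.DataFrame([
        node_row(EGO_ID),
        node_row("a1"), node_row("a2"), node_row("a3"),
        node_row("cat", arrival=1949, departure=1991, origin="exotic"),
        node_row("inv", arrival=1900, origin="exotic"),
    ])
    links = pd.DataFrame([
        link_row(EGO_ID, "a1"), link_row(EGO_ID, "a2"), link_row("a3", EGO_ID),
        link_row("cat", EGO_ID, first=1949),
        link_row("inv", EGO_ID, first=1905),
        link_row("a1", "a2", first=1920),
    ])
    return nodes, links


class TestSliceNetwork:
    def test_bracketed_presence(self, scripted_tables):
        nodes, links = scripted_tables
        at_1975 = et.slice_network(nodes, links, EGO_ID, 1975)
        assert "cat" in at_1975.alters
        at_1995 = et.slice_network(nodes, links, EGO_ID, 1995)
        assert "cat" not in at_1995.alters

    def test_persistence_between_events(self, scripted_tables):
        nodes, links = scripted_tables
        a = et.slice_network(nodes, links, EGO_ID, 1950)
        b = et.slice_network(nodes, links, EGO_ID, 1970)
        assert a.alter_ids == b.alter_ids
        assert {l.key for l in a.links} == {l.key for l in b.links}

    def test_link_waits_for_first_observation(self, scripted_tables):
        nodes, links = scripted_tables
        net = et.slice_network(nodes, links, EGO_ID, 1902)
        assert "inv" not in net.alter_ids  # present but its link is unobserved
        net = et.slice_network(nodes, links, EGO_ID, 1905)
        assert "inv" in net.alter_ids

    def test_event_replay_oracle(self, scripted_tables):
        """N(t) across years equals a hand-computed event ledger."""
        nodes, links = scripted_tables
        expected = {1800: 3, 1905: 4, 1949: 5, 1990: 5, 1991: 4, 2000: 4}
        for year, n in expected.items():
            assert et.slice_network(nodes, links, EGO_ID, year).n_alters == n

    def test_unknown_scenario_lists_known_tags(self):
        nodes = pd.DataFrame([
            node_row(EGO_ID), node_row("a1", scenarios="future_a"),
        ])
        links = pd.DataFrame([link_row(EGO_ID, "a1")])
        with pytest.raises(et.EgotrophError, match="future_a"):
            et.slice_network(nodes, links, EGO_ID, 1900, scenario="bogus")


class TestTrajectory:
    def test_single_slice_equals_descriptor_suite(self, scripted_tables):
        nodes, links = scripted_tables
        timeline = et.ScenarioTimeline(slices=(("1975", 1975),))
        traj = et.trajectory(nodes, links, EGO_ID, timeline, seed=3)
        net = et.slice_network(nodes, links, EGO_ID, 1975)
        record = et.descriptor_suite(net, seed=3)
        for field_name in ("n_alters", "n_links", "d1", "b_ego", "fragmentation"):
            assert traj.iloc[0][field_name] == getattr(record, field_name)

    def test_rows_independent_of_evaluation_order(self, scripted_tables):
        """Each row equals the standalone slice evaluation (stateless)."""
        nodes, links = scripted_tables
        timeline = et.ScenarioTimeline(
            slices=(("1800", 1800), ("1950", 1950), ("2000", 2000))
        )
        traj = et.trajectory(nodes, links, EGO_ID, timeline, seed=1)
        for label, year in reversed(timeline.slices):
            net = et.slice_network(nodes, links, EGO_ID, year)
            record = et.descriptor_suite(net, seed=1)
            row = traj.set_index("slice").loc[label]
            assert row["n_alters"] == record.n_alters
            assert row["d1"] == record.d1

    def test_empty_slice_gives_undefined_markers(self):
        nodes = pd.DataFrame([node_row(EGO_ID), node_row("a1", arrival=1900)])
        links = pd.DataFrame([link_row(EGO_ID, "a1", first=1900)])
        timeline = et.ScenarioTimeline(slices=(("1800", 1800), ("1950", 1950)))
        traj = et.trajectory(nodes, links, EGO_ID, timeline, seed=0)
        first = traj.iloc[0]
        assert math.isnan(first["d1"]) and math.isnan(first["n_alters"])
        assert traj.iloc[1]["n_alters"] == 1

    def test_branch_rows_fan_out_on_final_slice(self, scripted_tables):
        nodes, links = scripted_tables
        timeline = et.ScenarioTimeline(
            slices=(("1950", 1950), ("2100", 2100)),
            scenarios=("b1", "b2"),
        )
        nodes = pd.concat(
            [nodes, pd.DataFrame([node_row("b_only", arrival=2050,
                                           scenarios="b1")])],
            ignore_index=True,
        )
        links = pd.concat(
            [links, pd.DataFrame([link_row(EGO_ID, "b_only", first=2050)])],
            ignore_index=True,
        )
        traj = et.trajectory(nodes, links, EGO_ID, timeline, seed=0)
        assert len(traj) == 3
        by_scenario = traj.set_index("scenario")
        assert by_scenario.loc["b1", "n_alters"] == by_scenario.loc["b2", "n_alters"] + 1

    def test_timeline_years_must_increase(self):
        with pytest.raises(ValidationError, match="increasing"):
            et.ScenarioTimeline(slices=(("a", 1900), ("b", 1850)))

    def test_table_orientation(self, scripted_tables):
        nodes, links = scripted_tables
        timeline = et.ScenarioTimeline(slices=(("1800", 1800), ("1975", 1975)))
        traj = et.trajectory(nodes, links, EGO_ID, timeline, seed=0)
        wide = et.trajectory_table(traj)
        assert list(wide.columns) == ["1800", "1975"]
        assert "d1" in wide.index


class TestTurnover:
    def test_scripted_counts(self, scripted_tables):
        nodes, links = scripted_tables
        timeline = et.ScenarioTimeline(
            slices=(("1800", 1800), ("1950", 1950), ("1995", 1995))
        )
        records = et.turnover(nodes, links, EGO_ID, timeline)
        assert (records[0].native_in, records[0].native_out,
                records[0].exotic_in, records[0].exotic_out) == (0, 0, 2, 0)
        assert (records[1].exotic_out, records[1].native_out) == (1, 0)

    def test_constant_membership_all_zero(self):
        nodes, links = star_tables(4)
        timeline = et.ScenarioTimeline(slices=(("t0", 1800), ("t1", 1900)))
        records = et.turnover(nodes, links, EGO_ID, timeline)
        assert all(
            (r.native_in, r.native_out, r.exotic_in, r.exotic_out) == (0, 0, 0, 0)
            for r in records
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_ledger_identity_on_generated_timelines(self, seed):
        nodes, links, timeline = et.generate_timeline_dataset(seed=seed)
        for scenario in timeline.scenarios:
            records = et.turnover(nodes, links, EGO_ID, timeline, scenario)
            previous = et.slice_network(
                nodes, links, EGO_ID, timeline.slices[0][1], scenario
            ).n_alters
            for record in records:
                assert record.n_alters == previous + record.net_change
                previous = record.n_alters


class TestDescriptorCorrelations:
    def _traj(self, rows):
        return pd.DataFrame(rows, columns=list(CORRELATION_FIELDS))

    def test_identical_columns_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        data = {f: rng.normal(size=8) for f in CORRELATION_FIELDS}
        data["n_alters"] = base
        data["n_links"] = base.copy()
        coef, pval = et.descriptor_correlations(pd.DataFrame(data))
        assert coef.loc["n_alters", "n_links"] == pytest.approx(1.0)
        assert coef.shape == (10, 10)
        assert (pval.values.T == pval.values)[~np.isnan(pval.values)].all()

    def test_two_slices_insufficient(self):
        data = self._traj([[1.0] * 10, [2.0] * 10])
        with pytest.raises(et.EgotrophError, match="insufficient"):
            et.descriptor_correlations(data)

    def test_constant_column_marked_undefined(self):
        rng = np.random.default_rng(1)
        data = {f: rng.normal(size=6) for f in CORRELATION_FIELDS}
        data["d1"] = np.ones(6)
        coef, _ = et.descriptor_correlations(pd.DataFrame(data))
        assert coef.loc["d1"].drop("d1").isna().all()

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        data = {f: rng.normal(size=9) for f in CORRELATION_FIELDS}
        frame = pd.DataFrame(data)
        coef1, _ = et.descriptor_correlations(frame, method="spearman")
        frame2 = frame.copy()
        frame2["d1"] = np.exp(frame2["d1"])  # rank-preserving
        coef2, _ = et.descriptor_correlations(frame2, method="spearman")
        pd.testing.assert_frame_equal(coef1, coef2)

    def test_planted_correlation_recovered(self):
        """rho = 0.9 planted between two columns, n = 8 points, 200 replicates:
        the mean sample coefficient must sit near the analytic expectation."""
        rng = np.random.default_rng(42)
        estimates = []
        for _ in range(200):
            x = rng.normal(size=8)
            y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=8)
            data = {f: rng.normal(size=8) for f in CORRELATION_FIELDS}
            data["n_alters"], data["n_links"] = x, y
            coef, _ = et.descriptor_correlations(pd.DataFrame(data))
            estimates.append(coef.loc["n_alters", "n_links"])
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        # E[r] = rho * (1 - (1 - rho^2) / (2n)) + O(n^-2)  (Fisher expansion)
        expected = 0.9 * (1 - (1 - 0.81) / 16)
        assert abs(estimates.mean() - expected) < 4 * se


class TestBranchAgreement:
    def test_branches_identical_before_branch_point(self):
        nodes, links, timeline = et.generate_timeline_dataset(seed=11)
        for _, year in timeline.slices[:-1]:
            nets = [
                et.slice_network(nodes, links, EGO_ID, year, scenario,
                                 known_scenarios=timeline.scenarios)
                for scenario in timeline.scenarios
            ]
            assert nets[0].alter_ids == nets[1].alter_ids
            assert {l.key for l in nets[0].links} == {l.key for l in nets[1].links}

    def test_branches_differ_at_final_slice(self):
        nodes, links, timeline = et.generate_timeline_dataset(seed=11)
        year = timeline.slices[-1][1]
        with_mouse = et.slice_network(nodes, links, EGO_ID, year, BRANCH_WITH)
        without = et.slice_network(nodes, links, EGO_ID, year, BRANCH_WITHOUT)
        assert "mouse" in with_mouse.alter_ids
        assert "mouse" not in without.alter_ids
        assert with_mouse.alter_ids != without.alter_ids
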