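import math

import numpy as np
import pandas as pd
import pytest

from mcsf import (Visit, apply_missing_rules, build_parameter_table,
                  compute_aggregates, compute_indexes, compute_occurrence,
                  compute_relative_measures, compute_zone_descriptors)
from mcsf.descriptors import descriptor_row
from mcsf.errors import UsageError
from conftest import make_table


def V(zone, t0, t1, rat="r1", dist=0.0):
    return Visit(rat_id=rat, zone_id=zone, t_enter=t0, t_exit=t1,
                 distance=dist)


class TestZoneDescriptors:
    def test_hand_arithmetic(self, arena):
        d = compute_zone_descriptors(
            [V("dcr", 10, 25), V("dcr", 100, 130)], arena)
        assert d["LAT_dcr"] == 10
        assert d["FRQ_dcr"] == 2
        assert d["DUR_dcr"] == 45
        assert d["DURFRQ_dcr"] == 22.5

    def test_unvisited_zone(self, arena):
        d = compute_zone_descriptors([V("center", 0, 10)], arena)
        assert math.isnan(d["LAT_dcr"])
        assert d["FRQ_dcr"] == 0 and d["DUR_dcr"] == 0
        assert math.isnan(d["DURFRQ_dcr"])

    def test_whole_session_single_visit(self, arena):
        d = compute_zone_descriptors([V("center", 0, 1800)], arena)
        assert d["DUR_center"] == 1800 == d["DURFRQ_center"]

    def test_mixed_rats_rejected(self, arena):
        with pytest.raises(UsageError):
            compute_zone_descriptors(
                [V("dcr", 0, 1, rat="a"), V("dcr", 2, 3, rat="b")], arena)

    def test_velocity_is_distance_over_duration(self, arena):
        d = compute_zone_descriptors([V("center", 0, 10, dist=55.0)], arena)
        assert d["VEL_center"] == pytest.approx(5.5)


class TestAggregates:
    def test_corridor_sum_and_total_act(self, arena):
        visits = ([V("corr_a", i * 10, i * 10 + 5) for i in range(4)]
                  + [V("corr_b", 100 + i * 10, 105 + i * 10) for i in range(3)]
                  + [V("corr_c", 200 + i * 10, 205 + i * 10) for i in range(5)]
                  + [V("center", 300, 310)])
        d = compute_aggregates(compute_zone_descriptors(visits, arena), arena)
        assert d["FRQ_tot_corr"] == 12
        assert d["TOTAL_ACT"] == 13
        assert d["LAT_tot_corr"] == 0  # min member latency
        assert d["DUR_arena"] == pytest.approx(sum(
            d[f"DUR_{z}"] for z in arena.zone_ids))

    def test_empty_aggregates(self, arena):
        d = compute_aggregates(compute_zone_descriptors([], arena), arena)
        assert d["TOTAL_ACT"] == 0
        assert d["FRQ_tot_corr"] == 0
        assert math.isnan(d["LAT_tot_corr"])


class TestRelativeMeasures:
    def test_pct_frq(self, arena):
        visits = [V("dcr", i * 30, i * 30 + 10) for i in range(5)] \
            + [V("center", 200 + i * 30, 210 + i * 30) for i in range(45)]
        d = compute_aggregates(compute_zone_descriptors(visits, arena), arena)
        d = compute_relative_measures(d, arena)
        assert d["TOTAL_ACT"] == 50
        assert d["PCT_FRQ_dcr"] == pytest.approx(10.0)

    def test_pct_frq_sums_to_100(self, arena):
        visits = [V(z, i * 100 + j * 10, i * 100 + j * 10 + 5)
                  for i, z in enumerate(arena.zone_ids) for j in range(i + 1)]
        d = compute_aggregates(compute_zone_descriptors(visits, arena), arena)
        d = compute_relative_measures(d, arena)
        assert sum(d[f"PCT_FRQ_{z}"] for z in arena.zone_ids) \
            == pytest.approx(100.0)

    def test_pct_dur_trial_time(self, arena):
        d = compute_aggregates(compute_zone_descriptors(
            [V("center", 0, 180)], arena), arena)
        d = compute_relative_measures(d, arena, "trial_time",
                                      session_duration=1800.0)
        assert d["PCT_DUR_center"] == pytest.approx(10.0)

    def test_zero_activity_gives_missing(self, arena):
        d = compute_aggregates(compute_zone_descriptors([], arena), arena)
        d = compute_relative_measures(d, arena)
        assert math.isnan(d["PCT_FRQ_center"])


class TestOccurrence:
    def test_counts_positive_rats(self, arena):
        frq = [1, 2, 0, 3, 1, 0] + [0, 0, 0, 1, 2, 3]
        tab = make_table({"FRQ_bridge": frq}, ["A"] * 6 + ["B"] * 6)
        occ = compute_occurrence(tab, "FRQ_bridge")
        assert occ.loc["A", "positive"] == 4 and occ.loc["A", "n"] == 6
        assert occ.loc["B", "positive"] == 3

    def test_all_zero_column(self):
        tab = make_table({"FRQ_bridge": [0.0] * 6}, ["A"] * 3 + ["B"] * 3)
        occ = compute_occurrence(tab, "FRQ_bridge")
        assert (occ.positive == 0).all()

    def test_unknown_parameter(self):
        tab = make_table({"FRQ_bridge": [1.0, 2.0]}, ["A", "B"])
        with pytest.raises(UsageError):
            compute_occurrence(tab, "nope")


class TestMissingRules:
    def _table(self, arena):
        rows = [descriptor_row([V("center", 0, 100), V("corr_a", 100, 200)],
                               arena),
                descriptor_row([V("center", 0, 50), V("dcr", 60, 80)], arena)]
        idx = pd.MultiIndex.from_tuples(
            [("r1", "A", "1"), ("r2", "B", "1")],
            names=["rat_id", "group", "trial"])
        return pd.DataFrame(rows, index=idx)

    def test_between_trial_imputes_session_duration(self, arena):
        out = apply_missing_rules(self._table(arena), "between_trial",
                                  1800.0, arena)
        assert out.loc[("r1", "A", "1"), "LAT_dcr"] == 1800.0
        assert out.loc[("r1", "A", "1"), "FRQ_dcr"] == 0.0
        assert out.loc[("r1", "A", "1"), "DUR_dcr"] == 0.0
        assert math.isnan(out.loc[("r1", "A", "1"), "DURFRQ_dcr"])

    def test_within_trial_sets_missing(self, arena):
        out = apply_missing_rules(self._table(arena), "within_trial",
                                  1800.0, arena)
        for m in ("LAT", "FRQ", "DUR", "VEL"):
            assert math.isnan(out.loc[("r1", "A", "1"), f"{m}_dcr"])
        # within-trial mode must never write the imputation constant
        assert not (out == 1800.0).any().any() or \
            (self._table(arena) == 1800.0).any().any()

    def test_visited_zone_untouched(self, arena):
        raw = self._table(arena)
        for mode in ("within_trial", "between_trial"):
            out = apply_missing_rules(raw, mode, 1800.0, arena)
            assert out.loc[("r2", "B", "1"), "LAT_dcr"] == \
                raw.loc[("r2", "B", "1"), "LAT_dcr"]

    def test_idempotent(self, arena):
        raw = self._table(arena)
        for mode in ("within_trial", "between_trial"):
            once = apply_missing_rules(raw, mode, 1800.0, arena)
            twice = apply_missing_rules(once, mode, 1800.0, arena)
            pd.testing.assert_frame_equal(once, twice)


class TestIndexes:
    def test_symmetry_zero(self):
        idx = compute_indexes({"FRQ_dcr": 7.0, "FRQ_corr_a": 7.0})
        assert idx["shelter_corridor_index"] == 0

    def test_shelter_corridor(self):
        idx = compute_indexes({"FRQ_dcr": 2.0, "FRQ_corr_a": 6.0})
        assert idx["shelter_corridor_index"] == pytest.approx(-0.5)

    def test_slope_bridge_interval(self):
        idx = compute_indexes({"LAT_slope": 100.0, "LAT_bridge": 150.0})
        assert idx["slope_bridge_interval"] == pytest.approx(-0.5)
        idx = compute_indexes({"LAT_slope": 120.0, "LAT_bridge": 120.0})
        assert idx["slope_bridge_interval"] == 0

    def test_risk_shelter_duration(self):
        idx = compute_indexes({"DUR_bridge": 30.0, "DUR_dcr": 90.0})
        assert idx["risk_shelter_dur_index"] == pytest.approx(-0.5)

    def test_zero_denominator_missing(self):
        idx = compute_indexes({"FRQ_dcr": 0.0, "FRQ_corr_a": 0.0,
                               "FRQ_bridge": 0.0, "DUR_bridge": 0.0,
                               "DUR_dcr": 0.0, "LAT_slope": 0.0,
                               "LAT_bridge": 0.0})
        assert all(math.isnan(v) for v in idx.values())

    def test_ratio_indexes_bounded(self, rng):
        """All ratio-form indexes lie in [-1, 1] for any non-negative
        inputs; the slope/bridge interval is <= 0 whenever the slope is
        entered first."""
        for _ in range(200):
            d = {k: float(v) for k, v in zip(
                ("FRQ_dcr", "FRQ_corr_a", "DUR_bridge", "DUR_dcr",
                 "FRQ_bridge"), rng.uniform(0, 50, 5))}
            d["LAT_slope"] = float(rng.uniform(1, 1800))
            d["LAT_bridge"] = float(rng.uniform(1, 1800))
            idx = compute_indexes(d)
            for k in ("shelter_corridor_index", "risk_shelter_dur_index",
                      "risk_shelter_frq_index"):
                if not math.isnan(idx[k]):
                    assert -1 <= idx[k] <= 1
            if d["LAT_slope"] <= d["LAT_bridge"]:
                assert idx["slope_bridge_interval"] <= 0


def test_build_parameter_table_round_trip(arena, tmp_path):
    rows = []
    for rid, group in (("r1", "A"), ("r2", "B")):
        rows.append((rid, group, "1", "center", 0.0, 100.0, 500.0))
        rows.append((rid, group, "1", "corr_a", 100.0, 200.0, 400.0))
    log = pd.DataFrame(rows, columns=["rat_id", "group", "trial", "zone_id",
                                      "t_enter", "t_exit", "distance"])
    side = pd.DataFrame({"rat_id": ["r1", "r2"], "trial": ["1", "1"],
                         "rearings": [10, 20], "saps": [3, 4],
                         "grooming": [1, 1], "nose_pokes": [5, 2],
                         "urine_spots": [0, 1], "fecal_boli": [2, 0]})
    table = build_parameter_table(log, arena, sidecar=side)
    assert table.loc[("r1", "A", "1"), "FRQ_center"] == 1
    assert table.loc[("r2", "B", "1"), "rearings"] == 20
    assert table.loc[("r1", "A", "1"), "VEL_center"] == pytest.approx(5.0)
    assert table.loc[("r1", "A", "1"), "DUR_arena"] <= 1800.0 + 1e-9
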