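import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opdpipe.dynamics import (
    DEFAULT_CALENDAR,
    SeasonCalendar,
    accumulate,
    accumulated_batches,
    assign_spawning_season,
    batch_fecundity,
    build_table1,
    fecundity_vs_length,
    pool_pvo123,
    potential_batches,
    round_half_up,
    size_ratio_summary,
    spawning_duration,
    spawning_fraction,
)
from opdpipe.errors import MissingDataError, ModelDomainError

from table1_data import BATCHES, BF, CUMULATIVE_ROWS, DURATIONS, PF, populated_cells


class TestSeasonCalendar:
    def test_default_three_seasons(self):
        assert set(DEFAULT_CALENDAR.seasons) == {"SS1", "SS2", "SS3"}
        assert DEFAULT_CALENDAR.first_month("SS1") == 12
        assert DEFAULT_CALENDAR.last_month("SS1") == 5
        assert DEFAULT_CALENDAR.first_month("SS2") == 6

    def test_cyclic_neighbours(self):
        assert DEFAULT_CALENDAR.preceding("SS1") == "SS3"
        assert DEFAULT_CALENDAR.following("SS3") == "SS1"

    def test_non_contiguous_rejected(self):
        mapping = dict(DEFAULT_CALENDAR.month_to_season)
        mapping[1], mapping[7] = "SS2", "SS1"  # scatter the seasons
        with pytest.raises(ValueError):
            SeasonCalendar(mapping)

    def test_incomplete_rejected(self):
        with pytest.raises(ValueError):
            SeasonCalendar({1: "SS1"})


class TestSpawningFraction:
    def test_three_of_ten(self):
        records = pd.DataFrame(
            {"month": [3] * 12, "MAT": ["AS"] * 3 + ["SC"] * 5 + ["RT"] * 2 + ["IM"] * 2}
        )
        assert spawning_fraction(records, 3) == pytest.approx(0.3)

    def test_zero_actively_spawning(self):
        records = pd.DataFrame({"month": [4, 4], "MAT": ["SC", "DV"]})
        assert spawning_fraction(records, 4) == 0.0

    def test_no_mature_females(self):
        records = pd.DataFrame({"month": [5], "MAT": ["IM"]})
        with pytest.warns(UserWarning):
            assert np.isnan(spawning_fraction(records, 5))


class TestSeasonAssignment:
    def test_regenerating_first_month_goes_to_preceding(self):
        assert assign_spawning_season(6, "RT", False) == "SS1"

    def test_developing_no_markers_last_month_goes_to_next(self):
        assert assign_spawning_season(5, "DV", False) == "SS2"

    def test_developing_with_markers_stays(self):
        assert assign_spawning_season(5, "DV", True) == "SS1"

    def test_mid_season_stays(self):
        assert assign_spawning_season(7, "SC", False) == "SS2"

    def test_wrap_across_year_boundary(self):
        # SS1 starts in December; a regenerating female then belongs to SS3
        assert assign_spawning_season(12, "RT", False) == "SS3"
        # SS3 ends in November; early developer moves into SS1
        assert assign_spawning_season(11, "DV", False) == "SS1"

    def test_total_function_and_override_scope(self):
        for month in range(1, 13):
            for mat in ("IM", "DV", "SC", "AS", "RS", "RT"):
                season = assign_spawning_season(month, mat, False)
                assert season in {"SS1", "SS2", "SS3"}
                cal = DEFAULT_CALENDAR
                base = cal.season_of(month)
                if season != base:  # an override fired
                    assert month in (cal.first_month(base), cal.last_month(base))


class TestBatchArithmetic:
    def test_printed_cell_mean(self):
        assert batch_fecundity(300_000.0, 312_000.0) == pytest.approx(306_000.0)

    def test_equal_inputs(self):
        assert batch_fecundity(5.0, 5.0) == 5.0

    def test_one_sided(self):
        assert batch_fecundity(0.0, 10.0) == 5.0

    def test_both_zero_undefined(self):
        with pytest.raises(ModelDomainError):
            batch_fecundity(0.0, 0.0)

    def test_potential_batches(self):
        assert potential_batches(100.0, 100.0) == 2.0
        assert potential_batches(0.0, 50.0) == 0.0
        with pytest.raises(ModelDomainError):
            potential_batches(10.0, 0.0)

    def test_round_half_up(self):
        assert round_half_up(2.5) == 3
        assert round_half_up(2.49) == 2
        assert round_half_up(-2.5) == -3


class TestSpawningDuration:
    def test_62_batches(self):
        assert spawning_duration(62) == pytest.approx(8.3)

    def test_2_batches(self):
        assert spawning_duration(2) == pytest.approx(0.3)

    def test_zero(self):
        assert spawning_duration(0) == 0.0

    def test_rounding_switch_near_ten_months(self):
        assert spawning_duration(72) == pytest.approx(9.6)  # 9.6 stays decimal
        assert spawning_duration(76) == pytest.approx(10.0)  # 10.13 -> 10
        assert spawning_duration(80) == pytest.approx(11.0)  # 10.67 -> 11

    def test_linear_before_rounding(self):
        for b in (0, 5, 17, 40):
            assert spawning_duration(b, rounded=False) == pytest.approx(b * 4 / 30)


class TestAccumulate:
    def test_printed_50_60_ss1_through_ca(self):
        # PF through +CA is 995 thousand at BF 125 thousand -> 8 batches
        assert accumulated_batches(995.0, 125.0) == 8

    def test_printed_60_70_ss1_through_pvo4b(self):
        assert accumulated_batches(4900.0, 306.0) == 16

    def test_rows_monotone_and_additive(self):
        nos = {"VTO": 100.0, "EVTO": 100.0, "CAO": 50.0, "PVO4C": 30.0,
               "PVO4B": 30.0, "PVO4A": 20.0, "PVO1-3": 500.0}
        rows = accumulate(nos, BF=100.0)
        batches = [r.accumulated_batches for r in rows]
        assert batches == sorted(batches)
        for prev, cur, tok in zip(rows, rows[1:], list(nos)[1:]):
            assert cur.potential_fecundity == pytest.approx(
                prev.potential_fecundity + 2 * nos[tok]
            )

    def test_equal_vitellogenic_pools_give_two_then_four(self):
        nos = {"VTO": 100.0, "EVTO": 100.0}
        rows = accumulate(nos, BF=batch_fecundity(100.0, 100.0))
        assert rows[0].accumulated_batches == 2
        assert rows[1].accumulated_batches == 4
        # nothing beyond: batches stay at 4
        with pytest.warns(UserWarning):
            rows_full = accumulate(nos, BF=100.0)
        assert rows_full[-1].accumulated_batches == 4

    def test_pvo_pooling(self):
        pooled = pool_pvo123({"PVO1": 1.0, "PVO2": 2.0, "PVO3": 3.0, "VTO": 9.0})
        assert pooled == {"VTO": 9.0, "PVO1-3": 6.0}

    def test_mno_hyo_never_accumulated(self):
        nos = {"VTO": 100.0, "MNO": 1e9, "HYO": 1e9}
        with pytest.warns(UserWarning):
            rows = accumulate(nos, BF=100.0)
        assert rows[0].potential_fecundity == pytest.approx(200.0)
        assert all(r.stage_token not in ("MNO", "HYO") for r in rows)

    @given(st.lists(st.floats(0.0, 1e6), min_size=7, max_size=7), st.floats(1.0, 1e6))
    @settings(max_examples=80, deadline=None)
    def test_property_monotone_batches(self, nos, bf):
        order = ("VTO", "EVTO", "CAO", "PVO4C", "PVO4B", "PVO4A", "PVO1-3")
        rows = accumulate(dict(zip(order, nos)), BF=bf)
        batches = [r.accumulated_batches for r in rows]
        assert batches == sorted(batches)


class TestPrintedTable:
    """Exhaustive reproduction of every populated published cell."""

    @pytest.mark.parametrize(
        "tl_class,season,row,bf,pf,batches,duration",
        list(populated_cells()),
        ids=lambda v: str(v),
    )
    def test_batches_and_duration_cells(
        self, tl_class, season, row, bf, pf, batches, duration
    ):
        assert accumulated_batches(pf, bf) == batches
        assert spawning_duration(batches) == pytest.approx(duration)

    def test_sixty_six_batches_through_pvo4b(self):
        got = [
            accumulated_batches(PF["60-70"][s][4], BF["60-70"][s])
            for s in ("SS1", "SS2", "SS3")
        ]
        assert got == [16, 26, 24]
        assert sum(got) == 66

    def test_182_batches_through_pvo123(self):
        got = [
            accumulated_batches(PF["60-70"][s][6], BF["60-70"][s])
            for s in ("SS1", "SS2", "SS3")
        ]
        assert got == [38, 64, 80]
        assert sum(got) == 182

    def test_size_ratio_2_1(self):
        big = np.mean([PF["70-80"][s][6] for s in ("SS1", "SS2", "SS3")])
        small = np.mean([PF["50-60"][s][6] for s in ("SS1", "SS2", "SS3")])
        assert round(big / small, 1) == 2.1


class TestBuildTable1:
    @staticmethod
    def _records():
        """Females whose per-stage numbers reproduce the printed 60-70 block."""
        rows = []
        for season, month in (("SS1", 2), ("SS2", 7), ("SS3", 10)):
            pf = PF["60-70"][season]
            # potential fecundity doubles cumulative NO: invert to stage NOs
            cum = [p / 2 * 1e3 for p in pf]
            nos = np.diff([0.0] + cum)
            rows.append(
                {
                    "female_id": f"T{season}",
                    "month": month,
                    "MAT": "SC",
                    "TL_cm": 65.0,
                    "POF_present": False,
                    "NO_VTO": nos[0],
                    "NO_EVTO": nos[1],
                    "NO_CAO": nos[2],
                    "NO_PVO4C": nos[3],
                    "NO_PVO4B": nos[4],
                    "NO_PVO4A": nos[5],
                    "NO_PVO1": nos[6] / 3,
                    "NO_PVO2": nos[6] / 3,
                    "NO_PVO3": nos[6] / 3,
                }
            )
        return pd.DataFrame(rows)

    def test_reproduces_printed_60_70_block(self):
        """Stage numbers inverted from the printed cumulative column feed the
        report builder; every batch and duration cell comes back as printed.
        The builder's batch fecundity (mean of its vitellogenic pools) lands
        within rounding of the printed one, so the cells agree exactly."""
        report = build_table1(self._records())
        block = report[(report["tl_class"] == "60-70")]
        for season in ("SS1", "SS2", "SS3"):
            sub = block[block["season"] == season]
            assert list(sub["cumulative_stage"]) == list(CUMULATIVE_ROWS)
            got_pf = list(sub["PF_thousands"])
            got_b = list(sub["accumulated_batches"].astype(int))
            got_d = list(sub["duration_months"])
            assert got_pf == pytest.approx(PF["60-70"][season], rel=1e-9)
            assert got_b == BATCHES["60-70"][season]
            assert got_d == pytest.approx(DURATIONS["60-70"][season])

    def test_empty_cells_emitted_as_missing(self):
        records = self._records()
        report = build_table1(records)
        empty = report[(report["tl_class"] == "40-50")]
        assert len(empty) == 21  # 3 seasons x 7 cumulative rows
        assert empty["PF_thousands"].isna().all()

    def test_empty_input_gives_all_missing(self):
        records = self._records().iloc[0:0]
        with pytest.raises(MissingDataError):
            build_table1(records.drop(columns=[c for c in records.columns if c.startswith("NO_")]))
        report = build_table1(records)
        assert report["PF_thousands"].isna().all()

    def test_only_report_phases_included(self):
        records = self._records()
        records.loc[:, "MAT"] = "RT"  # regenerating: excluded
        report = build_table1(records)
        assert report["PF_thousands"].isna().all()


class TestSizeRatio:
    @staticmethod
    def _report():
        rows = []
        for tl_class, season_pf in PF.items():
            for season, col in season_pf.items():
                for label, pf in zip(CUMULATIVE_ROWS, col):
                    rows.append(
                        {
                            "tl_class": tl_class,
                            "season": season,
                            "cumulative_stage": label,
                            "PF_thousands": float(pf),
                        }
                    )
        return pd.DataFrame(rows)

    def test_printed_ratio(self):
        ratio = size_ratio_summary(self._report(), "70-80", "50-60", "+PVO1-3")
        assert round(ratio, 1) == 2.1

    def test_identical_classes(self):
        assert size_ratio_summary(self._report(), "60-70", "60-70", "VTO") == 1.0

    def test_missing_class_errors(self):
        with pytest.raises(MissingDataError):
            size_ratio_summary(self._report(), "90-100", "50-60", "VTO")


class TestFecundityVsLength:
    def test_cubic_cohort_positive_slope_every_run(self):
        rng = np.random.default_rng(11)
        detections = 0
        for _ in range(50):
            tl = rng.uniform(45, 80, size=40)
            no = 3.0 * tl**3 * np.exp(rng.normal(0, 0.1, size=40))
            seasons = rng.choice(["SS1", "SS2", "SS3"], size=40)
            res = fecundity_vs_length(
                pd.DataFrame({"TL_cm": tl, "NO_sum": no, "season": seasons})
            )
            detections += (res["slope"] > 0) and (res["slope_p"] < 0.05)
        assert detections == 50

    def test_season_invariant_rarely_flags_season(self):
        rng = np.random.default_rng(12)
        false_hits = 0
        runs = 100
        for _ in range(runs):
            tl = rng.uniform(45, 80, size=40)
            no = 1e3 * tl + rng.normal(0, 5e3, size=40)
            seasons = rng.choice(["SS1", "SS2", "SS3"], size=40)
            res = fecundity_vs_length(
                pd.DataFrame({"TL_cm": tl, "NO_sum": no, "season": seasons})
            )
            false_hits += res["season_p"] < 0.05
        assert false_hits / runs <= 0.10

    def test_flat_relation_slope_near_zero(self):
        tl = np.linspace(45, 80, 30)
        res = fecundity_vs_length(
            pd.DataFrame(
                {"TL_cm": tl, "NO_sum": np.full(30, 1e6), "season": ["SS1"] * 30}
            )
        )
        assert res["slope"] == pytest.approx(0.0, abs=1e-6)
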