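"""AOI-based crowd-navigation measures and task-performance statistics."""
import numpy as np
import pandas as pd
import pingouin as pg
import pytest

import crowdgaze as cg
from crowdgaze.timeline import ENCOUNTER_COLUMNS, EventTimeline, IncompleteEncounterError

from .conftest import make_recording


def timeline(start, end, encounters=()):
    rounds = pd.DataFrame({"round": [1], "start_s": [start], "end_s": [end]})
    enc = pd.DataFrame(list(encounters), columns=list(ENCOUNTER_COLUMNS)) if encounters \
        else pd.DataFrame(columns=list(ENCOUNTER_COLUMNS))
    return EventTimeline(rounds, enc)


def fixation_frame(rows):
    """rows: (onset_s, offset_s) pairs; duration in ms derived."""
    df = pd.DataFrame(rows, columns=["onset_s", "offset_s"])
    df["duration_ms"] = (df["offset_s"] - df["onset_s"]) * 1000.0
    df["mean_azimuth_deg"] = 0.0
    df["mean_elevation_deg"] = 0.0
    return df


class TestAnalysisWindow:
    def test_identical_coders(self):
        assert cg.analysis_window((timeline(10, 100), timeline(10, 100)), 1) == (10, 100)

    def test_intersection_of_coders(self):
        assert cg.analysis_window((timeline(10, 100), timeline(12, 98)), 1) == (12, 98)

    def test_irreconcilable_coders_rejected(self):
        with pytest.raises(ValueError):
            cg.analysis_window((timeline(10, 20), timeline(30, 40)), 1)

    def test_fixation_straddling_start_is_excluded(self):
        fix = fixation_frame([(9.5, 10.5), (20.0, 20.3)])
        q = cg.qualifying_fixations(fix, (10.0, 100.0))
        assert len(q) == 1
        assert q["onset_s"].iloc[0] == 20.0


class TestRoundDuration:
    def test_span_between_first_and_last_fixation(self):
        fix = fixation_frame([(5.0, 5.3), (50.0, 50.2), (90.0, 90.4)])
        assert cg.round_duration(fix, (0.0, 100.0)) == pytest.approx(85.4)

    def test_single_fixation(self):
        fix = fixation_frame([(5.0, 5.3)])
        assert cg.round_duration(fix, (0.0, 100.0)) == pytest.approx(0.3)

    def test_no_qualifying_fixation_flagged(self):
        fix = fixation_frame([(5.0, 5.3)])
        with pytest.warns(UserWarning):
            assert np.isnan(cg.round_duration(fix, (6.0, 100.0)))

    def test_scripted_round_duration_recovered(self):
        scen = cg.ScenarioSpec(round_duration_s=110.0)
        _, truth = cg.simulate_recording(scen, cg.NoiseModel(), seed=6)
        tl = truth.true_timeline
        window = cg.analysis_window((tl, tl), 1)
        dur = cg.round_duration(truth.true_fixations, window)
        assert dur == pytest.approx(110.0, abs=2.0)  # within one fixation span


class TestAoiSummary:
    def test_count_median_total(self):
        fix = fixation_frame([(1.0, 1.1), (2.0, 2.2), (3.0, 3.3)])
        consensus = pd.Series(["head_walker"] * 3)
        table = cg.aoi_summary(fix, consensus, (0.0, 10.0))
        row = table[table["aoi"] == "head_walker"].iloc[0]
        assert row["n_fixations"] == 3
        assert row["median_duration_ms"] == pytest.approx(200.0)
        assert row["total_duration_s"] == pytest.approx(0.6)

    def test_empty_aoi_reports_zero_and_missing_median(self):
        fix = fixation_frame([(1.0, 1.1)])
        table = cg.aoi_summary(fix, pd.Series(["walls"]), (0.0, 10.0))
        row = table[table["aoi"] == "objects"].iloc[0]
        assert row["n_fixations"] == 0
        assert row["total_duration_s"] == 0.0
        assert np.isnan(row["median_duration_ms"])

    def test_conservation_over_aois(self, default_sim):
        _, truth = default_sim
        fix = truth.true_fixations.copy()
        fix["duration_ms"] = (fix["offset_s"] - fix["onset_s"]) * 1000.0
        consensus = fix["aoi"]
        window = cg.analysis_window((truth.true_timeline, truth.true_timeline), 1)
        table = cg.aoi_summary(fix.drop(columns="aoi"), consensus, window)
        q = cg.qualifying_fixations(fix, window)
        assert table["n_fixations"].sum() == len(q)
        assert table["total_duration_s"].sum() == pytest.approx(
            q["duration_ms"].sum() / 1000.0
        )

    def test_scripted_schedule_recovered_exactly(self):
        fix = fixation_frame([(1.0, 1.2), (2.0, 2.4), (3.0, 3.1), (4.0, 4.5)])
        consensus = pd.Series(["walls", "walls", "objects", "head_walker"])
        table = cg.aoi_summary(fix, consensus, (0.0, 10.0)).set_index("aoi")
        assert table.loc["walls", "n_fixations"] == 2
        assert table.loc["walls", "median_duration_ms"] == pytest.approx(300.0)
        assert table.loc["objects", "total_duration_s"] == pytest.approx(0.1)
        assert table.loc["head_walker", "n_fixations"] == 1


class TestPeopleBounds:
    def test_worked_example_denominator(self):
        # 50 s in view at fixation proportion 0.8 -> 40-s upper denominator
        table = pd.DataFrame(
            {"aoi": ["group_distance"], "n_fixations": [1],
             "median_duration_ms": [100.0], "total_duration_s": [30.0]}
        )
        lower, upper = cg.people_relative_duration_bounds(table, 50.0, 0.8)
        assert lower == pytest.approx(30.0 / 50.0)
        assert upper == pytest.approx(30.0 / 40.0)

    def test_lower_never_exceeds_upper(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            total = rng.uniform(0, 30)
            table = pd.DataFrame(
                {"aoi": ["body_walker"], "n_fixations": [1],
                 "median_duration_ms": [100.0], "total_duration_s": [total]}
            )
            in_view = rng.uniform(31, 100)
            prop = rng.uniform(0.31, 1.0)
            lower, upper = cg.people_relative_duration_bounds(table, in_view, prop)
            assert lower <= upper

    def test_inconsistent_inputs_flagged(self):
        table = pd.DataFrame(
            {"aoi": ["head_walker"], "n_fixations": [1],
             "median_duration_ms": [100.0], "total_duration_s": [45.0]}
        )
        with pytest.warns(UserWarning):
            cg.people_relative_duration_bounds(table, 50.0, 0.8)


class TestGroupSizeMeasures:
    def test_relative_fixation_rate(self):
        assert cg.relative_fixations_eq1(20, 6, 4) == pytest.approx(1.0)
        assert cg.relative_fixations_eq1(0, 12) == 0.0
        for g in (6, 12, 20):
            assert cg.relative_fixations_eq1(10, g) == pytest.approx(10 / ((g - 1) * 4))

    def test_rejects_tiny_group(self):
        with pytest.raises(ValueError):
            cg.relative_fixations_eq1(5, 1)

    def test_in_group_window_and_missing_events(self):
        tl = timeline(0, 100, [(1, 0, 0, 20.0, 30.0, 45.0), (1, 1, 1, 50.0, 60.0, np.nan)])
        assert cg.in_group_window(tl, 0) == (30.0, 45.0)
        assert cg.group_in_view_window(tl, 0) == (20.0, 45.0)
        with pytest.raises(IncompleteEncounterError):
            cg.in_group_window(tl, 1)

    def test_truth_windows_recovered_from_generator(self, default_sim):
        _, truth = default_sim
        tl = truth.true_timeline
        for enc in tl.encounters["encounter"]:
            first, last = cg.in_group_window(tl, int(enc))
            row = tl.encounter_row(int(enc))
            assert first == row["first_out_s"] and last == row["last_out_s"]


class TestIccA1:
    def test_identical_columns_give_one(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert cg.icc_a1(x) == pytest.approx(1.0)

    def test_constant_offset_strictly_below_one(self):
        base = np.arange(10.0)
        x = np.column_stack([base, base + 5.0])
        val = cg.icc_a1(x)
        assert val < 1.0

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(2000, 2))
        assert abs(cg.icc_a1(x)) < 0.05

    def test_matches_pingouin_icc2(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n, k = 12, 3
            subject = rng.normal(0, 2, n)
            x = subject[:, None] + rng.normal(0, 1, (n, k)) + rng.normal(0, 0.5, k)
            long = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(n), k),
                    "raters": np.tile(np.arange(k), n),
                    "scores": x.ravel(),
                }
            )
            ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                                     ratings="scores")
            want = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
            assert cg.icc_a1(x) == pytest.approx(want, abs=1e-9)

    def test_zero_variance_defined_as_one(self):
        with pytest.warns(UserWarning):
            assert cg.icc_a1(np.full((5, 2), 3.0)) == 1.0


class TestRoundDifferences:
    @staticmethod
    def stacked_tables(values_r1, values_r2, observer="obs1"):
        rows = []
        for rnd, values in ((1, values_r1), (2, values_r2)):
            for aoi in cg.AOI_LABELS:
                n, med, tot = values.get(aoi, (0, np.nan, 0.0))
                rows.append((observer, rnd, aoi, n, med, tot))
        return pd.DataFrame(
            rows,
            columns=["observer", "round", "aoi", "n_fixations",
                     "median_duration_ms", "total_duration_s"],
        )

    def test_identical_rounds_zero_difference(self):
        vals = {"head_walker": (5, 200.0, 1.0)}
        diff = cg.round_differences(self.stacked_tables(vals, vals))
        assert np.allclose(diff["d_n_fixations"].fillna(0), 0)
        assert np.allclose(diff["d_total_duration_s"].fillna(0), 0)

    def test_head_increase_reported_positive(self):
        r1 = {"head_walker": (20, 200.0, 4.0)}
        r2 = {"head_walker": (30, 200.0, 6.0)}
        diff = cg.round_differences(self.stacked_tables(r1, r2)).set_index("aoi")
        assert diff.loc["head_walker", "d_n_fixations"] == 10
        assert diff.loc["head_walker", "d_total_duration_s"] == pytest.approx(2.0)

    def test_scripted_head_shift_sign_pattern(self):
        # dual-task round: more head fixations at the cost of body fixations
        for seed in (31, 32, 33):
            _, truth = cg.simulate_recording(seed=seed)
            fix = truth.true_fixations.copy()
            fix["duration_ms"] = (fix["offset_s"] - fix["onset_s"]) * 1000.0
            tl = truth.true_timeline
            tables = []
            for rnd in (1, 2):
                window = cg.analysis_window((tl, tl), rnd)
                table = cg.aoi_summary(fix.drop(columns="aoi"), fix["aoi"], window)
                table.insert(0, "round", rnd)
                table.insert(0, "observer", f"obs{seed}")
                tables.append(table)
            diff = cg.round_differences(pd.concat(tables)).set_index("aoi")
            assert diff.loc["head_walker", "d_n_fixations"] > 0
            assert diff.loc["body_walker", "d_n_fixations"] < 0

    def test_observer_missing_a_round_excluded(self):
        t = self.stacked_tables({"walls": (1, 100.0, 0.1)}, {"walls": (2, 100.0, 0.2)})
        extra = t[t["round"] == 1].assign(observer="obs2")
        with pytest.warns(UserWarning, match="obs2"):
            diff = cg.round_differences(pd.concat([t, extra]))
        assert set(diff["observer"]) == {"obs1"}


class TestDirectionStats:
    def test_constant_direction_zero_spread(self):
        az = np.full(200, 0.0)
        rec = make_recording(az)
        fix = fixation_frame([(0.0, 200 / 50.0)])
        stats = cg.fixation_direction_stats(rec, fix)
        for eye in ("left", "right"):
            assert stats[eye]["mean_azimuth_deg"] == 0.0
            assert stats[eye]["sd_azimuth_deg"] == 0.0

    def test_histogram_conserves_pooled_samples(self, default_sim):
        recording, truth = default_sim
        fix = truth.true_fixations.copy()
        fix["duration_ms"] = (fix["offset_s"] - fix["onset_s"]) * 1000.0
        stats = cg.fixation_direction_stats(recording, fix)
        for eye in ("left", "right"):
            assert stats[eye]["histogram"].sum() == stats[eye]["n_samples"]

    def test_known_gaussian_center_recovered(self):
        rng = np.random.default_rng(10)
        n = 5000
        az = rng.normal(-1.5, 10.0, n)
        el = rng.normal(-9.4, 7.0, n)
        rec = make_recording(az, el, az.copy(), el.copy())
        fix = fixation_frame([(0.0, n / 50.0)])
        stats = cg.fixation_direction_stats(rec, fix)
        se_az = 10.0 / np.sqrt(n)
        assert stats["left"]["mean_azimuth_deg"] == pytest.approx(-1.5, abs=4 * se_az)
        assert stats["left"]["sd_elevation_deg"] == pytest.approx(7.0, rel=0.05)

    def test_shift_invariance_of_measures(self):
        fix = fixation_frame([(5.0, 5.3), (8.0, 8.2)])
        consensus = pd.Series(["walls", "objects"])
        t1 = cg.aoi_summary(fix, consensus, (0.0, 10.0))
        shifted = fix.copy()
        shifted[["onset_s", "offset_s"]] += 100.0
        t2 = cg.aoi_summary(shifted, consensus, (100.0, 110.0))
        pd.testing.assert_frame_equal(t1, t2)
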