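from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from roostradar import (
    Box,
    DailySummary,
    Detection,
    PrecipSpec,
    QuantConfig,
    RoostSpec,
    Track,
    classify_day,
    cluster_roosts,
    compare_regions,
    daily_total,
    presence_reconciliation,
    sensitivity_profile,
    simulate_series,
    stable_vs_satellite,
    summarize_days,
)
from roostradar.summary import constant_daily_summaries

T0 = datetime(2014, 3, 1, 9, 24, tzinfo=timezone.utc)


def _track(birds, cls="clear", x=40.0, y=10.0, d=date(2014, 3, 1)):
    ts = datetime.combine(d, datetime.min.time(), tzinfo=timezone.utc).replace(hour=9)
    return Track(
        track_id=0,
        detections=[
            Detection(timestamp=ts, box=Box(x - 2, y - 2, x + 2, y + 2),
                      birds=birds, cls=cls)
        ],
    )


class TestClassifyDay:
    def test_clean_day_is_sampled(self, config_360, qc_open):
        roost = RoostSpec(center=(40, 10), first_scan_time=T0, total_birds=5000)
        series, _, _ = simulate_series(config_360, [roost], seed=0, qc=qc_open)
        assert classify_day(series, date(2014, 3, 1)) == "sampled"

    def test_insufficient_below_six_scans(self, config_360, qc_open):
        roost = RoostSpec(center=(40, 10), first_scan_time=T0, total_birds=5000)
        series, _, _ = simulate_series(config_360, [roost], seed=0, qc=qc_open)
        all_volumes = list(series.volumes)
        series.volumes = all_volumes[:5]
        assert classify_day(series, date(2014, 3, 1)) == "insufficient"
        series.volumes = all_volumes[:6]  # boundary: exactly 6 scans suffice
        assert classify_day(series, date(2014, 3, 1)) == "sampled"

    def test_precip_day_is_contaminated(self, config_360, qc_open):
        roost = RoostSpec(center=(40, 10), first_scan_time=T0, total_birds=5000)
        rain = PrecipSpec(center=(-30, -30), radius=5.0)
        series, _, _ = simulate_series(
            config_360, [roost], precip=[rain], seed=0, qc=qc_open
        )
        assert classify_day(series, date(2014, 3, 1)) == "contaminated"

    def test_failure_day(self, config_360, qc_open):
        d = date(2014, 3, 1)
        series, _, _ = simulate_series(
            config_360, [], days=[d], seed=0, qc=qc_open, failure_dates={d}
        )
        assert classify_day(series, d) == "radar_failure"

    def test_unknown_date_rejected(self, config_360, qc_open):
        series, _, _ = simulate_series(
            config_360, [], days=[date(2014, 3, 1)], seed=0, qc=qc_open
        )
        with pytest.raises(KeyError):
            classify_day(series, date(2019, 1, 1))


class TestDailyTotal:
    def test_no_tracks_is_zero(self):
        assert daily_total([]) == 0.0

    def test_sums_track_peaks(self):
        # the printed 2014 range endpoints as fixture inputs
        tracks = [_track(31_649), _track(1_487)]
        assert daily_total(tracks) == 33_136

    def test_rain_tracks_excluded_clutter_included_by_default(self):
        tracks = [_track(1000), _track(500, cls="rain"), _track(200, cls="clutter")]
        assert daily_total(tracks) == 1200
        assert daily_total(tracks, include_clutter_mixed=False) == 1000


class TestSummariesAndPresence:
    def test_daily_summary_invariants_enforced(self):
        with pytest.raises(ValueError):
            DailySummary(date(2014, 1, 1), 15, "contaminated", total_birds=5.0)
        with pytest.raises(ValueError):
            DailySummary(date(2014, 1, 1), 15, "sampled", presence=True,
                         true_zero=True, total_birds=5.0)

    def test_true_zero_and_contaminated_presence(self, config_360, qc_open):
        d_zero, d_rain = date(2014, 3, 1), date(2014, 3, 2)
        roost = RoostSpec(
            center=(40, 10),
            first_scan_time=T0 + timedelta(days=1),
            total_birds=5000,
        )
        rain = PrecipSpec(center=(-30, -30), radius=5.0,
                          active_dates={d_rain})
        series, _, ann = simulate_series(
            config_360, [roost], precip=[rain], days=[d_zero, d_rain],
            seed=0, qc=qc_open,
        )
        from roostradar import run_pipeline

        _, _, summaries = run_pipeline(series, ann, qc=qc_open)
        by_date = {s.date: s for s in summaries}
        assert by_date[d_zero].status == "sampled"
        assert by_date[d_zero].true_zero and not by_date[d_zero].presence
        assert by_date[d_rain].status == "contaminated"
        assert by_date[d_rain].presence and not by_date[d_rain].true_zero
        assert by_date[d_rain].total_birds is None

    def test_reconciliation_adds_categories(self):
        summaries = []
        summaries += constant_daily_summaries(2014, 100, 5000.0)
        for i in range(30):
            summaries.append(
                DailySummary(date(2014, 6, 1) + timedelta(days=i), 10,
                             "contaminated", presence=True)
            )
        for i in range(12):
            summaries.append(
                DailySummary(date(2014, 11, 1) + timedelta(days=i), 0,
                             "radar_failure")
            )
        recon = presence_reconciliation(summaries)
        row = recon.iloc[0]
        assert row["sampled_days"] == 100
        assert row["contaminated_presence_days"] == 30
        assert row["presence_days_total"] == 130


class TestClustering:
    def test_identical_centroids_single_cluster(self):
        pts = np.tile([[10.0, 5.0]], (8, 1))
        dates = [date(2014, 3, 1 + i) for i in range(8)]
        cs = cluster_roosts(pts, dates, bandwidth=10.0)
        assert len(cs) == 1
        assert cs.clusters[0].centroid == pytest.approx((10.0, 5.0))

    def test_two_sites_40km_apart_two_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal([10, 10], 1.0, size=(20, 2))
        b = rng.normal([50, 10], 1.0, size=(10, 2))
        pts = np.vstack([a, b])
        dates = [date(2014, 3, 1) + timedelta(days=i) for i in range(30)]
        cs = cluster_roosts(pts, dates, bandwidth=10.0)
        assert len(cs) == 2
        # labels ordered by member count: CL0000 is the 20-member site
        assert cs.clusters[0].label == "CL0000"
        assert cs.clusters[0].n_members == 20
        assert cs.clusters[0].centroid[0] == pytest.approx(10.0, abs=1.0)
        assert cs.clusters[1].centroid[0] == pytest.approx(50.0, abs=1.0)

    def test_label_assignment_order_independent(self):
        rng = np.random.default_rng(1)
        a = rng.normal([10, 10], 1.0, size=(12, 2))
        b = rng.normal([50, 10], 1.0, size=(5, 2))
        pts = np.vstack([a, b])
        dates = [date(2014, 3, 1) + timedelta(days=i) for i in range(17)]
        cs1 = cluster_roosts(pts, dates, bandwidth=10.0)
        perm = rng.permutation(17)
        cs2 = cluster_roosts(pts[perm], [dates[i] for i in perm], bandwidth=10.0)
        for c1, c2 in zip(cs1.clusters, cs2.clusters):
            assert c1.label == c2.label
            assert c1.centroid == pytest.approx(c2.centroid, abs=1e-6)
            assert c1.n_members == c2.n_members

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            cluster_roosts(np.array([[0.0, 0.0]]), [date(2014, 1, 1)], bandwidth=0)

    def test_stable_vs_satellite_flags(self):
        # site A occupied both years, B only 2014, C both but sparsely
        pts, dates = [], []
        for i in range(40):
            pts.append([10, 10]); dates.append(date(2014, 3, 1) + timedelta(days=i))
            pts.append([10, 10]); dates.append(date(2015, 3, 1) + timedelta(days=i))
        for i in range(35):
            pts.append([50, 10]); dates.append(date(2014, 6, 1) + timedelta(days=i))
        for i in range(5):
            pts.append([10, 50]); dates.append(date(2014, 8, 1) + timedelta(days=i))
            pts.append([10, 50]); dates.append(date(2015, 8, 1) + timedelta(days=i))
        cs = cluster_roosts(np.array(pts, dtype=float), dates, bandwidth=10.0)
        flags = stable_vs_satellite(cs, min_days_per_year=30)
        by_label = {c.label: c.stable for c in cs.clusters}
        # 80-member site stable; 35-member single-year site satellite;
        # 10-member sparse site satellite
        assert flags == [True, False, False]
        assert by_label["CL0000"] is True

    def test_cluster_occupancy_counts_distinct_dates(self):
        pts = np.array([[10.0, 10.0]] * 4)
        dates = [date(2014, 3, 1), date(2014, 3, 1), date(2014, 3, 2),
                 date(2015, 1, 1)]
        cs = cluster_roosts(pts, dates, bandwidth=5.0)
        assert cs.clusters[0].occupancy_by_year == {2014: 2, 2015: 1}


class TestSensitivityProfile:
    def test_constant_field(self, config_360, qc_open):
        series, _, _ = simulate_series(
            config_360, [], days=[date(2014, 3, 1)], seed=0, qc=qc_open,
            n_ranges=40,
        )
        for v in series.volumes:
            v.sweeps[0].dbz[:] = 10.0
        prof = sensitivity_profile(series)
        assert np.allclose(prof["min_dbz"], 10.0)
        assert np.allclose(prof["max_dbz"], 10.0)

    def test_no_echo_column_is_absent(self, config_360, qc_open):
        series, _, _ = simulate_series(
            config_360, [], days=[date(2014, 3, 1)], seed=0, qc=qc_open,
            n_ranges=40,
        )
        for v in series.volumes:
            v.sweeps[0].dbz[:] = 10.0
            v.sweeps[0].dbz[:, 20] = np.nan
        prof = sensitivity_profile(series)
        assert np.isnan(prof["min_dbz"].iloc[20])
        assert not np.isnan(prof["min_dbz"].iloc[19])

    def test_min_profile_tracks_range_dependent_floor(self, config_360, qc_open):
        series, _, _ = simulate_series(
            config_360, [], days=[date(2014, 3, 1)], seed=0, qc=qc_open,
            n_ranges=40,
        )
        rng = np.random.default_rng(2)
        floor = np.linspace(5.0, 20.0, 40)
        for v in series.volumes:
            noise = rng.uniform(0.0, 3.0, v.sweeps[0].dbz.shape)
            v.sweeps[0].dbz[:] = floor[None, :] + noise
        prof = sensitivity_profile(series)
        assert np.all(np.abs(prof["min_dbz"].to_numpy() - floor) < 1.0)

    def test_sample_fraction_subsamples_deterministically(self, config_360, qc_open):
        series, _, _ = simulate_series(
            config_360, [], days=[date(2014, 3, 1)], seed=0, qc=qc_open,
            n_ranges=40,
        )
        for i, v in enumerate(series.volumes):
            v.sweeps[0].dbz[:] = 5.0 + i
        p1 = sensitivity_profile(series, sample_fraction=0.3, seed=5)
        p2 = sensitivity_profile(series, sample_fraction=0.3, seed=5)
        pd.testing.assert_frame_equal(p1, p2)


class TestCompareRegions:
    def test_identical_series_unit_ratios(self):
        a = constant_daily_summaries(2014, 50, 1000.0)
        rc = compare_regions(a, a, 90_000.0, 90_000.0)
        assert rc.mean_ratio[2014] == pytest.approx(1.0)
        assert rc.area_ratio == pytest.approx(1.0)

    def test_printed_daily_means_reproduce_ratio(self):
        manaus = constant_daily_summaries(2014, 178, 71_606.0)
        lakes = constant_daily_summaries(2014, 100, 56_956.0)
        rc = compare_regions(manaus, lakes, 90_000.0, 787_229.0)
        assert round(rc.mean_ratio[2014], 2) == 1.26

    def test_printed_areas_reproduce_ratio(self):
        a = constant_daily_summaries(2014, 10, 1.0)
        rc = compare_regions(a, a, 90_000.0, 787_229.0)
        assert round(rc.area_ratio, 1) == 8.7

    def test_only_sampled_days_enter_stats(self):
        a = constant_daily_summaries(2014, 20, 1000.0)
        a.append(DailySummary(date(2014, 12, 1), 10, "contaminated",
                              presence=True))
        rc = compare_regions(a, constant_daily_summaries(2014, 5, 500.0),
                             1.0, 1.0)
        assert rc.mean_a[2014] == pytest.approx(1000.0)

    def test_nonpositive_area_rejected(self):
        a = constant_daily_summaries(2014, 5, 10.0)
        with pytest.raises(ValueError):
            compare_regions(a, a, 0.0, 1.0)
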