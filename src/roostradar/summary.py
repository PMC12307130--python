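"""Day-level bookkeeping, roost-site clustering, and region comparison.

A day counts as *sampled* for roost-size estimation only if the radar was up,
at least 6 of the expected 15 morning-window scans exist, and the day was not
flagged for precipitation or anomalous propagation.  Contaminated days still
contribute presence (a roost seen through rain is a real roost) but never
counts.  A *true zero* is a sampled day with the full field observable and no
roost anywhere.  Roost sites are found by mean-shift clustering of track
first-centroids (flat kernel); clusters occupied for at least a threshold
number of days in every study year are *stable*, the rest *satellite*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from sklearn.cluster import MeanShift

from .polar import ScanSeries, in_sampling_window
from .tracking import Track

__all__ = [
    "DailySummary",
    "RoostCluster",
    "RoostClusterSet",
    "RegionComparison",
    "classify_day",
    "daily_total",
    "summarize_days",
    "presence_calendar",
    "presence_reconciliation",
    "cluster_roosts",
    "stable_vs_satellite",
    "sensitivity_profile",
    "compare_regions",
]

MIN_SCANS_SAMPLED = 6


@dataclass
class DailySummary:
    date: date
    n_window_scans: int
    status: str                    # sampled | insufficient | radar_failure | contaminated
    presence: bool = False
    true_zero: bool = False
    total_birds: float | None = None

    def __post_init__(self) -> None:
        if (self.total_birds is not None) != (self.status == "sampled"):
            raise ValueError("total_birds present iff status == sampled")
        if self.true_zero and (self.status != "sampled" or self.presence):
            raise ValueError("true_zero requires a sampled day without presence")


def classify_day(series: ScanSeries, d: date) -> str:
    """Sampling status of one day: radar_failure, insufficient, contaminated
    or sampled (in that precedence order)."""
    if d not in series.day_notes:
        raise KeyError(f"no day notes for {d}")
    notes = series.day_notes[d]
    if notes.radar_failure:
        return "radar_failure"
    n = sum(
        1
        for v in series.volumes_on(d)
        if in_sampling_window(v.timestamp, series.config)
    )
    if n < MIN_SCANS_SAMPLED:
        return "insufficient"
    if notes.precipitation or notes.anomalous_propagation:
        return "contaminated"
    return "sampled"


def daily_total(tracks: list[Track], include_clutter_mixed: bool = True) -> float:
    """Sum of per-track peak counts for one sampled day.

    Rain-contaminated tracks are excluded (they flag presence only);
    clutter-mixed tracks were quantified through the clutter mask and are
    included by default.
    """
    total = 0.0
    for t in tracks:
        if t.rain_contaminated:
            continue
        if not include_clutter_mixed and t.contaminated:
            continue
        total += t.peak_count
    return total


def summarize_days(
    series: ScanSeries,
    tracks_by_date: dict[date, list[Track]],
    include_clutter_mixed: bool = True,
) -> list[DailySummary]:
    """One DailySummary per calendar date of the series."""
    out = []
    for d in series.dates():
        status = classify_day(series, d)
        tracks = tracks_by_date.get(d, [])
        presence = len(tracks) > 0
        total = None
        true_zero = False
        if status == "sampled":
            total = daily_total(tracks, include_clutter_mixed)
            true_zero = not presence
        out.append(
            DailySummary(
                date=d,
                n_window_scans=sum(
                    1
                    for v in series.volumes_on(d)
                    if in_sampling_window(v.timestamp, series.config)
                ),
                status=status,
                presence=presence,
                true_zero=true_zero,
                total_birds=total,
            )
        )
    return out


def presence_calendar(summaries: list[DailySummary]) -> pd.DataFrame:
    """Per-day presence and true-zero flags as a tidy frame."""
    return pd.DataFrame(
        [
            {
                "date": s.date,
                "status": s.status,
                "presence": s.presence,
                "true_zero": s.true_zero,
            }
            for s in summaries
        ]
    )


def presence_reconciliation(summaries: list[DailySummary]) -> pd.DataFrame:
    """Per-year reconciliation of the presence/absence bookkeeping.

    Presence/absence sampling combines clear (sampled) days with
    contaminated days on which a roost was still visible; the two categories
    must add up to the presence-analysis day total.
    """
    rows = {}
    for s in summaries:
        y = s.date.year
        r = rows.setdefault(
            y,
            {
                "year": y,
                "sampled_days": 0,
                "contaminated_presence_days": 0,
                "presence_days_total": 0,
                "true_zero_days": 0,
            },
        )
        if s.status == "sampled":
            r["sampled_days"] += 1
            r["true_zero_days"] += int(s.true_zero)
        elif s.status == "contaminated" and s.presence:
            r["contaminated_presence_days"] += 1
    for r in rows.values():
        r["presence_days_total"] = r["sampled_days"] + r["contaminated_presence_days"]
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["year"]))


@dataclass
class RoostCluster:
    label: str                       # CL0000, CL0001, ... by member count
    centroid: tuple[float, float]    # km east/north
    member_dates: list[date] = field(default_factory=list)
    n_members: int = 0
    occupancy_by_year: dict[int, int] = field(default_factory=dict)
    stable: bool = False


@dataclass
class RoostClusterSet:
    clusters: list[RoostCluster]
    bandwidth: float
    labels: np.ndarray               # per input centroid, index into clusters

    def __len__(self) -> int:
        return len(self.clusters)


def cluster_roosts(
    first_centroids: np.ndarray,
    dates: list[date],
    bandwidth: float = 10.0,
) -> RoostClusterSet:
    """Mean-shift clustering of track first-centroids into roost sites.

    Flat kernel of the given ``bandwidth`` (km).  Labels are reassigned in
    descending order of member count (ties by centroid x, east first) and
    formatted CL0000, CL0001, ...; per-year occupancy counts distinct dates
    with at least one member track.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    pts = np.asarray(first_centroids, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 1:
        raise ValueError("need at least one centroid")
    if len(dates) != pts.shape[0]:
        raise ValueError("dates and centroids must align")
    ms = MeanShift(bandwidth=bandwidth, bin_seeding=False, cluster_all=True)
    raw = ms.fit_predict(pts)
    order = sorted(
        np.unique(raw),
        key=lambda lab: (
            -int(np.count_nonzero(raw == lab)),
            float(ms.cluster_centers_[lab][0]),
        ),
    )
    clusters = []
    relabel = np.empty_like(raw)
    for rank, lab in enumerate(order):
        members = raw == lab
        relabel[members] = rank
        mdates = [d for d, m in zip(dates, members) if m]
        occ: dict[int, int] = {}
        for y in {d.year for d in mdates}:
            occ[y] = len({d for d in mdates if d.year == y})
        clusters.append(
            RoostCluster(
                label=f"CL{rank:04d}",
                centroid=tuple(ms.cluster_centers_[lab]),
                member_dates=sorted(mdates),
                n_members=int(np.count_nonzero(members)),
                occupancy_by_year=occ,
            )
        )
    return RoostClusterSet(clusters=clusters, bandwidth=bandwidth, labels=relabel)


def stable_vs_satellite(
    clusters: RoostClusterSet,
    min_days_per_year: int = 30,
    years: list[int] | None = None,
) -> list[bool]:
    """Flag each cluster stable iff occupied >= min_days_per_year in every
    observed study year; others are satellite (transient) sites."""
    if years is None:
        years = sorted(
            {y for c in clusters.clusters for y in c.occupancy_by_year}
        )
    flags = []
    for c in clusters.clusters:
        ok = all(c.occupancy_by_year.get(y, 0) >= min_days_per_year for y in years)
        c.stable = ok
        flags.append(ok)
    return flags


def sensitivity_profile(
    series: ScanSeries,
    sample_fraction: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-range-gate minimum and maximum detected reflectivity.

    For each sampled scan's first sweep, take the min and max over azimuths
    of the detected (non-sentinel) dBZ at each range gate, then average
    across scans.  Gates never carrying echo are NaN.  ``sample_fraction``
    subsamples scans (seeded) the way a large archive would be screened.
    """
    if not series.volumes:
        raise ValueError("series has no scans")
    vols = list(series.volumes)
    if sample_fraction < 1.0:
        rng = np.random.default_rng(seed)
        k = max(1, int(round(sample_fraction * len(vols))))
        idx = sorted(rng.choice(len(vols), size=k, replace=False))
        vols = [vols[i] for i in idx]
    import warnings as _warnings

    mins, maxs = [], []
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN gate columns
        for v in vols:
            dbz = v.first_sweep.dbz
            mins.append(np.nanmin(dbz, axis=0))
            maxs.append(np.nanmax(dbz, axis=0))
        min_prof = np.nanmean(np.vstack(mins), axis=0)
        max_prof = np.nanmean(np.vstack(maxs), axis=0)
    return pd.DataFrame(
        {
            "range_m": vols[0].first_sweep.range_centers,
            "min_dbz": min_prof,
            "max_dbz": max_prof,
        }
    )


@dataclass
class RegionComparison:
    """Daily-abundance comparison between two radar-sampled regions."""

    mean_a: dict[int, float]
    sd_a: dict[int, float]
    mean_b: dict[int, float]
    sd_b: dict[int, float]
    area_a: float
    area_b: float
    mean_ratio: dict[int, float]     # A over B, per shared year
    area_ratio: float                # B over A

    def to_frame(self) -> pd.DataFrame:
        years = sorted(self.mean_ratio)
        return pd.DataFrame(
            {
                "year": years,
                "mean_a": [self.mean_a[y] for y in years],
                "sd_a": [self.sd_a[y] for y in years],
                "mean_b": [self.mean_b.get(y, np.nan) for y in years],
                "sd_b": [self.sd_b.get(y, np.nan) for y in years],
                "mean_ratio": [self.mean_ratio[y] for y in years],
            }
        )


def _yearly_stats(summaries: list[DailySummary]) -> tuple[dict, dict]:
    by_year: dict[int, list[float]] = {}
    for s in summaries:
        if s.status == "sampled":
            by_year.setdefault(s.date.year, []).append(float(s.total_birds))
    means = {y: float(np.mean(v)) for y, v in by_year.items()}
    sds = {y: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for y, v in by_year.items()}
    return means, sds


def compare_regions(
    summaries_a: list[DailySummary],
    summaries_b: list[DailySummary],
    area_a: float,
    area_b: float,
) -> RegionComparison:
    """Per-year mean/SD of daily totals over sampled days, the A/B mean
    ratio per shared year, and the B/A sampled-area ratio."""
    if area_a <= 0 or area_b <= 0:
        raise ValueError("areas must be positive")
    mean_a, sd_a = _yearly_stats(summaries_a)
    mean_b, sd_b = _yearly_stats(summaries_b)
    if not mean_a or not mean_b:
        raise ValueError("each region needs at least one sampled day")
    ratios = {
        y: mean_a[y] / mean_b[y]
        for y in sorted(set(mean_a) & set(mean_b))
        if mean_b[y] != 0
    }
    return RegionComparison(
        mean_a=mean_a,
        sd_a=sd_a,
        mean_b=mean_b,
        sd_b=sd_b,
        area_a=area_a,
        area_b=area_b,
        mean_ratio=ratios,
        area_ratio=area_b / area_a,
    )


def constant_daily_summaries(
    year: int, n_days: int, daily_total_birds: float
) -> list[DailySummary]:
    """Fixture helper: n sampled days of a constant daily total (used to feed
    printed per-year means through compare_regions)."""
    from datetime import timedelta

    start = date(year, 1, 1)
    return [
        DailySummary(
            date=start + timedelta(days=i),
            n_window_scans=15,
            status="sampled",
            presence=daily_total_birds > 0,
            true_zero=daily_total_birds == 0,
            total_birds=daily_total_birds,
        )
        for i in range(n_days)
    ]
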