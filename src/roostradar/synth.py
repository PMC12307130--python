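"""Synthetic radar scenes with known ground truth.

The proprietary Manaus archive cannot be redistributed, so every downstream
stage is exercised on generated scenes instead: ring-shaped morning roost
dispersals of known total bird number, a static near-radar clutter annulus
with multiplicative scan-to-scan jitter, moving precipitation blobs, and the
~12-min scan cadence inside the 05:00-08:00 local morning window.

The generator *inverts* the quantification forward model: for each roost and
scan it chooses a uniform scatterer density d over the ring's first-sweep
gates such that the overlap-corrected volume integral sum(d * V_full * (1-f))
equals the airborne bird number.  Recovery tests therefore isolate pipeline
bugs rather than model mismatch.  A ``use_overlap_correction=False`` flag
generates against the naive (no-overlap) volume instead, to demonstrate the
bias the correction removes.

All signals are combined additively in linear reflectivity units; an active
precipitation blob overwrites (takes the max) where it is stronger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone

import numpy as np
import pandas as pd

from .polar import DayNotes, PolarSweep, RadarConfig, ScanSeries, ScanVolume
from .quantify import (
    Box,
    GeometryCache,
    QuantConfig,
    eta_to_z,
)

__all__ = [
    "RoostSpec",
    "ClutterSpec",
    "PrecipSpec",
    "RoostScanTruth",
    "GroundTruthManifest",
    "GenerationError",
    "daily_roosts",
    "simulate_series",
    "emit_annotations",
    "scan_id_for",
]


class GenerationError(ValueError):
    """The requested scene geometry is impossible to generate."""


@dataclass(frozen=True)
class RoostSpec:
    """One communal roost and the morning dispersals it produces.

    At the k-th scan after ``first_scan_time`` the airborne birds occupy the
    ground annulus [k*ring_expansion, k*ring_expansion + ring_width] km
    around ``center``; ``per_scan_airborne_fraction`` scales the fraction of
    ``total_birds`` aloft at each scan (scalar, or one value per scan).
    """

    center: tuple[float, float]          # km east/north of the radar
    first_scan_time: datetime
    n_scans: int = 4
    total_birds: float = 10_000.0
    ring_expansion: float = 1.5          # km per scan
    ring_width: float = 2.0              # km
    per_scan_airborne_fraction: float | tuple[float, ...] = 1.0

    def __post_init__(self) -> None:
        if self.total_birds <= 0:
            raise ValueError("total_birds must be positive")
        if self.ring_width <= 0:
            raise ValueError("ring_width must be positive")
        ts = self.first_scan_time
        if ts.tzinfo is None:
            object.__setattr__(self, "first_scan_time", ts.replace(tzinfo=timezone.utc))
        outer = (self.n_scans - 1) * self.ring_expansion + self.ring_width
        if math.hypot(*self.center) + outer > 100.0:
            raise ValueError("ring footprint must stay within 100 km of the radar")

    def fraction_at(self, k: int) -> float:
        f = self.per_scan_airborne_fraction
        if np.isscalar(f):
            return float(f)
        return float(f[k]) if k < len(f) else float(f[-1])

    def annulus_at(self, k: int) -> tuple[float, float]:
        """(inner, outer) ground radius km of the ring at scan k."""
        inner = k * self.ring_expansion
        return inner, inner + self.ring_width

    def true_box(self, k: int) -> Box:
        cx, cy = self.center
        _, outer = self.annulus_at(k)
        return Box(cx - outer, cy - outer, cx + outer, cy + outer)


@dataclass
class ClutterSpec:
    """Static near-radar clutter: a per-gate eta contribution within max_range.

    ``eta_field`` is applied to every sweep; ``jitter_sd`` is the log-scale
    SD of unbiased multiplicative lognormal noise redrawn each scan.
    """

    eta_field: np.ndarray | None = None   # (n_azimuths, n_ranges), cm^2 km^-3
    max_range: float = 27.5               # km
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.eta_field is not None:
            self.eta_field = np.asarray(self.eta_field, dtype=float)
            if np.any(self.eta_field < 0):
                raise ValueError("clutter eta must be nonnegative")

    @classmethod
    def annulus(
        cls,
        config: RadarConfig,
        n_ranges: int,
        eta_level: float,
        r_in: float = 2.0,
        r_out: float = 20.0,
        max_range: float = 27.5,
        jitter_sd: float = 0.0,
    ) -> "ClutterSpec":
        """Uniform clutter annulus between ground radii r_in..r_out km."""
        r_km = config.range_centers(n_ranges) / 1000.0
        band = (r_km >= r_in) & (r_km <= min(r_out, max_range))
        fld = np.zeros((config.n_azimuths, n_ranges))
        fld[:, band] = eta_level
        return cls(eta_field=fld, max_range=max_range, jitter_sd=jitter_sd)

    def is_empty(self) -> bool:
        return self.eta_field is None or not np.any(self.eta_field)


@dataclass(frozen=True)
class PrecipSpec:
    """A circular precipitation blob drifting at constant velocity."""

    center: tuple[float, float]           # km at the start of the morning window
    radius: float                         # km
    dbz_level: float = 40.0
    velocity: tuple[float, float] = (0.0, 0.0)   # km per hour
    active_dates: frozenset = frozenset()        # empty = active every day

    def __post_init__(self) -> None:
        if not -30.0 < self.dbz_level < 80.0:
            raise ValueError("dbz_level outside physical range (-30, 80)")
        object.__setattr__(self, "active_dates", frozenset(self.active_dates))

    def active_on(self, d: date) -> bool:
        return not self.active_dates or d in self.active_dates

    def center_at(self, hours_since_window_start: float) -> tuple[float, float]:
        return (
            self.center[0] + self.velocity[0] * hours_since_window_start,
            self.center[1] + self.velocity[1] * hours_since_window_start,
        )


@dataclass
class RoostScanTruth:
    """Per-scan record of one injected dispersal ring."""

    roost_index: int
    scan_id: str
    timestamp: datetime
    scan_k: int
    expected_birds: float
    box: Box
    n_gates: int


@dataclass
class GroundTruthManifest:
    """The generator's record of everything it injected — the recovery target."""

    roosts: list[RoostSpec]
    scans: list[RoostScanTruth]
    clutter: ClutterSpec
    precip: list[PrecipSpec]
    seed: int
    day_status: dict[date, str] = field(default_factory=dict)  # sampled/contaminated/failure/true_zero
    config: RadarConfig = field(default_factory=RadarConfig)

    def expected_daily_totals(self) -> dict[date, float]:
        """Per sampled day, the sum over roosts of the per-track peak number."""
        peaks: dict[tuple[date, int], float] = {}
        for rec in self.scans:
            d = rec.timestamp.date()
            key = (d, rec.roost_index)
            peaks[key] = max(peaks.get(key, 0.0), rec.expected_birds)
        out: dict[date, float] = {}
        for (d, _), peak in peaks.items():
            out[d] = out.get(d, 0.0) + peak
        for d, status in self.day_status.items():
            if status in ("sampled", "true_zero"):
                out.setdefault(d, 0.0)
        return out


def daily_roosts(
    center: tuple[float, float],
    dates: list[date],
    local_departure: time = time(5, 24),
    utc_offset: float = -4.0,
    **kwargs,
) -> list[RoostSpec]:
    """Expand one roost site into one dispersal event per date.

    A communal roost re-forms nightly, so a site occupied over a span of
    days produces one expanding-ring dispersal each morning.
    """
    specs = []
    for d in sorted(dates):
        t0 = (
            datetime.combine(d, local_departure) - timedelta(hours=utc_offset)
        ).replace(tzinfo=timezone.utc)
        specs.append(RoostSpec(center=center, first_scan_time=t0, **kwargs))
    return specs


def scan_id_for(ts: datetime) -> str:
    return ts.astimezone(timezone.utc).strftime("%Y%m%dT%H%M%S")


def _scan_times(d: date, config: RadarConfig) -> list[datetime]:
    """Scan timestamps whose local time falls in [05:00, 08:00) on day d."""
    start_local = datetime.combine(d, time(5, 0))
    start_utc = (start_local - timedelta(hours=config.utc_offset)).replace(
        tzinfo=timezone.utc
    )
    times, t = [], start_utc
    while t < start_utc + timedelta(hours=3):
        times.append(t)
        t = t + timedelta(minutes=config.scan_interval)
    return times


def simulate_series(
    config: RadarConfig,
    roosts: list[RoostSpec],
    clutter: ClutterSpec | None = None,
    precip: list[PrecipSpec] | None = None,
    days: list[date] | None = None,
    seed: int = 0,
    n_ranges: int = 120,
    qc: QuantConfig | None = None,
    failure_dates: set[date] = frozenset(),
    use_overlap_correction: bool = True,
) -> tuple[ScanSeries, GroundTruthManifest, pd.DataFrame]:
    """Generate a ScanSeries plus its ground-truth manifest and annotations.

    ``qc`` fixes the quantification forward model the roost densities are
    inverted against (defaults to the pipeline defaults).  Radar-failure days
    produce no volumes but are flagged in the day notes.  Reproducible given
    ``seed``.
    """
    clutter = clutter or ClutterSpec()
    precip = list(precip or [])
    qc = qc or QuantConfig()
    cache = GeometryCache(qc, theta=config.beamwidth)
    rng = np.random.default_rng(seed)
    if days is None:
        days = sorted({r.first_scan_time.date() for r in roosts}) or [date(2014, 3, 1)]

    for spec in roosts:
        dist = math.hypot(*spec.center)
        for k in range(spec.n_scans):
            inner, outer = spec.annulus_at(k)
            if inner <= dist <= outer:
                raise GenerationError(
                    f"roost ring at scan {k} collides with the radar origin"
                )

    # geometry shared by all first sweeps
    az = config.azimuth_centers()
    rc = config.range_centers(n_ranges)
    proto = PolarSweep(
        elevation=config.first_elevation,
        azimuth_centers=az,
        range_centers=rc,
        dbz=np.zeros((config.n_azimuths, n_ranges)),
    )
    gx, gy = proto.gate_positions()
    if use_overlap_correction:
        v_gate = cache.effective_volumes(proto, config.azimuth_step)
    else:
        v_gate = cache.effective_volumes(proto, config.azimuth_step) / (
            1.0 - cache.overlap_fraction(config.azimuth_step)
        )
    v_grid = np.broadcast_to(v_gate[None, :], (config.n_azimuths, n_ranges))

    volumes: list[ScanVolume] = []
    truth_scans: list[RoostScanTruth] = []
    day_notes: dict[date, DayNotes] = {}
    day_status: dict[date, str] = {}

    for d in sorted(days):
        precip_today = [p for p in precip if p.active_on(d)]
        if d in failure_dates:
            day_notes[d] = DayNotes(radar_failure=True)
            day_status[d] = "failure"
            continue
        day_notes[d] = DayNotes(precipitation=bool(precip_today))
        saw_roost = False
        window_start = _scan_times(d, config)[0]
        for ts in _scan_times(d, config):
            z_lin = np.zeros((config.n_azimuths, n_ranges))
            # roost rings (first sweep only)
            for ri, spec in enumerate(roosts):
                if ts < spec.first_scan_time:
                    continue
                k = round(
                    (ts - spec.first_scan_time).total_seconds()
                    / 60.0
                    / config.scan_interval
                )
                if k >= spec.n_scans:
                    continue
                inner, outer = spec.annulus_at(k)
                rr = np.hypot(gx - spec.center[0], gy - spec.center[1])
                sel = (rr >= inner) & (rr <= outer)
                n_gates = int(np.count_nonzero(sel))
                target = spec.fraction_at(k) * spec.total_birds
                if n_gates == 0:
                    continue
                v_sum = float(np.sum(v_grid[sel]))
                density = target / v_sum                     # birds km^-3
                eta = density * qc.sigma                     # cm^2 km^-3
                z_lin[sel] += eta_to_z(eta, config.wavelength, qc.km2)
                truth_scans.append(
                    RoostScanTruth(
                        roost_index=ri,
                        scan_id=scan_id_for(ts),
                        timestamp=ts,
                        scan_k=k,
                        expected_birds=target,
                        box=spec.true_box(k),
                        n_gates=n_gates,
                    )
                )
                saw_roost = True
            sweeps = []
            for elev in config.elevation_angles:
                if elev == config.first_elevation:
                    z_sweep = z_lin.copy()
                else:
                    z_sweep = np.zeros_like(z_lin)
                if not clutter.is_empty():
                    fld = clutter.eta_field
                    if fld.shape != z_sweep.shape:
                        raise GenerationError(
                            f"clutter field shape {fld.shape} != grid "
                            f"{z_sweep.shape}"
                        )
                    if clutter.jitter_sd > 0:
                        jit = rng.lognormal(
                            mean=-clutter.jitter_sd**2 / 2.0,
                            sigma=clutter.jitter_sd,
                            size=fld.shape,
                        )
                    else:
                        jit = 1.0
                    z_sweep += eta_to_z(fld * jit, config.wavelength, qc.km2)
                for p in precip_today:
                    hrs = (ts - window_start).total_seconds() / 3600.0
                    cx, cy = p.center_at(hrs)
                    blob = np.hypot(gx - cx, gy - cy) <= p.radius
                    z_sweep[blob] = np.maximum(
                        z_sweep[blob], 10.0 ** (p.dbz_level / 10.0)
                    )
                with np.errstate(divide="ignore"):
                    dbz = np.where(
                        z_sweep > 0, 10.0 * np.log10(np.maximum(z_sweep, 1e-300)), np.nan
                    )
                sweeps.append(
                    PolarSweep(
                        elevation=elev,
                        azimuth_centers=az.copy(),
                        range_centers=rc.copy(),
                        dbz=dbz,
                    )
                )
            volumes.append(ScanVolume(timestamp=ts, sweeps=sweeps, config=config))
        if precip_today:
            day_status[d] = "contaminated"
        elif saw_roost:
            day_status[d] = "sampled"
        else:
            day_status[d] = "true_zero"

    series = ScanSeries(volumes=volumes, day_notes=day_notes, config=config)
    manifest = GroundTruthManifest(
        roosts=list(roosts),
        scans=truth_scans,
        clutter=clutter,
        precip=precip,
        seed=seed,
        day_status=day_status,
        config=config,
    )
    annotations = emit_annotations(manifest)
    return series, manifest, annotations


def emit_annotations(
    manifest: GroundTruthManifest, margin: float = 0.5
) -> pd.DataFrame:
    """Bounding-box export for every injected dispersal ring, one row per scan.

    Label-Studio-style tabular schema: scan_id, timestamp, x_min, y_min,
    x_max, y_max (km east/north of the radar), class in {clear, rain,
    clutter}.  A box is rain-contaminated if it intersects an active
    precipitation blob at that scan, clutter-mixed if it touches the clutter
    region (within ``manifest.clutter.max_range`` of the radar), else clear.
    """
    rows = []
    for rec in manifest.scans:
        b = rec.box
        box = Box(b.x_min - margin, b.y_min - margin, b.x_max + margin, b.y_max + margin)
        cls = "clear"
        if not manifest.clutter.is_empty():
            # closest approach of the box to the radar at the origin
            nx = max(box.x_min, min(0.0, box.x_max))
            ny = max(box.y_min, min(0.0, box.y_max))
            if math.hypot(nx, ny) <= manifest.clutter.max_range:
                cls = "clutter"
        local_day = (
            rec.timestamp + timedelta(hours=manifest.config.utc_offset)
        ).date()
        window_start = _scan_times(local_day, manifest.config)[0]
        hrs = (rec.timestamp - window_start).total_seconds() / 3600.0
        for p in manifest.precip:
            if not p.active_on(local_day):
                continue
            cx, cy = p.center_at(hrs)
            nearest_x = max(box.x_min, min(cx, box.x_max))
            nearest_y = max(box.y_min, min(cy, box.y_max))
            if math.hypot(cx - nearest_x, cy - nearest_y) <= p.radius:
                cls = "rain"
                break
        rows.append(
            {
                "scan_id": rec.scan_id,
                "timestamp": rec.timestamp.isoformat(),
                "x_min": box.x_min,
                "y_min": box.y_min,
                "x_max": box.x_max,
                "y_max": box.y_max,
                "class": cls,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["scan_id", "timestamp", "x_min", "y_min", "x_max", "y_max", "class"],
    )
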