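"""Polar radar scan volumes: data model, on-disk container, and geometry helpers.

The radar observable is the reflectivity factor Ze in dBZ on a polar grid
(azimuth x range) per elevation sweep.  Gates with no detectable echo carry
NaN as an explicit sentinel — 0 dBZ is a real signal (Z = 1 mm^6 m^-3) and
must never be conflated with "no echo".

Conventions (fixed once so everything downstream is testable):

* azimuths are beam-axis centers in degrees clockwise from geographic north;
* range gate i spans [i*dr, (i+1)*dr) with its center at (i+0.5)*dr;
* ground projection is flat-earth: close-range use only, no refraction or
  4/3-earth beam-height model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "NO_ECHO",
    "RadarConfig",
    "PolarSweep",
    "ScanVolume",
    "ScanSeries",
    "DayNotes",
    "gate_center_position",
    "in_sampling_window",
    "read_series",
    "write_series",
]

#: Sentinel for gates with no detectable echo (distinct from 0 dBZ).
NO_ECHO = float("nan")

_MANAUS_ELEVATIONS = (
    0.9, 1.5, 2.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.5,
    12.0, 13.5, 15.0, 16.5, 18.0, 19.0,
)


class FormatError(ValueError):
    """A container file is missing or malforms a required metadata field."""


@dataclass(frozen=True)
class RadarConfig:
    """Static technical description of the radar and its scan strategy.

    Defaults follow the Manaus S-band Doppler radar: 0.10 m wavelength,
    1.8 degree beamwidth, 500 m range gates, first sweep at 0.9 degrees,
    and an azimuthal strategy of 294 or 360 beams per rotation.
    """

    latitude: float = -3.148889
    longitude: float = -59.991417
    wavelength: float = 0.10              # m
    beamwidth: float = 1.8                # degrees
    range_gate: float = 500.0             # m
    elevation_angles: tuple[float, ...] = _MANAUS_ELEVATIONS
    n_azimuths: int = 360
    scan_interval: float = 12.0           # minutes
    utc_offset: float = -4.0              # hours, Manaus local time
    max_range: float = 240_000.0          # m, unambiguous range

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.beamwidth <= 0:
            raise ValueError("beamwidth must be positive")
        if self.range_gate <= 0:
            raise ValueError("range_gate must be positive")
        if self.n_azimuths not in (294, 360):
            raise ValueError(f"n_azimuths must be 294 or 360, got {self.n_azimuths}")
        elevs = tuple(float(e) for e in self.elevation_angles)
        if list(elevs) != sorted(elevs):
            raise ValueError("elevation_angles must be sorted ascending")
        object.__setattr__(self, "elevation_angles", elevs)
        # n_azimuths * azimuth_step must close the circle
        if abs(self.n_azimuths * self.azimuth_step - 360.0) > 0.01:
            raise ValueError("azimuth strategy does not close 360 degrees")

    @property
    def azimuth_step(self) -> float:
        """Antenna rotation between consecutive beams, degrees."""
        return 360.0 / self.n_azimuths

    @property
    def first_elevation(self) -> float:
        return self.elevation_angles[0]

    def azimuth_centers(self) -> np.ndarray:
        return np.arange(self.n_azimuths) * self.azimuth_step

    def range_centers(self, n_ranges: int) -> np.ndarray:
        return (np.arange(n_ranges) + 0.5) * self.range_gate

    def to_dict(self) -> dict:
        return {
            "latitude": self.latitude,
            "longitude": self.longitude,
            "wavelength": self.wavelength,
            "beamwidth": self.beamwidth,
            "range_gate": self.range_gate,
            "elevation_angles": list(self.elevation_angles),
            "n_azimuths": self.n_azimuths,
            "scan_interval": self.scan_interval,
            "utc_offset": self.utc_offset,
            "max_range": self.max_range,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RadarConfig":
        required = {
            "latitude", "longitude", "wavelength", "beamwidth", "range_gate",
            "elevation_angles", "n_azimuths", "scan_interval", "utc_offset",
        }
        missing = required - set(d)
        if missing:
            raise FormatError(f"radar metadata missing field(s): {sorted(missing)}")
        kwargs = dict(d)
        kwargs["elevation_angles"] = tuple(d["elevation_angles"])
        return cls(**kwargs)


@dataclass
class PolarSweep:
    """One full antenna rotation at a fixed elevation angle.

    ``dbz`` has shape (n_azimuths, n_ranges); no-echo gates are NaN.
    """

    elevation: float
    azimuth_centers: np.ndarray
    range_centers: np.ndarray
    dbz: np.ndarray

    def __post_init__(self) -> None:
        self.azimuth_centers = np.asarray(self.azimuth_centers, dtype=float)
        self.range_centers = np.asarray(self.range_centers, dtype=float)
        self.dbz = np.asarray(self.dbz, dtype=float)
        if self.dbz.shape != (self.azimuth_centers.size, self.range_centers.size):
            raise ValueError(
                f"dbz shape {self.dbz.shape} != "
                f"({self.azimuth_centers.size}, {self.range_centers.size})"
            )
        if self.range_centers.size >= 2:
            dr = np.diff(self.range_centers)
            if np.any(dr <= 0):
                raise ValueError("range_centers must be strictly increasing")
        if self.azimuth_centers.size >= 2:
            da = np.diff(self.azimuth_centers)
            if not np.allclose(da, da[0], atol=1e-9):
                raise ValueError("azimuth spacing must be constant")

    @property
    def n_azimuths(self) -> int:
        return self.azimuth_centers.size

    @property
    def n_ranges(self) -> int:
        return self.range_centers.size

    def gate_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Ground (x east, y north) km of every gate center; shape (n_az, n_rng)."""
        az = np.deg2rad(self.azimuth_centers)[:, None]
        r_km = (self.range_centers / 1000.0)[None, :] * math.cos(
            math.radians(self.elevation)
        )
        return r_km * np.sin(az), r_km * np.cos(az)


@dataclass
class ScanVolume:
    """All sweeps of one volume scan, time-stamped in UTC."""

    timestamp: datetime
    sweeps: list[PolarSweep]
    config: RadarConfig

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.replace(tzinfo=timezone.utc)
        expected = self.config.elevation_angles[: len(self.sweeps)]
        got = tuple(s.elevation for s in self.sweeps)
        if got != expected:
            raise ValueError(
                f"sweep elevations {got} do not match config prefix {expected}"
            )

    @property
    def first_sweep(self) -> PolarSweep:
        return self.sweeps[0]

    def local_date(self) -> date:
        return (self.timestamp + timedelta(hours=self.config.utc_offset)).date()


@dataclass
class DayNotes:
    """Per-calendar-date condition flags taken during screening."""

    precipitation: bool = False
    anomalous_propagation: bool = False
    radar_failure: bool = False

    def to_dict(self) -> dict:
        return {
            "precipitation": self.precipitation,
            "anomalous_propagation": self.anomalous_propagation,
            "radar_failure": self.radar_failure,
        }


@dataclass
class ScanSeries:
    """Time-ordered scan volumes plus the per-day condition notes."""

    volumes: list[ScanVolume] = field(default_factory=list)
    day_notes: dict[date, DayNotes] = field(default_factory=dict)
    config: RadarConfig = field(default_factory=RadarConfig)

    def __post_init__(self) -> None:
        times = [v.timestamp for v in self.volumes]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("volumes must be strictly time-ordered")
        for v in self.volumes:
            self.day_notes.setdefault(v.local_date(), DayNotes())

    def __len__(self) -> int:
        return len(self.volumes)

    def __iter__(self) -> Iterator[ScanVolume]:
        return iter(self.volumes)

    def dates(self) -> list[date]:
        return sorted(self.day_notes)

    def volumes_on(self, d: date) -> list[ScanVolume]:
        return [v for v in self.volumes if v.local_date() == d]


def gate_center_position(
    azimuth: float, range_m: float, elevation: float
) -> tuple[float, float]:
    """Flat-earth ground projection of a gate center, km east/north of the radar.

    x = (r/1000) sin(az) cos(elev), y = (r/1000) cos(az) cos(elev).
    Close-range use only; no refraction model.
    """
    if range_m < 0:
        raise ValueError("range must be nonnegative")
    r_km = range_m / 1000.0
    az = math.radians(azimuth)
    ce = math.cos(math.radians(elevation))
    return r_km * math.sin(az) * ce, r_km * math.cos(az) * ce


def in_sampling_window(timestamp: datetime, config: RadarConfig) -> bool:
    """True iff the scan falls in the morning roost-dispersal window.

    The window is the half-open local-time interval [05:00, 08:00) — an hour
    before to two hours after sunrise at a near-equatorial site, treated as
    fixed clock time.
    """
    if timestamp.tzinfo is None:
        timestamp = timestamp.replace(tzinfo=timezone.utc)
    local = timestamp.astimezone(timezone.utc) + timedelta(hours=config.utc_offset)
    minutes = local.hour * 60 + local.minute + local.second / 60.0
    return 5 * 60 <= minutes < 8 * 60


# ---------------------------------------------------------------------------
# On-disk container
#
# Layout: <root>/manifest.json        radar config + day notes
#         <root>/<YYYY-MM-DD>/volume_<HHMMSS>.npz
# Each npz holds one float array "sweep_<k>_dbz" per sweep plus a "meta"
# array wrapping a JSON metadata block (timestamp, elevations, geometry).
# ---------------------------------------------------------------------------


def write_series(series: ScanSeries, path: str | Path) -> None:
    """Write a series in the documented container layout (stable across runs)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "roostradar-series-v1",
        "config": series.config.to_dict(),
        "day_notes": {
            d.isoformat(): notes.to_dict() for d, notes in sorted(series.day_notes.items())
        },
        "volumes": [],
    }
    for vol in series.volumes:
        local_day = vol.local_date().isoformat()
        daydir = root / local_day
        daydir.mkdir(exist_ok=True)
        fname = f"volume_{vol.timestamp.strftime('%Y%m%dT%H%M%S')}.npz"
        meta = {
            "timestamp": vol.timestamp.astimezone(timezone.utc).isoformat(),
            "elevations": [s.elevation for s in vol.sweeps],
            "n_azimuths": vol.sweeps[0].n_azimuths if vol.sweeps else series.config.n_azimuths,
            "range_gate": series.config.range_gate,
            "radar_latitude": series.config.latitude,
            "radar_longitude": series.config.longitude,
        }
        arrays = {
            f"sweep_{k:02d}_dbz": s.dbz for k, s in enumerate(vol.sweeps)
        }
        arrays["meta"] = np.frombuffer(
            json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
        )
        np.savez(daydir / fname, **arrays)
        manifest["volumes"].append(f"{local_day}/{fname}")
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_series(path: str | Path) -> ScanSeries:
    """Read a series written by :func:`write_series`; bit-exact round trip."""
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        if root.is_dir() and not any(root.iterdir()):
            return ScanSeries()
        raise FormatError(f"no manifest.json under {root}")
    manifest = json.loads(mpath.read_text())
    for fld in ("config", "day_notes", "volumes"):
        if fld not in manifest:
            raise FormatError(f"manifest missing field: {fld}")
    config = RadarConfig.from_dict(manifest["config"])
    volumes = []
    for rel in manifest["volumes"]:
        with np.load(root / rel) as data:
            if "meta" not in data:
                raise FormatError(f"{rel}: missing 'meta' block")
            meta = json.loads(bytes(data["meta"]).decode())
            for fld in ("timestamp", "elevations", "n_azimuths", "range_gate"):
                if fld not in meta:
                    raise FormatError(f"{rel}: metadata missing field '{fld}'")
            ts = datetime.fromisoformat(meta["timestamp"])
            sweeps = []
            for k, elev in enumerate(meta["elevations"]):
                dbz = data[f"sweep_{k:02d}_dbz"]
                n_az, n_rng = dbz.shape
                sweeps.append(
                    PolarSweep(
                        elevation=elev,
                        azimuth_centers=np.arange(n_az) * (360.0 / n_az),
                        range_centers=(np.arange(n_rng) + 0.5) * meta["range_gate"],
                        dbz=dbz,
                    )
                )
        volumes.append(ScanVolume(timestamp=ts, sweeps=sweeps, config=config))
    times = [v.timestamp for v in volumes]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("container holds unordered timestamps")
    day_notes = {
        date.fromisoformat(k): DayNotes(**v) for k, v in manifest["day_notes"].items()
    }
    return ScanSeries(volumes=volumes, day_notes=day_notes, config=config)
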