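"""Ground-clutter masks: low-quantile average reflectivity near the radar.

Low-elevation beams intercept trees and buildings out to ~27.5 km from the
radar, producing a persistent mid-level reflectivity annulus that would
inflate roost counts.  The mask is built by ranking scans by their total
summed linear reflectivity within the clutter range and averaging the
quietest 2% — scans in which essentially only the static clutter is present.
One mask is kept per (elevation, azimuth-strategy) pair and subtracted, in
linear eta units with a floor at zero, from every scan before counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .polar import PolarSweep, ScanSeries
from .quantify import GeometryCache, QuantConfig, dbz_to_z, z_to_eta

__all__ = [
    "ClutterMask",
    "MaskSet",
    "build_masks",
    "apply_mask",
    "clutter_birds",
    "save_masks",
    "load_masks",
]


@dataclass
class ClutterMask:
    """Mean background clutter reflectivity eta-bar (cm^2 km^-3).

    Zero beyond ``max_range`` km; one mask per (elevation, n_azimuths).
    """

    elevation: float
    n_azimuths: int
    eta_bar: np.ndarray           # (n_azimuths, n_ranges)
    range_centers: np.ndarray     # m
    max_range: float = 27.5       # km
    n_scans_used: int = 0
    quantile: float = 0.02
    source_scans: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.eta_bar = np.asarray(self.eta_bar, dtype=float)
        if np.any(self.eta_bar < 0):
            raise ValueError("clutter mask must be nonnegative")
        beyond = self.range_centers / 1000.0 > self.max_range
        if np.any(self.eta_bar[:, beyond] != 0):
            raise ValueError("clutter mask must be zero beyond max_range")

    def field_for(self, sweep: PolarSweep) -> np.ndarray:
        """eta-bar aligned to a sweep's grid (validates shape compatibility)."""
        if sweep.n_azimuths != self.n_azimuths:
            raise ValueError(
                f"mask built for {self.n_azimuths} azimuths, sweep has "
                f"{sweep.n_azimuths}"
            )
        if sweep.n_ranges == self.eta_bar.shape[1]:
            return self.eta_bar
        if sweep.n_ranges > self.eta_bar.shape[1]:
            out = np.zeros((self.n_azimuths, sweep.n_ranges))
            out[:, : self.eta_bar.shape[1]] = self.eta_bar
            return out
        return self.eta_bar[:, : sweep.n_ranges]


@dataclass
class MaskSet:
    """Masks keyed by (elevation, n_azimuths), plus build warnings."""

    masks: dict[tuple[float, int], ClutterMask] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def get(self, elevation: float, n_azimuths: int) -> ClutterMask | None:
        return self.masks.get((round(elevation, 3), n_azimuths))

    def for_sweep(self, sweep: PolarSweep) -> ClutterMask | None:
        return self.get(sweep.elevation, sweep.n_azimuths)


def _scan_total_linear(volume, max_range_km: float, use_dbz_sum: bool) -> float:
    """Ranking statistic: summed reflectivity within max_range, first sweep."""
    sweep = volume.first_sweep
    within = sweep.range_centers / 1000.0 <= max_range_km
    dbz = sweep.dbz[:, within]
    if use_dbz_sum:
        return float(np.nansum(dbz))
    return float(np.sum(dbz_to_z(dbz)))


def build_masks(
    series: ScanSeries,
    quantile: float = 0.02,
    max_range: float = 27.5,
    rank_in_dbz: bool = False,
) -> MaskSet:
    """Build average clutter masks from the quietest scans of a series.

    Scans are grouped by azimuth strategy, ranked by total summed linear
    reflectivity within ``max_range`` on the first sweep, and the scans at or
    below the ``quantile`` cutoff (ties broken by timestamp; at least one
    scan) are averaged per (elevation, strategy) gate, treating no-echo as 0.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    out = MaskSet()
    by_strategy: dict[int, list] = {}
    for vol in series:
        by_strategy.setdefault(vol.first_sweep.n_azimuths, []).append(vol)
    for n_az in (294, 360):
        vols = by_strategy.get(n_az, [])
        if not vols:
            out.warnings.append(
                f"no scans with the {n_az}-azimuth strategy; mask absent"
            )
            continue
        ranked = sorted(
            vols,
            key=lambda v: (_scan_total_linear(v, max_range, rank_in_dbz), v.timestamp),
        )
        # inclusive "at or below" cutoff; ties broken by timestamp in the sort
        k = max(1, int(np.ceil(quantile * len(ranked))))
        selected = ranked[:k]
        n_sweeps = min(len(v.sweeps) for v in selected)
        for si in range(n_sweeps):
            elev = selected[0].sweeps[si].elevation
            acc = None
            for v in selected:
                sweep = v.sweeps[si]
                eta = z_to_eta(dbz_to_z(sweep.dbz))
                acc = eta if acc is None else acc + eta
            eta_bar = acc / len(selected)
            beyond = selected[0].sweeps[si].range_centers / 1000.0 > max_range
            eta_bar[:, beyond] = 0.0
            out.masks[(round(elev, 3), n_az)] = ClutterMask(
                elevation=elev,
                n_azimuths=n_az,
                eta_bar=eta_bar,
                range_centers=selected[0].sweeps[si].range_centers,
                max_range=max_range,
                n_scans_used=len(selected),
                quantile=quantile,
                source_scans=[v.timestamp.isoformat() for v in selected],
            )
    return out


def apply_mask(sweep: PolarSweep, mask: ClutterMask) -> np.ndarray:
    """Clutter-corrected eta grid: eta' = max(eta - eta_bar, 0) gate-wise.

    Gates beyond the mask's max_range are unchanged; no-echo gates stay 0.
    """
    eta = z_to_eta(dbz_to_z(sweep.dbz))
    eta_bar = mask.field_for(sweep)
    return np.maximum(eta - eta_bar, 0.0)


def clutter_birds(
    sweep: PolarSweep,
    mask: ClutterMask,
    box,
    qc: QuantConfig | None = None,
    cache: GeometryCache | None = None,
) -> float:
    """Birds attributed to clutter within a box — the amount the mask removed.

    min(eta, eta_bar)/sigma integrated over the overlap-corrected gate
    volumes, so that uncorrected count = corrected count + clutter_birds
    holds exactly for every box.
    """
    from .quantify import box_counts_detail

    qc = qc or QuantConfig()
    cache = cache or GeometryCache(qc)
    return box_counts_detail(sweep, box, mask, qc, cache)["clutter_birds"]


def save_masks(masks: MaskSet, path) -> None:
    """Serialize a MaskSet to one npz file (same container style as sweeps):
    one eta_bar array per mask plus a JSON provenance block."""
    meta = []
    arrays = {}
    for i, ((elev, n_az), m) in enumerate(sorted(masks.masks.items())):
        arrays[f"mask_{i:02d}_eta"] = m.eta_bar
        arrays[f"mask_{i:02d}_ranges"] = m.range_centers
        meta.append(
            {
                "elevation": m.elevation,
                "n_azimuths": m.n_azimuths,
                "max_range": m.max_range,
                "n_scans_used": m.n_scans_used,
                "quantile": m.quantile,
                "source_scans": m.source_scans,
            }
        )
    arrays["meta"] = np.frombuffer(
        json.dumps({"masks": meta, "warnings": masks.warnings},
                   sort_keys=True).encode(),
        dtype=np.uint8,
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def load_masks(path) -> MaskSet:
    """Inverse of :func:`save_masks`."""
    out = MaskSet()
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        for i, m in enumerate(meta["masks"]):
            mask = ClutterMask(
                elevation=m["elevation"],
                n_azimuths=m["n_azimuths"],
                eta_bar=data[f"mask_{i:02d}_eta"],
                range_centers=data[f"mask_{i:02d}_ranges"],
                max_range=m["max_range"],
                n_scans_used=m["n_scans_used"],
                quantile=m["quantile"],
                source_scans=list(m["source_scans"]),
            )
            out.masks[(round(mask.elevation, 3), mask.n_azimuths)] = mask
        out.warnings = list(meta["warnings"])
    return out
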