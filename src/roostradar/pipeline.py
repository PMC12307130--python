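"""End-to-end glue: annotations + scan series -> counts -> tracks -> summaries.

The stages are deliberately thin wrappers over the per-module operations so
that the command-line tool, the analysis scripts, and the tests all run the
same code path.
"""

from __future__ import annotations

import logging
import warnings
from datetime import date, datetime, timedelta
from typing import Mapping

import pandas as pd

from .clutter import MaskSet
from .polar import ScanSeries
from .quantify import Box, GeometryCache, QuantConfig, box_counts_detail
from .summary import DailySummary, summarize_days
from .synth import scan_id_for
from .tracking import Detection, Track, link_detections

__all__ = [
    "quantify_annotations",
    "detections_by_day",
    "track_table",
    "run_pipeline",
]

log = logging.getLogger("roostradar")

DETECTION_COLUMNS = [
    "scan_id", "timestamp", "x_min", "y_min", "x_max", "y_max", "class",
    "n_gates", "n_filtered", "birds", "clutter_birds",
]


def quantify_annotations(
    series: ScanSeries,
    annotations: pd.DataFrame,
    masks: MaskSet | None = None,
    qc: QuantConfig | None = None,
    missing_mask: str = "warn",
) -> pd.DataFrame:
    """Count birds in every annotated bounding box of a series.

    Counts use the first sweep only (higher sweeps overlap it or overshoot
    the dispersal).  Boxes that reach into the clutter region but have no
    matching mask trigger a warning (default) or an error, per
    ``missing_mask``.
    """
    qc = qc or QuantConfig()
    cache = GeometryCache(qc, theta=series.config.beamwidth)
    by_scan = {scan_id_for(v.timestamp): v for v in series}
    rows = []
    for rec in annotations.to_dict("records"):
        vol = by_scan.get(rec["scan_id"])
        if vol is None:
            warnings.warn(
                f"annotation references unknown scan {rec['scan_id']}", stacklevel=2
            )
            continue
        sweep = vol.first_sweep
        box = Box(rec["x_min"], rec["y_min"], rec["x_max"], rec["y_max"])
        mask = masks.for_sweep(sweep) if masks is not None else None
        cls = rec.get("class", "clear")
        if mask is None and cls == "clutter":
            msg = (
                f"box on scan {rec['scan_id']} is clutter-mixed but no mask "
                "is available"
            )
            if missing_mask == "error":
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        detail = box_counts_detail(sweep, box, mask, qc, cache)
        rows.append(
            {
                "scan_id": rec["scan_id"],
                "timestamp": rec["timestamp"],
                "x_min": box.x_min,
                "y_min": box.y_min,
                "x_max": box.x_max,
                "y_max": box.y_max,
                "class": cls,
                "n_gates": detail["n_gates"],
                "n_filtered": detail["n_filtered"],
                "birds": detail["birds"],
                "clutter_birds": detail["clutter_birds"],
            }
        )
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def detections_by_day(
    detections: pd.DataFrame, utc_offset: float = 0.0
) -> dict[date, list[list[Detection]]]:
    """Group quantified detections into per-local-day, per-scan lists."""
    out: dict[date, dict[str, list[Detection]]] = {}
    for rec in detections.to_dict("records"):
        ts = rec["timestamp"]
        if isinstance(ts, str):
            ts = datetime.fromisoformat(ts)
        det = Detection(
            timestamp=ts,
            box=Box(rec["x_min"], rec["y_min"], rec["x_max"], rec["y_max"]),
            birds=max(float(rec["birds"]), 0.0),
            cls=rec.get("class", "clear"),
            scan_id=rec["scan_id"],
        )
        d = (det.timestamp + timedelta(hours=utc_offset)).date()
        out.setdefault(d, {}).setdefault(rec["scan_id"], []).append(det)
    return {
        d: [groups[sid] for sid in sorted(groups)] for d, groups in out.items()
    }


def track_table(tracks_by_date: Mapping[date, list[Track]]) -> pd.DataFrame:
    """Tabular track export: one row per dispersal track."""
    rows = []
    for d in sorted(tracks_by_date):
        for t in tracks_by_date[d]:
            rows.append(
                {
                    "track_id": t.track_id,
                    "date": d.isoformat(),
                    "n_detections": len(t.detections),
                    "first_timestamp": t.detections[0].timestamp.isoformat(),
                    "last_timestamp": t.detections[-1].timestamp.isoformat(),
                    "first_centroid_x": t.first_centroid[0],
                    "first_centroid_y": t.first_centroid[1],
                    "peak_count": t.peak_count,
                    "contaminated": t.contaminated,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id", "date", "n_detections", "first_timestamp",
            "last_timestamp", "first_centroid_x", "first_centroid_y",
            "peak_count", "contaminated",
        ],
    )


def run_pipeline(
    series: ScanSeries,
    annotations: pd.DataFrame,
    masks: MaskSet | None = None,
    qc: QuantConfig | None = None,
    overlap: str = "area",
    include_clutter_mixed: bool = True,
) -> tuple[pd.DataFrame, dict[date, list[Track]], list[DailySummary]]:
    """quantify -> track -> summarize in one call."""
    detections = quantify_annotations(series, annotations, masks, qc)
    grouped = detections_by_day(detections, utc_offset=series.config.utc_offset)
    tracks_by_date = {
        d: link_detections(scans, overlap=overlap,
                           utc_offset=series.config.utc_offset)
        for d, scans in grouped.items()
    }
    summaries = summarize_days(series, tracks_by_date, include_clutter_mixed)
    return detections, tracks_by_date, summaries
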