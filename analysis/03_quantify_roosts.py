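#!/usr/bin/env python
"""Quantify every annotated dispersal box: dBZ -> eta -> birds.

Applies the 5-30 dBZ pixel filters, subtracts the clutter mask in linear
units, and integrates bird density over the overlap-corrected conical
frustum volumes of the first (0.9 degree) sweep.  Writes the per-detection
table (including the birds attributed to clutter) to results/detections.csv.
"""

from pathlib import Path

import pandas as pd

from roostradar import QuantConfig, quantify_annotations, read_series
from roostradar.clutter import load_masks

ROOT = Path(__file__).resolve().parents[1]

QC = QuantConfig(mc_samples=100_000, mc_seed=11)  # sigma 15.2 cm^2, 5-30 dBZ


def main() -> None:
    series = read_series(ROOT / "scratch" / "scenes")
    annotations = pd.read_csv(ROOT / "results" / "annotations.csv")
    masks = load_masks(ROOT / "scratch" / "masks.npz")
    detections = quantify_annotations(series, annotations, masks, QC)
    detections.to_csv(ROOT / "results" / "detections.csv", index=False)
    by_class = detections.groupby("class")["birds"].agg(["count", "sum"])
    print(f"quantified {len(detections)} detections")
    print(by_class.to_string())
    clutter_share = detections["clutter_birds"].sum()
    print(f"birds attributed to clutter and removed: {clutter_share:,.0f}")


if __name__ == "__main__":
    main()
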