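#!/usr/bin/env python
"""Build the average ground-clutter masks from the quietest scans.

Ranks every scan of the archive by its total linear reflectivity within
27.5 km of the radar and averages the lower 5% into a per-gate clutter mask
(the sparser this synthetic archive, the higher the quantile needed to catch
a few genuinely roost-free scans; a two-year operational archive would use
the 2% default).  Writes the mask to scratch/ and a summary table to
results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from roostradar import build_masks, read_series
from roostradar.clutter import save_masks

ROOT = Path(__file__).resolve().parents[1]

QUANTILE = 0.05
MAX_RANGE = 27.5  # km


def main() -> None:
    series = read_series(ROOT / "scratch" / "scenes")
    masks = build_masks(series, quantile=QUANTILE, max_range=MAX_RANGE)
    save_masks(masks, ROOT / "scratch" / "masks.npz")
    rows = []
    for (elev, n_az), m in sorted(masks.masks.items()):
        nonzero = m.eta_bar[m.eta_bar > 0]
        rows.append(
            {
                "elevation_deg": elev,
                "n_azimuths": n_az,
                "n_scans_used": m.n_scans_used,
                "quantile": m.quantile,
                "max_range_km": m.max_range,
                "n_clutter_gates": int(nonzero.size),
                "mean_eta": float(nonzero.mean()) if nonzero.size else 0.0,
                "max_eta": float(m.eta_bar.max()),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "clutter_mask_summary.csv", index=False)
    print(df.to_string(index=False))
    for w in masks.warnings:
        print("note:", w)


if __name__ == "__main__":
    main()
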