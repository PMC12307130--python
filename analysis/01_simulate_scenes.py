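#!/usr/bin/env python
"""Generate the synthetic two-season study archive.

Builds a scan archive emulating the Manaus morning-window sampling: two
roost sites (one in open terrain at 41 km, one at 16 km inside the ground
clutter annulus), static jittered clutter, one rain-contaminated day, one
radar-failure day, and one roost-free (true-zero) day per season.  Scan
volumes go to scratch/scenes (binary); the ground-truth day table and the
annotation boxes go to results/.
"""

from datetime import date, timedelta
from pathlib import Path

import pandas as pd

from roostradar import (
    ClutterSpec,
    PrecipSpec,
    QuantConfig,
    RadarConfig,
    daily_roosts,
    simulate_series,
    write_series,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "scenes"
RESULTS = ROOT / "results"

SEED = 2014
CONFIG = RadarConfig(elevation_angles=(0.9,), n_azimuths=360)
QC = QuantConfig(mc_samples=100_000, mc_seed=11)
N_RANGES = 120  # gates out to 60 km


def build_scenario():
    days_2014 = [date(2014, 3, 1) + timedelta(days=i) for i in range(10)]
    days_2015 = [date(2015, 3, 1) + timedelta(days=i) for i in range(8)]
    rain_day = days_2014[6]
    zero_day_14, zero_day_15 = days_2014[7], days_2015[6]
    fail_day = days_2014[8]

    # open-terrain site, occupied in both seasons (larger in 2015)
    site_a_14 = [d for d in days_2014 if d not in (zero_day_14, fail_day)]
    site_a_15 = [d for d in days_2015 if d != zero_day_15]
    roosts = (
        daily_roosts((40.0, 10.0), site_a_14, total_birds=20_000)
        + daily_roosts((40.0, 10.0), site_a_15, total_birds=30_000)
        # near-river site inside the clutter annulus, 2014 only
        + daily_roosts((14.0, 8.0), days_2014[:5], total_birds=12_000,
                       ring_width=3.0)
    )
    clutter = ClutterSpec.annulus(CONFIG, N_RANGES, eta_level=150.0,
                                  r_in=3.0, r_out=25.0, jitter_sd=0.2)
    rain = PrecipSpec(center=(40.0, 10.0), radius=12.0, dbz_level=45.0,
                      active_dates={rain_day})
    return simulate_series(
        CONFIG, roosts, clutter=clutter, precip=[rain],
        days=days_2014 + days_2015, seed=SEED, n_ranges=N_RANGES, qc=QC,
        failure_dates={fail_day},
    )


def main() -> None:
    series, manifest, annotations = build_scenario()
    SCRATCH.parent.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    write_series(series, SCRATCH)
    annotations.to_csv(RESULTS / "annotations.csv", index=False)
    truth = pd.DataFrame(
        [
            {
                "date": d.isoformat(),
                "status": s,
                "expected_total": manifest.expected_daily_totals().get(d),
            }
            for d, s in sorted(manifest.day_status.items())
        ]
    )
    truth.to_csv(RESULTS / "ground_truth_days.csv", index=False)
    n_sampled = (truth["status"].isin(["sampled", "true_zero"])).sum()
    print(f"wrote {len(series)} scan volumes over {len(truth)} days "
          f"({n_sampled} clean) to {SCRATCH}")
    print(f"{len(annotations)} annotation boxes; day statuses: "
          f"{truth['status'].value_counts().to_dict()}")


if __name__ == "__main__":
    main()
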