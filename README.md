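# roostradar

Quantifying swallow and martin communal-roost dispersals from operational
S-band weather radar.

When swallows and martins (Hirundinidae) leave a communal roost at dawn,
their synchronized departure paints an expanding ring of elevated
reflectivity on the nearest weather radar. `roostradar` turns those rings
into bird counts and season-level summaries: it reads polar reflectivity
volumes, masks ground clutter, converts reflectivity inside annotated
bounding boxes into bird numbers, links per-scan detections into dispersal
tracks, aggregates daily abundance and presence/true-zero calendars,
clusters roost locations into sites, and compares regions. A synthetic
scene generator with exact ground truth stands in for proprietary radar
archives, so the whole pipeline is testable end to end.

## The model in brief

Reflectivity factor Ze (dBZ) is converted per gate to linear Z = 10^(dBZ/10)
(mm⁶ m⁻³), then to reflectivity η = 10³(π⁵/λ⁴)|Km|²·Z (cm² km⁻³, λ in cm),
and divided by a per-bird radar cross section σ (default 15.2 cm², a 51 g
Purple Martin) to give a density d = η/σ in birds km⁻³. Each gate samples a
conical frustum of beamwidth θ = 1.8°; because the antenna steps less than
the beamwidth between azimuths (1° or 360/294°), adjacent beams overlap,
and the birds in each overlap are split between the two claiming beams:

    gate count = N_left/2 + N_core + N_right/2 = d · V_full · (1 − f)

with the overlap fraction f = V_int/V_full estimated once per azimuth
strategy by Monte Carlo (f ≈ 0.331 at 1°, ≈ 0.206 at 1.22°). Gates outside
5–30 dBZ are discarded as non-bird echoes; a low-quantile average clutter
mask is subtracted in linear units near the radar. Summing gates inside a
roost's bounding box gives its count for that scan; the maximum over a
linked track is the roost-size estimate; daily totals sum across roosts.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

```python
from datetime import date, datetime, timezone
from roostradar import (QuantConfig, RadarConfig, RoostSpec,
                        run_pipeline, simulate_series)

config = RadarConfig(elevation_angles=(0.9,), n_azimuths=360)
roost = RoostSpec(center=(40.0, 10.0),   # km east/north of the radar
                  first_scan_time=datetime(2014, 3, 1, 9, 24, tzinfo=timezone.utc),
                  n_scans=4, total_birds=10_000)
qc = QuantConfig()                        # sigma 15.2 cm^2, 5-30 dBZ filters
series, manifest, boxes = simulate_series(config, [roost], seed=42, qc=qc)
detections, tracks, summaries = run_pipeline(series, boxes, qc=qc)

for s in summaries:
    print(s.date, s.status, round(s.total_birds))
for t in tracks[date(2014, 3, 1)]:
    print("track peak:", round(t.peak_count), "first centroid:", t.first_centroid)
```

prints

```
2014-03-01 sampled 10000
track peak: 10000 first centroid: (40.0, 10.0)
```

i.e. the 10,000-bird synthetic dispersal is recovered exactly: the morning
is a clean sampled day, its four detections link into one track whose peak
count is the roost-size estimate, anchored at the injected site.

The same stages are scriptable from the shell (`roostradar simulate |
build-mask | quantify | track | summarize | cluster | compare`, each taking
a YAML config), and `analysis/01…06` run them as a narrative study on a
two-season synthetic archive, writing tables under `results/`.

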