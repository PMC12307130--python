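# Methods

`roostradar` converts operational weather-radar reflectivity into estimates
of the number of swallows and martins (Hirundinidae) leaving communal
roosts, and aggregates those estimates into daily abundance, presence
calendars, and roost-site maps. This note records the model, its
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Quantification model

The radar measures the reflectivity factor Ze in dBZ per gate of a polar
grid (azimuth × range) at each elevation sweep. The chain to birds is the
standard bioscatter conversion:

1. **dBZ → linear.** Z = 10^(dBZ/10), in mm⁶ m⁻³. Gates with no detectable
   echo carry NaN, a sentinel deliberately distinct from 0 dBZ (which is a
   real signal, Z = 1); no-echo maps to Z = 0.
2. **Z → η.** η = 10³ · (π⁵/λ⁴) · |Km|² · Z with λ in cm, giving the
   scattering cross-section density in cm² km⁻³. For this S-band radar
   (λ = 0.10 m) and |Km|² = 0.93 the factor is ≈ 28.46. η is conventionally
   printed in cm² km⁻³; occasional appearances of "cm⁶ km⁻³" in the
   surrounding literature are treated as a typographical slip.
3. **η → density.** d = η/σ, birds km⁻³, where σ is the radar cross section
   of one bird. The default σ = 15.2 cm² is the published value for a 51 g
   Purple Martin, the largest Hirundinidae in the Americas, chosen to keep
   counts conservative. The mass–RCS power law log₁₀RCS = 0.699·log₁₀mass
   actually evaluates to 15.6 cm² at 51 g; the discrepancy presumably stems
   from an intercept omitted in the printed relationship. Both values are
   exposed (`rcs_from_mass`), and 15.2 stays the default for fidelity to
   the published analysis.
4. **density → birds.** Each gate samples a conical frustum of beamwidth
   θ = 1.8° between its range bounds; V = (π/3)(r₂−r₁)(R₁² + R₁R₂ + R₂²)
   with Rᵢ = rᵢ·tan(θ/2). The exact tangent is used rather than the
   small-angle θ/2 — the difference is below 0.01 % at 1.8°, but the
   contract must pick one.

**Pixel filters.** Gates with raw dBZ above 30 or below 5 are discarded
before any clutter subtraction: such echoes are implausible for roosting
swallows (rain and strong clutter above, noise below). Filtering raw rather
than clutter-corrected values keeps the 5 dBZ floor independent of the mask;
the order is configurable but the default is documented here. Counts use
only the first sweep (0.9° elevation): higher sweeps either overlap it
(because the beam is wide) or overshoot the shallow morning dispersal.

## Beam-overlap correction

The antenna steps 1° (360-azimuth strategy) or 360/294 ≈ 1.22° (294-azimuth
strategy) between beams while the beam itself is 1.8° wide, so each wedge of
air between adjacent beam axes is sampled twice. Counting every gate at its
full frustum volume would double-count birds in those overlaps. The overlap
volume V_int of two adjacent frustums is estimated by Monte Carlo: points
are drawn uniformly inside one beam (direction uniform over the spherical
cap of half-angle θ/2, radius r²-weighted) and tested against the
neighbouring axis. Birds in the left and right overlap are split evenly
between the two claiming beams, so a gate contributes

    N_left/2 + N_core + N_right/2 = d · V_full · (1 − f),   f = V_int/V_full.

f is range-independent in this small-angle regime (verified by MC at 5 km
and 60 km), so one MC run per azimuth strategy is cached and reused; V_full
is recomputed per range gate from the closed form. An independent
small-angle oracle — the circle-lens area formula on the beam cross-sections
— gives f ≈ 0.331 for the 360-azimuth strategy and f ≈ 0.206 for the
294-azimuth strategy; the MC estimate must agree within 3 binomial standard
errors, and the limits f(0) = 1, f(θ) = 0 hold exactly. A second independent
MC (the union volume of the full beam ring) confirms conservation: the
halving makes the summed contributions of a uniform ring equal density ×
union volume, i.e. nothing is double-counted and nothing is lost. The two
axes are separated by exactly Δφ in angle (the sub-0.02 % cos(elevation)
foreshortening of azimuthal separation is ignored, consistently with the
closed-form oracle).

Default MC settings: 10⁵ samples, fixed seed in `QuantConfig`; the standard
error is always carried on the geometry object.

## Ground-clutter masks

Low beams intercept trees and buildings out to ~27.5 km, producing a
persistent mid-level echo annulus that a bounding box drawn around a
near-radar roost would otherwise absorb. The mask is the per-gate arithmetic
mean of η over the scans ranked lowest by total summed linear reflectivity
within 27.5 km (first sweep; linear rather than dBZ summation, because dBZ
sums are dominated by gate count — both selectable). The default cutoff is
the lower 2 % quantile of scans, at least one scan, ties broken by
timestamp; one mask is kept per (elevation, azimuth-strategy) pair.
Subtraction is gate-wise in linear η with a floor at zero — negative
scatterer densities are meaningless. The birds removed are reported
separately (`clutter_birds` = min(η, η̄)/σ integrated over effective
volumes), so that *uncorrected count = corrected count + clutter birds*
holds exactly for every box. No Doppler or texture-based clutter filtering
is attempted; only the static average-mask method.

## Tracking, daily summaries, clustering

A dispersal unfolds over several ~12-minute scans; detections are linked
scan-to-scan into tracks by maximal raw box-intersection area (IoU
available as an option), ties resolved by nearest centroid, greedy
one-to-one in descending overlap so the result is independent of input
order; unmatched detections start new tracks, and tracks never bridge a
scan gap. The track's peak count is the roost-size estimate; daily totals
sum peaks across a day's tracks.

A day is *sampled* only if the radar was up, at least 6 of the expected 15
morning-window scans exist, and the day carries no precipitation or
anomalous-propagation flag. The window is the fixed local interval
[05:00, 08:00), half-open — an hour before to two hours after sunrise at a
near-equatorial site, where clock time is an adequate stand-in for a solar
ephemeris. Contaminated days contribute presence (a roost visible through
rain is a real roost) but never counts; a *true zero* is a sampled day with
the whole field observable and no roost anywhere ("full-field visibility"
means exactly the absence of those flags — no finer criterion is defined).
Rain-contaminated tracks are excluded from totals; clutter-mixed tracks are
included by default since they were quantified through the mask (a switch
excludes them).

Roost sites are mean-shift clusters (flat kernel, scikit-learn) of track
first-centroids. The bandwidth default is 10 km — roughly the scale
separating distinct river-island roosts — and is a free parameter surfaced
in the outputs rather than hidden. Labels CL0000, CL0001, … are assigned by
descending member count, ties by centroid easting, making labels
order-independent. A cluster is *stable* if occupied at least
`min_days_per_year` (default 30) distinct days in every observed year,
otherwise a transient *satellite* site; the threshold is an artifact
convention recorded in the output metadata.

Region comparison takes per-year means and SDs of daily totals over sampled
days only and reports the mean ratio between regions alongside the
sampled-area ratio.

## Synthetic scenes

The SIPAM Manaus archive is proprietary and not redistributable, so the
generator fabricates scenes with known ground truth: at scan k after first
departure, a roost's airborne birds occupy the ground annulus
[k·expansion, k·expansion + width] around its center (the classic expanding
"doughnut" signature), with a uniform density chosen by *inverting the same
forward model the pipeline applies* — so recovery tests isolate pipeline
bugs, not model mismatch. A flag generates against the naive no-overlap
volume instead, to demonstrate the ~33 % bias the correction removes.
Static clutter (optionally with unbiased lognormal scan-to-scan jitter) is
added in linear units; precipitation blobs overwrite where stronger; the
result is log-converted with NaN for empty gates. Ring expansion speed
(1.5 km/scan) and width (2 km) are synthetic conventions — no published
values exist for Manaus. Bird numbers of roughly 10³–10⁵ on
correspondingly scaled rings keep the signal inside the 5–30 dBZ filter
band (a 10⁴-bird roost on the default ring sits near 18–26 dBZ).

What the generator does *not* emulate: insect blooms, anomalous-propagation
physics (represented only as a day flag), Doppler/dual-pol fields, partial
beam filling, range biases, or annotation error (boxes are exact with a
margin). Passing recovery tests therefore demonstrates the correctness of
the extraction arithmetic and bookkeeping, not robustness to the screening
and annotation noise of a real archive.

## Numerical and scale choices

* Flat-earth ground projection, no 4/3-earth-radius beam height, no
  refraction: roosts occur at close range and range biases are deliberately
  out of scope, mirroring the published analysis.
* Gate membership in a box is by gate-center point-in-rectangle; no
  partial-gate weighting (matches pixel-level extraction from rendered
  scans).
* The scan cadence is 12 minutes — inferred from "15 expected scans" in a
  3-hour window, not a published number.
* Test and demonstration scenes use a single 0.9° sweep, 360 azimuths and
  gates to 50–60 km; days–weeks of scans rather than the two-year archive.
  These sizes exercise every code path; statistics on them are not
  field-scale results.
* The analysis scripts' synthetic archive uses a 5 % mask quantile (13 of
  255 scans): with only 18 days simulated, the 2 % default would select a
  single scan and forfeit jitter averaging. The operational default
  remains 2 %.

## Known limitations

Counts inherit every assumption above: a fixed σ for a mixed-species
aggregation, no range-dependent sensitivity correction (the per-gate
min/max sensitivity profile quantifies, but does not correct, what the
radar can see), no vertical integration beyond the first sweep, and manual
(here: synthetic) annotation as the detection step. Absolute abundances
should be read as order-of-magnitude indices; within-radar comparisons over
time are the intended use.
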