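# Methods

`lspsmap` re-implements, as a tested pipeline, the analysis of laser
scanning photostimulation (LSPS) glutamate-uncaging experiments that map
the cortical innervation of single striatal projection neurons (SPNs).
One SPN is recorded in whole-cell voltage clamp at −80 mV while glutamate
is uncaged at every site of a 29×16 grid (75 µm spacing) laid over the
barrel cortex; a site whose stimulation evokes an EPSC marks the position
of presynaptic cell bodies, because focal uncaging drives cortical neurons
to fire only within ~75 µm of their soma.  This note documents the model
behind each stage, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical choices a
maintainer would want to know.

## Grid geometry and layers

Grid indices are 1-based with row 1 at the pia, so the laminar convention
is literal: rows 1–6 are L2/3, 7–9 L4, 10 L5a, 11–13 L5b, 14–16 L6.
Columns increase laterally; every lateral position is expressed in µm
relative to a horizontal anatomical reference (Ref_hor, the junction of
striatum, GPe and internal capsule), carried per slice as the signed
offset of grid column 1 (`refhor_col_offset_um`).  Alignment across slices
is metadata-only — a coordinate shift, with L5a as the vertical reference —
and maps are never resampled.  Currents are stored signed (inward
negative); all reported EPSC amplitudes are positive magnitudes.

## Detection

Per repetition, the baseline mean and SD are computed over the 100 ms
pre-stimulus segment; the response amplitude is the magnitude of the
most-negative baseline-subtracted sample in the 50 ms window after
stimulus onset, kept only when it exceeds 3 baseline SDs (~9.2 pA at the
default noise level).  A site is connected only when at least two
repetitions carry a detection; single occurrences are treated as
spontaneous activity and zeroed.  The map value is the mean over the
repetitions *with* a detection: at 2-of-3 detections, including the zero
would understate the ~40 pA amplitude scale by a third (the zero-inclusive
mean is available via `mean_mode="all"`).  Peak search uses the raw signed
minimum — no smoothing by default; a boxcar pre-filter is exposed as
`boxcar_ms` for noisier data.  An SD floor of 1e−6 pA guards degenerate
flat traces.  Whether per-repetition peaks should be baseline-subtracted
or absolute is an open choice; subtraction is used.  The ≥2 rule is read
literally as "at least 2 of however many repetitions exist" (2–4), not as
a majority.

False-positive pressure: with spontaneous EPSCs of 10–20 pA (all above
the ~9.2 pA threshold) at rate λ, the probability that a spontaneous peak
falls in the 50 ms window is p ≈ 1 − e^(−0.05λ) per repetition, and with
three repetitions the ≥2 rule passes spurious sites at 3p²(1−p) + p³.  At
the default 2 Hz this is ≈2.5% of sites — an irreducible property of the
rule itself, not of the detector implementation.  Bringing it under 1%
requires λ ≲ 1.2 Hz or two repetitions.  The spontaneous rate is therefore
an explicit configuration knob (`spont_rate_hz`), and cohort-level results
on synthetic data should be read with this floor in mind.

## Synthetic cohorts

The generator plants ground-truth connectivity and synthesises raw sweeps
so every downstream stage can be validated against a known answer.

**Connectivity patterns.**  Cluster counts are drawn from a distribution
over 1–6 with mean 1.9; cluster widths over 1–4 collapsed columns with
mean ~2.1 sites (~160 µm, about one barrel); inter-cluster gaps are
geometric with mean 3.5 columns (~265 µm).  Secondary clusters alternate
sides around a primary cluster placed at a cortical anchor; gaps shorten
when the grid edge is near (flagged `clipped`), so the realised cluster
count tracks the configured distribution.  Each connected column hosts
sources in 1–3 rows (55% single-row, matching the observation that a
column most often innervates an SPN from a single layer), with rows drawn
from layer weights dominated by L5a (0.40 of the per-site mass, then L4
0.25, L5b 0.18, L2/3 0.12, L6 0.05).  Site amplitudes are log-normal with
mean 40 pA (cv 0.5); each site carries 1–5 presynaptic contacts.

**Topography.**  The planted map is placed around a random cortical
anchor, and the cell's striatal position is then *defined* by the linear
model `CM = slope·position + intercept + ε`, with ε ~ N(0, jitter_sd).
With jitter 0 the cohort's CM–position relation is exactly linear (the
recovery oracle); the jitter that yields a target correlation R follows
from `jitter_sd = sd(CM)·sqrt(1/R² − 1)`, with sd(CM) estimated once from
a fixed-seed jitter-free probe cohort.  The default targets R ≈ 0.6, a
loose topography.

**Sweeps.**  Each trace is 100 ms baseline + 450 ms post-stimulus window
at 5 kHz (the digitisation rate is a stored parameter of every sweep, not
an assumption; 5 kHz resolves the 1 ms EPSC rise while keeping desk-scale
cohorts cheap).  Evoked EPSCs use a difference-of-exponentials kernel
(rise 1 ms, decay 10 ms — standard AMPA-like kinetics, well inside the
50 ms window), latency N(7, 2) ms clipped into the window, and a
per-repetition amplitude that sums per-contact draws around the site mean
(cv 0.2).  Spontaneous EPSCs are Poisson at 2 Hz, uniform 10–20 pA, over
the whole trace.

**Noise.**  Baseline noise is Gaussian-core with bounded extremes:
white Gaussian samples smoothed by a double boxcar (~1 ms correlation),
passed through a soft saturation (tanh at 2 SD) and rescaled to an SD of
3.07 pA, so the detector's 3-SD threshold lands at the ~9.2 pA level.
The saturation is deliberate.  A pointwise extreme-value detector applied
to *unbounded* Gaussian noise crosses a 3-SD threshold in a 250-sample
window far too often (tens of percent of windows), which no choice of
bandwidth fixes as long as the per-sweep SD estimate has chi-squared
tails.  Bounding the excursions at ~2.5× the final SD makes noise-only
crossings structurally negligible while leaving the central ±2 SD of the
distribution Gaussian.  This is the main idealisation of the generator:
real amplifier noise is broadband and unbounded, real pipelines smooth or
average before peak-picking, and spontaneous activity is not strictly
Poisson.  Consequently, passing recovery tests demonstrate the
correctness of the analysis rules, not the detector's performance on raw
rig data.

**Excitation profiles.**  Current-clamp AP-count maps on a dense 50 µm
grid (8×8, or 24×8 to reach L1): sites within `excitation_radius_um`
(default 75 µm) of the soma fire 1–2 APs — the double-spike probability is
3–4% per cell type so spikes-per-site averages 1.03–1.04 — and all other
sites stay silent.  No conductance-based modelling; the profile is the
geometric footprint the mapping analysis needs.

**Determinism.**  All randomness flows through one `numpy` Generator per
call; the CLI derives per-stage generators from the run seed by fixed
spawn keys, so toggling one stage never changes another stage's draws.

## Pattern metrics

The connectivity map (binary support of the input map) is collapsed along
the vertical axis by a column-wise OR.  A cluster is a maximal run of
connected columns; with a barrel spanning ~150 µm ≈ 2 grid columns, a run
of n sites counts ceiling(n/2) cortical columns.  The input field spans
first to last connected column inclusive, so widths count site extent —
(last − first + 1)×75 µm — and a single-site field is 75 µm wide, not
zero.  The gap fraction is the percentage of unconnected columns inside
the field; inter-cluster spacings are gap runs × 75 µm.  The
dominant-cluster ratio divides the strongest cluster's EPSC sum (all rows
of its columns) by the **mean** of the other clusters' sums; dividing by
their **total** is available via `others="total"` — the definition is
genuinely ambiguous and both attain the observed ranges, so the less
compressive reading is the default.  Cells with empty maps are excluded
from pattern metrics and reported separately.  Clustering is defined on
the collapsed profile only; no 2-D clustering is attempted.

## Centers of mass

The connectivity CM weights each column by its vertical count of
connected sites: Σ(count·x)/Σ(count), equal to the plain mean of lateral
positions over connected sites.  The synaptic-input CM weights each
column by its vertical **mean** EPSC taken over all rows of the
thresholded map — equivalently, amplitude-sum weighting:
Σ(amp·x)/Σ(amp) over sites.  This reading makes the two CMs coincide
exactly when all amplitudes are equal, which is the property that lets
their comparison isolate the contribution of synaptic strength to
topography.  A connected-sites-only column mean (which re-weights columns
by response strength irrespective of depth coverage) is available via
`column_mean="connected"`.  Cohort topography is summarised by Pearson
and Spearman correlations of CM versus SPN position plus signed
least-squares residuals; residual comparison between the two CM
definitions is descriptive only (no covariance-adjusted testing here).
The projection-zone width bins connected-site positions every 150 µm
along the cortex, anchored at Ref_hor, and reports the maximum pairwise
distance between the SPNs reached from each bin (NaN with fewer than two
cells).

## Pairwise heterogeneity

For two same-slice cells: field overlap is the inclusive intersection
length of their [first, last] column intervals (0 when disjoint); a
connected site is *aligned* when its column contains a connected site of
the other map, and *overlapping* when the exact (row, col) site is shared.
Both percentages pool the two maps' sites in the denominator —
100·(alignedA + alignedB)/(|A| + |B|) and 100·2|A∩B|/(|A| + |B|) — so
overlap ≤ aligned always; per-map fractions are emitted alongside.
Column matching is strict (±0 columns) even though the 75 µm excitation
radius could justify ±1; strictness keeps the statistic conservative.
Distance bins are half-open [k·100, (k+1)·100) µm and empty bins are NaN,
never zero.

## Excitation-profile analysis

AP counts come from per-site spike counts (upward crossings of 0 mV when
raw traces are given).  sAP is the number of firing sites at the
profile's grid spacing; spikes-per-firing-site is total spikes / sAP.
Converting a firing-site count between grid spacings uses the
area-preserving ratio sAP × (spacing_from/spacing_to)², because a coarser
grid tiles the same excitable area with proportionally fewer sites — a
count converted 50 → 75 µm must *shrink* by (50/75)² = 4/9.  The inverse
ratio sometimes quoted for this conversion would inflate the count by
2.25× and contradicts the measured ~2.8 firing sites on the 75 µm grid
implied by the measured per-type spike statistics (weighted L5 mean
≈ 6.3 sites at 50 µm × 4/9 ≈ 2.8); we treat that form as a typo.  The
weighting across the two L5 sub-types is by cell count (n=30 RS, n=10
non-RS).

## Truncation Monte-Carlo

The SPN dendritic field is a sphere of radius 200 µm centred on the soma.
80% of synapses are dendritic, at radii drawn from a radial density
table; 20% are somatic and never lost.  Directions are isotropic, so for
a synapse at radius r the coordinate toward the cut surface is z = r·u
with u uniform on [−1, 1].  Slicing removes one spherical cap: a
dendritic synapse is lost iff z exceeds the soma depth (default 80 µm,
the shallowest recording depth — a conservative fixed plane rather than a
depth distribution; the far face of the 350 µm slice is ignored).  The
default radial density is triangular — rising from 0 at the soma to a
peak at 80 µm and vanishing at 200 µm — encoding that mid-arbor synapses
dominate and distal ones are proportionally rare; it is an assumption,
fully overridable through `radial_density`, not a fitted curve.  Under it
the expected loss is ∫ f(r)·(r−80)/(2r) dr × 0.8 ≈ 7.1%, below the 10%
bound that rules out truncation as the source of sparse maps.  Estimates
report the binomial standard error √(p(1−p)/n) at n = 100,000 samples,
and single-radius configurations are verified against the closed form
frac·(r−d)/(2r) within 3 SE.

## Problem sizes and numerical choices

Validation cohorts use 200 cells × 464 sites × 3 repetitions (~280k
traces) for exact-recovery checks, 10 cohort seeds × 200 cells for the
topography calibration, 1,000 random maps for the formula/oracle
equivalences, and 100,000 Monte-Carlo samples for truncation — sizes
chosen so the full suite runs on a single CPU in minutes.  Ties and
degenerate inputs: empty maps raise (`ValueError`) rather than returning
sentinels; the dominant-cluster ratio requires ≥2 clusters; pair metrics
require both maps non-empty and a shared slice; correlation summaries
require ≥3 cells.  Evoked latencies are clipped to [1, 45] ms so the
kernel peak stays inside the detection window.  HDF5 round trips are
lossless (amplitudes bit-identical).

## Known limitations

* The noise model's bounded tails are an idealisation (see above); the
  detector's false-positive rate on real recordings will be higher and
  should be controlled with the boxcar pre-filter or a lower spontaneous
  rate assumption.
* Connected sites are planted exactly at grid sites; the ~75 µm spatial
  blur of real photostimulation (which can smear one source across
  adjacent columns) is not modelled, so recovery tests do not probe
  column-assignment errors.
* No feedforward inhibition, no IPSCs (cells held at −80 mV), no
  conductance-based neuron models, no reconstructed morphologies (the
  sphere is the model), and no image registration or atlas handling.
* Inferential statistics on the metrics (rank tests, covariance-adjusted
  slope comparisons) are intentionally out of scope; the pipeline emits
  the per-cell and per-pair tables those tests would consume.
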