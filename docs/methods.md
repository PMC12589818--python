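# Methods

## The QA process model

A PSQA record is one pre-treatment verification of one plan: gamma passing
rates (%) at one or more dose-difference/distance-to-agreement criteria
(3%/3 mm always; 2%/2 mm where measured) and a signed absolute dose
difference (%). Records are stratified by facility and by disease site
(CNS, head & neck, chest, pelvis, other), because both the achievable
passing rate and its spread differ strongly across those cells. Within a
stratum the passing-rate series is treated as a univariate process observed
once per verification, in QA-date order.

### Limits

For a stratum with sample mean x̄, sample SD σ (n−1 denominator, the
process-capability convention) and target T, the tolerance width is
ΔA = β·√(σ² + (x̄−T)²). The squared-bias-plus-variance form penalizes a
systematic offset from target exactly like random spread. β defaults to 6
(a ±3σ-style band for an on-target process) and is exposed in
configuration. The action limit for passing rates is AL = 100 − ΔA/2,
one-sided: only low passing rates demand intervention. The dose-difference
channel is two-sided about T = 0 with limits ±ΔA/2.

The tolerance limit is defined through the individuals control chart: over
the chronologically ordered values, TL = centerline − 2.660·m̄R (and the
matching upper limit for two-sided channels), where m̄R is the average
moving range. The centerline is the arithmetic mean of the series. The
constant 2.660 is 3/d₂ with d₂ = 1.128 for moving ranges of span two.
Because AL is moment-based and TL is moving-range-based they are not
ordered by construction; an unstable process can yield TL < AL, which is
flagged (`TL<AL`) but reported — it is diagnostic, not an error. Strata
with fewer than `min_n` (default 20) records are flagged `provisional`.

### Monitoring and alerting

Rule 1 (a point outside [LCL, UCL]) is always evaluated; run rules (eight
consecutive points on one side of the centerline, six monotone points) are
available but off by default, since breach-only flagging is the
conservative baseline for QA review. Chart limits are reported unclamped —
a UCL above 100% describes process spread, not an achievable measurement.

Outlier scanning uses Tukey fences at Q1 − k·IQR and Q3 + k·IQR with
k = 1.5 by default, quartiles by linear interpolation between order
statistics (the numpy default; the convention matters at small n, which is
why fewer than four values are refused). Scanning is per
(facility, site) stratum by default so a wide site does not mask a tight
one. Breach comparisons are strict: a value exactly on AL or TL passes,
because the limits are defined as the lower bound of acceptability. A value
below both TL and AL produces a single most-severe `AL_breach` alert
annotated that the TL is also crossed.

### Validation and curation

Ingest is flat RFC-4180 CSV with one column per gamma criterion
(`gamma_3_3`, `gamma_2_2`), ISO-8601 dates, and a pseudonymous
`patient_key` (a public artifact must never carry identifiable IDs).
Row-level rules: missing mandatory fields, gamma outside [0, 100], dose
difference outside a configurable plausibility window (default ±10%),
unparseable dates and unmappable disease sites are errors (row rejected and
itemized); machine/device/facility labels outside the controlled
vocabulary are warnings (row kept). Disease-site normalization is a
documented, overridable synonym table onto five categories; unmappable
labels yield an explicit `UNMAPPED` marker, never a guess. Every input row
is accounted for exactly once as accepted or rejected.

## The synthetic cohort generator

The generator emulates a four-facility, five-site QA consortium. Per
stratum, each channel is drawn i.i.d. Gaussian with spec (mean, sd); gamma
channels are then clipped to [0, 100]. Clipping was chosen over a truncated-
normal model for transparency; the realized clip fraction per channel is
recorded in the manifest so its bias on observed moments can be bounded,
and `clip=False` exposes the unbounded process for studies whose analytic
oracles assume Gaussian moments. QA dates are evenly spaced over the
stratum's range (2016-01-01 to 2025-06-30 by default) in chronological
order; a single RNG stream consumed in (stratum, record, channel) order
makes generation bit-identical under a fixed seed, and the manifest
regenerates the cohort exactly.

The `showa2016` preset holds 835 records split 147/256/89/258/85 across
CNS / head & neck / chest / pelvis / other, divided as evenly as possible
across the four facilities. Its per-stratum pre-clip parameters were solved
once, offline, by analytic truncated-normal moment matching so that the
*observed* (post-clip) cohort reproduces the pooled study conditions —
3%/3 mm ≈ 99.4 ± 1.3%, 2%/2 mm ≈ 94.3 ± 7.7%, dose difference
0.46 ± 0.98% — while the per-site action limits within the reference
facility (≈99.0 / 96.4 / 97.8 / 93.6 / 97.0%) and the pelvis cross-facility
spread (AL ≈ 93.6 / 97.6 / 99.5 / 88.7%, Northern Yokohama tightest,
Fujigaoka widest) match the published benchmark ordering. The solver
parameterized each stratum as σ_fs = s_site·g_facility with a common
mean-offset ratio (100 − μ)/σ, and the resulting twenty (μ, σ) pairs are
frozen in `psqakit.synthetic`. Individual stratum values are model choices
consistent with that structure, not measured data.

What the generator does **not** model: correlation between the two gamma
channels within a plan, plan-complexity or device-physics effects,
seasonal workload patterns, repeated measurements of one patient, and the
left-skewed shape of real passing-rate distributions (a clipped Gaussian
piles probability at 100% instead). Passing tests therefore demonstrate
correctness of the statistics on data with the stated first and second
moments, not robustness to every feature of clinical data.

Anomaly injection is additive on a chosen channel after placing the cohort
in chronological order: a step shift adds its magnitude from the onset
index on, a linear drift ramps from zero at onset to full magnitude at the
final record, and point outliers add the magnitude at listed indices only.
Injected values are deliberately not re-clipped so the ground-truth
magnitude is exactly recoverable by detection tests.

## Numerical and design choices

* Quartile convention: linear interpolation (`numpy.percentile` default).
* Sample SD everywhere uses ddof = 1; series shorter than 2 are refused
  rather than silently returning 0.
* Chronological ordering sorts by QA date with a stable sort, so same-day
  records keep input order (m̄R is order-dependent; the tie-break is
  documented rather than arbitrary).
* The individuals-chart centerline is the arithmetic mean (1/n)Σxᵢ — the
  standard choice for this chart type.
* Alert severity collapses to the most severe level per (record, channel)
  so a gross failure raises one alert, not a cascade.
* Analysis problem sizes: the acceptance workflow runs the full 835-record
  preset; recovery studies use single strata of 400–10 000 records, large
  enough that CLT-scale tolerances (a few standard errors) are meaningful.
* Report provenance embeds a SHA-256 digest of the canonical CSV rendering
  of the input records plus the full configuration and seed, so an audit
  can tie limits to the exact data that produced them.

## Known limitations

* The AL/TL framework assumes an approximately in-control, roughly
  Gaussian process per stratum; limits derived from contaminated or
  strongly skewed histories inherit that contamination (garbage-in,
  garbage-out — screen with the outlier scan first).
* TL as a chart limit is sensitive to ordering and to autocorrelation;
  strongly trending series deflate m̄R locally and can make TL optimistic.
* Because the 3%/3 mm strata sit so close to 100%, roughly 46% of their
  synthetic draws touch the bound and are clipped (≈5% for 2%/2 mm); the
  preset calibration absorbs this into the observed moments, but the
  resulting point mass at exactly 100% is sharper than in real data.
* Gamma passing rates are consumed as precomputed percentages; computing
  the gamma index from dose grids, DICOM-RT handling, and predictive
  (machine-learning) QA are out of scope.
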