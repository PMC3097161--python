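# Methods

This note documents the models, conventions and numerical choices in
`pmkinetics`, the assumptions behind its synthetic-data generator, and
what its tests do and do not establish about real instrument data.

## Data model

A *kinetic curve* is one well's intensity time series: strictly
increasing times in minutes, finite intensities in instrument units.
Raw instrument data are non-negative, and the parser and generator
enforce that; derived curves (z-scored profiles, replicate means on a
resampled grid) may be negative, so the `KineticCurve` constructor takes
`require_nonnegative=False` at those internal call sites. A
*well record* attaches the full metadata coordinate — project, species,
strain, phenotype, plate, well, replicate, temperature — and the tuple
(project, strain, phenotype, plate, well, replicate, temperature) is
unique within a record set.

Record selection is conjunctive field filtering: a step-wise drill-down
(project → strain → phenotype → replicate → temperature) composes to
the same subset as a single conjunctive filter, so the filter API is the
more general primitive. Two consequences worth noting:

- **Temperature is part of the replicate-group key.** Runs at different
  temperatures are different experiments and are never averaged
  together.
- **Species is metadata, not a filter level** — the selection hierarchy
  is project/strain/phenotype/replicate/temperature; plate and well are
  additionally filterable for completeness.

## File dialect

Instrument exports are comma-separated, one plate-run per file. No
public specification of the vendor layout exists, so the package defines
a canonical dialect (metadata header rows, then a `Time(min)` — or
`Hour`, converted ×60 on read — column followed by well columns
A01–H12) that the generator emits and the parser reads; a thin adapter
can map a real export onto it. Phenotype labels are not part of the
export: a sidecar `phenotype_map.csv` (plate, well → phenotype) supplies
them, with `<plate>_<well>` as the default label, because the
proprietary plate compositions are not public and should not be
hard-coded.

Numbers are written with `repr` full precision and parsed with numpy's
correctly-rounded string conversion, which makes write→parse exact and
write→parse→write byte-identical. (pandas' fast float path is *not*
correctly rounded in the last ulp and is deliberately bypassed.)
"Spreadsheet" report outputs are plain CSV — portable, diffable, and
opened natively by spreadsheet software.

A full plate (96 well columns) is required on parse by default; the
check is relaxed (`require_full_plate=False`) when re-reading the
partial-plate files that the `filter` subcommand legitimately produces.

## Curve numerics

- **Common grid**: spans the *intersection* of the curves' time ranges
  (never extrapolates), with as many evenly spaced points as the
  longest member (keeps maximal resolution). Disjoint ranges are an
  error naming the offending curves.
- **Interpolation is linear** — the minimal monotonicity-preserving
  choice for 15-minute-sampled growth data; grid points that coincide
  with observations reproduce them exactly.
- **Z-scores** use the sample (n−1) standard deviation; a zero-variance
  curve maps to all zeros and is treated as degenerate downstream.
- **Curve summary** default is the trapezoid area under the curve
  (intensity·minutes): it integrates the whole kinetic response and is
  robust to single-time-point noise. `max` and `endpoint` are available
  alternatives; no published convention fixes the choice, so it is a
  documented default rather than a claim.

## Quality control

**Outlier screen.** "Median correlation" is computed *per member*: the
median of that record's pairwise Pearson correlations with every other
member of its (strain, phenotype, plate) group. Only a per-record
statistic can say *which* record is aberrant; the group-level median is
reported alongside for reference. Default threshold 0.5, always
user-overridable. Zero-variance members (a flat replicate among growing
ones) have undefined correlations; they are reported as degenerate and
flagged, since a flat curve in a growing group is aberrant by
definition. Groups of size 1 are skipped with a warning. Note that
no-growth wells measured twice are pure noise against pure noise: their
replicate correlations hover near zero and they are flagged at any
reasonable threshold. That is informative (no reproducible signal), but
users screening whole plates should expect flat wells to dominate the
flagged list.

**Negative controls.** Quantile curves use linear interpolation between
order statistics (the convention of standard statistical environments),
default levels {0.05, 0.25, 0.5, 0.75, 0.95}, computed per time point
across all selected control wells, pooled across plates (per-plate
analysis is a filter away). The per-level maximum over time is reported
as a candidate threshold and drawn as a horizontal line; no automatic
signal/noise boundary is chosen — the output guides a user decision.
Controls and the optional non-control overlay share one grid so the
curves are directly comparable.

## Profile statistics

- **Correlation matrix**: full symmetric Pearson matrix on the joint
  grid; zero-variance records get NaN rows/columns and a warning;
  well-defined diagonal entries are exactly 1.
- **Correlation p-values** use the exact t-transform
  (t = r·√((n−2)/(1−r²)), n−2 df, two-sided); |r| = 1 short-circuits to
  p = 0. r is computed by the direct covariance formula, which returns
  exactly ±1 in the perfect-correlation limit.
- **Profile search** correlates *raw* intensities (matching the
  correlation matrix's treatment); z-scoring is available as an option
  but changes nothing for Pearson r. Patterns are piecewise-linear
  through their anchor points and are resampled like any curve, on the
  record set's grid restricted to the pattern's range. Results are
  ordered by descending r; degenerate records sort last with NaN.
- **k-means** runs on z-scored curves with Euclidean distance,
  k-means++ ("spread-out") initial centres, best of `restarts` runs
  (default 10) by within-cluster sum of squares, at most 300 Lloyd
  iterations, deterministic for a fixed seed (default 42). Cluster ids
  are renumbered 1..k by first appearance in record order so output is
  stable across library versions. Centroids are recomputed as the mean
  of the members' scaled vectors (the definition, independent of solver
  internals), and each member's Pearson r to its centroid is reported.
  scikit-learn provides the solver; exhaustive partition enumeration on
  small instances and adjusted-Rand checks on planted families verify
  it independently in the test suite.

## Strain comparison

Replicate curves are reduced to scalars (AUC by default), then for each
(plate, well): ratio of mean test summary to mean parent summary —
*ratio of means*, matching "average replicates, then compare", not mean
of ratios — converted to the signed fold-change convention (FC = ratio
if ≥ 1 else −1/ratio; FC at exactly 1 is +1 by fiat for determinism),
with Welch's t-test on the two replicate-summary samples. Degenerate
cases are defined, not errors: both groups zero-variance with equal
means → t = 0, p = 1; unequal means → p = 0 with a warning; fewer than
2 replicates → the fold change is reported with p marked unavailable;
parent mean summary ≤ 0 → the cell is marked incomputable.

P-values are raw, uncorrected for multiple testing — the conventional
screen in this assay reports p < 0.05 with |FC| ≥ 2 on raw values.

The heat-map figure lays wells A01–H12 as rows and plates as columns
per test strain. Colour encodes sign(FC)·log₂|FC| on a diverging scale
centred at no change — a symmetric transform used *only* for colour;
all reported numbers are fold changes. The fold-change colour bar sits
horizontally beneath each panel.

One caution inherent to thresholded screens: a well whose *true* fold
change sits exactly at the cutoff (ratio 2.0 or 0.5 under the default
|FC| ≥ 2 filter) is estimated with symmetric error and lands on either
side of the threshold with roughly even odds. The filter's specificity
(nulls never pass) is a property of the statistics; the fate of
knife-edge wells is a property of thresholding itself.

## Synthetic data generator

The generator emulates the standard two-strain screening design — by
default 2 strains × 20 plates × 96 wells × 2 replicates, read every
15 minutes for 72 hours (289 points per curve). Each (plate, well)
draws one kinetic model shared by all strains and replicates (the same
substrate should behave the same everywhere, absent a planted effect):

v(t) = baseline + A·σ(±r·(t − t_m)) + ε,  ε ~ N(0, noise_sd²), clipped at 0

with σ the logistic function — the simplest sigmoid covering the three
observed behaviours: growth (+), inhibition/decay (−), and no growth
(A = 0). Defaults: baseline 20 intensity units; amplitude uniform on
[120, 280]; rate uniform on [0.005, 0.02] min⁻¹ (half-rise widths of
hours); midpoint uniform on [600, 2400] min (10–40 h, inside the 72 h
window); noise_sd 2 (≈1% of a typical amplitude, so clipping at zero is
rare); 70% of wells growing. All randomness flows from one seeded
generator in a fixed iteration order, so a fixed seed is bit-identical.

Planted ground truth, recorded in a `TruthTable`:

- **Outliers** replace a replicate's noiseless curve with its time
  reversal (maximally anti-correlated with its partners) before noise;
  slots are drawn among growth wells only, since reversing a flat curve
  changes nothing.
- **Fold changes** scale the *whole* noiseless curve of the test strain
  by the planted ratio ρ, which makes the expected summary ratio
  exactly ρ for any of the summary statistics (scaling only the
  amplitude would be diluted by the baseline and make the planted
  "truth" summary-dependent).
- **Cluster labels** are the shape family (growth / inhibition / flat)
  of each well.

Negative controls are flat noisy wells (A = 0) carrying the reserved
phenotype label `negative_control`.

What the generator does *not* emulate — and therefore what passing
tests do not establish about real data: dye chemistry and saturation,
plate-edge and other spatial effects (explicitly out of scope), real
substrate panels, heteroscedastic or autocorrelated noise, and
replicate-to-replicate lag shifts. Recovery results on synthetic data
validate the *machinery* (the statistics compute what they claim, at
the design's scale); they do not calibrate biological effect sizes.

## Figures

Vector formats only (postscript default — the traditional
publication-quality choice — plus pdf and svg). "Single file"
multi-panel outputs are genuinely multi-page in PDF; the postscript and
SVG backends write one page, so those formats pack all panels onto one
page grid. Output is deterministic for fixed inputs: timestamp metadata
is stripped and the SVG id-hash salt is fixed. Categorical shading (by
phenotype, strain, or both) uses a deterministic palette keyed on
sorted category labels.

## Problem sizes in the validation suite

The test and acceptance runs use: the full 2 × 20 × 96 × 2, 72 h design
for design arithmetic, the end-to-end CLI workflow and round-trip
checks; 100 random small instances per statistic for oracle
equivalence (tolerance 1e-10); 50 seeded repetitions of
4-concordant-plus-1-reversed replicate groups for outlier recovery; 20
seeds of two 6-member shape families (plus exhaustive 2-partition
enumeration on 6-record instances) for clustering; one plate at 3
replicates with planted ratios {4, 2, 1, 0.5, 0.25} for fold-change
recovery; and 200 null wells for Welch calibration (99% binomial band
0.0103–0.0897 around 0.05). The whole suite runs in well under a
minute of compute; sizes were chosen as the smallest that exercise each
design fully.

## Known limitations

- The scalar behind the strain-comparison ratio (AUC) is a documented
  default, not a community standard; conclusions sensitive to the
  summary should be checked under `max`/`endpoint` too.
- Pooled (not per-plate) negative-control quantiles assume noise is
  homogeneous across plates.
- No multiple-testing correction by default; with 1,920 wells the
  p < 0.05 screen expects ~96 null passes by chance — the joint |FC|
  filter, not the p-value alone, carries the specificity.
- k-means with user-chosen k; no automatic model selection, and
  elongated or overlapping shape families can split arbitrarily.
- The parser reads the package's own canonical dialect; real vendor
  exports may need a mapping step.
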