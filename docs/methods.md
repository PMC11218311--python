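# Methods

This note documents the models, numerical choices, and limitations behind
each analysis stage, and what the synthetic generators do and do not
emulate.

## Coordinate and angle conventions

All physical quantities are in µm. x runs along image columns, y along
rows; the center of pixel (row r, col c) is at ((c + 0.5)·s, (r + 0.5)·s)
for pixel size s. Angles are measured counterclockwise from the +x axis
(`atan2(dy, dx)`), and angular intervals are half-open [start, end) so that
degree partitions are exact. All thresholds default to Otsu; detection-type
thresholds (rays, puncta, somata, plaques) are additionally floored at a
robust noise level (median + 5σ, σ estimated as the upper half-spread
q84 − q50, which survives zero-clipping), because Otsu always splits a
signal-free channel and would otherwise promote pure noise to foreground.
Area-fraction measurements skip the floor, since there the positive class
may legitimately dominate the ROI; an ROI containing nothing but noise is
therefore not special-cased in area fractions.

## Plaque quantification

Plaques are 4-connected components of the thresholded plaque channel
(4-connectivity avoids diagonal bridging of adjacent deposits), filtered at
a minimum area of 10 µm², ordered deterministically by (y, x) centroid.
The plaque "center" is the intensity-weighted centroid. The equivalent
diameter is 2·√(area/π). High-magnification stacks are reduced by a
maximum-intensity projection of the three optical slices through the
plaque's central plane (clamped at stack boundaries); single-plane surveys
pass through unchanged. Plaque-associated microglia are somata whose
centroid lies within 25 µm (inclusive) of the plaque center — radius from
the center, not diameter. Soma detection is a local-maximum search on the
Gaussian-smoothed Iba1 channel at the 6 µm soma scale; maxima closer than
~0.8 soma diameters merge into the brighter detection, a documented
behavior rather than an error. When the Iba1 channel also contains
peri-plaque coverage bands, an exclusion mask (dilated plaque region)
should be passed so ridge points along the band are not counted as somata;
the CLI does this automatically.

## Barrier coverage and sector dystrophy

One ray per 1° bin is cast from the plaque centroid (step = half a pixel).
The outermost plaque-mask sample along the ray is the perimeter crossing;
the bin is covered iff any Iba1⁺ sample lies within ±1 µm of the crossing
along the ray. The ±1 µm colocalization band makes an inherently manual
judgement (does the microglial process touch the plaque surface here?)
reproducible, and is exposed in the API. Coverage is exact integer
arithmetic in Δθ units, so covered + uncovered degrees ≡ 360.

For dystrophy, every Lamp1⁺ pixel outside the plaque mask is assigned to
the angular bin of its angle from the centroid and kept if within that
bin's Lamp1 outer extent plus half a pixel diagonal of slack (off-ray
pixels sit up to that far beyond the on-ray extent); bins whose ray saw no
Lamp1 apply no radial cap. Because each pixel lands in exactly one bin,
covered + uncovered areas equal the total exactly, by construction. A
sector class spanning 0° has an undefined per-degree value, reported as
NaN, never as 0.

A brute-force cross-check (`angular_profile_bruteforce`) recomputes
coverage without rays: each pixel's footprint subtends an interval of
angles seen from the centroid; per bin, the perimeter radius is the largest
plaque-pixel radius among footprints containing the bin-center angle, and
the bin is covered when any Iba1⁺ footprint containing that angle lies
within the band of that radius. Ray-cast and pixel-histogram routes agree
on ≥ 99% of 1° bins for convex plaques at the default 0.5 µm pixels;
residual disagreement is confined to ±1–2 bins at covered-interval edges,
where pixel footprints (2–4° wide at these radii) quantize the transition.

Coverage–dystrophy correlation is Pearson's r (two-sided p from the
t-distribution with n − 2 df) within plaque-diameter bins, default
[0, 9), [9, 18), [18, ∞) µm — only the < 9 µm edge is anchored in the
motivating observations; the others are config-exposed defaults. Total
Lamp1 area is correlated by default, per-degree area available via
`lamp1_field`. Bins with fewer than 3 plaques or zero variance are
reported as missing with a reason. The covered-vs-uncovered contrast is a
paired two-sided t-test across plaques that have both sector classes.

## Sholl analysis

From SWC: edges are straight segments between consecutive nodes; for each
radius the number of solutions of |p(t)| = r with t ∈ (0, 1] is counted
per edge (exact quadratic roots; tangency counts once; t = 0 excluded so a
crossing at a shared node belongs to exactly one edge — a node exactly on
a circle is attributed to its inbound edge). Radii run from Δr (default
5 µm) to the farthest node distance rounded up to Δr. SWC type codes
filter basal vs apical dendrites when present; otherwise all neurites
count.

From masks: circles are rasterized with the Andres midpoint variant (no
diagonal holes) and an intersection is one 8-connected component of
ring ∩ mask. The two routes agree within ±1 on noiseless renders *away
from node-grazing radii*: when a circle passes within ~1 µm of a branch
point, the rendered blob around the node merges the two child crossings —
a genuine property of image-based Sholl (the ImageJ plugin behaves the
same), so the equivalence tests exclude radii within 1 µm of a node
distance. Rendered neurites are given a finite width (0.5 µm default) as
in real thresholded images; a one-pixel-thin diagonal line can cross a
rasterized circle without sharing a pixel.

AUC is the trapezoidal integral of counts over radii; a simple
counts-times-Δr sum is exposed as an option since reported AUCs do not
always state the rule.

## Phagocytosis scoring

The built-in segmenter is a nuclei-seeded watershed: nuclei are smoothed,
thresholded and labeled as markers; the watershed floods the inverted
smoothed cell-marker channel restricted to the cell mask. Label images
from external segmenters (e.g. cellpose) are accepted directly and
relabeled sequentially. A cell is Aβ⁺ when it contains at least one
*contiguous* above-threshold FITC punctum of ≥ 1 µm² — contiguity matters:
scattered single bright pixels from noise must not qualify. The positive
threshold defaults to Otsu over cell pixels with the noise floor. Reported
intensity is the mean FITC over above-threshold pixels of positive cells,
on the raw scale (no background subtraction), which recovers the
generator's punctum amplitude within a few percent at the default punctum
size (1.25 µm radius) and PSF (0.15 µm).

## miRNA screen

Filtering keeps features with count ≥ 10 in strictly more than 50% of the
samples of each group (both groups must pass). With 11 cases / 14 controls
that means ≥ 6 of 11 and ≥ 8 of 14.

TMM: the reference sample is the one whose upper-quartile depth-normalized
count is closest to the mean; per sample, M = log2 ratio of
depth-normalized counts vs the reference over co-expressed features, doubly
trimmed (30% on M, 5% on the average abundance A), averaged with
delta-method inverse-variance weights; factors are rescaled to geometric
mean 1. The implementation is cross-checked against edgeR's
calcNormFactors in the test suite. Exact invariance to rescaling one
library holds only in the pure-depth case (identical compositions); in
general the precision weights depend weakly on depth, so factors are
stable to ~1% rather than machine precision — inherent to TMM, not an
implementation artifact.

Testing uses a negative-binomial conditional exact test: counts are scaled
to a common effective depth, group sums are NB with a common
method-of-moments dispersion (median over features of (var − mean)/mean²,
clipped at 0; dispersion 0 reduces the conditional law to a binomial), and
the two-sided p-value sums the probabilities of all case-sum outcomes no
more likely than the observed one. log2FC is the ratio of TMM-CPM group
means with pseudo-count 0.5 (avoids log 0; recorded in the output
metadata). DEMs require |log2FC| > 1 and BH-FDR < 0.05. TPM is emitted for
reporting; for equal-length mature miRNAs it coincides with CPM, which is
what the test consumes.

The 95%-interval signature rule is ambiguous between a CI of the control
mean and an interval for individual control values; since the rule is
applied to individual case samples, the default is a prediction-style
interval, mean ± t₀.₉₇₅,(n−1)·sd·√(1 + 1/n), with the CI-of-mean variant a
config option. A feature is flagged iff *every* case sample falls outside;
features detected in ≥ 1 case and 0 controls are marked exclusive-to-cases.
Zero control variance degenerates the interval to a point (flagged in the
output). PCA is a centered SVD with a deterministic sign convention (the
largest-magnitude loading of each component is positive).

One source inconsistency is surfaced rather than resolved: the cohort is
11 cases throughout, although the signature rule is described once as
holding in "all 12" cases; 11 is used everywhere here.

## Synthetic generators

The histology generator renders, per plaque: a uniform disk in the plaque
channel; an Iba1 envelope band (radius − 0.5 µm to radius + 2 µm) over the
specified covered intervals; Lamp1 puncta (0.8 µm radius) placed uniformly
in the halo annulus at per-sector-class target area fractions; 6 µm soma
disks at controlled distances (associated somata within 25 µm, background
somata kept > 27 µm from every plaque center so the association counts
stay exact). Slices fade from the central plane with a Gaussian axial
falloff, then Gaussian PSF blur (σ = 0.3 µm) and additive Gaussian noise
(σ = 4 intensity units against signal amplitudes of 150–200) are applied.
Defaults emulate a 40× confocal acquisition (0.5 µm pixels, 3 µm z-step,
five slices); imaging noise levels are not pinned down by the motivating
experiments, so `noise_sd` is exposed rather than fixed. Ground-truth
coverage is exact interval arithmetic; ground-truth Lamp1 areas are
measured on the rendered noiseless masks (exact pixel counts), so
downstream recovery tests compare against what was actually drawn, not
just what was requested.

The count generator draws NB counts (dispersion 0.15, a realistic
biological CV for plasma miRNA cohorts) with baseline abundances
log2-uniform over [3, 10], per-sample depth factors log-uniform over
[0.7, 1.4], cohort 11 cases vs 14 controls, 10% DE features at log2FC 2
applied multiplicatively to the case mean.

What the generators do **not** emulate: microglial process morphology
(coverage is a clean annulus, not ramified processes), optical sectioning
physics and spectral bleed-through, plaque shape irregularity (disks
only — the degenerate-centroid fallback for concave plaques is implemented
but exercised only synthetically), cell-type mixtures in the phagocytosis
co-culture, and count-matrix batch effects. Passing tests therefore
demonstrate correctness of the measurement machinery against known
geometry and statistics, not robustness to every failure mode of real
microscopy.

## Problem sizes

The validation suite and the acceptance script use 100 single-plaque
fields for coverage recovery (5 coverage levels × 20 seeds), 70 plaques
for the cohort-scale effect directions, 8 fields for oracle equivalence,
100-cell phagocytosis fields, and 5000-feature null matrices for test
calibration — sizes chosen so each property is measured with comfortable
statistical margin while the whole suite runs in well under a minute per
stage on one CPU.

## Determinism

Every generator draws from `numpy.random.default_rng(seed)` carried in its
config; identical configs give bit-identical arrays and tables. Analysis
stages contain no randomness. CLI runs write the resolved config and stamp
every table with the version and config hash, and re-running a stage
reproduces its tables byte-for-byte.
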