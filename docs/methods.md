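# Methods

`nucleimap` re-creates, as tested software on synthetic data, the
computational chain used to build a cytoarchitectonic atlas of the human
deep cerebellar nuclei and to characterise their function: histological
morphometry, shrinkage-corrected volumetry with permutation statistics,
multi-subject probabilistic atlas construction, seed-based activation
likelihood estimation (ALE) meta-analysis, and binomial functional
decoding.  This note records the models, the parameters that matter, and
the design choices made where the methodology was genuinely open.

## Cell density: the Grey Level Index

The GLI of a region on a cell-body-stained section is the area fraction of
segmented cell bodies,

    GLI = (segmented cell area) / (structure area),

a dimensionless quotient in [0, 1] stored as a fraction and displayed on
the conventional ×100 (percent) scale.  Segmentation defaults to Otsu's
automatic threshold computed inside the region mask; a fixed-threshold
override exists for calibrated material.  Polarity is explicit
(`cells_are_dark`): internally the light-cells case negates the image, which
makes inverted-contrast inputs reproduce the dark-cells mask exactly because
Otsu's criterion is shift- and mirror-equivariant.

The synthetic micrograph generator plants non-overlapping disks ("cells")
until a target area fraction is reached, trimming the final disk toward the
remaining deficit, so the realised fraction sits within a fraction of one
minimal disk (≲ 3·10⁻⁵ at the defaults) of the target.  Defaults: 1024²
pixels at 1 µm/pixel, disk radii 3–8 µm, dark cells (mean 80) on a light
background (mean 200) with Gaussian noise (SD 10) — a sharp-edged,
noise-only model without optical blur.  Real micrographs add point-spread
blur, uneven staining and touching cells; passing the recovery tests
therefore demonstrates correctness of the estimator and of the
segmentation plumbing, not robustness to real histological artifacts.

Dorsal/ventral density comparisons use an exact Wilcoxon signed-rank test
on per-brain mean values (two-sided by default; the exact null is enumerated
rather than normal-approximated because cohorts are of order n = 10), with
Bonferroni correction across the comparisons made.  The paired-density
generator draws, per brain, a shared baseline (SD 0.55 on the percent
scale) plus part-specific noise (SD 0.35): marginal SDs are then ≈ 0.65,
matching the observed spread, while paired differences only carry the
part-specific noise — the within-brain design that gives a ten-brain cohort
its power.  All-zero paired differences are reported as "no information",
never as a fabricated p-value.

## Folding Index

For a simple closed contour, FI = (contour perimeter)/(convex-hull
perimeter) ≥ 1, with equality exactly for convex shapes; the ratio is
scale-invariant.  Contours are validated (simple, closed, ≥ 3 vertices)
and hulls computed on the vertex set.  The synthetic fixture is a
star-shaped polygon r(θ) = R + (A/2)(1 + cos kθ) + jitter, which is simple
by construction; k (teeth) and A (amplitude) control the folding.  The
pipeline defaults (k = 14, A = 4.2 for the microgyric part; k = 7, A = 16
for the macrogyric part, at R = 10) were chosen so both parts land near the
folding magnitude observed for the dentate nucleus (FI ≈ 1.7), mirroring
the empirical finding that the two parts do not differ in FI despite
different fold geometry.

## Volumetry

Volumes are Cavalieri estimates over a 1-in-k systematic section sample:

    V_raw = Σᵢ areaᵢ × (section thickness × sampling interval),

with areas from pixel counts.  Defaults follow standard histological
practice for this material: 20 µm sections, every 60th delineated
(1.2 mm spacing); the spacing is an explicit parameter because delineation
and scanning intervals can differ.  A per-brain multiplicative shrinkage
factor (an input, of order 1.5–2.5; its estimation is out of scope)
rescales to fresh-tissue volume, and volumes are normalised to each brain's
total volume (also an input) before testing.  On ellipsoid fixtures the
estimator is within 2% of the analytic volume at 0.3 mm spacing for
6-mm-scale shapes.

Group effects use permutation tests on the difference of means: sex
permutes group labels over bilateral normalised fractions; hemisphere
sign-flips within-brain right−left differences (paired design); the
sex-by-hemisphere interaction permutes sex labels over those differences.
Which permutation scheme the original analysis used for the hemisphere
contrast is not documented; the paired sign-flip is this package's choice
and is flagged as such.  Exhaustive enumeration replaces sampling whenever
the number of distinct relabelings is ≤ 20,000 (seed-free); sampled mode
requires an explicit seed and uses the add-one estimator
(1 + #{|t*| ≥ |t|})/(1 + n).  Benjamini–Hochberg FDR is controlled across
the full family of contrasts.

The cohort-table aggregation rule — hemisphere means with SDs, sex means of
per-brain left/right averages, bilateral = right mean + left mean, displayed
at 0.1 mm³ — reproduces published bilateral volumes exactly wherever the
printed rows are additively consistent; two rows of the published table
carry a 0.1 mm³ rounding inconsistency and are excluded from the exactness
check.

## Probabilistic atlas and maximum probability maps

Per nucleus, the probability map on the 1 mm isotropic reference grid is
the voxelwise fraction of subjects whose (already spatially normalised)
binary label contains the voxel; values are exact multiples of 1/N.
Spatial normalisation itself is out of scope: inputs are assumed on the
reference grid, and the synthetic generator produces them there, applying
one translation-plus-scale perturbation per subject (defaults: translation
SD 1.0 mm, scale SD 0.03 — chosen once to represent low-to-moderate
residual misregistration, since no quantitative inter-subject variability
is published for these nuclei).  Applying one transform per subject keeps
within-subject nucleus masks disjoint, as in real delineations.  Grids
must match exactly; there is no silent resampling.

The MPM assigns each voxel to the arg-max nucleus wherever the maximum
probability is nonzero and ≥ `min_prob` (default 0; e.g. 0.4 for
conservative seeds).  Exact ties resolve by higher mean probability over
the 26-voxel neighbourhood, then lower nucleus index; every tie decision is
logged in a provenance list.  Labelled voxels partition the supra-threshold
support exactly.

## Meta-analytic connectivity modeling

Seed filtering retains experiments with ≥ 1 focus whose nearest voxel (via
the seed grid's affine) lies in the seed mask.  Each experiment's modelled
activation (MA) map places an isotropic 3-D Gaussian at each focus,
normalised to peak 1, and takes the voxelwise **maximum** over the
experiment's foci (no within-experiment self-reinforcement).  The kernel
FWHM follows the standard two-component convention (per the Eickhoff et
al. 2009 formulation, not values from the atlas study itself): Euclidean
uncertainties of 11.6 mm (between-subject, shrinking as 1/√n) and 5.7 mm
(between-template), each converted to a per-axis Gaussian SD via
E|d| = 2·√(2/π)·σ and combined in quadrature — giving FWHM ≈ 10 mm at
n = 10 and monotone non-increasing in n.  Kernels are truncated at 3.5 σ.
Experiments combine by the probabilistic union

    ALE(v) = 1 − Πₑ (1 − MAₑ(v)),

so ALE dominates every single MA map and never decreases when an
experiment is added.

Significance uses a Monte-Carlo null: each iteration redistributes every
experiment's foci uniformly over the background-mask volume (a uniformly
chosen mask voxel plus a uniform sub-voxel offset — the same continuous law
the synthetic generator uses for background foci), preserving focus counts
and kernel widths.  Two complementary summaries come from the same null
maps:

* **voxel p** — each voxel's own empirical null, with add-one smoothing
  (1 + #{nullᵢ(v) ≥ ALE(v)})/(1 + n_null).  This per-voxel form is exactly
  calibrated by exchangeability; a histogram pooled across voxels would
  bias boundary voxels, which see systematically less kernel mass.
* **cluster-forming threshold** — the pooled (voxels × iterations)
  1 − p quantile of null ALE values (default p = 0.001 uncorrected, the
  field convention).  Pooling is used here because a per-voxel null with a
  few hundred iterations cannot resolve the 10⁻³ tail.

Clusters form at the threshold under 26-connectivity; a cluster's
family-wise-error p is the add-one fraction of null iterations whose
largest supra-threshold cluster is at least as large, reported against
FWE p < 0.05.  Cluster peaks on saturated-ALE plateaus resolve to the tied
voxel nearest the cluster centroid.  Note that seed-filtered experiment
sets converge inside the seed *by construction* (selection, not error);
calibration statements about false positives apply to exchangeable
(unselected) experiment sets.

Seed-vs-seed contrasts compute the voxelwise ALE difference and permute
experiment membership between the two sets (sizes preserved), symmetrising
the null with ±d* so the two one-sided maps swap exactly when the inputs
are swapped; voxels significant at p < 0.05 are restricted, by default, to
the union of the two main-effect significant masks.

The default synthetic background mask is a brain-shaped ellipsoid of radii
(40, 48, 36) mm on a 2 mm grid — any fixed compact mask supports null
calibration; what it does not emulate is the grey-matter prior an archival
coordinate database implicitly applies.  Database defaults: 1000
experiments (the lower end of the realistic archive scale; the compute
cost sits in the ALE null, not the database), 1 + Poisson(3) foci and
8–30 subjects per experiment.

## Functional decoding

For each taxonomy label (behavioural domain or paradigm class), the count
k of seed-associated experiments carrying the label among n is tested
against the database base rate k_db/n_db with an exact binomial test,
one-sided toward enrichment by default (the question is "more often than
chance"); FDR is controlled across the labels of one axis.  Labels are not
mutually exclusive — an experiment counts once per label it carries.
Profile contrasts between two seeds use Fisher's exact test on the 2×2
table of per-seed counts, FDR across labels.  The synthetic database
plants enrichments by replacing base rates for seed-hitting experiments
(default: one domain at 3× its base rate).

## Pipeline, sizes and reproducibility

The `run` orchestrator executes simulate → morphometry → volumetry → atlas
→ MACM → decoding from one JSON-serialisable config.  Every stochastic
stage carries an explicit seed (validated before anything runs); a failure
halts downstream stages and leaves a manifest recording the partial state.
The manifest stores the config hash, per-output SHA-256 checksums, stage
durations and library versions; identical configs reproduce identical
checksums.

Default problem sizes — 512² demo micrographs, 10 subjects, 400
experiments, 150 null iterations and 150 contrast permutations — complete
the demo in well under a minute; the verification suite uses 1024²
micrographs, 500–1000-experiment databases and 200 null iterations per
analysis, the sizes at which the calibration and recovery statements are
made.

## Numerical notes and limitations

* ALE values saturate (float 1.0) wherever many kernels coincide; ranking
  and cluster statistics are unaffected, but peak heights inside strongly
  converged clusters are not informative beyond saturation.
* Monte-Carlo p-values are discrete (granularity 1/(1+n_null)) and
  conservatively add-one smoothed; the calibration tests account for both
  (randomised tie-breaking is used only inside the test, never for
  inference).
* MACM requires axis-aligned grids; arbitrary affines are supported for
  I/O and coordinate mapping but not for kernel placement.
* Exhaustive permutation limits (2ⁿ or C(n, k) ≤ 20,000) keep exact mode
  automatic for the cohort sizes this package targets.
* The generators emulate magnitudes (cell-area fractions, nucleus volumes,
  archive scale, planted effects), not anatomy: nuclei are smooth
  parametric shells, micrographs are disk fields, and co-activations are
  single planted targets.  Green tests certify the estimators and their
  calibration under these conditions, not performance on real tissue or
  real archival coordinates.
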