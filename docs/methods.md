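# Methods

This note documents the statistical model, the reconstruction choices made
where the published description is underspecified, the synthetic-data
generator, and the numerical conventions. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Design and condition ordering

The 12 conditions are the cross of three sequence types (stem, inflected,
phrase) with four stem categories ordered by verb dominance (verb_unique,
verb_dominant, noun_dominant, noun_unique). The ordering is fixed —
sequence types major, categories in the order above — so that RDM cell
indices are stable across code, TSV files and figures. Dominance weights
default to the stimulus-set means 1.0 / 0.84 / 0.06 / 0.0 (dimensionless,
verb/(verb+noun) corpus frequency ratio per category) and may be overridden
with any values in [0, 1]. The stimulus manifest (160 stems, 40 per
category, each realised in all three sequence forms → 480 test items,
alongside 240 acoustic-baseline and 240 silence trials) uses placeholder
stem identifiers: the matched word lists themselves are not redistributed.

## Model RDMs: reconstruction choices

The published model matrices exist only as colored figures, so their cell
values are explicit reconstructions:

- **General complexity** — two-class categorical model: dissimilarity 0
  within {inflected ∪ phrase} and within {stem}, 1 between. Stem–stem
  cells default to 0 (the standard "category present" rank test); a switch
  leaves them unconstrained instead.
- **Complexity type** — three-class categorical model, 0 within each
  sequence type, 1 between types, fully constrained.
- **Detectors** — 0 within the target type, 1 between target and
  non-target; non-target–non-target cells are *unconstrained* (excluded
  from every correlation), because a detector should be agnostic to
  structure among conditions it does not select for. A configurable
  variant sets them to 0.5 for users wanting fully constrained models.
- **Dominance-modulated detectors** — within-target dissimilarity
  |w_i − w_j| of the category weights, which groups the verb sets
  {1.0, 0.84} apart from the noun sets {0.06, 0.0}; the published
  description says only that detectors are weighted by relative dominance,
  and the absolute difference is the simplest metric with that grouping
  property. Alternatives (e.g. 1 − w_i·w_j) are noted but not implemented.

Every model is symmetric, has an unconstrained diagonal, values in [0, 1],
and at least two distinct constrained values (rank and linear correlation
are undefined against a constant).

## First-order RDMs

Dissimilarity is the correlation distance 1 − Pearson *r* across voxels,
so cells lie in [0, 2] with an exactly zero diagonal. No voxel
normalisation is applied: Pearson *r* is invariant to positive affine
transforms of each condition's pattern, which the test suite asserts.
Zero-variance condition patterns raise a named error (identifying the
condition, subject and region) instead of emitting NaN; the pipeline drops
the offending subject × region pair with a logged reason, because silent
NaNs would corrupt subject-averaged RDMs. Averaging is cell-wise across
subjects, and model fitting operates on the averaged RDM (per-subject
statistics are additionally retained for the model-comparison test).

## Second-order inference

**Statistic.** The model–data correspondence is the correlation between
the data RDM and the model RDM over the model's constrained
upper-triangle cells. The default is **Pearson**, the second-order
analogue of the first-order correlation distance. The choice matters:
categorical models are heavily tied, and the Spearman correlation between
a two-valued model vector and continuous data is bounded by the tied group
sizes rather than by fit quality (0.632 for a 6-vs-32 cell split) — so
ranking models by Spearman systematically mistakes a fully constrained
rival for the true generating geometry, an error that subject-level noise
does not wash out. With Pearson, data generated exactly from a detector
geometry correlates 1 with its own model, and best-model identification on
the default study is exact in repeated simulation. Spearman and Kendall
τ-a (tied pairs counting zero, denominator n(n−1)/2) are provided for
rank-based analyses and are verified against brute-force oracles.

**Permutation test.** The null distribution is obtained by applying the
same random permutation of condition labels to the rows and columns of the
data RDM and recomputing the statistic, n_perm times (default 10,000; the
analysis scripts use 1,000). The p-value is the one-sided add-one estimator
(1 + #{null ≥ observed − 1e−12}) / (n_perm + 1): strictly positive, valid,
with ties counted in favour of the null. One-sidedness reflects the
directional hypothesis that a model *fits* (positive correspondence).

**Model comparison.** The better-fit test is not described in the source
beyond its results, and is reconstructed as a subject-level sign-flip
permutation: each subject's RDM is correlated with each model on that
model's own constrained cells, and the mean of the per-subject differences
is tested two-sidedly against all 2^S sign flips (exhaustive for S ≤ 12,
Monte-Carlo beyond).

**FDR.** q-values follow the Storey procedure per model family across the
regions tested: π0(λ) = #{p > λ} / (m(1 − λ)) on the grid λ = 0.05, …,
0.90, summarised by its **median** and clamped to [1/m, 1]. The median was
chosen over spline/polynomial smoothers because the families corrected
here are small (m = 22 regions) and smoothers extrapolated at λ → 1 are
unstable at that size, occasionally collapsing π0 and flooding the family
with spurious discoveries. q_i = min over thresholds t ≥ p_i of
π0·m·t / #{p ≤ t}, which equals π0 times the Benjamini–Hochberg adjusted
p-value (asserted against statsmodels in the tests). BH step-up is
available as the alternative `fdr` mode.

## Region handling

World coordinates are MNI millimetres through the NIfTI affine; voxel
indices are 0-based; sphere membership uses voxel centres without
partial-volume weighting (e.g. the frontal-operculum ROI is a 10 mm sphere
at (−36, 20, −3), mirrored to (36, 20, −3)). Temporal gyri are split into
anterior/posterior halves at a world-y boundary; no cut coordinate is
published, so the default is the mask's own median y (making the halves a
partition of every mask), configurable to a fixed coordinate. All images
in a run must share one voxel grid — registration and normalisation are
out of scope, and the synthetic exporter guarantees a shared grid.

## Synthetic data generator

The generator emulates the study at the GLM-beta level: 18 subjects, 22
bilateral regions with voxel counts drawn log-uniformly in [50, 500], the
12-condition design. For a region planted with model M, the condition
similarity S is 1 − dissimilarity on constrained cells, **0.5 on
unconstrained cells** (neutral: halfway between alike and unlike, so that
detectors generate fully defined geometry), 1 on the diagonal; the
condition covariance is Σ = α·S + (1 − α)·I projected to the nearest PSD
matrix by eigenvalue clipping (α default 0.7 — strong planted structure
while keeping Σ well-conditioned). Each voxel's 12-condition response is
√SNR · N(0, Σ) plus independent N(0, 1) noise, so SNR is the planted
signal-to-noise variance ratio (default 5: a clearly recoverable effect).
"noise" regions are pure N(0, 1). The default scenario plants the
inflection detector in L BA44, L pSTG and L aITG and the phrase detector
in bilateral aSTG, bilateral aMTG and L pMTG, mirroring the reported
topography, with the remaining 14 regions noise.

What the generator does **not** emulate: spatial noise correlation
(voxels are independent; smoothness is an extension point), hemodynamic
time-series structure, between-subject anatomical variability, or
non-Gaussian artefacts. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery on its stated
model, not robustness to the full noise structure of real fMRI.

**Identifiability.** Some model pairs are nested: the stem detector's
constrained cells carry exactly the general-complexity model's predictions
on those cells, so data planted with either geometry is perfectly fit by
both and "the planted model is the unique best fit" is not a well-posed
requirement for nested pairs under any statistic. The recovery guarantees
are therefore stated (and tested) for the non-nested detector geometries
the default scenario plants.

**Problem sizes.** The validation studies use sizes chosen to estimate
each rate precisely at desk scale: 600–1,000 null simulations at
n_perm = 500 for type-I error, the full 18 × 22 study at n_perm = 1,000
for recovery, 100 runs of 8 subjects × 100 voxels for model
discrimination, and 200 repetitions of m = 1,000 p-values for FDR
calibration.

## Geometry embedding

Region–model distances are 1 − second-order correlation; region–region
cells correlate full RDM upper triangles; model–model cells correlate
jointly constrained cells, falling back — when two models are constant on
their joint cells, as any two detectors are — to the union of constrained
cells with the neutral value 0.5 imputed on each model's unconstrained
cells (the same neutral similarity the generator uses). Classical MDS
double-centres the squared distances and eigendecomposes; axes are ordered
by eigenvalue, negative eigenvalues (non-Euclidean input) contribute zero
coordinates, and each axis's sign is fixed by requiring the
lexicographically smallest entity with a nonzero coordinate to be
positive — keyed on labels rather than input position so the embedding is
invariant to entity order. Because 2-D projection distorts a 25-entity
correlation geometry, per-pair residuals (embedded minus true distance)
are written alongside the coordinates rather than encoding distances in
line area as the original figure does.

## Determinism

Every stochastic component takes a seed or NumPy Generator; the pipeline
derives independent child streams from the run seed via `SeedSequence`,
iterates regions and subjects in fixed sorted order, and writes TSVs with
fixed float formatting — same config and seed give byte-identical outputs.
The run manifest records the config hash, seeds, package versions, dropped
data and the reconstruction decisions in force.

## Known limitations

- The model cell values (D-choices above) are reconstructions of figures,
  not published matrices.
- Storey's π0 is noisy at m = 22; with an unlucky batch of null p-values a
  family can over-discover (the acceptance study quantifies specificity).
- No noise-ceiling estimation, bootstrap CIs or crossvalidated distances
  (crossnobis/LDC) — the pipeline matches the original plain
  correlation-distance analysis.
- The CLI `fit`/`mds` stages operate on averaged-RDM TSVs and therefore
  cannot run subject-level model comparisons; use `run` (or the library)
  for the full analysis.
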