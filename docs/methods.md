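# Methods

## Enhancement maps

A DCE study is a stack of T1-weighted volumes with acquisition times
relative to contrast injection; at least one phase precedes injection.
Nominal analysis phases (1 min, 2.5 min, 7 min) are mapped to acquired
phases by nearest timestamp, because fast DCE sequences sample every
8–15 s and never land exactly on a nominal time; a request at or before
t = 0 returns the last pre-contrast phase, and a nominal time farther than
half the maximum inter-phase gap from every acquired phase is an error
rather than a silent approximation.

Per voxel, with S_pre, S_early, S_late the phase intensities:

- PE = (S_early − S_pre)/S_pre × 100.  Undefined (flagged invalid, never
  raised) where S_pre ≤ 0, which is routine in background air.
- SER = (S_early − S_pre)/(S_late − S_pre).  Three regimes:
  - non-enhancing voxels (S_early ≤ S_pre) are invalid for SER — PE is
    still computed and may be ≤ 0, and such voxels can never pass a
    strict PE threshold anyway;
  - complete wash-out (denominator within 10⁻⁶ of the study's dynamic
    range of zero) gets SER = 10, far above the threshold-grid maximum of
    2.0, and stays valid: a voxel whose late signal has fully returned to
    baseline is precisely the fast-washout tissue SER exists to flag;
  - otherwise the ratio is taken directly.

Both maps are ratios of intensities, hence invariant under any global
intensity rescaling; intensities are treated as arbitrary-unit magnitudes
and no B1/T1 or motion correction is attempted.  A combined validity flag
(PE-valid AND SER-valid) gates every downstream voxel count.

## Volumetrics

All volumes are reported in cm³; spacing is carried in mm and converted
once at the ETV/FTV boundary.  The voxel volume uses the slice
*increment* (the per-slice table advance), not the slice thickness:
overlapping-slice protocols advance by half the thickness, and using
thickness would double every volume.

FTV counts mask-true, valid voxels with PE and SER *strictly* above the
threshold pair.  Strictness matters at the grid origin: with a non-strict
rule, threshold (0, 0) would admit voxels with zero enhancement.  The
full-grid computation (`ftv_grid`) forms one boolean comparison per
threshold axis and takes a matrix product over candidate voxels, which is
exactly the per-pair count — the test suite asserts pairwise equality
with the scalar `ftv` on every grid cell.

Caliper diameters (for LD and ellipsoid TV) are accepted as inputs; the
package does not automate caliper measurement on clinical images.  For
synthetic data, where tumors are axis-aligned ellipsoids, the bounding-box
helper `mask_to_diameters` converts mask extents × spacing into an exact
diameter triplet.

### Mask refinement

Manual contours are refined by histogram thresholding: mask voxels whose
subtraction-image intensity exceeds the Otsu threshold of the within-mask
intensity distribution are retained.  Two deliberate choices:

- The Otsu split is computed *exactly* over the observed values
  (cumulative-sum maximization of between-class variance across all
  realizable strict-threshold partitions, smallest maximizer on ties)
  rather than over a binned histogram.  On continuous intensities a
  256-bin histogram can place the cut a few samples away from the true
  between-class-variance maximum; the exact form makes the operation
  reproducible and testable against exhaustive search.
- Refinement only applies when the within-mask distribution is actually
  bimodal: the best split must explain at least 75% of the total variance
  (a single Gaussian mode yields ≈ 64% at its best split; two separated
  modes approach 100%).  Below the guard the mask is returned unchanged,
  which makes refinement idempotent — a second pass sees a unimodal
  enhancing region and leaves it alone instead of whittling it down.

Whether FTV should count voxels of the manual or the refined mask is
ambiguous in practice; the pipeline exposes both and defaults to refined
(`AnalysisConfig.use_refined_mask`).

## Threshold grid search

The grid is PE ∈ {0, 5, …, 220}% (45 values) × SER ∈ {0, 0.05, …, 2.00}
(41 values, stored as integer hundredths so every value is exact).  For a
cohort, the AUC of the per-patient FTV values is computed at every pair
(rank-based, ties counted ½, vectorized over the 1845 cells) and the
maximizing pair is selected.  Ties at the maximum are broken toward the
minimal pair in lexicographic (PE, SER) order — this coincides with the
componentwise minimum whenever one exists — and the full tie set is
retained on the fitted surface and in the run log.

Orientation: the positive class is residual disease (non-pCR) throughout,
with higher values more positive.  That holds for raw volumes (residual
disease keeps more enhancing tissue) and for relative changes
(non-responders shrink less, so their percent changes are higher, i.e.
less negative); AUCs therefore land on the ≥ 0.5 side by construction
rather than by taking max(AUC, 1 − AUC).

Degenerate cells are defined, not dropped: where every patient's FTV is
zero (thresholds above all voxels) all scores tie and the AUC is 0.5.
For relative-change surfaces, a patient whose baseline FTV is zero *at
that cell* has no defined change and is dropped from that cell only, with
per-cell counts recorded; a cell left with fewer than 2 patients in
either class carries no usable discrimination signal and takes the tie
value 0.5, so near-empty cells cannot win the argmax with spuriously
perfect one-patient "AUCs".

The selection is in-sample by design — the analysis this package
implements optimizes thresholds on the cohort being reported — and the
optimism that entails is quantified only through the synthetic-recovery
tests (a flat-truth cohort's baseline surface stays near 0.5).

## Statistics

- Mann–Whitney U (U counts pairs a > b plus half-ties): exact enumeration
  when the combined sample is ≤ 20 with no ties, else the tie-corrected
  normal approximation with continuity correction.  The cut at 20 keeps
  exactness where enumeration is cheap and reproducibility elsewhere.
- AUC: U/(n₁n₀); its 95% CI and the test against AUC = 0.5 use DeLong's
  variance estimate (deterministic, the default in common statistical
  software).  Perfect separation gives zero estimated variance: the CI
  collapses to the point estimate, a warning is emitted, and the p-value
  is floored at the smallest positive float so it stays in (0, 1].
- Best cutoff: Youden's J over observed scores, smallest maximizer on
  ties, classifying positive at score ≥ cutoff.
- Fisher's exact test for r × c tables (Freeman–Halton): depth-first
  enumeration of all tables with the observed margins in log-factorial
  space, summing the probability of every table no more probable than the
  observed one (relative tolerance 10⁻⁷ guards against float-equality
  artifacts).  A table budget (default 2 × 10⁶) protects against
  combinatorial blow-up; past it, a Monte-Carlo mode samples tables with
  Patefield's algorithm.  The 2 × 2 case reduces to the classical
  hypergeometric test, and the r × c values are validated against R's
  `fisher.test` in the test suite.
- α = 0.05 throughout; no multiple-testing correction is applied, by
  design — the report mirrors a per-measurement descriptive table, not a
  confirmatory family of hypotheses.

## Synthetic cohort generator

The generator emulates the structure the analysis needs, with exact
ground truth, not breast anatomy:

- Geometry: one axis-aligned ellipsoidal tumor per patient at the grid
  center, baseline mean radius ~ Normal(14 mm, 4 mm) (floored at 2 mm)
  with per-axis anisotropy U(0.85, 1.15); default grid 48 × 64 × 64
  voxels at (1.0, 1.0, 1.5) mm spacing.  A tumor that would leave the
  grid is a configuration error.
- Kinetics: tumor voxels follow S(t) = S0·(1 + A·w(t)) with S0 = 100,
  wash-in amplitude A ~ U(0.5, 1.5) and wash-out fraction W ~ U(0.1, 0.7)
  per patient (both arms share these ranges — response is a volume
  effect, not a kinetics effect); w ramps linearly from 0 at injection to
  1 at the first early phase and decays linearly to 1 − W at the late
  phase.  Zero-noise closed forms: PE(1 min) = 100·A,
  SER(1 min) = 1/(1 − W) (capped at W = 1), which the tests check to
  machine precision.
- Phases: (−10, 60, 150, 420) s, one pre-contrast.
- Response: labels are a binomial draw at pCR rate 0.49.  Enhancing
  volume scales by arm-specific factors — pCR 0.35 (C2) / 0.02 (C4),
  non-pCR 0.75 / 0.45 — with per-patient lognormal jitter (σ = 0.25 on
  the log factor) modeling response heterogeneity, so arms overlap
  realistically instead of separating degenerately.  Zero volume at C4 is
  a valid complete response (empty mask, FTV 0, %C4/BL = −100).
- Noise: additive Gaussian (σ = 5 on S0 = 100) on every voxel of every
  phase.  Gaussian rather than Rician, deliberately: subtraction-image
  tumor SNR is high, and the additive model keeps the zero-noise limit
  exactly closed-form.
- Determinism: one seed drives the label draw and per-patient spawned
  streams; identical (config, seed) serialize byte-identically (gzip
  members are written with zeroed mtime).

What passing synthetic tests does **not** show: performance under Rician
noise floors, motion, field inhomogeneity, irregular tumor shapes,
multi-focal disease, or reader variability in contouring.  The generator
validates the computational pipeline, not clinical performance.

## Problem sizes in the checks

The test suite exercises cohorts of 4–100 patients on 16³–32³-scale
grids with correspondingly smaller tumors (radius 6–7 mm) — sizes chosen
so the full suite runs in well under a minute of compute per module while
every code path (including 100-patient grid searches) is covered.  The
acceptance script runs the default conditions: 100 patients on the
48 × 64 × 64 grid, about a minute end to end.  Effect-size recovery is
asserted across three seeds: C4 FTV AUC > 0.90 in each, baseline FTV AUC
within (0.35, 0.65) in at least two of three.

## Known limitations

- Caliper diameters for LD/TV come from mask bounding boxes; on real
  (non-ellipsoidal) tumors these differ from radiologist calipers.
- The Freeman–Halton enumeration is exponential in table size; large
  sparse tables need the Monte-Carlo mode.
- The in-sample threshold optimization is reported as-is; no
  cross-validated generalization estimate is produced.
- DeLong's normal-theory p-value is anti-conservative at extreme AUCs
  with small samples; the degenerate-variance flag marks the fully
  separated case explicitly.
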