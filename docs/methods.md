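# Methods

This note documents the models, numerical choices and limitations of
`corticompare`: what the synthetic world simulates, how the registration
and correspondence are computed, and what the statistical cascade assumes.

## Synthetic two-pipeline cohorts

The generator's defaults encode the study design the statistics are built
for: four diagnostic groups — controls (CTR, n=69), stable MCI (sMCI,
n=37), progressive MCI (pMCI, n=27) and AD (n=52) — observed at baseline,
month 12 and month 24 by two pipelines that see the same cortex.

**Ground truth.**  Per-ROI true thickness on the source-pipeline (CV)
scale.  A subject in group G has baseline thickness
`2.5 mm + offset(roi, G) + between-subject noise`, where the group offsets
are the published baseline CTR-vs-group contrast means and the
between-subject SD is the published CTR-vs-AD sigma of that ROI
(interpreted as the pooled between-subject SD — the tables print a single
sigma per contrast, so this is an assumption).  The 2.5 mm healthy
baseline is a package default: the tables report contrasts, not per-ROI
absolute baselines.  Two-year changes are drawn around the published
per-group longitudinal Delta-means with the published change SDs; month 12
sits halfway.  Between-subject and change noise split 0.6/0.8 into a
shared subject factor and an ROI-local residual, so ROIs correlate within
subject (needed for realistic dependent-correlation and paired-AUC
structure).  With these defaults the mean two-year thinning magnitude is
ordered CTR ≤ sMCI ≤ pMCI ≤ AD in the temporal (AD-signature) ROIs.

**Covariates.**  MMSE is sampled from the published group means/SDs
(baseline and two-year change), truncated to [0, 30] and integer-rounded.
Hippocampal volume (cm³) is generated with a configurable correlation to
the subject's mean temporal-lobe thickness — default r = 0.4 in pMCI and
AD, 0.25 in sMCI, 0.1 in CTR, reflecting the weak-to-medium range reported
for real cohorts.

**Pipeline observation model.**  A pipeline profile renders vertex
thickness as `scale × truth + offset + spatially smooth noise` on its own
icosphere template.  Defaults: the CV profile is the truth scale
(scale 1.0, ICO6); the FS profile reads 30% thinner (scale 0.70, ICO7)
and shrinks its follow-up noise by 0.6, emulating a longitudinal
processing stream that reuses within-subject information.  Noise is
low-frequency value noise: i.i.d. normals on a 42-node coarse sphere,
Gaussian-kernel interpolated to the template and rescaled to the target
SD (~tens of mm smoothness on a brain-sized sphere) — smoothness is a
modelling choice; without it cluster-like significance patterns cannot
emerge.  Surfaces get (a) a deterministic per-pipeline smooth radial
morphology bias (default 2 mm amplitude for the FS profile) — the two
algorithms reconstruct systematically different surface shapes, which is
precisely what the registration exists to remove — and (b) a mild
subject-specific smooth radial deformation (1.5 mm amplitude).

**What the synthetic world does not contain:** volumetric anatomy (the
28-region registry is realized as a mirrored spherical Voronoi
parcellation, not a projected atlas), folding geometry, scanner/site
effects, conversion-time modelling for pMCI, and ApoE genetics.  Passing
tests therefore demonstrate that the framework recovers known injected
structure under its own assumptions, not that either real pipeline is
accurate on real MRI.

## Hybrid-template registration

Hemispheres are disjoint closed icospheres (no medial-wall cut); all units
are millimetres.  Per-pipeline average surfaces (vertex-wise means over
shared connectivity, 10+10+10 subjects) are registered source → target:

1. **Edge map.**  The target surface is voxelized on an isotropic grid
   (desk default 1–3 mm) and f = exp(−d/σ) with σ = 2× spacing.  By
   default d is the *exact* point-to-surface distance at every voxel
   center (vectorized closest-point-on-triangle over kd-tree candidate
   faces), and the signed variant φ (negative inside, sign from the
   owning face's outward normal) is kept alongside f.
2. **GVF.**  Explicit generalized-diffusion sweeps
   v ← v + dt·[μ∇²v − |∇f|²(v−∇f)], μ = 0.1 by default, dt at 0.9× the
   3D diffusion stability bound h²/(6μ) and additionally capped by the
   reaction term's stiffness (dt ≤ 1.8/(12μ/h² + max|∇f|²)); the
   discrete energy (forward-difference smoothness term, so it is the
   exact Lyapunov function of the update) is recorded per sweep and the
   run aborts if it ever increases.  Sweeps run to a 1e-4 relative energy
   change by default.
3. **FFD.**  15 update cycles (the iteration count is interpreted as FFD
   cycles with GVF precomputed to convergence).  Each cycle samples the
   field at the current vertices for the step *direction* and the edge
   map's distance estimate for the step *magnitude*; within one voxel of
   the surface, where the discrete field straddles the edge ridge and its
   direction degrades, the update switches to the signed-distance Newton
   step −φ∇φ sampled from the same volume — this is what gives sub-voxel
   convergence.  Control-point increments are fitted by sparse regularized
   least squares with the penalty λ[(1−p)·first-difference +
   p·second-difference] (λ = 1e-2, p = 0.5; "percentage thin plate" is
   realized as this convex blend), solved per component with a factorized
   normal-equations solve.  Out-of-domain points clamp with a warning;
   connectivity never changes and the deformed mesh is topology-checked.

**Registration quality** is reported as the *directed* mean
source-vertex-to-target-surface distance: the symmetric variant is floored
by the tessellation mismatch between the two resolutions (a coarse
polyhedron inscribed in the same smooth surface as a fine one cannot get
closer than its own facet sag), which registration neither causes nor can
remove.  The ground-truth recovery harness (random smooth invertible FFD
warp of an ICO4 sphere, amplitude 2.5 mm on a 20 mm sphere, 1 mm grid,
12³ lattice) achieves a median post/pre ratio ≈ 0.12 over 5 seeds.

Desk-scale defaults (ICO4 source / ICO5 target — preserving the 4:1
vertex-count ratio between pipelines — 16³ lattice, 3 mm grid) keep the
full study around a minute on one CPU; the published-scale ICO6/ICO7 and
denser lattices are plain configuration values, with the edge-map grid
guarded at 256³.

## Correspondence

Vertex-to-vertex matching (thickness exists only at vertices),
one-directional source → target, kd-tree accelerated but exactly equal to
brute force: candidate ties found by a k=2 query are resolved to the
lowest target index.  Mutual-nearest filtering is available but off by
default.  Transfer is nearest-vertex (no interpolation).

## Statistical cascade

* Within-group thinning: paired t per vertex; zero-variance vertices get
  p = 1 and a flag rather than being dropped (they occur with noise-free
  synthetic data).  Between groups: Welch's t (the cross-sectional test
  form was an open choice; Welch avoids the equal-variance assumption).
  No surface smoothing is applied before testing.
* FDR: Benjamini–Hochberg step-up at α = 0.01, implemented directly (a
  dozen lines) and tested against exhaustive step-up enumeration.
* Disease effect: ΔFS − ΔCV per vertex; thinning deltas are negative, so
  negative disease effect ⇒ the FS-style pipeline registers more atrophy.
* Tukey–Kramer: studentized-range tail at
  q = |mᵢ−mⱼ| / sqrt(MSW/2·(1/nᵢ+1/nⱼ)) with pooled within-group MSW;
  reduces to classic HSD at equal n.  The same routine runs from raw
  records or from printed summary statistics; recomputing the published
  longitudinal table's flags from its own printed means/sigmas at α = 0.01
  reproduces ~94% of the rounding-stable cells (cells whose flag flips
  within the ±0.005 print-rounding box are enumerated as marginal and set
  aside).
* Hedge's g with J = 1 − 3/(4(n₁+n₂)−9); cross-pipeline comparison by
  z = (g₁−g₂)/√(se₁²+se₂²) treating the two estimates as independent (as
  the z-test formulation implies) even though they share subjects — a
  paired-bootstrap alternative (`paired_bootstrap_g_diff`) is provided and
  is the more defensible choice when the shared-subject correlation is
  large.  The pipeline's longitudinal effect size is the standardized mean
  change (mean/SD of the per-subject two-year change).
* Correlations: Pearson per ROI; Steiger's Z₁* (one variable in common,
  Fisher transforms, covariance evaluated at the backtransformed average
  correlation; invalid correlation triples are rejected).  Kendall τ-b
  with the normal-approximation z and the Greiner relation
  r = sin(πτ/2) — the published phrasing of the tau-to-r conversion is
  ambiguous; Greiner's mapping is the standard reading and is consistent
  under bivariate normality.
* ROC: candidates gated at |g| > 0.8 (cross-sectional) / 0.6
  (longitudinal), ordered by |g| with ties by ROI id; greedy sequential
  forward selection accepts an ROI only if it improves the seeded 5-fold
  cross-validated AUC (the selection protocol is unstated in the source
  analyses; cross-validation is this package's guard against the noted
  over-fitting risk).  Both in-sample and CV AUCs are reported and
  labelled.  AUC is the tie-corrected Mann–Whitney statistic; its SE the
  Hanley–McNeil (1982) formula.  For the correlated-AUC z-test, the
  between-score correlation r is estimated as the average of the two
  within-class score correlations (Pearson by default, Kendall-based
  optionally) — the historical lookup-table step is replaced by this
  direct estimate because the printed table is not reproducible to
  sufficient precision, and an exact DeLong covariance route
  (`use_delong=True`) is provided as the cross-check; under the null all
  four comparison tests (FDR, effect-size z, Steiger, correlated AUC)
  calibrate to their nominal type-I error in the package's Monte-Carlo
  harnesses.
* Logistic scoring is an unpenalized maximum-likelihood fit; on perfect
  separation it falls back to a ridge-penalized fit with a logged note.

## Degenerate inputs and tie-breaks

Empty point sets, single-class labels, all-tied covariates, |r| = 1,
groups with n < 2 and zero pooled SDs raise ValueError rather than
returning NaNs.  CPS ties break to the lowest index; forward-selection
ties resolve by candidate order (|g| then ROI id); CV folds are seeded.

## Problem sizes used by tests and the acceptance script

Statistics run on ICO2 two-hemisphere templates (324 vertices) with the
full 185-subject cohort; registration harnesses use ICO3/ICO4 spheres at
1 mm grids; the end-to-end study runs at the ICO4/ICO5 desk default.
These sizes are the package's default desk scale; every quantity is a
scale-free ratio, rate or effect size, and the resolution-scaling check in
the pipeline tests verifies that ROI-level conclusions survive the
down-scaling.

## Known limitations

* The spherical synthetic world cannot validate anatomical-accuracy
  claims; only the machinery (registration, correspondence, statistics)
  is validated, against injected ground truth.
* The per-pipeline morphology bias and subject deformations are smooth
  radial fields; real surface differences include tangential and
  topological components the FFD never faces here.
* Signed distance uses the nearest face's normal for its sign: adequate
  for the smooth, consistently oriented surfaces generated here, not for
  meshes with flipped or degenerate faces.
* The Hanley–McNeil r estimate and the independence assumption of the
  effect-size z-test are approximations; the DeLong and paired-bootstrap
  alternatives are the stricter routes.
* ICO7's published total vertex count is printed as 327 680 in the source
  table while the table's own formula gives 2·(10·4⁷+2) = 327 684; the
  formula is used.
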