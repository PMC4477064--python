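# Methods

`surfhomog` implements a surface-based analysis of local functional
homogeneity in multi-site resting-state fMRI: per-vertex 2dReHo maps
(Kendall's coefficient of concordance over mesh ring-neighborhoods), a
nuisance-adjusted vertexwise group GLM with a diagnosis × age interaction,
clusterwise permutation inference, leave-one-site-out replication, and
symptom-scale correlations.  Real cortical data are out of scope; a
synthetic-cohort generator with known ground truth exercises every stage.

## The spatial domain

All maps live on a triangulated sphere built by subdividing the icosahedron
`k` times and projecting onto the unit sphere, giving `V = 10·4^k + 2`
vertices (order 5 reproduces the 10,242-vertex-per-hemisphere standard
spherical grid that registered cortical surfaces are resampled to).  Twelve
vertices keep degree 5; all others have degree 6.  Midpoint vertices are
indexed deterministically (faces scanned in order, edges keyed by sorted
endpoint pair), so meshes — and everything downstream — are bit-reproducible.

Neighborhoods are defined by graph distance on the triangulation, not by
Euclidean distance: the closed one-ring neighborhood holds K = 7 series at
interior vertices (6 at the twelve degree-5 vertices), the closed two-ring
K = 19 at vertices whose two-ring avoids degree-5 vertices.  The convention
of counting the center vertex into K follows volumetric ReHo practice; the
open (center-excluded) one-ring count is the familiar "6 neighbors".
Real spherical surfaces can be loaded through the FreeSurfer-geometry and
GIFTI readers; any mesh satisfying the closed-2-manifold invariants works.

## The statistic

For a vertex v with closed neighborhood of K vertices and n timepoints,

    W = 12 · Σ_i (R_i − R̄)² / (K² (n³ − n)),

where R_i is the sum of the K series' midranks at timepoint i and
R̄ = K(n+1)/2.  W ∈ [0, 1]; W = 1 iff all K series share one strict temporal
ordering; E[W] = 1/K under independence (≈ 0.143 for ring 1, ≈ 0.053 for the
interior two-ring — both verified by Monte Carlo in the tests).  Midranks
handle ties; no tie-correction denominator is applied, which keeps W ≤ 1 and
is immaterial for continuous BOLD data.  A fully tied (constant)
neighborhood returns W = 0 with a warning rather than erroring, so whole-map
computation is total.  The map computation is vectorized — rank all series
once, then one sparse indicator-matrix product yields every neighborhood's
rank sums — and is tested for exact agreement with an explicit-loop oracle.

Because W depends on the data only through temporal ranks, ReHo maps are
invariant under any per-vertex strictly increasing transform; this is
asserted bit-wise and underlies several pipeline properties (for example,
invariance to where grand-mean scaling occurs in the chain).

## Time-series conditioning and QC

The implementable surface-level subset of a standard resting-state pipeline,
applied in this order by default (the order is configurable):

1. **Despike** — per vertex, with m the median and s = 1.4826·MAD, values
   beyond m ± c (c = clip_sigma·s, default clip_sigma = 4) are compressed by
   x ↦ m + c·tanh((x−m)/c); values inside the band pass through unchanged.
2. **Grand-mean scaling** of the overall mean intensity to 10,000.
3. **Nuisance regression** per vertex on the Friston-24 motion expansion
   ([m, m_lag, m², m_lag²] of the six rigid-body parameters, lag row zero-
   padded) plus caller-supplied WM/CSF mean columns; the temporal mean is
   preserved.  No tissue segmentation is performed — confound series are
   inputs.
4. **Band-pass** 0.01–0.1 Hz as an ideal discrete-Fourier filter (mean
   removed and restored).  Filtering before detrending mirrors the listed
   pipeline order even though the reverse is more common elsewhere.
5. **Detrend** linear and quadratic terms, mean restored.

Motion QC quantities: maxTran is the largest framewise Euclidean translation
norm (mm); maxRot the largest per-axis absolute rotation (degrees; a
per-axis reading of "maximum degree of rotation" — the rotation-vector norm
would differ only in rare edge cases); meanFD is Power's framewise
displacement, Σ|Δtranslation| + 50 mm·Σ|Δrotation in radians|, averaged over
frames 2..T.  The exclusion filter retains a subject iff maxTran ≤ 2 mm,
maxRot ≤ 2°, meanFD ≤ 0.4 mm and mcBBR < 0.75 (note the strict inequality on
the registration cost); missing metrics exclude with reason `missing-qc`.
mcBBR is always an input scalar — boundary-based registration itself is out
of scope.

## Group statistics

**Stage 1 (nuisance adjustment).**  Per vertex, the subjects × 1 vector of
ReHo values is regressed on mean-centered [global-mean ReHo, meanFD, mcBBR,
vertexwise Jacobian]; the fitted nuisance contribution is subtracted with
the intercept retained, so the grand mean survives.  The Jacobian enters
per vertex (each vertex's fit uses that vertex's Jacobian across subjects);
a global Jacobian summary would be the alternative reading.  The fits are
batched over vertices via normal equations (shared scalar block plus one
per-vertex column), so the stage costs one `numpy.linalg.solve` over a
(V, 5, 5) stack.

Two consequences of the global-mean term worth knowing: (i) any effect that
is spatially uniform — including a uniform site offset — moves every
subject's global mean and is absorbed by the adjustment; site variability is
therefore mapped on *unadjusted* stacks when a global offset is the signal
of interest.  (ii) A focal effect occupying a large fraction of the mesh
leaks into the global mean and is partially removed; at the demo scale this
is why effect-recovery analyses run on the order-3 (642-vertex) grid, where
a ~20-vertex region is ~3 % of the surface, approximating the region/surface
ratio of real cortical clusters.

**Stage 2 (group GLM).**  Per vertex, ordinary least squares of the adjusted
values on intercept + site dummies (reference = first site alphabetically) +
centered age + fIQ + group + group × centered age, with group effect-coded
(+1 patient, −1 control) so the group coefficient is the difference at mean
age.  Sex is not modeled (the emulated sample is male-only); extra
covariates can be appended via config.  t and two-sided p maps are produced
for group, interaction, age and fIQ, a joint F test for the site block, and
signed significance maps −sign(t)·log10(p) (positive where patients exceed
controls; p = 0 is clamped to the smallest positive float with a warning).
The vectorized fit is cross-checked against statsmodels OLS per vertex in
the tests.

Fitting the two stages jointly (nuisances alongside the design) is *not*
algebraically identical to the two-stage procedure: stage 1 estimates
nuisance betas without protecting the design terms, so finite-sample
correlations between nuisances and group transfer signal between stages.
The two agree asymptotically; at 180 subjects on the order-3 grid the
largest vertexwise |Δt| is < 0.1, which is what the equivalence test
asserts.  At 60 subjects deviations up to ~0.4 occur — sampling, not error.

**Cluster inference.**  Supra-threshold vertices (two-sided cluster-defining
p = 0.01), positive and negative separately, are grouped into edge-connected
components.  Cluster-level p values come from within-site permutation of the
group labels: each permutation refits the GLM (the interaction column is
rebuilt from the permuted labels) and records the maximum cluster statistic
anywhere on the mesh, either sign; a cluster's corrected p is
(1 + #{null ≥ observed}) / (n_perm + 1), so it can never undercut
1/(n_perm+1).  When fewer distinct within-site relabelings exist than
requested permutations, the count is reduced and noted in the result.
Random-field-theory correction is not used — no smoothness-estimation recipe
is assumed; permutation is assumption-light and exactly testable.

Two cluster statistics are available: **extent** (vertex count; the default,
matching how clusters are tabulated) and **mass** (Σ(|t| − t_crit) over the
cluster).  On small meshes the extent null is coarsely discrete — at the
40-subject/162-vertex calibration scale the achievable α jumps from ~0.07
(extent 3) to ~0.02 (extent 4) — so extent-based corrected p values are
valid but conservative (measured family-wise error ~0.01 at nominal 0.05
over 250 null cohorts).  The continuous mass statistic restores near-nominal
calibration (~0.04 in the same experiment) and is what the family-wise-error
calibration test asserts against the 0.05 ± 0.03 band; the extent rate is
additionally asserted not to exceed it.  At realistic mesh resolutions and
smoothness the discreteness penalty shrinks.

## Reproducibility and behavior

**LOSOV.**  For each site s, the entire group analysis — nuisance
adjustment (which is sample-dependent and therefore redone), GLM, cluster
definition, permutation correction — is rerun on the cohort minus site s.  A
vertex replicates in fold s if it lies inside a corrected-significant
cluster whose sign matches the full-sample group t map; replication counts
are the per-vertex sums over folds (bounded by the number of sites).  Folds
draw child seeds from one seed sequence, so a LOSOV run is reproducible from
a single seed.  Degenerate folds (fewer than two remaining sites containing
both groups) are skipped and recorded.

**Behavior.**  Within patients only, each significant cluster's mean
adjusted ReHo is Pearson-correlated with symptom subscales (ADOS, ADI and
the Gotham ADOS scores are registered as column-name constants).  A subscale
participates only when strictly more than 40 % of all patients have a
non-missing score; correlations use pairwise-complete records, p values come
from the t transform with n−2 df, and no multiplicity correction is applied
by default (Benjamini–Hochberg sits behind a flag).  Adjusted (stage-1)
values are used for the cluster means, consistent with the group model.

## The synthetic cohort generator

The generator emulates exactly the statistical structure the analysis
assumes, at desk scale.

*Signal model.*  Per subject, a vertices × timepoints field of independent
N(0, 1) innovations receives per-vertex fractional one-ring mean smoothing
(amount a applies ⌊a⌋ full passes plus a blended partial pass) and AR(1)
temporal coloring (stationary variance), then is placed on a BOLD-like scale
(baseline 1000, fluctuation sd 10 — ranks, hence ReHo, are insensitive to
this).  Spatial smoothing is the single control of local homogeneity.

*Calibration.*  Kendall's W has no closed-form inverse in the smoothing
amount, so a Monte-Carlo curve (whole-mesh mean ring-1 ReHo at a grid of
amounts, 3 replicates each, monotonized and cached per design) is inverted
by linear interpolation.  Every homogeneity target — baseline (default
amount 2 ≈ ReHo 0.67), per-site offsets, the patient effect region
(`effect_size_delta`, in ReHo units), and the age-drift region with
group-specific slopes (age centered mid-range) — is painted as a per-vertex
smoothing-amount map.  Elevated targets extend one ring beyond the nominal
region: ReHo is a neighborhood property, and without the halo the region
boundary would be strongly attenuated (the halo is why recovered clusters
run slightly larger than the seeded region).

*Per-patient trait.*  Patients additionally receive a stable, mean-zero
regional homogeneity offset (sd `effect_trait_sd`, default 0.03 ReHo) in the
effect region.  This is the severity-like subject-level variation that
symptom correlations presuppose: without it, between-patient differences in
region-mean ReHo are pure measurement noise, which preprocessing
re-randomizes and global-mean adjustment strips, leaving nothing for a
symptom score to track downstream.

*Phenotypes and confounds.*  Ages are uniform on the design range (default
8–30 y); fIQ is N(108, 15) truncated to ±2 sd (the 78–138 window); the
cohort is all-male.  Motion traces are mean-reverting (AR 0.95) rigid-body
walks with occasional single-frame spikes, with per-subject step sds and
spike scales drawn so the four QC metrics straddle their thresholds (~10 %
of subjects excluded, each criterion exercised); the stored QC scalars are
computed from the stored traces by the package's own metric definitions.
mcBBR is drawn N(0.5, 0.13) clipped to [0.02, 1.2].  Two AR-colored WM/CSF-
like confound series are weakly mixed into the signal (relative sd 0.05,
scaled by the local field sd so contamination is uniform across smoothing
levels) and emitted for the regression step.  Jacobian maps are smooth
fields around 1.  ADOS-like subscores are built by linearly mixing the
sample-standardized region-mean ReHo (computed from the generated data) with
orthogonalized noise so the pre-rounding sample correlation equals
`ados_correlation_rho` exactly, then shifting/rounding to plausible
non-negative integers; controls' scores are missing by construction.

*Default study conditions.*  4 sites × 5 subjects per site per group
(40 subjects), 120 timepoints at TR = 2 s, AR(1) φ = 0.3, base smoothing 2.
These are the conditions of the null-calibration experiments; effect-
recovery analyses seed a ring-2 region (19 vertices) with ΔReHo = +0.15 and
age slopes ±0.008 ReHo/yr on the order-3 grid.  Everything derives from one
integer seed via spawned seed sequences; identical seeds give bit-identical
cohorts.

*What the generator does not emulate.*  Hemodynamics, scanner drifts and
artifacts, real cortical geometry and folding, spatially structured site
effects (site enters as a uniform homogeneity offset), subject-level
differences in temporal autocorrelation, and volume-space phenomena
(slice timing, realignment, projection).  Passing tests therefore certify
the statistical machinery — rank concordance, adjustment, GLM inference,
permutation calibration, replication counting — not robustness to real-data
artifacts.

## Numerical choices and degenerate inputs

Constant time series despike/scale as no-ops or errors as documented;
nuisance columns with (numerically) zero variance are skipped with a
warning; rank-deficient designs raise errors naming the collinear columns;
all-tied neighborhoods yield W = 0 with a warning; permutation p values
include the observed statistic in the null; cluster peak = largest |signed
log p|; the despike band is discontinuous at its edge by construction (the
tanh map applies only beyond the band).  Sparse adjacency, edge lists and
neighbor tables are built once per mesh; the permutation inner loop uses
union-find over supra-threshold edges only.

## Problem sizes

The shipped analyses and tests use order-2/3 grids (162 / 642 vertices),
40–200 subjects, 120 timepoints, and 100–500 permutations; calibration
experiments use 100 simulated null cohorts.  These sizes were chosen so the
whole suite exercises every stage end-to-end in well under an hour on one
core while keeping Monte-Carlo error small relative to the asserted
tolerances; all scale linearly in vertices × timepoints, and the order-5
grid (10,242 vertices) builds and maps in seconds.

## Known limitations

- Extent-based corrected p values are conservative on coarse meshes (see
  above); use the mass statistic when calibration matters at small V.
- The two-stage adjustment is only asymptotically equivalent to the joint
  model; with < ~100 subjects, vertexwise t values can differ noticeably
  from a joint fit.
- Site effects are modeled as covariates, not harmonized; uniform site
  offsets are indistinguishable from global-mean variation after adjustment.
- The medial wall is not masked: the global mean runs over all vertices
  (an optional mask argument exists).
- Behavioral correlations at small n are attenuated by preprocessing and
  adjustment; the generator's ρ is defined at generation time, upstream of
  those steps.
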