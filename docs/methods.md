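# Methods

## Model

Each subject's masked BOLD run is a time × voxel matrix
`X = TC · M + E`: `M` holds spatially (near-)independent component maps
shared across subjects, `TC` the per-subject component timecourses, `E`
Gaussian noise. Group ICA estimates `M` from all subjects jointly; dual
regression projects the group estimate back into each subject.

**Two-step PCA.** Each run is temporally demeaned per voxel and spatially
demeaned per volume, then reduced along time to C₁ = ⌈1.5·C⌉ principal
components (a GIFT-like retention; only the final order C is canonical).
The reduced matrices are concatenated across subjects and reduced again
to C components with whitening. Per-voxel *variance* normalization is
deliberately not applied in this path: dividing each voxel's timecourse
by its SD rescales the columns of `M` voxel-wise and distorts the mixing
model (we observed recovery dropping from |r| ≈ 0.99 to ≈ 0.85 with it).
Variance normalization is used only inside the MDL order criterion, where
scale-free eigenspectra are wanted.

**Order selection.** The MDL criterion operates on the eigenvalues of the
temporal covariance of the standardized data, with voxels as the i.i.d.
samples. Because per-voxel demeaning always removes one temporal degree
of freedom, the smallest eigenvalue is structurally zero; the criterion
therefore drops it, and a rank below T − 1 short-circuits to the exact
rank. MDL is consistent only when voxels vastly outnumber time points
(the regime of real whole-brain data, V ≳ 10⁴); at desk-scale grids
(~10³ voxels) it underestimates, so the pipeline runs at the configured
order and the order-estimation routine is validated separately in the
voxel-rich regime.

**Infomax.** Full-batch natural-gradient ascent of the entropy of
logistic-squashed outputs: `ΔW ∝ (I + (1 − 2·σ(WX))(WX)ᵀ/n) W`, starting
from a random orthonormal matrix, step-halving on overshoot, stopping at
relative weight change < 1e-7 (max 2000 iterations). The logistic
nonlinearity targets supergaussian sources, which sparse blob-like
spatial networks are. Full-batch iteration makes each run deterministic
given its seed; randomness enters only through the initial matrix, which
is exactly what ICASSO needs to probe identifiability — Gaussian sources
leave the likelihood rotation-invariant, so restarts disagree and the
stability index drops, while identifiable sources converge from any
start. Each map is sign-flipped to positive skewness ("activation
positive"); ICA scale/sign is otherwise arbitrary.

**ICASSO.** Estimates from n_runs restarts (default 10 here; large
studies use 100 — the default trades a negligible stability-estimate
variance for run time) are pooled and clustered by average-linkage
agglomeration on 1 − |corr| distance, cut at C clusters. The centrotype
is the member with maximal summed within-cluster similarity; the
stability index is mean within-cluster similarity minus mean similarity
to outside estimates, clipped to [0, 1]. A single run returns stability 1
by convention.

**Dual regression.** Both regression steps include an intercept (the
common dual-regression contract, although textbook equation forms omit
it; on demeaned data the intercept estimates are ~0 and the choice is
inconsequential — the noiseless identity test passes either way).
Rank-deficient group maps are rejected by name. Z-scoring standardizes
each spatial row and temporal column; constant components raise.

## Task design and condition-specific FC

The 0-back/1-back preset counts the 2 s instruction screen inside its
block's first trial slot; only then do 6 × 22 s + 5 × 24 s sum to 252 s =
126 volumes at TR 2 s, matching the acquisition count. The canonical HRF
is the double-gamma (peak delay 6 s, undershoot 16 s, ratio 1/6, 32 s
support, unit peak; the mode of this parameterization sits at 5 s).
Working-memory-specific FC removes the 0-back volumes after shifting each
block window forward 3 volumes (6 s) to absorb the hemodynamic lag;
indices running past the acquisition end are truncated, never wrapped
(wrapping would splice run boundaries). Whether the shifted window should
exclude the instruction slot is not specified anywhere; it is retained.
Inter-network FC uses the condition-specific timecourses (a full-run
variant is a flag away, since which one the original analysis used is
ambiguous).

## Inference

Group comparisons fit `value ~ group + age + gender(0/1) + education` by
OLS; the group coefficient's t is reported with two-sided p. Groups are
coded by sorted label ("patient" > "control" ⇒ patient coded 1), so the
sign convention is row-order independent and a label swap negates t.
Cohen's d standardizes the covariate-adjusted group means by the
residual-based pooled SD.

The cluster-extent threshold k* is the smallest extent whose max-cluster
exceedance frequency over n_sim smoothed, re-standardized unit-variance
Gaussian fields falls below α. Re-standardizing after smoothing keeps the
voxel-level threshold calibrated (the AFNI convention). The neighbor set
follows the literal distance rule: 5 mm radius with 3 mm voxels keeps
face and edge neighbors, excludes corners (√3·3 ≈ 5.2 mm). k* is
recomputed per analysis mask, since it depends on mask size and shape.
The voxel-wise group comparison thresholds the t-field at the two-sided
voxel p using the t distribution with the model's residual df (not the
Gaussian), so the per-voxel rate is exact at any df.

The positive-FC mask uses Bonferroni FWE over in-mask voxels on the
one-sample t of the z-maps (random-field theory is out of scope at these
grid sizes); partial correlation residualizes both variables on
[1, covariates] and tests r with df = n − n_cov − 2. A variable lying in
the covariate span leaves only numerical dust as residual and is
rejected rather than correlated.

Demographic tables: pooled t, Welch t (Satterthwaite df), Pearson χ²
without continuity correction, Mann-Whitney U with tie-corrected normal
approximation, and a Shapiro-Wilk gate (p ≥ 0.05 → t-test route). Both t
variants are always printed, because published tables are not always
consistent about which was used — the glycated-hemoglobin row of the
reference table reproduces only under Welch, while every other row
matches the pooled formula.

## Synthetic cohort

The generator emulates *preprocessed* multi-subject block-design BOLD:
spatially independent networks (smoothed Gaussian blobs, σ = 1.5 voxels,
thresholded at 0.05, unit RMS, pairwise |cosine| < 0.2) on a 12 × 12 × 8
grid partitioned into cartoon tissue territories (lower slabs CSF and
white matter, upper half gray with a cerebellar corner), one component
per non-gray class so triage exercises every branch. Timecourses are
AR(1) backgrounds (φ = 0.3, mimicking BOLD autocorrelation) plus, for
task components, the HRF-convolved 1-back boxcar scaled by
task_amplitude = 0.7 and a per-group activation gain (patients 1.3,
emulating working-memory over-recruitment). A designated component pair
shares an AR(1) latent weighted so the *full* timecourse correlation
(task signal included) hits the per-group target (0.5 control, 0.15
patient ⇒ Δz ≈ 0.4). In patients, the deficit component's contribution
inside its 30 strongest voxels is scaled by 0.4 with variance-matched
noise injected — reduced coupling, preserved amplitude. I.i.d. Gaussian
voxel noise with SD 1.2 puts the aggregate SNR near 2 for six unit-RMS
maps. Behavioral records draw subject accuracy around group means
(0.95 vs 0.90, the patient deficit), Bernoulli trials, Gaussian RTs
(620/650 ms, floored at 150 ms); demographics sit in the range typical
of a middle-aged diabetes cohort.

What the generator does **not** emulate: motion, spikes, physiological
noise, spatial autocorrelation of the scanner noise, susceptibility
dropout, registration error, atlas-shaped anatomy. Passing tests
therefore demonstrate the correctness and calibration of the
computational chain under its own model assumptions, not robustness to
real-data artifacts.

## Problem sizes and numerical choices

Default analyses use 10 + 10 subjects (inference calibrations use the
study-sized 20 vs 19), grids of ~10³ voxels, 126 volumes, 1000
Monte-Carlo iterations for cluster thresholds, 200 cohorts for
family-wise-error and power estimates — sizes chosen so the entire
validation suite reruns from scratch in well under a minute while leaving
Monte-Carlo error far smaller than the margins tested. Tolerances:
dual-regression identity at 1e-8 relative; MDL eigenvalue floor at
1e-10 of the leading eigenvalue; MPM ties break gray > white > CSF and
are logged; the inter-network diagonal is stored as NaN (atanh(1) is
undefined); an AlphaSim threshold exceeding the mask size is flagged
unreachable rather than clamped.

## Known limitations

- MDL order estimation needs voxel-rich data; it is not wired into the
  default pipeline at desk scale (see above).
- The "cerebral blood flow" third tissue prior named in some published
  descriptions is treated as the standard CSF template.
- The intra-network deficit appears in z-scored subject maps as a core
  decrease plus a compensatory periphery increase (z-scoring is
  scale-invariant), so detected clusters can exceed the planted core;
  calibration tests therefore use the direct map-level generator where
  the effect size is exact.
- Behavioral defaults produce a significant accuracy deficit and, as a
  side effect of the RT offset, an IES difference; only the accuracy
  deficit is a modeled target.
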