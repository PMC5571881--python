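# Methods

## Signal model and relaxometry

Gradient-echo magnitude signal is modelled mono-exponentially,
S(TE) = S₀·exp(−TE/T2\*), with Rician noise: the magnitude of a complex
signal whose two quadrature channels carry independent zero-mean Gaussian
noise of standard deviation σ (single receiver channel; no non-central-χ
multi-coil generalisation). At σ = 0 the generator reduces exactly to the
closed form, which the tests exploit.

The voxelwise fit is weighted least squares of ln S on TE with weights
proportional to S². Log-transforming an additively noised signal inflates
the variance of small samples by a factor ≈ 1/S²; squared-signal weights
undo this, making the fast log-linear fit nearly efficient at moderate SNR.
A nonlinear exponential refit exists only as an independent test oracle.
Echoes at or below zero signal — and all later echoes, which are no longer
trustworthy after a signal void — are dropped; fewer than two usable echoes
marks the voxel invalid rather than raising. Post-fit gates: decay rate
must be positive, T2\* ≤ `t2star_cap` (default 200 ms, beyond plausible
tissue values at 3 T), and weighted R² ≥ `r2_min` (default 0.5). The
Rician noise floor is not modelled as an offset term; at the wall SNR used
here (S₀/σ = 50) the induced bias is ≈ 0.5% of T2\*, measured by the
acceptance script.

## Phantom

Axis-aligned concentric ellipsoids — lumen inside intraluminal thrombus
inside aneurysm wall — on a 44×44×28 grid at 2 mm isotropic spacing,
enough geometry to exercise wall-confined clustering without mesh
machinery. Default tissue T2\*: lumen 40, thrombus 20, wall 30, background
15 ms; S₀ = 1000, echoes at 5–30 ms in 5 ms steps, σ = 20. USPIO uptake is
a spherical lesion intersected with the wall whose post-contrast T2\* is a
fraction (default 0.2, i.e. an 80% reduction) of the pre value; a lesion
whose centre leaves the wall is rejected. Inter-visit motion is a rigid
transform (default 3 mm-scale translation plus ~1.7° rotation); the
generator resamples the post-contrast volume through the motion's inverse
and records the forward transform as the registration target, then noises
both visits independently. Truth masks partition the grid and regeneration
from the same seed is bit-identical.

What the phantom does **not** emulate: B0 inhomogeneity, k-space
artefacts, partial-volume anatomy, perfusion, or deformable motion.
Passing the end-to-end tests therefore shows the chain is correct under
its stated model, not that it is robust to clinical acquisition physics.

## Registration

Generic intensity-based rigid registration (SimpleITK): mean-squared
difference (or normalised correlation) metric evaluated on the full grid
(no random sampling, hence deterministic), multi-resolution pyramid
(default 2 levels), regular-step gradient descent, centre-of-mass
initialisation. It replaces the study-specific semiautomatic tool, whose
interactive element is out of scope; the contract is transform recovery on
phantoms, not clinical robustness. Registration runs on the first-echo
volumes (highest SNR); the recovered transform is then applied to the
post-visit T2\* map. Volumes with a single slice fall back to an in-plane
3-parameter registration.

Coordinates: 0-based voxel indices, world = index × spacing, axis-aligned
only (no NIfTI orientation matrix support — a documented limitation).
Recovered and true transforms are compared by their action on the grid
corners, which is invariant to the choice of rotation centre. When a T2\*
map is resampled, the validity mask is interpolated with the same linear
kernel and any output voxel touching invalid or out-of-field input
(interpolated validity < 0.999) is itself marked invalid — stricter than
nearest-neighbour mask resampling, and the reason registration fallout
cleanly leaves both numerator and denominator of downstream statistics.

## Enhancement classification

Percent change is defined as the *reduction* 100·(T2\*pre − T2\*post)/T2\*pre,
positive where iron shortens T2\*; T2\* increases are simply below
threshold. The call is *enhanced* iff some connected cluster of
suprathreshold wall voxels reaches `min_cluster_voxels` (default 10,
threshold default 71%). Clustering is volumetric with face (6-neighbour)
connectivity by default — the conservative reading of "contiguous" — with
the 26-neighbour variant configurable. The threshold comparison carries an
absolute slack of 10⁻⁹ on the percent scale so a voxel computed exactly at
the boundary (pre 30 ms → post 8.7 ms) is not lost to floating-point
rounding. The study's two-observer consensus step is modelled
deterministically: a quality gate issues *indeterminate* when more than
`max_invalid_fraction` (default 0.20) of the wall ROI is unusable. The
wall ROI is an input; automatic segmentation is out of scope.

## Cohort generator

Per patient: sex (85% male), current smoking (30%), systolic blood
pressure N(140, 18²) mmHg — marginals chosen as typical surveillance-
population values since the source tables are not machine-readable — and
baseline diameter N(49.6, 7.7²) mm truncated at 30 mm. True USPIO status
follows a logistic model in centred diameter (0.075/mm) and smoking (0.9),
intercept −0.56, giving ≈ 43% prevalence and the observed size gradient.
Growth is linear per patient, slope N(2.8, 2.4²) mm/yr marginally with a
+0.6 mm/yr shift under enhancement (mean-centred so the marginal mean is
preserved); six-monthly ultrasound visits measure diameter with 3.5%
multiplicative CV until exit. Note the *fitted* slopes have larger spread
than 2.4 mm/yr because measurement noise adds slope-estimation variance on
top of the true between-patient spread.

Events follow an exponential proportional-hazards model: baseline hazard
1.09·10⁻³/day (calibrated so a mean-covariate patient reaches ≈ 41%
primary-event probability by two years), log-hazards ln(1.077)/mm of
diameter and ln(1.464) for smoking, administrative censoring at 3 years.
Fired events draw a type from the published outcome proportions (ruptures :
repairs : aneurysm / cardiovascular / other deaths = 17 : 126 : 17 : 12 :
19); death types censor the rupture-or-repair endpoint at the event time,
mirroring how a primary-endpoint analysis treats competing deaths.
Covariates are mutually independent except where modelled — the joint
distribution is not published. All randomness descends from one integer
seed through `numpy.random.SeedSequence` spawning, so every sub-stream is
independent and reproducible.

## Statistics

* **Two-proportion comparison** — unpooled Wald interval on the absolute
  difference, pooled-variance normal z for the two-sided test. This exact
  combination reproduces the published counts-to-CI arithmetic
  (69/146 vs 68/191 → 11.7%, 1.1–22.2, p = 0.0308) and is therefore fixed.
  The stratified enhancement rates use determinate-only denominators
  (185 and 152), the only accounting that reproduces 35.1%/53.3%. The
  published interval 7.7–28.9 for that stratum difference is *not* Wald
  (which gives 7.5–28.8); the original method is unclear, and the interval
  is not asserted anywhere.
* **Kaplan–Meier / log-rank** — `lifelines`, events-before-censorings tie
  convention, two-group log-rank with hypergeometric variance.
* **Cox regression** — own implementation: Newton–Raphson on the Efron
  partial likelihood with step halving, covariates centred for
  conditioning (coefficients unaffected). Convergence when the gradient
  max-norm falls below 10⁻⁸ × max(1, |log-likelihood|): the scaling keeps
  the criterion attainable in double precision on large samples, where the
  gradient's rounding-noise floor grows with the accumulated sums, and
  reduces to the absolute criterion on small ones. Coefficients beyond
  |β| > 30 flag monotone likelihood (separation). Wald intervals;
  Harrell's c on the linear predictor; Breslow baseline cumulative hazard
  for absolute risk at a horizon. `lifelines` serves as an independent
  cross-check in the tests, never as the implementation.
* **Harrell's c** — usable pairs: an event preceding a longer survival, or
  an event tied in time with a censored subject; score ties count ½.
  Event–event ties in time are not orderable and are skipped.
* **NRI** — category-free ("unconditional") variant at a 2-year horizon:
  events by the horizon score +1/−1 as the extended model raises/lowers
  their risk, non-events the reverse; subjects censored before the horizon
  are excluded as uninformative. Percentile bootstrap CI (default 2000
  resamples, seeded); since the statistic depends only on the nine
  event-status × risk-direction category counts, resampling patients is
  implemented exactly as multinomial count resampling.
* **Sample-size planner** — n = events/rate rounded to nearest, inflated
  by 1/(1 − dropout) rounded up: 130 events at 41% → 317 analyzable,
  353 recruited.
* Growth slopes need ≥ 2 distinct measurement times (the lightest rule
  consistent with most-but-not-all patients contributing); the baseline
  scan enters at t = 0; the enhanced-vs-not growth comparison uses
  Welch's unequal-variance t.

## Problem sizes

Chosen as the package's own working scale: phantoms 44×44×28×6 echoes;
20 phantoms for end-to-end agreement; 10⁴ Monte-Carlo voxels for fit bias;
10⁴ simulated patients for hazard-ratio recovery; 100 seeded runs for NRI
null coverage. The demo pipeline (`ironmark run --n 6`) completes in a few
seconds on one CPU.

## Known limitations

No multi-compartment or complex-valued fitting, no B0 correction, no
deformable registration, no competing-risks modelling, no missing-data
imputation, no DICOM ingestion. Published patient-level results (c-statistic
0.7924, NRI −13.5%, the reported hazard-ratio point estimates) depend on
the undeposited clinical dataset and are used here only to calibrate the
generator — the pipeline recovers its own generative parameters, which is
the strongest claim a synthetic stand-in supports.
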