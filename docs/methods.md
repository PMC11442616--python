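# Methods

This note records the models, conventions and numerical choices behind
`dtialps`, and what the synthetic validation does and does not establish.

## Coordinate and data conventions

All b-vectors are direction cosines in a fixed image frame with
x = right–left, y = anterior–posterior, z = feet–head; the NIfTI affine is
never used to reorient them. This sidesteps the scanner-vs-image bvec
ambiguity of vendor exports — the phantom generator and the fitter share
one frame by construction, which is what makes the designed-vs-recovered
ALPS comparison meaningful. Consequences: real data whose bvecs follow a
different convention must be brought into this frame by the user, and the
ALPS index is only meaningful when the subject is aligned with these axes
(the index reads *diagonal* tensor elements, which are not rotation
invariant — that direction-dependence is the point of the method).

Voxel indices are 0-based; box ROIs are half-open `[start, start + size)`.
Only single-shell schemes (one b = 0 set plus one non-zero shell) are
supported. The shipped default scheme has 64 directions at b = 1000 s/mm²
from an electrostatic-repulsion layout frozen into a fixture file; its
direction second-moment matrix is within 0.1 % of isotropy, which keeps the
trace-image ADC within ~1e-4 of the tensor's mean diffusivity.

## Tensor estimation

Per masked voxel the mono-exponential model `S_i = S0 exp(-b_i g_i^T D g_i)`
is linearised by the log and solved by unweighted ordinary least squares
for `(ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`. Choices:

* **Unweighted OLS**, not weighted or nonlinear fitting: deterministic,
  exact on noiseless data, and adequate at the SNR (~30) this pipeline is
  validated at. At low SNR the log transform biases diffusivities; users
  fitting noisy clinical data should be aware the index inherits that bias
  (it partially cancels in the ratio).
* **Signal floor** `1e-6 · max(signal)` before the log, so zero or
  negative magnitudes cannot produce infinities.
* **No positivity constraint** on D. The ALPS index consumes raw diagonal
  elements; projecting to the PSD cone would silently alter the statistic.
* Scheme admissibility = at least one b = 0 volume plus ≥ 6
  diffusion-weighted directions whose quadratic-form design matrix has
  rank 6.

FA is computed from the eigenvalues,
`FA = sqrt(3/2) · ||λ − λ̄|| / ||λ||`, clipped to [0, 1], zero on
degenerate (non-positive-trace) voxels. The ADC map follows the
trace-image route: geometric mean of the diffusion-weighted volumes, then
`ADC = ln(S_b0 / S_trace)/b`; with the geometric mean this equals the
directional average of `g^T D g` exactly, so it matches the eigenvalue
mean whenever the direction set is isotropic.

## ROIs, the index, and tumor ADC

Projection/association ROIs are explicit 2×2×1-voxel boxes (4×4 mm
in-plane at 2 mm voxels, the standard footprint); the size is enforced
with an explicit override flag. The index is
`mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)` with arithmetic
ROI means; it is scale-invariant and maps to its reciprocal when numerator
and denominator roles are swapped.

Expert consensus placement is not an algorithm, so placement is an input.
The advisory `suggest_roi` helper scans 2×2 windows on one slice (FA ≥ 0.2
in all four voxels) and scores alignment of the principal eigenvector with
z (projection) resp. y (association); it is never applied when explicit
ROIs are supplied.

Tumor ADC uses a circular in-plane ROI of configurable area (default
5.3 mm²) centred on a physical-space point, rasterized to voxel centers,
with the center voxel always included — at 2×2 mm voxels the default area
is sub-voxel, so the rule reduces to the center voxel and is stated
explicitly to be testable. Whether an ALPS ROI sat inside peritumoral
edema is a recorded flag on the subject, not a computed quantity.

## The digital phantom

The default phantom (18×18×6 voxels of 2 mm) paints five compartments:
CSF ventricle (isotropic 3.0e-3 mm²/s), projection area (dominant z,
diag(Dxx, 0.8, 1.6)·1e-3), association area (dominant y,
diag(Dxx, 1.6, 0.8)·1e-3), isotropic tumor (1.6e-3) and isotropic
background (0.8e-3). The fiber-compartment Dxx sets the designed index:
1.12e-3 gives ALPS = 1.4 ("contralateral-like"), 1.0e-3 gives 1.25
("ipsilateral-like") — magnitudes chosen to echo the hemisphere-level
effect a unilateral-tumor cohort exhibits, as configuration rather than
as a claim about tissue. The perivascular contribution is represented as
that elevated Dxx within a single tensor per voxel; no intra-voxel
compartment mixing is modelled, because a single-tensor fit is also what
the index reads on real data.

Signals follow the noiseless model exactly, then Rician corruption
`|S + n1 + i·n2|` with seeded two-channel Gaussians. The phantom omits EPI
distortion, motion, eddy currents, partial-volume averaging at compartment
boundaries, and spatially varying noise. Passing the phantom suite
therefore shows the *computational* chain is correct and noise-stable at
SNR 30 — it does not show robustness to acquisition artifacts, nor that
ROI placement on real anatomy is right.

## Cohort statistics

* **Signed-rank test** (paired hemispheres): differences `x − y`, zeros
  discarded (the classical treatment, matching the one zero-difference
  pair in the packaged cohort; the Pratt variant is available), midranks
  on |d|, statistic `min(W+, W−)`. Exact two-sided p by full enumeration
  of sign assignments when ≤ 15 effective pairs (dynamic programming over
  doubled ranks); otherwise a normal approximation with variance
  `Σr²/4` — identically the tie-corrected formula — and a 0.5 continuity
  correction. The continuity correction is exposed as a flag because a
  widely used commercial toolbox omits it; at n = 23 the two conventions
  give 7.1e-5 vs 6.7e-5 on the packaged cohort.
* **Rank-sum test** (subgroups): U from midranks, exact enumeration when
  the pooled size is ≤ 12 without ties, else the tie-corrected
  continuity-corrected normal approximation. Both tests hold their nominal
  level empirically (rejection rate ≈ 0.04 at α = 0.05 over 2,000 null
  simulations at the study's group sizes).
* **Regression**: simple OLS with the two-sided slope t-test (n − 2 df),
  delegated to `scipy.stats.linregress`.
* **Descriptives**: sample sd (n − 1) by default with `ddof=0` available
  (the source tables print population-style sds); quartiles are
  midpoint-of-halves hinges with the median excluded — printed quartiles
  from other software may differ because quantile conventions vary, which
  is why only medians (convention-free for even n) are treated as
  reproducible.
* **Control matching**: greedy nearest-age same-sex assignment within a
  ±2-year tolerance; controls may serve several patients; ties broken by
  lowest control id. Which control hemisphere plays the "ipsilateral" role
  is genuinely ambiguous (tumor-side mirror vs a fixed hemisphere), so it
  is an explicit `hemisphere_rule` parameter and the matched-control
  p-values are reported but not treated as reproduction targets.
* Report rounding (2 decimals, half away from zero) happens only in the
  rendering layer; stored and serialized numbers are full precision.
* The age dichotomy is strict `< 55` vs `> 55`; no packaged subject is 55,
  so the boundary is moot but fixed.
* No multiple-testing correction is applied, matching the source analysis.

## Synthetic cohorts

`CohortSimSpec` defaults are the study conditions: 24 patients
(ipsilateral 1.26 ± 0.24, contralateral 1.43 ± 0.28), 12 controls
(1.28 ± 0.22), ages uniform on [24, 73], 14/24 male, 17/24 primary
tumors, 5/24 ROIs inside edema. Hemisphere pairs are bivariate normal
with within-subject correlation 0.7 — paired measurements in one brain
are strongly coupled, and this value gives the paired design realistic
power (≈ 0.97 at the 0.17 effect, n = 24) while keeping the null level
nominal. The generator draws independent rows; it does not model
age-index trends or exclusion mechanisms.

## Problem sizes used in validation

Phantom checks fit 1,944 voxels against a 65-measurement scheme; noise
stability uses 10 seeds at SNR 30; test-level checks use 2,000 null
simulations; power checks 500 (fixed effect) and 3 × 200 (monotonicity)
simulated cohorts. These sizes make the whole suite run in seconds while
keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

* Single-shell, single-tensor only; no robust fitting, kurtosis or
  multi-compartment models.
* No motion/eddy/distortion correction; inputs are assumed preprocessed.
* ROI placement on real data remains the user's responsibility; the
  suggestion helper is geometric, not anatomical.
* The matched-control hemisphere convention is a parameter, not a
  resolved question.
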