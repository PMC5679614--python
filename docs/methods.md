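# Methods

`r2tstar` estimates the tissue-specific transverse relaxation rate R2t*
from multi-gradient-echo (GRE) MRI, aggregates it over brain regions, and
runs the cohort statistics used to relate regional R2t* and atrophy to
clinical scores. This note documents the model, the estimation choices,
the synthetic-data design, and what the tests do and do not demonstrate.

## Signal model

The magnitude of the GRE signal at echo time TE is modeled as

    S(TE) = S0 · exp(−R2t*·TE) · F_BOLD(TE) · F(TE)

* **S0** — signal magnitude at TE = 0 (arbitrary units).
* **R2t\*** — tissue-specific decay rate (s⁻¹). About 1 s⁻¹ in CSF and
  15–20 s⁻¹ in normal brain tissue; it tracks the density of the
  cellular/macromolecular environment of tissue water.
* **F_BOLD** — extravascular blood-oxygenation (BOLD) dephasing in the
  static-dephasing regime around a random venous network:
  `F_BOLD(TE) = exp(−ζ · f_s(δω·TE))`, with ζ the deoxygenated blood
  volume fraction (dimensionless, physiologically ~0.01–0.03) and δω the
  characteristic frequency shift (s⁻¹, default 70).
  `f_s(x) = (1/3)∫₀¹ (2+u)√(1−u)(1−J₀(1.5xu))/u² du`; it behaves as
  0.3·x² for small x and x + const for large x.
* **F** — macroscopic field inhomogeneity. The package uses a
  through-voxel linear-gradient model, `F(TE) = |sinc(g·Δz·TE)|`, where g
  is the through-slab field gradient (Hz/mm) and Δz the voxel's slab
  thickness (mm). This is a first-order, invertible stand-in for a full
  voxel-spread-function correction: it captures the dominant slab-axis
  dephasing and supports both model-side multiplication and data-side
  pre-division; it does not capture in-plane or nonlinear field structure.

Default acquisition: 10 echoes, TE₁ = 4 ms, ΔTE = 4 ms, TR = 50 ms, flip
30°, 1×1×2 mm³ voxels. All operations also accept explicit TE vectors for
non-uniform trains. Units are seconds, s⁻¹, Hz/mm and mm throughout; any
conversion happens at the I/O boundary.

### Numerical evaluation of f_s

The integrand is finite at u→0 (the 1−J₀ zero cancels the 1/u² pole) but
naive evaluation of 1−J₀(z) loses ~8 digits for small z; a short series is
used below |z| < 0.1. The reference path is adaptive quadrature
(relative tolerance ≤ 1e−8). For vectorized fitting a dense table on
x ∈ [0, 100] (spacing 0.01, refined to 0.0025 below x = 1) is built with a
160-node Gauss–Legendre rule after the substitution u = 1−t², which
removes the √(1−u) endpoint singularity; monotone PCHIP interpolation
keeps the table within 1e−6 of the quadrature (measured ~2e−11 typical).

## Pre-corrections

**Navigator phase.** Physiological fluctuations are modeled as one global
phase per excitation (zeroth order), with excitations mapped to image rows
along the phase-encode axis. Correction multiplies row j by exp(−iφⱼ) and
is exact whenever the disturbance really is global per excitation; any
spatially-varying component is untouched (and tested to remain). Because
the phase is constant across the echoes of an excitation, magnitude-domain
fitting is unaffected by such a drift by construction — the correction
matters for the phase-based field estimation and for any downstream
complex-domain use. This is a deliberate simplification: real per-line
phase errors in k-space produce ghosting that an image-domain model cannot
reproduce.

**Field mapping.** B0 per voxel is the least-squares slope of the
temporally-unwrapped phase over TE (valid for |B0| < 1/(2ΔTE) = 125 Hz at
the default spacing); the through-slab gradient is the central finite
difference of B0 along z divided by the slab thickness (one-sided at
edges). No spatial unwrapping is needed because each voxel's series is
unwrapped in time.

## Voxelwise fitting

Bounded nonlinear least squares (trust-region reflective, analytic
Jacobian) of the magnitude model, initialized from the log-linear OLS
estimate of (S0, R2t*) with ζ₀ = 0.01. Default mode fixes δω = 70 s⁻¹ and
fits (S0, R2t*, ζ): ten magnitude points constrain a four-parameter model
poorly; joint (ζ, δω) fitting is available behind a switch. Tolerance
1e−10 on the cost decrease, at most 200 function evaluations;
non-convergence returns the initialization flagged `converged=False`
rather than raising.

**Bounds:** S0 ≥ 0, R2t* ∈ [0, 100] s⁻¹, δω ∈ [10, 300] s⁻¹, and
ζ ∈ **[−0.2, 0.2]**. The negative ζ floor is intentional. fs(70·TE) is
0.99-correlated with TE over the 4–40 ms train, so noise drives large,
nearly symmetric excursions along the ζ–R2t* trade-off direction;
truncating ζ at its physical floor of zero rectifies those excursions and
biases R2t* low by ~7% (mean) at SNR 50. Permitting negative ζ estimates —
exactly as variance-component estimators permit negative estimates — keeps
the R2t* Monte-Carlo bias near +1% at SNR 50 at the cost of a larger
variance. Per-voxel ζ maps should therefore be read as noisy, regionally
interpretable estimates, not voxelwise physiology.

**Quality mask.** A voxel leaves the quality mask if the fit did not
converge, the sinc attenuation at the last echo falls below 0.3 (severe
through-slab dephasing), the expected last-echo SNR falls below 3 (Rician
bias regime; no Rician likelihood is used), or the residual RMS exceeds 5×
the noise floor when one is known. Fits are voxel-independent, so results
are traversal-order invariant and bit-reproducible.

## Region aggregation

Regional R2t* is the **median** over labeled voxels intersected with the
quality mask — a few mislabeled or artifact voxels must not drag the
regional value, and the quality intersection extends the same robustness
logic to fit failures. Volumes count **all** labeled voxels (atrophy
measurement must not depend on fit quality): V = n·voxel-volume, and the
skull-normalized volume NV = V·scaling factor, with the per-subject
scaling factor supplied as an input. The default region set is eleven
limbic regions × two hemispheres in FreeSurfer-convention naming; any
conforming label table works. Empty regions yield missing-value rows, not
errors.

## Cohort statistics

* **Group comparisons** (`ancova_compare`): OLS of value ~ group + age +
  gender; omnibus extra-sum-of-squares F-test against the covariate-only
  model; pairwise contrasts as t-tests on dummy-coefficient differences.
  Hemispheres are analyzed separately (a repeated-measures variant is not
  implemented). A group with fewer than 3 subjects is an error.
* **Partial Pearson** (`partial_pearson`): residualize x and y on
  [1, covariates], correlate residuals; t = r·√(df/(1−r²)), df = n−k−2.
  **Partial Spearman** rank-transforms first (average ranks for ties).
  Score associations are run on MS patients only, controlled for age,
  gender, lesion load and treatment (binary); cognitive scores (z-scored
  PASAT 3s/2s, SDMT) use Pearson, the skewed EDSS/timed-walk/peg-test
  scores use Spearman. The nine-hole peg test is restricted to
  right-handed patients, pairing dominant-hand times with left-hemisphere
  measures and non-dominant with right.
* **Multiple testing** (`bh_fdr`): Benjamini–Hochberg step-up, adjusted
  p < 0.05 flags significance. Families are one per (measure, method)
  block of the battery (all region×hemisphere×score Pearson cells for
  R2t* form one family, etc.) and one per (measure, hemisphere) for the
  ANCOVA contrasts; the procedure is applied exactly once per family.
  Family definitions are a reporting choice and are stated in the report
  header.
* Missing data: complete-case per cell, with n reported per cell.

## Synthetic data

`make_phantom` builds a piecewise-constant 16×16×8 phantom (CSF slab at
1 s⁻¹, white-matter filler at 19 s⁻¹, per-hemisphere gray-matter region
blocks near 17 s⁻¹), applies the forward model exactly, adds a linear B0
field, per-excitation navigator drift and complex Gaussian noise
(σ = S0_gm/SNR per component, magnitude therefore Rician). At σ = 0 the
voxel signal equals the closed-form model to machine precision.

`make_cohort` draws 31 healthy controls and 80 MS patients (32 RRMS, 32
SPMS, 16 PPMS) with age ~ N(49.5, 14) truncated to 23–85, ~65% female,
73/80 right-handed, lognormal lesion load and a 75% treatment rate.
Regional truths are HC mean + group effect + age slope + N(0, 1.2²)
subject noise; the 1.2 s⁻¹ between-subject spread matches the magnitude
seen in regional gray-matter R2t* measurements in adults. Designed
couplings build each score as ρ·z + √(1−ρ²)·ε, where z is the
standardized residual of the regional truth on the covariate model, so the
partial correlation equals ρ in expectation; skewed clinical scores
(EDSS, timed tests) are strictly monotone transforms of their latent,
which exercises the Spearman path without claiming the true clinical
distributions. Default designed effects: SPMS R2t* deficits in
hippocampus/amygdala (−0.5…−1.2 s⁻¹), SPMS/PPMS volume deficits, ρ = 0.4
SDMT coupling (left hippocampus), ρ = 0.36 PASAT-2s coupling (left
amygdala), ρ = −0.30 EDSS coupling (right amygdala); everything else null.

`make_end_to_end_fixture` writes a complete miniature study (per-subject
magnitude/phase NIfTI pairs + echo-time sidecars, navigator TSVs, label
volumes/tables, one cohort TSV) in exactly the formats the real-data path
consumes. Fixture SNR defaults to 100 — representative of a 12-minute 3D
GRE acquisition — and the miniature regions hold ~35 voxels. With
~35-voxel regions the regional-median measurement error attenuates a
designed partial correlation by √(sd²/(sd²+SE²)) ≈ 0.93 at SNR 100; at
much lower SNR or smaller regions the attenuation is a scaled-geometry
artifact rather than a property of the method, which is why the fixture
does not go below this operating point.

**What the synthetic data do not emulate:** anatomy (regions are
cuboids), coil-level noise and combination, k-space trajectories and the
ghosting produced by per-line phase errors, in-plane or nonlinear B0
structure, partial-volume effects, and real clinical score distributions.
Passing tests demonstrate correctness of the estimation and statistics
chain under the stated model, not performance on scanner data.

## Problem sizes and runtimes

Chosen so the full suite and the acceptance script each run comfortably
on one CPU: Monte-Carlo calibration uses 500 repeats at SNR 50 and 200 at
SNR 20/100; the statistics null calibration uses 1000 ANCOVA repetitions;
the end-to-end study fits all 111 subjects at 16×16×8 (~620 masked voxels
each, ~1 ms per voxel fit); the 20-seed false-positive calibration runs
the statistics path on cohort-level truths rather than re-fitting 20×111
images, since the imaging stage contributes no additional statistical
structure to that property.

## Known limitations

* The sinc F-term corrects only the first-order through-slab gradient.
* The zeroth-order navigator model cannot represent spatially-resolved
  physiological phase errors.
* Magnitude-domain fitting discards BOLD phase information; Rician bias
  is masked, not modeled.
* Per-voxel ζ is poorly determined at clinical SNR (see bounds above);
  δω is fixed by default and not claimed to reproduce the original
  method's degrees of freedom.
* The repeated-measures (hemisphere) ANCOVA variant and class-level
  treatment encoding are not implemented.
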