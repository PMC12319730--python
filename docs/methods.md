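# Methods

## Problem and design

`pipefpr` estimates the type-I-error behavior of between-group
mass-univariate fMRI analyses in which each group's subject-level contrast
maps were produced by a different processing pipeline and the pipeline is
*not* modeled as a confound. Both groups are drawn from one subject pool,
so the population null holds by construction and every suprathreshold voxel
is a false positive; the pipeline difference is perfectly confounded with
the group label — deliberately the worst case, matching the data-reuse
scenario where each public dataset comes with its own pipeline.

The empirical false positive rate (FPR) over R repeated draws is compared
with the central 95% region of Binomial(R, α)/R computed at the *nominal*
α (0.037–0.064 for R = 1,000, α = 0.05). A Wilson interval for the
empirical rate is reported alongside: the binomial region answers "is this
rate compatible with a correctly calibrated test?", the Wilson interval
answers "how precisely did we measure the rate?".

## Synthetic cohort model

Per subject i, one latent acquisition; per pipeline p, a parametric
transform of it:

    map_ip = unit_scale_p · [ Smooth(gain_p·μ + b_i + √v_p·ε_i, h_p) + o_p ]

- **μ** — true-effect field: Gaussian-profile blobs (center voxel, radius =
  half-width-at-half-max in mm, amplitude in percent BOLD). Defaults: two
  blobs of amplitude 1.0 and 0.8% BOLD with radii 8 and 6 mm — focal
  task activation of realistic magnitude for a strong motor contrast.
- **b_i** — scalar between-subject random effect, N(0, subject_sd²),
  default subject_sd = 0.25% BOLD. A scalar (not a field) is the simplest
  structure that preserves exchangeability across groups; a smooth-field
  subject effect is deliberately not the default.
- **ε_i** — white Gaussian noise, default noise_sd = 4.0% BOLD before
  smoothing, smoothed to intrinsic FWHM noise_fwhm = 4 mm. After the
  default pipeline kernel this yields an in-mask per-voxel SD of ≈0.35%
  BOLD across subjects, i.e. within-group t-SNR typical of n = 50 studies.
- **gain_p** — multiplies the true-effect field only. It stands in for
  amplitude-scale differences between first-level models (HRF basis sets,
  motion-regressor sets), which shift the mean and variance of group
  statistics without a separately specified generative mechanism.
- **o_p** — smooth additive pipeline bias field (SD = offset_field_amplitude,
  default 0), low-frequency (FWHM = ¼ field of view), shared by all
  subjects of the pipeline.
- **unit_scale_p** — raw-unit convention: 2.5 for SPM-like maps, 100 for
  FSL-like maps (theoretical percent-BOLD units times the software's
  scaling), inverted exactly by the default harmonization factors 0.4 and
  0.01.
- **Smoothing** — kernels compose in quadrature: applying pipeline kernel
  h_p to a field of intrinsic FWHM f gives total smoothness
  √(f² + h_p²). Default h_p = 7 mm → total ≈ 8.06 mm ≈ 4 voxels at the
  2 mm default resolution, which puts desk-scale masks in the
  several-hundred-resel regime typical of whole-brain analyses.
- **Masks** — template "brain" is a super-ellipsoid (exponent 2.5,
  semi-axes ¾ of the half field of view); per-pipeline masks differ by
  binary erosion (default 0). Pipelines may live on their own grids;
  maps are cubic-spline resampled onto them at generation time.
- **Randomness** — one root seed; subject i uses the NumPy SeedSequence
  substream with spawn key (0, i), pipeline j's bias field (1, j). Cohorts
  are therefore bit-reproducible and parallelizable by subject.

The same b_i and ε_i underlie every pipeline's map of a subject — the
shared-latent-acquisition assumption. Real multi-pipeline maps decorrelate
somewhat across pipelines (different interpolation chains, different
first-level residual structure); the generator treats pipelines as pure
deterministic transforms, which makes the same-pipeline comparison an
exact null and pipeline effects fully parameterized. Consequently, passing
tests demonstrate the *machinery* is calibrated and sensitive; they do not
certify any particular real pipeline pair as safe or unsafe. What the
generator also does not emulate: raw BOLD time series, first-level GLM
fitting, registration error, spatially varying (nonstationary) smoothness,
and non-Gaussian artifacts.

Default cohort: 1,080 subjects on a 32×32×32 grid at 2 mm (desk scale,
seconds to generate); 91×109×91 is available for realism at proportional
cost.

## Inference chain

**Harmonization** (order: resample → intersect masks → mask → rescale).
Values use third-order spline interpolation (nilearn's continuous
resampler); masks use nearest-neighbour and are restricted to voxels whose
centers fall inside the source field of view, so spline extrapolation never
enters statistics. Rescaling refuses maps already in percent BOLD (a
double-scaling guard). Inside the validity loop, harmonized maps are
memoized per (subject, pipeline) — pipeline masks are fixed, so the common
mask and each harmonized map are invariant across repetitions.

**t maps.** Welch (unequal variance, per-voxel Satterthwaite df) is the
default, matching the stated group model; pooled variance (df = n₁+n₂−2,
the T₉₈ reference at 50 per group) is exposed because second-level packages
differ in their nonsphericity handling and the diagnostics' reference null
is the pooled-df Student law. For thresholding under Welch, the scalar df
is the median per-voxel Satterthwaite df. Voxels with zero variance in
both groups are excluded from detection and counted, not zero-filled.

**Smoothness.** Per-axis FWHM from the mean squared spatial first
difference g of per-voxel-standardized residuals: the lag-1 autocorrelation
1 − g/2 is inverted under a Gaussian ACF (exact in expectation for
Gaussian-ACF fields; at FWHM 2 voxels the first-order estimator
√(4ln2/g) it falls back to for rough fields is ~9% biased). Estimates
below 1 voxel warn (the continuum approximation is degraded). Resel
counts: R0–R2 from lattice point/edge/face counts (exact intrinsic volumes
for a solid box); R3 = voxel count / ∏FWHM.

**Threshold.** ρ_d are the unified EC densities for Student fields. The
solver brackets the root of E[EC(u)] = α on the decreasing branch (the
densities are non-monotone near u = 0, and below df ≈ 10 with small masks
a root below u = 50 may not exist — the solver then raises rather than
extrapolate) and refines with Brent's method to 1e−8 on the α scale.
Detection uses the closed comparison t ≥ u so exact ties count
deterministically.

**Monte-Carlo oracle.** `realized_fwe_montecarlo` simulates stationary
periodic Gaussian fields at known smoothness, forms pooled-variance null t
fields, and measures the fraction exceeding the solved threshold. It
exists to validate the EC/resel/solver chain (transcription errors are the
main risk) and is not an inference method. Its default conditions — FWHM
6 voxels, 40³ field with a central 36³ box mask, 30 subjects per group
(df 58), 2,000 fields — sit in the regime the continuum theory models.
This matters: at 3–5-voxel FWHM, voxel-wise RFT is intrinsically
conservative on a lattice (realized FWE roughly half of nominal in our
measurements, consistent with published simulation studies), because the
sampled grid misses narrow continuum peaks and the discrete excursion-set
EC runs below the continuum prediction. That conservatism is a property of
the method being studied, not an implementation error; the oracle's job is
to check the formulas where the theory's assumptions hold.

## Diagnostics

Ordered one-tailed p-values (against Student df_ref, default 98) are
plotted in Bland–Altman form: x = −log₁₀ k/(N+1),
y = −log₁₀ p₍ₖ₎ − x, with pointwise 95% bands from Beta(k, N−k+1)
quantiles mapped to the y scale. The bands assume independent p-values;
voxel statistics are spatially correlated, so pooled statistics are thinned
(default every 100th voxel) before plotting, and band escapes should be
read as effect direction/size, not calibrated tests. Zero p-values are
floored at 1e−300 before the log transform and counted. The distribution
report flags |mean| > 3·SE or an SD ratio outside [0.9, 1.1] against the
reference SD √(ν/(ν−2)).

## Scales used in the shipped checks

Test-suite and acceptance scales were chosen for single-CPU desk runs:
200 repetitions for baseline validity (acceptance-region quantiles are
recomputed at the actual R), 100 repetitions per point of the gain sweep
(gains 1.0/1.1/1.25/1.5 versus a unit-gain pipeline — amplitude biases of
0–50%, the range single first-level modeling choices plausibly span),
2,000 fields for the Monte-Carlo oracle, and 500 replicates of N = 1,000
uniform samples for P-P band coverage. The documented paper-scale
configuration is 1,000 repetitions with the same group size.

## Known limitations

- The shared-latent assumption makes cross-pipeline maps maximally
  correlated; real pipeline pairs add decorrelation that this generator
  does not model.
- Stationary, isotropic-by-default smoothness; no nonstationary RFT.
- Voxel-level inference only: no cluster-extent or peak inference, no FDR,
  no permutation inference (the Monte-Carlo simulation is a test oracle,
  not a user-facing method).
- One-tailed tests only, run separately per direction, as in the
  between-group design under study.
- The Welch/pooled duality is exposed, not resolved: which variant a given
  second-level package effectively ran is not recoverable in general.
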