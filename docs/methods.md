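# Methods

This note documents the models, numerical choices and known limitations of
`fpetkit`, in the spirit of a package methods appendix.  All times are in
minutes and all activities in arbitrary units; TACs are assumed
decay-corrected.

## Arterial input model

An AIF is the convolution of a decaying biexponential impulse response
`h(t) = a₁e^{−λ₁t} + a₂e^{−λ₂t}` (amplitudes ≥ 0, λ₁ ≥ λ₂ > 0) with the
delivery schedule `r(t)`: a constant rate for CI, plus a rectangle of
area `K_bol × rate` over the first `bolus_width` minutes for B+CI.
`K_bol` is the relative bolus size in minutes of equivalent constant
infusion; the default 19.3 min matches published B+CI practice.  The
bolus rectangle width defaults to 1 min — the precise sub-minute shape is
immaterial once convolved with `h`, and a 1-min rectangle is stable on
the 1-s simulation grid.  Convolution uses the trapezoid rule on the
simulation grid; the single-exponential case agrees with the closed-form
integral to < 0.1% at `dt = 0.01` min.

`fit_aif` recovers the response by bounded nonlinear least squares with
eight deterministic starts on a log-spaced rate grid (biexponential fits
are multi-modal) and non-negative amplitudes.  Under a pure CI schedule
the fast pair `(a₁, λ₁)` is poorly identified — the output depends on
them mostly through `a₁/λ₁` — so parameter-level recovery should only be
expected from bolus-containing data, which excite the fast component.
Curve-level recovery is good under both schedules.

## Tissue model and integration

The reversible two-tissue compartment model (free tracer C₁,
phosphorylated tracer C₂; rates K₁, k₂, k₃, k₄) is integrated by implicit
(backward) Euler: each step solves the 2×2 system
`(I − dt·A)·C^{n+1} = C^n + dt·b^{n+1}` exactly.  The scheme is
first-order: against an adaptive LSODA reference at `rtol = 1e−10` the
maximum relative error is ≈ 0.008% at the default 1-s step and halves
with the step.  The default rate constants are literature gray-matter
values (K₁ = 0.102 mL/min/g, k₂ = 0.13, k₃ = 0.062, k₄ = 0.0068 min⁻¹).
No blood-volume term is included (V_b = 0): the simulated signal is the
two tissue compartments only.  Physical decay appears nowhere in the
signal model (data are decay-corrected) and only in the noise model
below.

Frames average the fine-grid TAC with the trapezoid rule, timestamped at
frame midpoints — exact for linear signals.  A 95-min CI scan at 16-s
frames gives 356 frames; a 105-min B+CI scan at 30-s frames gives 210.

Patlak analysis regresses `C(t)/C_a(t)` on `∫C_a/C_a` for frames past
`t*` (default 30 min — a conventional late-window choice; the estimate is
insensitive to `t*` beyond it).  In the k₄ = 0 limit the slope matches
the analytic `K₁k₃/(k₂+k₃)` within 2%; with k₄ > 0 the slope is biased
low, as expected for dephosphorylation.

## The five baseline models

All methods can drop the initial pre-equilibration minutes.  A frame is
excluded when it **starts** before the boundary, so no kept frame
overlaps the excluded window (95-min/16-s data keep 318 frames after a
10-min cut).  Polynomial bases are evaluated on time centered and scaled
to [−1, 1] for conditioning over ~350 frames.

- **P3** — cubic OLS per parcel.
- **P3MT** — stage 1 fits a cubic to the unweighted cortical-mean TAC
  (with the task regressor as an unconstrained nuisance when a task is
  being analyzed); stage 2 fits intercept + amplitude of the stage-1
  curve per parcel.
- **MT** — OLS on {1, cortical-mean TAC} per parcel.  By linearity of
  OLS the cortex-mean residual vanishes identically, while per-parcel
  residuals reflect regional kinetic heterogeneity.
- **SA** — spectral analysis.  The basis is `ψ_β = AIF ⊗ e^{−βt}` for 48
  log-spaced β in [10⁻³, 1] min⁻¹ (spanning effective FDG clearance
  rates), plus the β = 0 trapping integral, computed on the fine AIF grid
  and frame-averaged exactly like the data.  Spectral coefficients are
  constrained ≥ 0 (conventional in tracer spectral analysis) via NNLS,
  with the intercept — and the task nuisance, when given — left
  unconstrained through column mirroring.  Any TAC inside the basis span
  is reproduced with residual RMS ≤ 10⁻⁶ of signal scale.
- **EXP2** — the analytic baseline implied by the compartment model under
  a constant-infusion input approaching plateau:
  `B(t) = c₀ + c₁t + c₂e^{−μ₁t} + c₃e^{−μ₂t}`.  Because a decay-corrected
  tissue curve starts at zero activity with zero slope, the analytic
  family satisfies `B(0) = 0` and `B′(0) = 0`, which ties
  `c₀ = −(c₂+c₃)` and `c₁ = μ₁c₂ + μ₂c₃`; the default fit uses this
  anchored two-basis form `B = c₂g_{μ₁} + c₃g_{μ₂}` with
  `g_μ(t) = e^{−μt} − 1 + μt`.  The rates represent the input
  equilibration rate and the tissue clearance rate `k₂+k₃`, so they share
  bounds `[10⁻³, 1]` min⁻¹ — the same effective-kinetics span as the SA
  grid.  Fitting is variable-projection nonlinear least squares with a
  deterministic multi-start over a log-spaced rate grid (ties broken by
  the smaller fast rate) and a bounded local refinement.  A free
  four-amplitude variant (`anchored=False`) is available for generic
  curve fitting.  The anchoring is what makes EXP2 *informed*: it fits CI
  data well but cannot absorb a bolus overshoot, which is exactly the
  regime where it underperforms even a cubic.

On noise-free simulations the residual ordering is: SA best everywhere;
EXP2 well below P3 for CI but several-fold above P3 for B+CI; excluding
the first 10 minutes shrinks the P3 residual under both protocols, with
the larger *fractional* reduction for B+CI (the bolus transient is
concentrated early).  Residual summaries use a 2-min-FWHM Gaussian
temporal filter (σ = FWHM/2√(2 ln 2) ≈ 0.849 min, truncated at ±4σ,
kernel renormalized at the scan edges rather than padding) followed by
the RMS over time; maps average the per-subject RMS across subjects.

## Sham GLM analysis

Task regressors are alternating on/off blocks (default 10/10 min) with a
configurable initial rest.  The default GLM shape is the **ramp** — the
running time-integral of the block boxcar, unit slope during on-blocks —
because a metabolic task effect changes the *slope* of a cumulative TAC;
the boxcar is retained as an option.  Regressors are demeaned.

Sham-regressor selection correlates candidates with a reference residual
pattern **after projecting both orthogonal to the baseline design**: a
ramp's dominant linear trend is absorbed by every baseline model, so the
projected correlation is the quantity that actually drives the task-beta
bias; the unprojected correlation is available by passing no projection
basis.  Three picks are reported: most positive, closest to zero, and
the most negative with |r| in [0.2, 0.6] (falling back to the most
negative overall).

Subject GLMs are per-parcel OLS on [baseline regressors | task].  For
the linear methods the baseline regressors enter directly; for SA and
EXP2, whose baselines are fit nonlinearly, the per-parcel fitted baseline
curve enters the GLM as a single regressor alongside an intercept (a
standard two-stage construction that keeps the classical t machinery
valid).  For P3MT and SA the sham regressor is included as a nuisance
when the baseline itself is created, so the baseline does not absorb the
putative task.  Collinearity beyond a standardized condition number of
10⁸ triggers a warning but results are returned.

PSC per parcel is `100 × β_task × on_slope / slope_late`, with
`slope_late` the OLS slope of the fitted baseline over the final third of
the kept scan ("late" is not sharply defined; the final third is past
equilibration for both protocols).  Parcels with non-positive late slope
get NaN.  PSC is invariant to rescaling a subject's data.

Group inference is a one-sample t-test across subjects' task betas
(summary-statistics random effects; dof = N−1, two-sided p), with
Benjamini–Hochberg FDR across parcels at q = 0.05.  Zero between-subject
variance yields a ±10⁶ sentinel t, flagged so FDR stays computable.
Parcel aggregation (unweighted mean TAC per group) is the desk-scale
proxy for spatial smoothing: averaging suppresses independent noise while
shared residual patterns survive, so group |t| of a biased analysis grows
as parcels merge.

Steiger's Z uses the Z₁* form: Fisher-z difference of the two dependent
correlations divided by its standard error with the pooled-r covariance
term; one-sided upper-tail p.  For spatial-map comparisons n is the
number of parcels.

## Synthetic cohort generator

Defaults mirror a resting-state CI study: 24 subjects, 100 cortical
parcels, 95-min scans at 16-s frames (B+CI preset: 105 min at 30-s
frames, K_bol = 19.3 min).  What it emulates, and how:

- **Regional kinetics**: each parcel's rates are drawn lognormally around
  the literature center with CV 0.15 per rate — lognormal guarantees
  positivity and a 15% regional spread is a realistic anatomical range.
- **Arterial inputs**: one response per protocol.  CI data expose the
  minutes-scale equilibration phase (λ₁ = 0.25 min⁻¹, i.e. a ~10-min
  initial dynamic phase, the reason analyses consider excluding 10 min)
  plus a slow quasi-linear rise (λ₂ = 0.012 min⁻¹); bolus data
  additionally reveal the sub-minute vascular distribution phase
  (λ₁ = 3 min⁻¹), which is what lets B+CI scans equilibrate within
  minutes.  Subject-level variability multiplies each response parameter
  by a lognormal factor with CV 0.10.
- **Noise**: independent Gaussian per frame with standard deviation
  `noise_scale × late_mean × √(1 min / frame) × e^{+λ_phys t/2}`,
  λ_phys = ln 2 / 109.77 min⁻¹ — decay correction amplifies counting
  noise late in the scan, and shorter frames collect fewer counts.  The
  default `noise_scale = 0.01` (≈ 2% per 16-s frame) describes
  parcel-averaged data, where the detrending residual pattern is plainly
  visible in single subjects; this is the regime in which the bias
  mechanism the package studies operates.  The generator's noise is
  white across frames and parcels — real data have spatially and
  temporally correlated noise, motion residuals and physiological
  drifts, so passing tests demonstrate the mechanism, not empirical
  effect sizes.
- **Task effects**: `additive_ramp` adds `effect × slope_late` of extra
  slope during on-blocks (ground-truth PSC exactly `100 × effect`);
  `k3_modulation` re-simulates with `k₃ → k₃(1+δ)` during on-blocks — a
  time-varying coefficient in the ODE — with ground truth from the
  steady-state influx ratio `(1+δ)(k₂+k₃)/(k₂+k₃(1+δ)) − 1`.  Note that
  a ramp-GLM estimate of a k₃ modulation is systematically *attenuated*
  relative to that asymptote: the compartment transient
  (τ ≈ 1/(k₂+k₃) ≈ 5 min plus a slow k₄ eigenmode) does not complete
  within a 10-min block, so the realized slope change is roughly half
  the asymptotic value and the fitted ramp captures less still.  The
  additive mode exists precisely to provide an exactly controllable
  recovery target.
- **Reproducibility**: all randomness flows from one integer seed via
  `numpy.random.SeedSequence` spawning; `(spec, seed)` regenerates a
  cohort bit-identically.

## Problem sizes

The test suite and the acceptance script run the cohort analyses at the
study scale (24 × 100 parcels; 500 parcels for the aggregation
comparison), Monte-Carlo calibrations at 10,000 replicates, and
parameter-recovery studies on small noise-free cohorts (3 subjects × 8
parcels), which is ample for noise-free quantities.

## Known limitations

- No image-domain processing: reconstruction, attenuation and motion
  correction, voxel-wise smoothing and parcellation are out of scope;
  parcel aggregation stands in for spatial smoothing.
- The AIF response family is biexponential; real input functions contain
  more distribution phases and dispersion.
- Noise is Gaussian, white, and uncorrelated across parcels.
- Group inference is a one-sample t on betas; permutation or
  mixed-effects alternatives are not implemented.
- The EXP2 anchoring reconstructs an analytic compartment baseline from
  first principles; other parameterizations of a "linear plus
  biexponential" baseline exist and the free variant is provided for
  comparison.
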