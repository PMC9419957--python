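# Methods

`chronodcm` asks whether resting-state fMRI carries time-of-day structure,
and if so, whether it lives in the neuronal coupling (effective
connectivity) or in the hemodynamics that translate neuronal activity into
BOLD.  The package implements the full analysis chain — generative model,
spectral data features, variational inversion, hierarchical empirical Bayes,
Bayesian model comparison — together with a synthetic cohort generator that
produces data from the same generative model, so every stage can be scored
against a known ground truth.

## Generative model

Neuronal states of an `n`-region network follow linear stochastic dynamics

    dx/dt = A x + v,

where `A` (Hz) has free off-diagonal couplings and self-connections
`-0.5 * exp(a_self_i)`; the zero point of the log-scale parameter therefore
corresponds to a self-inhibition rate of −0.5 Hz.  The endogenous
fluctuation `v` and the observation noise both have power-law spectra

    g(f) = exp(alpha) / 64 * f^(-exp(beta)),

with `alpha`, `beta` log-deviations about documented means (amplitude scale
1/64, exponent 1): one pair for the fluctuations, one for the noise, shared
across regions.

Each region's activity drives a Balloon model — vasodilatory signal `s`,
inflow `f`, venous volume `v`, deoxyhemoglobin `q`:

    s' = x − κ s − γ (f − 1),         κ = 0.64 · exp(decay) s⁻¹, γ = 0.32 s⁻¹
    f' = s
    τ v' = f − v^(1/α),               τ = 2 · exp(transit_i) s, α = 0.32
    τ q' = f E(f)/E₀ − v^(1/α) q / v,  E(f) = 1 − (1−E₀)^(1/f), E₀ = 0.4

with the 3 T BOLD observer `y = V₀ [k₁(1−q) + k₂(1−q/v) + k₃(1−v)]`,
`V₀ = 4`, `k₁ = 6.93·ϑ₀·E₀·TE` (ϑ₀ = 40.3 s⁻¹), `k₂ = ε·r₀·E₀·TE`
(r₀ = 25 s⁻¹), `k₃ = 1−ε`, `ε = exp(epsilon)`, TE = 33.1 ms.  All constants
live in one frozen table (`forward.HemoConstants`); none are fitted.
`transit` is regional; `decay`, `epsilon` and the spectral parameters are
global, matching the structure of the group analysis.

Linearizing the coupled system about its resting fixpoint gives the
transfer function `G(ω) = L (iωI − J)⁻¹ B` and the model cross-spectral
density

    S(f) = G g_v(f) G* + g_e(f) I,

a complex Hermitian `n × n` matrix per frequency.  Gradients of `S` with
respect to every parameter are computed analytically from
`dG = L R (dJ) R B` (R the resolvent); the analytic Jacobian is verified
against central differences in the tests and a finite-difference path is
retained as a configuration option.

## Synthetic cohorts

The generator emulates the study design end to end: six two-hour timespan
bins between 09:00 and 21:00, two sessions (LR/RL) per subject with shared
subject-level parameters, mid-scan times drawn uniformly within each bin.
Defaults mirror the acquisition it stands in for: TR 0.72 s, 1200 volumes
(14.4 min), 96 subjects per timespan, 8 regions — all scalable downward.

Group time-of-day effects are injected by shifting chosen parameters
(`decay`, CSD amplitude, `transit`, `epsilon`, or the off-diagonal `A`) in
proportion to any of the 18 design columns.  The default effect is 0.1 on
the log scale of `decay` and CSD amplitude under model 7 (a deviation over
the two morning timespans) — a ~10 % modulation of the vasodilatory decay
rate, large enough to be decisively detectable at the cohort's own scale
while small enough to stay in the regime where decay changes do not leak
into the connectivity estimates.  Between-subject variability is an
independent Gaussian perturbation of every parameter (default SD 0.1, log
scales), redrawn until the neuronal system is stable with a damping margin
of 0.1 Hz (relaxation < 10 s; weaker damping produces excursions the
nonlinear Balloon model cannot absorb).

Endogenous noise is synthesized exactly in the frequency domain (Gaussian
rfft coefficients matching the target PSD, zero DC) and integrated through
the nonlinear Balloon equations with Heun's method at dt = TR/16; 64
burn-in volumes are discarded.  The drive is attenuated by 1/32 and the
BOLD deviation rescaled by 32: the linearized response — and hence the
model spectrum — is invariant under this joint rescaling, which simply pins
flow/volume excursions to the few-percent regime of resting BOLD where the
Balloon nonlinearity is mild.  A long-run test confirms the Welch spectrum
of the simulator matches the analytic CSD within 15 % in band.

What the generator does *not* emulate: scanner artifacts, motion-induced
signal (confounds are generated as separate regressors with configurable
leakage, default zero), spatial structure beyond small rendered test
volumes, non-Gaussian subject variability, and chronotype covariates.
Passing tests therefore demonstrate internal consistency of the method
under its own assumptions, not performance on real acquisitions.

## Preprocessing

ROIs are 6 mm spheres (voxel-centre inclusion, affine-authoritative
mm↔voxel mapping) summarized by the first eigenvariate (unit variance,
sign fixed by positive mean loading).  Before extraction, voxel series are
cleaned by linear regression on motion regressors plus WM/CSF sphere
eigenvariates at (0, −24, −33) and (0, −40, −5) mm.  Synthetic confounds
carry 12 motion-like smoothed random walks plus WM/CSF-like slow noise (14
columns).

## Subject-level inversion

Observed cross-spectra come from a least-squares multivariate
autoregression (default order 8) evaluated on a grid of 32 frequencies from
the series fundamental up to 0.25 Hz; a Welch estimator with Hann windows
serves as an independent oracle, never as the fitted feature.  The band
deliberately extends above the 0.1 Hz ceiling of resting-state fluctuations
because the vasodilatory-decay resonance sits near 0.1–0.2 Hz; capping at
0.1 Hz leaves `decay` weakly identified and lets hemodynamic effects
masquerade as self-connection changes.

The spectrum is rescaled by one global constant so its in-band mean power
matches the prior-mean model (the constant is logged), and features are
whitened by the subject's own auto-spectral shape, `sqrt(S_ii S_jj)` per
entry — the variance structure of smoothed spectral estimators, which makes
the residuals approximately homoscedastic and keeps the steep low-frequency
auto-spectra from drowning the mid-band cross-spectra that identify the
coupling.

Fitting is Gauss–Newton ascent on a variational free energy with Gaussian
shrinkage priors (variance 1/64 on connectivity and spectral parameters,
1/256 on transit/decay/epsilon), a Levenberg damping factor (×2 on
rejection, ÷2 on acceptance, bounds 10⁻⁶–10⁶), and one log-precision
hyperparameter per feature block (auto real / cross real / cross imaginary)
updated by Newton steps inside the same ascent.  Because the features are a
deterministic function of the MAR coefficients, the data likelihood is
raised to the power (MAR degrees of freedom / feature count) ≈ 0.27 —
without this the posteriors are 2–3× overconfident and the group hierarchy
misreads estimation noise as structure.  Convergence is declared after
three consecutive steps (accepted or rejected) that change the free energy
by less than 10⁻², or 64 iterations.  The posterior covariance is the
inverse curvature at the optimum, symmetrized with an eigenvalue floor of
10⁻⁸.  On linear-Gaussian problems the scheme reproduces the conjugate
posterior and exact log evidence to 10⁻⁶, which is how it is validated.

## Group analysis

The hierarchy follows the study design: one mean-only parametric
empirical Bayes (PEB) fit per (timespan, session) cell, then a second level
across the 12 cell posteriors.  PEB is implemented through the closed-form
Gaussian evidence change under prior replacement (Bayesian model
reduction), which makes the group posterior and free energy analytic for a
fixed between-subject scale; one scale per parameter family (off-diagonal
coupling, self-connections, transit, decay, epsilon, CSD amplitude, CSD
exponent, observation noise) is optimized by deterministic golden-section
coordinate ascent with a N(0, 16) log-scale hyperprior.  Families matter:
one shared scale lets the noisiest block (spectral amplitude, which absorbs
the per-subject normalization) inflate the between-subject variance of
`decay` several-fold and corrupt effect sizes.

Two structural facts about the 12-cell design shape the second level:

* The LR and RL cells of a timespan contain the *same* subjects, so their
  means share every session-stable component — true subject deviations and
  subject-specific estimation bias, with their cross-parameter
  correlations.  That shared covariance is estimated directly as the pooled
  cross-session covariance of subject posteriors (session-independent noise
  cancels in the cross-product) and added, scaled by 1/n, to each cell
  posterior.  Cell posteriors are otherwise diagonalized: their approximate
  cross-parameter correlations would be deconvolved into spurious joint
  "effects".
* All 18 time-effect columns live inside the five-dimensional space of
  timespan contrasts.  The second level therefore fits *one* model whose
  contrast block spans that space (mean + five sum-to-zero codes) and
  scores each design by Bayesian model reduction: the design's prior
  concentrates the contrast block along its own time column (variance 4×
  the first-level prior along the pattern; a 10⁻⁸ ridge elsewhere; the null
  model keeps only the ridge).  Every design is thus judged against the
  same fitted between-cell variance; fitting each design separately would
  let its free variance component absorb the very pattern under test.  The
  between-cell log-scale hyperprior is tight (variance 1/16): the cells are
  exchangeable replicates once first-level uncertainty is propagated.

Model probabilities are the softmax of free energies under a uniform model
prior.  Bayesian model averaging moment-matches the probability-weighted
mixture of the 18 reduced posteriors; per-parameter posterior probabilities
of a nonzero time effect come from pruning that parameter's contrast
entries (prior variance → 0) and converting the evidence change through a
logistic, thresholded at 0.95 for reporting.  Cohen's d for a parameter is
the absolute time-effect coefficient divided by the square root of its
family's optimized first-level between-subject variance.

The full analysis runs twice per cohort: over the connectivity block
(`n²` A-parameters) and over the hemodynamic block (regional transit,
decay, epsilon, CSD amplitude, CSD exponent).

## Numerical and design choices, in brief

* Effects coding (sum-to-zero) for the timespan factor; rows timespan-major
  with LR before RL; the sinusoid family has one full period over the six
  bins, so models three steps apart are sign-inverted pairs.
* The canonical 12×7 designs are rank-deficient by construction (the time
  column lies in the span of the factor codes); identification is through
  the priors, and `peb_fit` rejects only genuinely degenerate input
  (duplicated columns).
* Deconvolution guard: a posterior direction contributes data to the group
  level only when its precision exceeds 5 % of the prior precision;
  deconvolving flatter ridges amplifies approximation error.
* Sphere masks use the voxel-centre rule with 0-based indices; the last
  timespan interval is closed on the right so 21:00 is admissible.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; reruns are bit-identical.

## Problem sizes used by the test suite

Desk-scale checks run 4-region networks.  Parameter-recovery tests use 400
volumes per session; the qualitative-reproduction suite simulates cohorts
of 32 subjects per timespan × 6 timespans × 2 sessions (384 inversions per
cohort) for ten replicate cohorts per condition, with an injected
hemodynamic-only morning effect of 0.1 or none.  Simulator/forward-model
consistency is checked on a 2¹⁷-volume run.  At these sizes the realized
group pattern of a cohort carries subject-sampling noise (SD
0.1/√32 ≈ 0.018 per timespan mean against pattern values of ±0.067), so a
minority of replicates genuinely favour a neighbouring morning design over
the injected one; this is a property of the study size, not of the
estimator, and it bounds how often exact model identification can succeed.

## Known limitations

* The observation model treats whitened spectral residuals as independent
  Gaussians within three precision blocks; real MAR estimation error is
  correlated, which the likelihood tempering compensates only on average.
* The CSD amplitude parameter is only weakly identified once each
  subject's spectrum is rescaled to the prior-mean power; amplitude effects
  are therefore harder to detect than decay effects of equal size.
* Epsilon (the intra/extravascular ratio) is essentially prior-bound at
  these data sizes.
* Between-subject variability is Gaussian by assumption; heavy-tailed
  subject estimates (which do occur for spectral parameters) are handled
  only through the fitted variance scales.
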