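# chronodcm

Does resting-state fMRI change with the time of day — and if it does, is it
the brain's effective connectivity that changes, or the vascular machinery
that turns neuronal activity into a BOLD signal?  `chronodcm` implements the
full analysis that separates those two explanations, for researchers who
study diurnal effects in resting-state acquisitions or who want to stress
test that analysis on data with a known ground truth:

* a spectral dynamic causal model: linear neuronal dynamics
  `dx/dt = A x + v` with self-connections `−0.5·exp(a_self)` Hz, power-law
  endogenous fluctuations `g(f) = e^α/64 · f^(−e^β)`, and a nonlinear
  Balloon hemodynamic model (regional transit time, global decay and
  epsilon) with a 3 T BOLD observer;
* cross-spectral data features (multivariate autoregression, with a Welch
  oracle) fitted by variational Laplace — Gauss–Newton ascent on a free
  energy `F = log p(y|θ) + log p(θ) + ½log|2πΣ|` — giving each
  subject-session a Gaussian posterior and an evidence bound;
* hierarchical parametric empirical Bayes: one pooled estimate per
  (timespan, session) cell — six two-hour bins from 09:00 to 21:00, two
  phase-encoding sessions — then a second level over the 12 cells, scored
  against 18 competing time-of-day design matrices (single-timespan
  deviations, adjacent-pair deviations, phase-shifted circadian sinusoids,
  and a null model) by Bayesian model reduction and compared through
  softmax of free energies, with Bayesian model averaging and Cohen's d
  effect sizes;
* a seeded synthetic cohort generator that produces multi-subject,
  multi-session ROI time series from the same generative model, with
  injectable group effects on any parameter, so every stage is scorable.

The package is a library: import it, or run the narrative scripts in
`examples/`.

## Worked example

`examples/full_timeofday_analysis.py` simulates a cohort of 32 subjects per
timespan (4 ROIs, 400 volumes, TR 0.72 s) with a morning effect — model 7,
a deviation over the 09:00–13:00 timespans — injected *only* into the
hemodynamic decay parameter (0.1 on its log scale, against a between-subject
SD of 0.1), inverts all 384 subject-sessions, and runs the hierarchical
analysis twice:

```
384 subject-sessions, 384 converged ({'simulate_s': 13.553, 'invert_s': 35.745, 'peb_s': 6.853})

connectivity analysis: winning model 18
  model 18: posterior probability 1.000
  model  5: posterior probability 0.000
  model  1: posterior probability 0.000

hemodynamic analysis: winning model 7
  model  7: posterior probability 0.989
  model  2: posterior probability 0.008
  model 14: posterior probability 0.001

hemodynamic effect sizes (Cohen's d): {'decay': 0.942, 'alpha_v': 0.067}

mean effective connectivity (Hz, from columns to rows, pp>0.95):
        roi1    roi2    roi3    roi4
roi1  -0.439   0.148  -0.143  -0.166
roi2  -0.226  -0.436  -0.098  -0.020
roi3  -0.120  -0.078  -0.437  -0.099
roi4   0.209  -0.094   0.186  -0.442
```

Reading it: the connectivity analysis finds no time-of-day structure (the
null model 18 wins outright — correct, nothing was injected there), while
the hemodynamic analysis decisively selects the morning model 7 and
recovers the injected standardized decay effect (true d = 1.0, estimated
0.94; the untouched CSD amplitude stays near zero).  The connectivity table
shows posterior mean coupling in Hz with sub-threshold entries blanked; the
diagonal self-inhibition rates sit near the −0.5 Hz reference.

The other examples build the 18-design space (`design_space.py`), check the
simulator against the analytic spectrum (`simulate_and_check_spectra.py`),
and score single-subject parameter recovery (`invert_single_subject.py`).

## Layout

```
src/chronodcm/
  model_space.py   timespan allocation, 18 second-level designs
  synthetic.py     seeded cohort generator (the ground-truth machine)
  preprocess.py    sphere ROIs, eigenvariates, nuisance regression
  forward.py       neuronal + Balloon model and its cross-spectrum
  spectra.py       MAR / Welch estimators, feature mapping
  inversion.py     variational Laplace, priors, subject fits
  peb.py           empirical Bayes, model reduction/comparison/averaging
  pipeline.py      end-to-end orchestration and reporting
docs/methods.md    the model, assumptions, numerical choices, limitations
```
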