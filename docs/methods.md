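# Methods

## The signal model

Diffusion-weighted MRI of perfused tissue mixes true molecular diffusion
with perfusion-driven pseudo-diffusion (intravoxel incoherent motion, IVIM).
The two-compartment (bi-exponential) model is

    S(b) = S0 [ PF e^(-b D_fast) + (1 - PF) e^(-b D_slow) ],

with the b-value in s/mm^2 and both coefficients in mm^2/s.  Liver tissue
additionally contains a very fast third pool (sinusoidal/vascular), giving
the three-compartment model

    S(b) = S0 [ F_slow e^(-b D_slow) + F_fast e^(-b D_fast)
                + F_vfast e^(-b D_vfast) ],

with F_slow + F_fast + F_vfast = 1 and D_slow < D_fast < D_vfast.  The
bi-exponential PF corresponds to F_fast + F_vfast =: F_tot.

## The shifted-start identity and the Y_i estimator

If the bi-exponential fit is anchored at a nonzero start b_i (normalising
by S(b_i) and fitting only b >= b_i), the decay rates are unchanged and the
apparent perfusion fraction becomes

    PF_i = PF e^(-b_i D_fast) / [ PF e^(-b_i D_fast) + (1-PF) e^(-b_i D_slow) ],

whose log-odds is exactly linear in b_i:

    Y_i := ln[(1 - PF_i)/PF_i] = b_i (D_fast - D_slow) + ln[(1 - PF)/PF].

The estimator therefore repeats the segmented fit over the start grid
b_i = 2, 4, 7, 10, 15, 20 s/mm^2, transforms the fitted PF_i, and fits an
unweighted ordinary-least-squares line to (b_i, Y_i).  Then

* `d_fast_yi = slope + d_slow`, with d_slow from the shared high-b
  mono-exponential step — a pseudo-diffusion estimate supported by every
  grid start rather than a single fit;
* the intercept encodes the perfusion fraction of the *bi-exponential part*
  of the signal.  Because every fit starts at b >= 2 and the very fast pool
  has decayed by then, the intercept fraction is normalised to the
  vfast-free sub-signal: it estimates F_fast / (F_fast + F_slow).  The
  package converts it to the absolute compartment fraction with

      F_fast = (1 - F_tot) e^(-intercept),      F_vfast = F_tot - F_fast,

  where F_tot is the conventional segmented PF at b = 0.  This
  renormalisation is exact under the three-compartment model whenever the
  very fast pool is gone by the first grid point; the naive inverse-logit
  (available via `vfast_correction=False`) instead returns
  F_fast/(1 - F_vfast), which overshoots by F_vfast·F_fast/(1-F_vfast)
  (~0.024 at the default fractions) even on noiseless data.

b = 0 is never part of the line: the very fast pool inflates PF_0, so Y_0
sits systematically below the line.  The extrapolated residual at b = 0
(`residual_b0`) is the diagnostic for that component, and including b = 0
in the fit measurably lowers R^2 — both behaviours are asserted in the
tests on synthetic tri-exponential data.

## Fitting conventions

* **Segmented fit.**  OLS of ln S on (b - b_start) over the high-b subset
  gives -D_slow (slope) and, through the intercept extrapolated back to the
  start, PF_i = 1 - e^intercept / S(b_start).  A one-parameter bounded
  nonlinear least-squares step then determines D_fast over all b >= b_start
  with the other two fixed and S(b_start) as normalisation.
* **Threshold.**  The mono-exponential subset is b > 60 s/mm^2 (exclusive,
  i.e. the six points 72–600 on the default scheme; configurable via
  `include_threshold`).  The exclusive convention halves the bias described
  below.
* **Bounds** (mm^2/s): D_slow in [1e-4, 3e-3], D_fast in [3e-3, 0.5],
  D_vfast in [0.1, 10]; fractions in [0, 1].  Disjoint rate intervals
  enforce the compartment ordering.  Solutions pinned at a bound are
  flagged `converged=False`.
* **Initialisation** is deterministic: the full bi-exponential fit starts
  from the segmented result; the tri-exponential fit from
  (0.7, 0.15, 0.15, 1e-3, 50e-3, 0.5).  No random restarts, so identical
  inputs give bit-identical outputs.  Convergence tolerances are 1e-10
  (ftol/xtol/gtol), max 1000 evaluations.
* **Tri-exponential fit.**  Six free parameters with S(0) fixed as
  normalisation and fractions renormalised to unit sum afterwards; a
  five-parameter variant with the sum constraint built in is available
  (`constrain_sum=True`).  Both recover noiseless truth to <0.02 on
  fractions and <10% on rates in the tests.
* **High-b weighting.**  The log-linear step is unweighted; the per-b NSA
  counts drive only the noise simulation.

### Intrinsic accuracy limit of the segmented step

On the 16-b scheme the fast compartment is not fully decayed at the first
mono-exponential point (at D_fast = 50e-3, the remnant at b = 72 is ~0.7%
of the slow signal).  The OLS intercept inherits this, biasing PF_i by
about -3e-3 at the canonical liver parameters (pf 0.2, D_slow 1e-3, D_fast
50e-3) and up to ~0.02 for slow D_fast (35e-3) combined with high pf
(~0.4).  Propagated through the log-odds line this caps the noiseless
accuracy of the Y_i estimator at roughly +2.3% on d_fast_yi, 2.4e-3 on
F_fast, and R^2 ~ 1 - 8e-6 for the canonical parameters.  These are
properties of the method, not of the implementation: a dual-route test
checks the fitted values against hand-written normal equations on the
exact log-signal to 1e-12.  Tolerances in the test suite are set at these
measured limits.

## PF_i validity window

The log-odds transform is usefully linear only for PF_i roughly in
(0.05, 0.4); below 0.05 a small PF error explodes in Y.  Fitted grid
points outside the window are dropped from the line by default
(`window_policy="drop"`, falling back to all valid points if fewer than
three survive); `"flag"` retains them for a strictly fixed-grid analysis.
The drop policy is what makes the estimator robust at the simulated noise
level: an ROI-mean curve at per-excitation SNR 100 pushes PF_20 below 0.05
in about half the scans, and retaining those points lets their amplified
log-odds noise dominate the slope.

QC at scan level: the line's R^2 must reach 0.5, the conventional PF at
b = 0 must lie in (0.001, 0.6), and every component fit must converge;
failures are reported with reasons and excluded from cohort statistics
(the `repro` command applies exclusions as a common cohort across methods,
so all methods see the same scans).

## Synthetic data

`generate_decay` evaluates the tri-exponential forward model and applies
magnitude (Rician) noise per excitation — each of NSA repeats is the
magnitude of a complex Gaussian centred on the noiseless value — then
averages the repeats, exactly as a scanner averages NSA.  SNR is defined
at b = 0 per excitation (sigma = S0/snr); default 100.  The sample mean is
validated against the closed-form Rician mean and the NSA averaging
against the 1/sqrt(NSA) law.

Default truth for cohorts: F_fast = 0.150, F_vfast = 0.136 (healthy-liver
means), D_slow = 1.0e-3, D_fast = 55e-3 mm^2/s.  D_vfast = 2.0 mm^2/s is
calibrated so that the apparent PF drops from ~0.28 at b = 0 to ~0.145 at
b = 2 — the observed signature of the very fast pool vanishing between
b = 0 and the first nonzero b-value; a slower pool (e.g. 0.5) would leave
37% of it at b = 2 and contradict that drop.  Between-subject spread is
15% relative SD per parameter (truncated normals respecting the model
invariants) and the rescan perturbation is 5% relative — a plausible
physiological day-to-day change; neither is identifiable from published
group summaries, so both are package choices, configurable in
`CohortSpec`.

One master seed drives a cohort through
`SeedSequence([seed, subject, session])`, making every subject
reproducible independently of cohort size.

What the generator does **not** emulate: respiratory motion, per-slice ROI
editing, partial-volume and T2/TE compartment weighting, spatially
correlated noise, and the effective-b-value deviation of real gradients
(nominal b-values are treated as exact).  Passing the simulation tests
therefore demonstrates correctness of the estimators under the stated
noise model, not clinical performance.

## Scan-rescan statistics

CoV = sample SD (n-1) / mean over all scans; wSD = sqrt(sum d_i^2 / 2n)
over pairs; Bland-Altman mean difference with 1.96-SD limits; ICC(2,1)
(two-way random effects, absolute agreement, single measurement) from the
ANOVA mean squares, with ICC(3,1) by flag.  A fully degenerate table is
defined as ICC 1.  The Monte-Carlo comparison in the acceptance script
(100 subjects x 2 scans, SNR 100, Rician) reproduces the expected
stability ranking: the Y_i estimator's d_fast shows roughly half the wSD
and a lower CoV than conventional segmented fitting anchored at b = 0,
whose constrained D_fast step is pulled far above the true rate by the
very fast pool.

## Problem sizes

Simulation-backed checks use 100 subjects (200 scans) per cohort, 100
parameter draws for the closed-form sweeps, and 10^4 replicate draws for
the noise calibration — sizes at which every asserted ordering is several
standard errors wide while the whole suite stays lightweight.

## Known limitations

* d_fast_yi inherits the segmented step's fast-remnant bias (~+2-3% at
  liver-typical parameters); an unbiased variant would need a higher
  threshold or an iterative remnant correction, both outside the method's
  definition.
* The estimator deliberately does not recover D_vfast.
* The Y_i line is fitted unweighted although PF_i at large b_i is noisier;
  the validity window, not weighting, is the robustness mechanism.
* Pixelwise maps run the same per-curve estimators per voxel; at voxel-level
  SNR many voxels fail QC and are returned as NaN with the QC map alongside.
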