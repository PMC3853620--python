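# Methods

## The forward model

A brief (sub-second) stimulus elicits a burst of sympathetic sudomotor nerve
activity (SNA), which the sweat glands transduce into a phasic skin
conductance response.  The peripheral transduction is treated as linear and
time-invariant, so the observed conductance is the convolution of a neural
input train with a response function, plus slow tonic drift and measurement
noise.  Under the additional assumption that each burst is infinitely short
and occurs at the stimulus, estimation reduces to ordinary least squares on a
convolution design — the general linear convolution model (GLM).

### Canonical response function

The canonical skin conductance response function (SCRF) is implemented as a
gamma-type curve

    h(t) = (t / tp)^a · exp(a (1 − t / tp)),    a = (tp / d)²,

parameterized by its peak latency `tp` and a dispersion `d`.  By construction
h(0) = 0, h peaks at exactly `tp` with unit amplitude, and decays
monotonically thereafter.  Defaults, registered once and used everywhere:
`tp = 3.5 s`, `d = 1.5 s` (shape a ≈ 5.4), which puts the peak in the
empirically typical 1–6 s window and decays below 1 % of peak well before
60 s.  The unit-peak convention makes the coefficient on the SCRF regressor
directly interpretable as SNA amplitude in μS.  All parameters are exposed
(`SCRFParams`); downstream tests are written against these registered
defaults rather than any external curve, so the package is self-consistent
whatever canonical shape a user substitutes.

### Basis sets

* `scrf` — canonical SCRF only (bf = 1).
* `scrf-td` / `scrf-tdd` — SCRF plus temporal derivative (numerical gradient
  × sampling rate) and optionally a dispersion derivative (central finite
  difference of `d`, step 1 % of its value), bf = 2 / 3.  These Taylor-like
  expansions absorb between-subject latency and width differences.
* `fir15` / `fir30` — contiguous 1 s boxcar bins (bf = 15 / 30), a fully
  nonparametric response model.
* `fourier4` / `fourier8` — constant plus sine/cosine pairs over a 60 s
  window, bf = 2·order + 1 = 9 / 17.  The set is realized as sine *and*
  cosine pairs (not cosines alone) because only 2n + 1 columns yields these
  cardinalities.
* `srf` — a subject-specific response function: peristimulus epochs of the
  minimum stimulus onset asynchrony (8.65 s in the slow paradigm) are
  stacked, column-mean centered, and decomposed by PCA; the first component
  over time (sign-flipped so its extreme is positive) is fitted with the
  impulse response of a second-order linear ODE
  (h'' + a₁h' + a₀h = g·δ, three free parameters, stability enforced via
  positivity bounds) by `scipy.optimize.least_squares`; the unit-peak fitted
  curve becomes a one-column basis.  Centering before PCA is a documented
  choice; the short epoch window is a known weakness of this estimator.

### Orthogonalization

Multi-column sets are serially Gram-Schmidt orthogonalized (first column
bit-exact, later columns residualized, no renormalization) at two levels:

1. **Basis level** (`scrf-td`, `scrf-tdd`): derivative columns are
   residualized against the SCRF so their coefficients capture only shape
   deviation.
2. **Regressor level** (in `build_design`): after convolution and filtering,
   every non-primary regressor (higher basis functions, parametric
   modulators) is residualized against the span of the constant, all primary
   (first-basis-function) regressors, and previously processed columns, via
   a joint least-squares projection.  Basis-level orthogonality does not
   survive convolution with overlapping delta trains and filtering; the
   regressor-level step makes the central invariance *exact*: adding
   derivative regressors cannot move the canonical coefficients (the normal
   equations decouple).  The unit-triangular mixing matrix of this
   residualization is stored, and coefficients are mapped back to basis
   coordinates for response reconstruction, so noise-free amplitude recovery
   is also exact.

### Amplitude readout

For bf = 1 the SNA estimate is the coefficient itself.  For richer sets the
per-condition response is reconstructed as Σ_i β_i b_i(τ) (basis
coordinates, unmodulated regressors only) and the estimate is the waveform's
value at its point of largest absolute value, sign retained.  Parametric
modulators — per-trial covariates mean-centered within condition and
multiplied onto the delta masses — get their own reconstructed-peak readout.

## Preprocessing

First-order Butterworth filters, always applied exactly twice:
*bidirectional* (forward then backward) is zero-phase and preserves peak
latency; *unidirectional* applies two forward passes so the effective order
matches.  Filtering uses zero initial state and no padding; edge transients
are therefore real and documented, and the tests measure steady-state
behaviour.  The standard chain is a 5 Hz bidirectional low-pass
(anti-alias), the high-pass of choice, then decimation by sample-picking to
the 10 Hz model rate; both filters run at the acquisition rate.  The default
high-pass is 0.05 Hz unidirectional; 0.0159 Hz bidirectional (a 10 s time
constant) is the legacy setting.  Regressors pass through the identical
filter routine as the data.  Recordings with block breaks are filtered as
one continuous trace by default.

The recording-chain helpers model a constant-voltage coupler that maps
conductance affinely to pulse frequency (offset 100 Hz, gain 31 Hz/μS,
50 μS ↔ 1650 Hz).

## Peak-scoring baselines

Trough-to-peak scoring: within a post-stimulus latency window ((1, 4) s or
(1, 3) s), the response onset is the local minimum preceding the steepest
positive slope (the steepest-slope point itself is selectable, since the
published onset criterion is ambiguous); the score is the maximum within
(0.5, 5) s after onset minus the onset value; scores below 0.01 μS are
non-responses (zero).  *Magnitude* averages all trials, *amplitude* averages
responders only and is undefined (NaN) with no responders.  The simpler
peak-minus-baseline variant subtracts a 1 s pre-stimulus mean from the
(1, 4) s post-stimulus maximum, unthresholded, so negative scores are
possible.  Scoring is intended for the low-pass-filtered trace; the methods
are invariant to constant offsets by construction.

## Trial-wise nonlinear model

Each trial's burst has free onset shift ∈ [0, 2] s after the stimulus, free
duration (SD of a unit-mass Gaussian; 0 degenerates to a delta) and free
nonnegative amplitude, convolved with the unit-peak SCRF and summed over
trials plus a constant offset.  All 3N parameters are estimated jointly by
bounded least squares (`scipy.optimize.least_squares`, trust-region
reflective) with a multistart over initial onset shifts {0, 0.5, 1.0, 1.5} s,
because overlapping responses at 4.4 s onset asynchrony make per-trial greedy
fitting inconsistent.  This model strictly nests the single-trial GLM, so its
RSS can only be lower.  Joint bounded least squares is this package's own
estimator for this model class; probabilistic (variational) inversion
schemes are out of scope.

## Model comparison

Within-subject fit: LL = n·log(RSS/n) (natural log; RSS = 0 is rejected as
degenerate), AIC = LL + 2k with k the number of non-constant regressors
(bf × j for standard designs, bf × N for single-trial, 3N for the nonlinear
model; the intercept is excluded from k).  Predictive validity: a
second-level GLM with the contrast code (±1 on two conditions; pairwise for
three-condition designs) as response and the SNA estimates plus subject
indicator columns as predictors; its RSS converts to LL by the same
relation, with n the number of (subject, condition) observations.  The LL
difference between two estimate sets is reported as a log Bayes factor;
|LBF| > 3 (strict) is flagged decisive.  LBF differences are invariant to
affine recoding of the contrast and to per-subject mean shifts of the
estimates (absorbed by the subject effects) — both are property-tested.
Trial-wise explained variance: per-subject R² of single-trial estimates on
per-trial predictors (e.g. normative arousal and trial index); the group
summary sums n_s·log(RSS_s/TSS_s) over subjects — the per-subject relative
residual variance passed through the LL relation.

## Synthetic cohorts

`simulate_subject` generates: trial amplitude = condition mean ×
(1 − slope·(rank − 1)) + N(0, trial SD), floored at 0 (an exponential
habituation variant is available); a unit-mass delta at the stimulus
(optionally jittered in latency per trial) convolved with a per-subject SCRF
whose peak latency is shifted by N(0, latency SD) and dispersion scaled by
1 + N(0, scale SD); plus sub-0.01 Hz sinusoidal drift with random phases, an
optional random walk, and white noise.  Everything derives from
`(seed, subject_index)` via `numpy` SeedSequence spawning, so cohorts
regenerate bit-identically from the written YAML manifest.

Paradigm presets: `exp1` (2 conditions × 45 trials, 1 s stimuli, ISI drawn
from {7.65, 9, 10.35} s → minimum onset asynchrony 8.65 s, 3 blocks with
45 s breaks) and `exp2` (3 conditions × 16 trials, fixed 4.4 s ISI, one
block).  Default condition means 0.3 / 0.6 / 0.5 μS (neutral / aversive /
positive) with 0.1 μS trial SD and habituation slope 0.007 per trial — values
chosen once as representative of picture-viewing electrodermal experiments,
where aversive-vs-neutral effects are roughly half the neutral baseline
response and responses decline by a few tenths over an experiment.
Between-subject response-function variability defaults to 0.3 s latency SD
and 10 % dispersion SD, sized so that canonical-only estimation is visibly
misfit (inter-individual variability of this order is what motivates the
derivative regressors); drift sinusoids default to 0.5/0.3/0.2 μS at
0.002/0.006/0.01 Hz.

What the simulator does *not* emulate: spontaneous (non-evoked) SCR
fluctuations, motion and pressure artefacts, electrode drift nonstationarity,
skewed amplitude distributions, or peripheral nonlinearity (saturation).
Passing recovery tests therefore shows estimator correctness under the
model's own assumptions plus the listed perturbations — not robustness to
every feature of real recordings.

## Numerical choices and degenerate inputs

Onsets map to samples by `round(onset × rate)` with ties to even.  OLS uses
`numpy.linalg.lstsq`; rank-deficient designs warn and return the
minimum-norm solution.  Gram-Schmidt keeps a column that lies in its
predecessors' span as an explicit zero column with a warning; an all-zero
first column is an error.  A constant parametric modulator (zero variance
after centering) is an error.  Filters reject cutoffs at or above Nyquist,
and the preprocessing chain additionally rejects high-pass cutoffs above the
post-decimation Nyquist.  Downsampling requires an integer rate ratio.
Stochastic cohort-level tests use 20 cohorts of 20 subjects on the `exp1`
schedule — large enough for the qualitative orderings to be stable across
seeds while the full suite runs in well under a minute.

## Known limitations

* The canonical SCRF shape is a registered package default, not a population
  estimate; absolute amplitude estimates scale with the assumed kernel.
* The SRF estimator inherits the short-epoch bias noted above, and a
  second-order ODE impulse response cannot represent the gamma-type default
  kernel exactly (its fit R² is reported).
* The nonlinear trial-wise estimator's objective is non-convex; the
  multistart mitigates but does not guarantee global optimality.
* AIC is used as the model-evidence approximation throughout; no
  cross-validated or fully Bayesian evidence is computed.
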