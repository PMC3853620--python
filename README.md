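# scrglm

Model-based analysis of evoked skin conductance responses (SCR): estimate the
amplitude of the sympathetic nerve activity (SNA) bursts that drive phasic
electrodermal activity, from nothing but the measured conductance trace and
the stimulus timing.

Phasic SCRs are well described by a linear time-invariant peripheral system:
a brief sudomotor burst at the stimulus is convolved with a stereotyped skin
conductance response function (SCRF) to produce the observed response.  That
makes a general linear convolution model the natural estimator — exactly as
in event-related fMRI analysis.  For conditions *c* with onset delta trains
*u_c(t)* and basis functions *b_i(τ)*:

    y(t) = Σ_c Σ_i β_{c,i} (u_c * b_i)(t) + β_0 + ε(t)

Data and regressors pass through the identical first-order Butterworth
high-pass filter, ordinary least squares yields the β, and the SNA amplitude
per condition is read off as the peak of largest modulus of the reconstructed
response Σ_i β_{c,i} b_i(τ).  Available basis sets: canonical SCRF alone or
with its temporal and dispersion derivatives, FIR boxcar sets (15/30 bins),
cosine/Fourier sets (9/17 columns), and a subject-specific response function
estimated from peristimulus epochs via PCA plus a second-order-ODE fit.
Alongside the GLM the package provides classical trough-to-peak scoring
baselines, a trial-wise nonlinear burst estimator (free onset, duration,
amplitude within 2 s of each stimulus), model comparison via
LL = n·log(RSS/n), AIC = LL + 2k and log Bayes factors, a second-level
predictive-validity GLM, and a forward simulator of whole cohorts so every
estimator is testable by parameter recovery.

Intended users: psychophysiologists analysing event-related electrodermal
data, and methodologists benchmarking SCR analysis pipelines.

## Worked example

Simulate one subject of a picture-viewing paradigm (2 conditions × 45 trials,
1 s stimuli, ISI ∈ {7.65, 9, 10.35} s, three blocks), with between-subject
response-function variability, then estimate condition SNA amplitudes:

```python
from scrglm import exp1_config, simulate_subject, FilterSpec
from scrglm.pipeline import subject_sna
from scrglm.synth import RFJitter
from scrglm.modelcomp import ModelStat, compare_models

cfg = exp1_config(n_subjects=1, seed=7,
                  rf_jitter=RFJitter(latency_shift_sd=0.3,
                                     dispersion_scale_sd=0.1))
ts, events, truth = simulate_subject(cfg, 0)
hp = FilterSpec("highpass", 0.05, "unidirectional")

stats = []
for name in ("scrf", "scrf-td"):
    amps, fit, basis = subject_sna(ts, events, name, hp)
    print(name, amps, fit.rss, fit.k)
    stats.append(ModelStat(name, fit.rss, fit.n, fit.k))
print(compare_models(stats, reference="scrf", penalize=True))
```

Output (10254 samples at 10 Hz, 90 trials):

```
scrf    {'neutral': 0.248, 'negative': 0.507}  RSS=32.763  k=2
scrf-td {'neutral': 0.248, 'negative': 0.508}  RSS=32.390  k=4
  model            LL  k           AIC     n        LBF  decisive
   scrf -58920.807054  2 -58916.807054 10254    0.00000     False
scrf-td -59038.106764  4 -59030.106764 10254 -113.29971      True
```

The estimates recover the ground-truth per-condition means of this simulated
subject (0.245 and 0.507 μS): aversive pictures drive roughly twice the
sympathetic response of neutral ones.  Adding the time-derivative regressors
improves the within-subject fit decisively (LBF = −113 on AIC) while leaving
the canonical amplitude estimates essentially unchanged — the serial
orthogonalization guarantees exactly that.

The same pipeline is scriptable from the shell:

```sh
scrglm simulate out/ --preset exp1 --n-subjects 20 --seed 7
scrglm glm out/sub-00_ts.csv out/sub-00_events.csv fit.json --basis scrf-td
scrglm peakscore out/sub-00_ts.csv out/sub-00_events.csv scores.csv
```

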