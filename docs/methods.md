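# Methods

`prestim` is a testbed for a question that arises whenever event-related
synchronization (ERS) or desynchronization (ERD) is tracked across repeated
learning trials: because ERS/ERD is a *relative* measure (post-stimulus
power against a pre-stimulus baseline), a change across repetitions can
come from the pre-stimulus side, the post-stimulus side, or both. The
package implements the full analysis chain needed to separate the two —
synthetic epoched EEG with known ground truth, sliding-window spectral
estimation, aperiodic/periodic decomposition, individual-alpha-frequency
(IAF) anchored band power, two baseline-correction schemes, and causal
mediation on linear mixed models — and the simulation that motivates the
per-subject baseline scheme.

## Synthetic cohort

`synthgen.generate_epochs` produces epoched EEG for a two-group cohort
(labels `young`/`older`) on a 500 Hz grid from −750 to 1150 ms around
stimulus onset, 8 stimuli per sequence repetition, up to 8 repetitions of
up to 6 sequences per subject. Each epoch is the sum of:

* **Aperiodic background** — Gaussian noise shaped in the frequency domain
  with amplitude ∝ f^(−χ/2), giving exact control of the aperiodic
  exponent χ (default 1.5 young, 1.3 older — the older default encodes the
  usual flatter-slope direction and is documented configuration, not an
  empirical claim). RMS 10 µV.
* **Alpha oscillation** on the parietal channels at the subject's IAF,
  drawn per group from a truncated normal (defaults 10.53 ± 1.25 Hz young,
  10.24 ± 1.40 Hz older, truncated to 7.5–13.5 Hz).
* **Theta burst** on the frontal channels: a Hanning-windowed sinusoid at
  IAF − 5 Hz (so it always falls inside the IAF-relative theta band),
  centered 250 ms post-onset, 400 ms long, plus a small constant
  pre-stimulus theta tone.

The mediation structure lives in the alpha amplitude trajectory, written
on the log10-power scale where the downstream analysis is linear. With
repetition r, subject intercept u_s ~ N(0, σ_u), and per-repetition noise
ε_r ~ N(0, σ_r):

    pre-stimulus log power   x_r = a·(r−1) + u_s + ε_r
    post-stimulus log power  y_r = x_r + d0 + c·(r−1) + (b−1)·ε_r

Amplitudes are `base · 10^(logpower/2)` and switch at stimulus onset.
Under the per-subject baseline scheme the event-related outcome is
`y_r − mean_r(x_r)`, so regressing it on the pre-stimulus term and
repetition recovers a mediator slope of b and a positive direct effect
c + a(1−b); the indirect effect has the sign of a·b. The defaults
(a = 0.06, b = −0.7, c = 0.03, d0 = −0.35) encode rising pre-stimulus
alpha whose increase deepens desynchronization — a negative indirect and
positive direct effect, i.e. the inconsistent-mediation pattern the
analysis is designed to expose. The generator is a study in structure, not
realism: it has no artifacts, no topographic mixing beyond the two-region
split, no inter-channel correlation, stationary 1/f background, and a
phase-random sinusoidal alpha rather than bursty oscillations. Passing
tests therefore certify the *pipeline arithmetic and inference*, not that
real EEG satisfies the generative assumptions.

`generate_power_table` bypasses the signal level entirely and draws
directly from the two-equation mixed system (`prestim = a·rep + u₁ + ε₁`,
`outcome = b·prestim + c′·rep + u₂ + ε₂`, independent subject intercepts)
for testing the mediation machinery at scale. `generate_behavior` draws
per-item recall correctness from a logistic curve in repetition number
(the task literature reports no generative behavioral model, so this is a
deliberate minimal choice) under the stopping rule "three fully-correct
recalls in total, else eight repetitions". `generate_gaze` emits traces
with an exact inside-square fraction for exercising the fixation
classifier.

## Spectral estimation

`spectral.sliding_tfr`: 500 ms Hanning window sliding in 50 ms steps,
zero-padded to a 0.2 Hz grid (the 500 ms window's native resolution is
2 Hz), 1–40 Hz. Time stamps are window centers, so the −750..1150 ms epoch
yields 29 estimates on −500..900 ms. Linear power is averaged across the 8
stimulus epochs of a repetition before the log10 transform. Normalization:
a unit-amplitude sinusoid at a bin center gives 0.25 linear power; a
floor of 1e−30 is added before the log so silent input stays finite (both
recorded in the output container). Epochs with any |amplitude| > 90 µV
are rejected beforehand.

## Aperiodic/periodic decomposition

`specparam.fit_spectrum` models a log10 spectrum as
`offset − exponent·log10(f)` (optionally with a knee) plus Gaussian peaks.
The algorithm: robust aperiodic fit (OLS in log-log space, refit on the
points whose positive residual is below the 2.5th percentile so peaks
cannot drag the curve); iterative peak seeding from the flattened spectrum
(largest maximum above both an absolute floor of 0.05 log10 units and 2 SD
of the flattened spectrum; width guessed from half-height extent; seeds
within one SD of the spectrum edge or overlapping a taller seed within
1.5 SD are dropped); joint nonlinear refinement of all Gaussians with
width bounded to 1–8 Hz bandwidth and at most 6 peaks; aperiodic refit on
the peak-removed spectrum; fitted peaks below the height floor are pruned.
R² is the squared Pearson correlation of model and data. Flat-zero input
returns exponent 0 with undefined R². Aperiodic-adjusted power is the
input minus the reconstructed aperiodic curve only (peaks stay in).

In the pipeline the model is fit per (repetition, channel) on the
time-averaged spectrum and its aperiodic curve subtracted from every time
bin of that repetition/channel — the aperiodic background is treated as
stationary within the 1.9 s epoch. This is a deliberate economy over
fitting all 29 time bins separately; it changes nothing for the band-power
contrasts, which compare time windows under a shared aperiodic estimate.
Repetitions whose channel-averaged R² falls below 0.9 are excluded (QC).

## IAF and bands

The IAF spectrum concatenates all of a subject's epochs and estimates
power with Welch-averaged 5 s Hanning segments (50% overlap), giving a
genuine 0.2 Hz resolution; a sine-free DPSS multitaper variant is
available (`method="multitaper"`). After parameterization and adjustment,
the IAF is the argmax of adjusted power in 7–14 Hz. No IAF is returned
when the argmax sits on the first or last bin of the search grid, or when
the adjusted power there is below 0.05 log10 units — the same minimum
detectable-peak height the parameterization uses, so noise ripple in
peak-free spectra is not reported as alpha. Ties resolve to the lower
frequency with a logged warning. Bands: theta [IAF−6, IAF−4] Hz analyzed
at 100–500 ms, alpha [IAF−4, IAF+2] Hz at 250–900 ms, baseline −500..−250
ms; closed intervals, bin-center inclusion. A theta band reaching below
2 Hz is flagged (it approaches the 1 Hz fit floor) but not rejected.
Subjects without a detected IAF are excluded downstream.

## Baseline schemes

Per repetition: `ers_erd_rep = post − baseline` (log10 units on the
adjusted path; the conventional variant is `10·log10(post/baseline)` on
linear power). Per subject: the average baseline over a sequence's
repetitions is subtracted instead, and the residual
`prestim = baseline − average_baseline` becomes the mediator. Exact
identities, tested to 1e−12: `ers_erd_subj = ers_erd_rep + prestim` and
per-sequence mean prestim = 0.

The `scenarios` module demonstrates why the distinction matters. Four
second-repetition variants of a reference ERD curve (pre-stimulus
increase; post-stimulus decrease; both; decrease in both) are calibrated
to share one post-minus-pre level change: with magnitudes (m_pre, m_post)
the common change is −(m_pre+m_post) and the pre-stimulus shifts are
A: +(m_pre+m_post), B: 0, C: +m_pre, D: −m_pre. Under per-repetition
correction all four corrected curves coincide — computed through an
algebraically equivalent shared expression so the coincidence is bitwise
exact, not merely within rounding — while per-subject correction orders
the pre-stimulus levels by their true shifts. The reference shape (flat
pre level, raised-cosine dip) is a documented choice that the exact
results do not depend on.

## Mixed models and mediation

All mediation variables are z-scored over the included rows. Three models
with subject random intercepts: M0 `outcome ~ repetition`, M
`mediator ~ repetition`, Y `outcome ~ mediator + repetition`. Estimation
delegates to statsmodels `MixedLM` (REML); a fit whose random-intercept
variance collapses to zero falls back to OLS with a logged warning and is
reported as singular. A random intercept requires at least five grouping
levels. Before mediation the treatment effect must be present in M0 or M
(premise check; failure warns rather than aborts). Point estimates:
ACME = a·b, ADE = c′, total = ACME + ADE (exact in this linear,
no-interaction system). ACME and ADE of opposite sign set the
inconsistent-mediation flag; |total| < 0.01 marks the proportion mediated
undefined.

Uncertainty: the primary route is a nonparametric **cluster bootstrap**
resampling subjects with replacement (the random-intercept structure makes
the subject the exchangeable unit) and refitting M and Y per draw, with
percentile CIs and doubled-crossing p-values; refits are warm-started from
the full-data estimates, and failures are dropped and counted. The
secondary route draws (a, b, c′) from independent normals at their
estimates and standard errors (the quasi-Bayesian approximation); it is
orders of magnitude cheaper and serves as the cross-check of the bootstrap
in the test suite. The null-calibration study (coverage of the ACME
interval when b = 0) uses the quasi-Bayesian route with 200 replicate
datasets of 40 subjects so it runs in seconds per replicate on one CPU;
the bootstrap route is exercised at full size (100 subjects × 8
repetitions, 1000 draws) in the parameter-recovery check. Mediation is run
separately per age group and band; the sequence random intercept is
dropped inside the mediation models, which carry only `(1|subject)`.

## Pipeline and problem sizes

`pipeline.run_pipeline` chains generation (or HDF5+TSV ingest) →
amplitude rejection → TFR → decomposition/QC → IAF/bands → band-power
table → per-group mediation, writing every intermediate as TSV/HDF5 plus
a manifest with parameters, seeds, stage counts and a SHA-256 per output;
re-running an unchanged config reproduces the hashes. The documentation
dataset (`pipeline demo`, `demo_config`) uses 20 subjects per group, 8
channels (4 frontal + 4 parietal), one sequence of 8 repetitions, and
quasi-Bayesian mediation CIs — chosen as the smallest cohort that
exercises every stage and reliably shows the inconsistent-mediation
pattern; it completes in about a minute on one CPU.

## Known limitations

* The per-repetition specparam granularity of the reference analysis
  (a fit per 50 ms bin) is replaced by one fit per repetition/channel on
  the time-averaged spectrum; time-resolved aperiodic drift within an
  epoch is therefore not modeled.
* The IAF spectrum uses Welch/sine tapers by default rather than DPSS
  multitapers; the multitaper option exists but is not the default.
* The quasi-Bayesian draws treat a, b and c′ as independent normals; the
  small correlation between b and c′ within model Y is ignored.
* Learning-state thresholds (newly learned / known / very well known as
  1st / 2nd / 3rd cumulative correct recall) are a documented assumption,
  configurable per call.
* Proportion mediated is reported without bias correction and suppressed
  entirely near zero total effect.
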