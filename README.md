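# prestim

**Pre-stimulus oscillatory power, ERS/ERD baseline schemes, and
mixed-model mediation for incremental sequence-learning EEG.**

Event-related synchronization and desynchronization (ERS/ERD) — the
post-stimulus rise of mid-frontal theta power and fall of parietal alpha
power relative to a pre-stimulus baseline — are workhorse measures of
memory formation. But ERS/ERD is a *relative* quantity: when it changes
across repeated learning trials, the change may sit in the pre-stimulus
baseline, in the post-stimulus response, or in both, and the conventional
per-repetition baseline correction cannot tell these apart. `prestim`
implements the analysis chain that can:

* a **synthetic cohort generator** — two age groups, epoched EEG (500 Hz,
  −750..1150 ms around onset) with a 1/f^χ aperiodic background, a
  subject-specific alpha rhythm near 10 Hz whose pre-stimulus power
  drifts with learning, a post-stimulus theta burst, recall behavior
  under the "3 total correct or 8 repetitions" stopping rule, and gaze
  traces — all with known ground truth;
* **sliding-window spectral estimation** (500 ms Hanning window, 50 ms
  steps, zero-padded to 0.2 Hz, estimates on −500..900 ms) with 90 µV
  amplitude rejection;
* **spectral parameterization** into an aperiodic component
  (`offset − exponent·log10 f`) plus Gaussian oscillatory peaks, with
  aperiodic-adjusted power and an R² ≥ 0.9 quality filter;
* **individual alpha frequency (IAF)** detection from a high-resolution
  concatenated-trial spectrum (argmax of adjusted power in 7–14 Hz,
  border peaks rejected), anchoring subject-specific bands: theta
  [IAF−6, IAF−4] Hz at 100–500 ms, alpha [IAF−4, IAF+2] Hz at 250–900 ms;
* **two baseline schemes** — per repetition
  (`ERS/ERD = post − baseline`) and per subject
  (`post − average baseline`), whose difference
  `prestim = baseline − average baseline` is a zero-mean per-repetition
  mediator;
* **causal mediation** on linear mixed models: M
  `prestim ~ repetition + (1|subject)` and Y
  `ERS/ERD ~ prestim + repetition + (1|subject)` give the average causal
  mediation effect ACME = a·b, the average direct effect ADE = c′, and
  total = ACME + ADE, with subject-level cluster-bootstrap or
  quasi-Bayesian confidence intervals. Opposite signs of ACME and ADE
  flag *inconsistent mediation* — the pattern in which a learning-related
  rise of pre-stimulus alpha masks an opposite direct effect on alpha ERD.

A small simulation module (`prestim.scenarios`) proves the motivating
point exactly: second-repetition power trajectories that differ only in
*where* the change happens (pre vs post stimulus) become bitwise identical
after per-repetition baseline correction, and are separated again by
per-subject correction.

## Worked example

```bash
prestim pipeline demo --seed 0 --out-dir demo_out
```

generates the documentation cohort (20 subjects per group, 8 channels,
one sequence of 8 repetitions), runs every stage, and prints the
per-band, per-group mediation table:

```
 band group      acme       ade     total   a_path    b_path  ...  inconsistent
theta young  0.008688 -0.266523 -0.257836 0.087132  0.099705  ...          True
theta older  0.001806 -0.248577 -0.246772 0.057108  0.031618  ...          True
alpha young -0.329266  1.272840  0.943574 0.859107 -0.383265  ...          True
alpha older -0.293694  1.222429  0.928735 0.824301 -0.356295  ...          True
```

Reading the alpha rows (standardized units): pre-stimulus alpha rises
steeply with repetition (`a_path` ≈ 0.86), higher pre-stimulus alpha
deepens the desynchronization (`b_path` < 0), so the indirect effect
`acme = a·b` is negative while the direct effect `ade` is positive — the
generator's built-in suppression structure, recovered end-to-end from raw
synthetic epochs. For theta the generator couples no pre-stimulus drift
into the burst, and the pipeline correctly reports a near-zero ACME with
a negative direct effect (the burst amplitude falls with learning).
Artifacts (`band_power.tsv`, `iaf.tsv`, `mediation.tsv`,
`specparam_qc.tsv`, `manifest.json` with content hashes) land in
`demo_out/`.

The same stages are available as library calls
(`prestim.synthgen.generate_epochs`, `prestim.spectral.sliding_tfr`,
`prestim.specparam.fit_spectrum`, `prestim.iaf.detect_iaf`,
`prestim.erd.build_band_power_table`, `prestim.mediation.mediate`) and as
per-stage CLI subcommands operating on the HDF5 + TSV containers; real
epoched data can enter through the same container format
(`EpochSet.load`, datasets `samples`/`time_axis`, attribute
`sampling_rate`, plus a TSV metadata table with columns subject, group,
sequence, repetition, stimulus, fixation).

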