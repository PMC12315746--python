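"""Synthetic cohort generation.

Everything downstream of this module (time-frequency decomposition, spectral
parameterization, IAF-relative band power, baseline schemes, mediation) is
testable against the ground truth produced here.  Three generators:

``generate_epochs``
    Time-domain epochs: power-law (1/f^chi) Gaussian background + a
    subject-specific alpha sinusoid whose pre-stimulus log power drifts
    linearly across sequence repetitions + a Hanning-windowed post-stimulus
    theta burst.  The alpha trajectory realizes a known
    treatment -> mediator -> outcome path structure on the log10-power
    scale (see :class:`prestim.config.SimConfig`).

``generate_power_table``
    Draws directly from the two-equation linear mixed system
    ``prestim = a*rep + u1 + eps1`` and
    ``outcome = b*prestim + c'*rep + u2 + eps2``
    with random subject intercepts, for mediation-model testing at scale.

``generate_behavior`` / ``generate_gaze``
    Per-item recall correctness under a logistic learning curve with the
    "three total correct or eight repetitions" stopping rule, and gaze
    traces with a controlled fraction of samples inside the central
    fixation square.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = [
    "EpochSet",
    "generate_epochs",
    "generate_power_table",
    "generate_behavior",
    "generate_gaze",
    "powerlaw_noise",
]


@dataclass
class EpochSet:
    """Time-domain epochs indexed by subject/group/sequence/repetition/stimulus.

    ``samples`` is ``[epoch, channel, time]`` in microvolt; ``metadata`` has
    one row per epoch with columns subject, group, sequence, repetition,
    stimulus, fixation.
    """

    samples: np.ndarray
    times: np.ndarray            # ms relative to stimulus onset
    channels: list[str]
    metadata: pd.DataFrame
    sampling_rate: float
    truth: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.samples.shape[0] != len(self.metadata):
            raise ValueError("metadata row count must equal epoch count")
        if self.samples.shape[2] != len(self.times):
            raise ValueError("time axis length mismatch")
        dt = np.diff(self.times)
        step = 1000.0 / self.sampling_rate
        if len(dt) and not np.allclose(dt, step):
            raise ValueError("time axis must be uniform at 1000/fs ms")

    @property
    def n_epochs(self) -> int:
        return self.samples.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            samples=self.samples[mask],
            times=self.times,
            channels=self.channels,
            metadata=self.metadata.loc[mask].reset_index(drop=True),
            sampling_rate=self.sampling_rate,
            truth=self.truth,
        )

    # -- HDF5 + TSV container --------------------------------------------
    def save(self, h5_path: str | Path, tsv_path: str | Path | None = None):
        h5_path = Path(h5_path)
        if tsv_path is None:
            tsv_path = h5_path.with_suffix(".tsv")
        with h5py.File(h5_path, "w") as f:
            f.create_dataset("samples", data=self.samples)
            f.create_dataset("time_axis", data=self.times)
            f.attrs["sampling_rate"] = self.sampling_rate
            f.attrs["channels"] = list(self.channels)
        self.metadata.to_csv(tsv_path, sep="\t", index=False)

    @classmethod
    def load(cls, h5_path: str | Path, tsv_path: str | Path | None = None):
        h5_path = Path(h5_path)
        if tsv_path is None:
            tsv_path = h5_path.with_suffix(".tsv")
        with h5py.File(h5_path, "r") as f:
            samples = f["samples"][()]
            times = f["time_axis"][()]
            fs = float(f.attrs["sampling_rate"])
            channels = [c.decode() if isinstance(c, bytes) else str(c)
                        for c in f.attrs["channels"]]
        metadata = pd.read_csv(tsv_path, sep="\t")
        return cls(samples, times, channels, metadata, fs)


def powerlaw_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    n_times: int,
    sampling_rate: float,
    exponent: float,
    rms_uv: float,
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to f^-exponent.

    White Gaussian noise is shaped in the frequency domain (amplitude
    proportional to f^(-exponent/2)), which gives exact control of the
    target aperiodic exponent; the result is rescaled to the requested RMS.
    """
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sampling_rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    z = rng.standard_normal(shape + (len(freqs),)) + 1j * rng.standard_normal(
        shape + (len(freqs),)
    )
    x = np.fft.irfft(z * amp, n=n_times, axis=-1)
    scale = x.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return x / scale * rms_uv


def _truncated_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def generate_epochs(config: SimConfig, seed: int | None = None) -> EpochSet:
    """Generate the full synthetic epoched EEG cohort.

    Per subject: IAF drawn from the group distribution (truncated), a random
    alpha log-power intercept ``u_s``.  Per sequence repetition ``r`` the
    pre-stimulus alpha log power is ``x = a*(r-1) + u_s + eps_r`` and the
    post-stimulus alpha log power ``x + d0 + c'*(r-1) + (b-1)*eps_r``, so
    that regressing the per-subject-baselined event-related power on
    pre-stimulus power and repetition recovers slopes ``b`` and (approx.)
    a direct effect term; amplitudes scale as ``10**(logpower/2)``.

    The alpha sinusoid is placed on the parietal channels, the theta burst
    (carrier IAF - 5 Hz, Hanning envelope) and the constant pre-stimulus
    theta tone on the frontal channels.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    fs = config.sampling_rate
    t0, t1 = config.epoch_window
    n_t = int(round((t1 - t0) * fs / 1000.0))
    times = t0 + np.arange(n_t) * 1000.0 / fs
    t_sec = times / 1000.0
    post_mask = times >= 0

    channels = list(config.channels)
    n_ch = len(channels)
    frontal_idx = np.arange(config.n_frontal)
    parietal_idx = np.arange(config.n_frontal, n_ch)

    burst_half = config.theta_burst_duration / 2.0
    burst_mask = np.abs(times - config.theta_burst_latency) <= burst_half
    burst_env = np.zeros(n_t)
    if burst_mask.any():
        phase = (times[burst_mask] - (config.theta_burst_latency - burst_half))
        burst_env[burst_mask] = 0.5 * (
            1 - np.cos(2 * np.pi * phase / config.theta_burst_duration)
        )

    all_samples = []
    meta_rows = []
    truth_rows = []

    for group in config.groups:
        chi = config.aperiodic_exponent[group]
        for s_idx in range(config.n_subjects_per_group):
            subject = f"{group[0]}{s_idx + 1:03d}"
            iaf = _truncated_normal(
                rng, config.iaf_mean[group], config.iaf_sd[group],
                *config.iaf_truncate,
            )
            u_s = rng.normal(0.0, config.alpha_subject_sd)
            theta_f = iaf - 5.0

            for seq in range(1, config.n_sequences + 1):
                for rep in range(1, config.max_repetitions + 1):
                    eps = rng.normal(0.0, config.alpha_rep_sd)
                    x_pre = config.alpha_pre_slope * (rep - 1) + u_s + eps
                    x_post = (
                        x_pre
                        + config.alpha_event_change
                        + config.alpha_post_slope * (rep - 1)
                        + (config.alpha_prestim_coupling - 1.0) * eps
                    )
                    amp_pre = config.alpha_base_amp_uv * 10 ** (x_pre / 2.0)
                    amp_post = config.alpha_base_amp_uv * 10 ** (x_post / 2.0)
                    theta_amp = config.theta_burst_amp_uv * 10 ** (
                        config.theta_post_slope * (rep - 1) / 2.0
                    )
                    truth_rows.append(
                        dict(subject=subject, group=group, sequence=seq,
                             repetition=rep, iaf=iaf, alpha_logpow_pre=x_pre,
                             alpha_logpow_post=x_post, u_subject=u_s)
                    )

                    noise = powerlaw_noise(
                        rng, (config.n_stimuli, n_ch), n_t, fs, chi,
                        config.noise_scale_uv,
                    )
                    epochs = noise
                    # alpha on parietal channels: amplitude steps at onset
                    if len(parietal_idx) and config.alpha_base_amp_uv > 0:
                        ph = rng.uniform(0, 2 * np.pi, size=config.n_stimuli)
                        carrier = np.sin(
                            2 * np.pi * iaf * t_sec[None, :] + ph[:, None]
                        )
                        env = np.where(post_mask, amp_post, amp_pre)
                        alpha_sig = carrier * env[None, :]
                        epochs[:, parietal_idx, :] += alpha_sig[:, None, :]
                    # theta on frontal channels: constant tone + burst
                    if len(frontal_idx):
                        ph = rng.uniform(0, 2 * np.pi, size=config.n_stimuli)
                        carrier = np.sin(
                            2 * np.pi * theta_f * t_sec[None, :] + ph[:, None]
                        )
                        theta_sig = carrier * (
                            config.theta_pre_amp_uv
                            + theta_amp * burst_env[None, :]
                        )
                        epochs[:, frontal_idx, :] += theta_sig[:, None, :]

                    all_samples.append(epochs)
                    for stim in range(1, config.n_stimuli + 1):
                        meta_rows.append(
                            dict(subject=subject, group=group, sequence=seq,
                                 repetition=rep, stimulus=stim,
                                 fixation=int(
                                     rng.random() < config.fixation_kept_prob
                                 ))
                        )

    samples = np.concatenate(all_samples, axis=0)
    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    return EpochSet(samples, times, channels, metadata, fs, truth=truth)


def generate_power_table(
    config: SimConfig,
    seed: int | None = None,
    n_subjects: int | None = None,
    standardize: bool = False,
    share_subject_intercept: bool = False,
) -> pd.DataFrame:
    """Draw per-subject, per-repetition (prestim, outcome) pairs.

    ``prestim = a*rep + u1 + eps1``; ``outcome = b*prestim + c'*rep + u2 +
    eps2`` with independent N(0, subject_intercept_sd) random intercepts per
    subject (a single shared intercept when ``share_subject_intercept``).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    if config.subject_intercept_sd < 0 or config.residual_sd < 0:
        raise ValueError("variance components must be non-negative")

    n_sub = n_subjects or config.n_subjects_per_group
    reps = np.arange(1, config.max_repetitions + 1)
    rows = []
    for group in config.groups:
        for i in range(n_sub):
            subject = f"{group[0]}{i + 1:03d}"
            u1 = rng.normal(0, config.subject_intercept_sd)
            u2 = u1 if share_subject_intercept else rng.normal(
                0, config.subject_intercept_sd
            )
            e1 = rng.normal(0, config.residual_sd, size=len(reps))
            e2 = rng.normal(0, config.residual_sd, size=len(reps))
            prestim = config.path_a * reps + u1 + e1
            outcome = (
                config.path_b * prestim + config.path_c_prime * reps + u2 + e2
            )
            for r, m, y in zip(reps, prestim, outcome):
                rows.append(dict(subject=subject, group=group,
                                 repetition=int(r), prestim=m, ers_erd=y))
    table = pd.DataFrame(rows)
    if standardize:
        from .mediation import standardize as _std
        table = _std(table, ["repetition", "prestim", "ers_erd"])
    return table


def generate_behavior(config: SimConfig, seed: int | None = None
                      ) -> pd.DataFrame:
    """Per-item recall correctness under the logistic learning curve.

    Returns a long table (subject, group, sequence, repetition, item,
    correct).  A sequence terminates after ``completion_correct_total``
    fully-correct repetitions (not necessarily consecutive) or
    ``max_repetitions``, matching the task's stopping rule.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    rows = []
    for group in config.groups:
        slope = config.learning_slope[group]
        offset = config.learning_offset[group]
        for i in range(config.n_subjects_per_group):
            subject = f"{group[0]}{i + 1:03d}"
            for seq in range(1, config.n_sequences + 1):
                n_full = 0
                for rep in range(1, config.max_repetitions + 1):
                    from scipy.special import expit
                    p = float(expit(slope * (rep - offset)))
                    correct = rng.random(config.n_stimuli) < p
                    for item, c in enumerate(correct, start=1):
                        rows.append(dict(subject=subject, group=group,
                                         sequence=seq, repetition=rep,
                                         item=item, correct=int(c)))
                    if correct.all():
                        n_full += 1
                    if n_full >= config.completion_correct_total:
                        break
    return pd.DataFrame(rows)


def generate_gaze(
    config: SimConfig,
    inside_fraction: float = 1.0,
    n_trials: int = 1,
    seed: int | None = None,
    square_side_deg: float = 1.26,
    outside_offset_deg: float = 5.0,
) -> pd.DataFrame:
    """Gaze traces (x, y in degrees) with a controlled inside-square fraction.

    One trace per trial covers the stimulus presentation period at the EEG
    sampling rate.  Exactly ``round(inside_fraction * n_samples)`` samples
    fall inside the central square, the rest at ``outside_offset_deg``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n_samples = int(round(config.stimulus_duration * config.sampling_rate
                          / 1000.0))
    half = square_side_deg / 2.0
    rows = []
    for trial in range(1, n_trials + 1):
        n_in = int(round(inside_fraction * n_samples))
        x = np.full(n_samples, outside_offset_deg)
        y = np.full(n_samples, outside_offset_deg)
        jitter = rng.uniform(-0.9 * half, 0.9 * half, size=(2, n_in))
        x[:n_in] = jitter[0]
        y[:n_in] = jitter[1]
        t = np.arange(n_samples) * 1000.0 / config.sampling_rate
        for k in range(n_samples):
            rows.append(dict(trial=trial, t_ms=t[k], x=x[k], y=y[k]))
    return pd.DataFrame(rows)
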