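"""Configuration objects for the simulation and analysis pipeline.

All tunable parameters of the synthetic cohort and of each analysis stage
live here, with defaults chosen to emulate a two-group (young / older)
sequence-learning EEG study: 500 Hz epochs around stimulus onset, a 1/f
aperiodic background, a subject-specific alpha rhythm near 10 Hz whose
pre-stimulus power drifts with learning, a post-stimulus theta burst, and a
known treatment -> mediator -> outcome path structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: Electrode clusters used for region averaging.  The generic default montage
#: mirrors the cluster sizes of the EGI-128 presets below (8 frontal + 23
#: parietal channels); the E-number lists are shipped as a named preset and
#: accepted as aliases.
EGI_MIDFRONTAL = ("E5", "E6", "E7", "E11", "E12", "E106", "E13", "E112")
EGI_PARIETAL = (
    "E75", "E70", "E83", "E62", "E72", "E67", "E71", "E77", "E76", "E52",
    "E65", "E60", "E61", "E59", "E66", "E78", "E90", "E92", "E85", "E84",
    "E91", "E58", "E96",
)


def default_channels(n_frontal: int = 8, n_parietal: int = 23) -> list[str]:
    """Generic channel labels: ``F1..Fn`` frontal, ``P1..Pn`` parietal."""
    return [f"F{i + 1}" for i in range(n_frontal)] + [
        f"P{i + 1}" for i in range(n_parietal)
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Amplitude trajectories are parameterized on the log10-power scale so the
    mediation path structure is linear in the units the analysis operates in:
    pre-stimulus log power follows ``a * (rep - 1) + u_subj + eps`` and the
    event-related outcome follows ``b * prestim + c' * rep`` by construction
    (see :mod:`prestim.synthgen`).
    """

    n_subjects_per_group: int = 20
    groups: tuple[str, ...] = ("young", "older")
    n_sequences: int = 6
    max_repetitions: int = 8
    completion_correct_total: int = 3
    n_stimuli: int = 8

    sampling_rate: float = 500.0          # Hz
    epoch_window: tuple[float, float] = (-750.0, 1150.0)   # ms
    stimulus_duration: float = 600.0      # ms
    offset_to_onset_isi: float = 1300.0   # ms

    # aperiodic background, per group (log10 power at 1 Hz, exponent chi)
    aperiodic_offset: dict = field(
        default_factory=lambda: {"young": 1.0, "older": 1.0}
    )
    aperiodic_exponent: dict = field(
        default_factory=lambda: {"young": 1.5, "older": 1.3}
    )
    noise_scale_uv: float = 10.0          # RMS of the background, microvolt

    # individual alpha frequency, per group (Hz)
    iaf_mean: dict = field(
        default_factory=lambda: {"young": 10.5277, "older": 10.2362}
    )
    iaf_sd: dict = field(
        default_factory=lambda: {"young": 1.2478, "older": 1.4032}
    )
    iaf_truncate: tuple[float, float] = (7.5, 13.5)

    # alpha oscillation: base amplitude (uV) and log10-power path structure
    alpha_base_amp_uv: float = 8.0
    alpha_pre_slope: float = 0.06      # a: log10 power per repetition (pre)
    alpha_prestim_coupling: float = -0.7   # b: outcome slope on prestim
    alpha_post_slope: float = 0.03     # c': direct log10-power/rep (post)
    alpha_event_change: float = -0.35  # baseline event-related drop (ERD)
    alpha_subject_sd: float = 0.10     # SD of subject intercept, log10 units
    alpha_rep_sd: float = 0.08         # per-repetition noise, log10 units

    # theta burst (post-stimulus ERS); carrier at IAF - 5 Hz so the burst
    # falls inside the IAF-relative theta band by construction
    theta_burst_amp_uv: float = 6.0
    theta_burst_latency: float = 250.0   # ms, burst center
    theta_burst_duration: float = 400.0  # ms, Hanning envelope support
    theta_post_slope: float = -0.04      # log10 power per repetition
    theta_pre_amp_uv: float = 2.0        # constant pre-stimulus theta level

    # behavioral learning curve: P(correct item) = logistic(slope*(rep-offset))
    learning_slope: dict = field(
        default_factory=lambda: {"young": 1.1, "older": 0.55}
    )
    learning_offset: dict = field(
        default_factory=lambda: {"young": 1.5, "older": 3.5}
    )
    fixation_kept_prob: float = 0.9

    # power-table generator (two-equation linear mixed system)
    path_a: float = 0.15
    path_b: float = -0.6
    path_c_prime: float = -0.1
    subject_intercept_sd: float = 0.2
    residual_sd: float = 0.3

    channels: list[str] = field(default_factory=lambda: default_channels())
    n_frontal: int = 8

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views ----------------------------------------------------
    @property
    def frontal_channels(self) -> list[str]:
        return list(self.channels[: self.n_frontal])

    @property
    def parietal_channels(self) -> list[str]:
        return list(self.channels[self.n_frontal:])

    def validate(self) -> None:
        for name in ("iaf_sd", "aperiodic_exponent"):
            for g, v in getattr(self, name).items():
                if not v >= 0:
                    raise ValueError(f"{name}[{g}] must be >= 0, got {v}")
        for name in (
            "alpha_subject_sd", "alpha_rep_sd",
            "subject_intercept_sd", "residual_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for g, m in self.iaf_mean.items():
            if not 7.0 <= m <= 14.0:
                raise ValueError(f"iaf_mean[{g}]={m} outside [7, 14] Hz")
        lo, hi = self.epoch_window
        if not lo < 0 < hi:
            raise ValueError("epoch window must span stimulus onset")
        if self.max_repetitions < self.completion_correct_total:
            raise ValueError(
                "max_repetitions must be >= completion_correct_total"
            )
        burst_end = self.theta_burst_latency + self.theta_burst_duration / 2
        if burst_end > hi:
            raise ValueError("epoch window cannot contain the theta burst")
        import math
        for name in ("alpha_base_amp_uv", "theta_burst_amp_uv",
                     "theta_pre_amp_uv", "noise_scale_uv"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(d["groups"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        for key in ("epoch_window", "iaf_truncate"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SpectralConfig:
    window_ms: float = 500.0
    step_ms: float = 50.0
    taper: str = "hanning"
    pad_resolution_hz: float = 0.2
    fmin: float = 1.0
    fmax: float = 40.0
    reject_threshold_uv: float = 90.0


@dataclass
class SpecParamConfig:
    mode: str = "fixed"               # or "knee"
    max_n_peaks: int = 6
    peak_width_limits: tuple[float, float] = (1.0, 8.0)
    min_peak_height: float = 0.05     # log10 units
    peak_threshold: float = 2.0       # SD of flattened residuals
    qc_threshold: float = 0.9


@dataclass
class BandConfig:
    """IAF-relative bands and analysis windows (all closed intervals)."""
    theta_rel: tuple[float, float] = (-6.0, -4.0)   # Hz relative to IAF
    alpha_rel: tuple[float, float] = (-4.0, 2.0)
    theta_window: tuple[float, float] = (100.0, 500.0)    # ms
    alpha_window: tuple[float, float] = (250.0, 900.0)
    baseline_window: tuple[float, float] = (-500.0, -250.0)


@dataclass
class MediationConfig:
    n_draws: int = 1000
    ci_method: str = "bootstrap"      # or "montecarlo"
    alpha_level: float = 0.05


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    specparam: SpecParamConfig = field(default_factory=SpecParamConfig)
    bands: BandConfig = field(default_factory=BandConfig)
    mediation: MediationConfig = field(default_factory=MediationConfig)
    out_dir: str = "prestim_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for name, sub in (
            ("sim", SimConfig), ("spectral", SpectralConfig),
            ("specparam", SpecParamConfig), ("bands", BandConfig),
            ("mediation", MediationConfig),
        ):
            if name in raw:
                block = raw[name]
                if name == "sim":
                    kwargs[name] = SimConfig.from_dict(block)
                else:
                    for key in ("peak_width_limits", "theta_rel", "alpha_rel",
                                "theta_window", "alpha_window",
                                "baseline_window"):
                        if key in block:
                            block[key] = tuple(block[key])
                    kwargs[name] = sub(**block)
        for name in ("out_dir", "seed", "log_level"):
            if name in raw:
                kwargs[name] = raw[name]
        return cls(**kwargs)
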