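"""Epoch screening and sliding-window time-frequency decomposition.

The decomposition follows the standard short-time FFT recipe for epoched
EEG: a 500 ms Hanning-tapered window slides in 50 ms steps over each epoch,
each segment is zero-padded to a 0.2 Hz frequency grid, and linear power is
averaged over the 8 stimulus epochs of a sequence repetition before the
log10 transform.  Output time stamps are window CENTERS, so an epoch of
-750..1150 ms yields power estimates on -500..900 ms (29 bins): the first
250 ms of the epoch is consumed by the first half-window.

Power normalization: a unit-amplitude sinusoid at a bin center yields 0.25
linear power (amplitude^2 / 4), i.e. ``power = (2|X| / sum(w))^2 / 4``.
A small positive floor (recorded in the output) keeps silent inputs finite
under the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import SpectralConfig
from .synthgen import EpochSet

__all__ = ["SpectralTensor", "reject_epochs", "sliding_tfr"]

#: additive floor on linear power before the log10 transform
POWER_FLOOR = 1e-30


@dataclass
class SpectralTensor:
    """Log10 power, ``[repetition-group, channel, frequency, time]``.

    One slab per (subject, sequence, repetition) group, averaged over the
    stimulus epochs of that repetition; ``meta`` indexes the slabs.
    """

    log_power: np.ndarray
    frequencies: np.ndarray     # Hz
    times: np.ndarray           # ms, window centers
    channels: list[str]
    meta: pd.DataFrame
    window_ms: float = 500.0
    taper: str = "hanning"
    pad_resolution_hz: float = 0.2
    floor: float = POWER_FLOOR
    adjusted: bool = field(default=False)   # True after aperiodic adjustment

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.log_power)):
            raise ValueError("log power must be finite")
        if self.log_power.shape[0] != len(self.meta):
            raise ValueError("meta row count must equal slab count")

    def save(self, h5_path: str | Path, tsv_path: str | Path | None = None):
        h5_path = Path(h5_path)
        if tsv_path is None:
            tsv_path = h5_path.with_suffix(".tsv")
        with h5py.File(h5_path, "w") as f:
            f.create_dataset("log_power", data=self.log_power)
            f.create_dataset("frequencies", data=self.frequencies)
            f.create_dataset("times", data=self.times)
            f.attrs["channels"] = list(self.channels)
            f.attrs["window_ms"] = self.window_ms
            f.attrs["taper"] = self.taper
            f.attrs["pad_resolution_hz"] = self.pad_resolution_hz
            f.attrs["floor"] = self.floor
            f.attrs["adjusted"] = self.adjusted
        self.meta.to_csv(tsv_path, sep="\t", index=False)

    @classmethod
    def load(cls, h5_path: str | Path, tsv_path: str | Path | None = None):
        h5_path = Path(h5_path)
        if tsv_path is None:
            tsv_path = h5_path.with_suffix(".tsv")
        with h5py.File(h5_path, "r") as f:
            return cls(
                log_power=f["log_power"][()],
                frequencies=f["frequencies"][()],
                times=f["times"][()],
                channels=[c.decode() if isinstance(c, bytes) else str(c)
                          for c in f.attrs["channels"]],
                meta=pd.read_csv(tsv_path, sep="\t"),
                window_ms=float(f.attrs["window_ms"]),
                taper=str(f.attrs["taper"]),
                pad_resolution_hz=float(f.attrs["pad_resolution_hz"]),
                floor=float(f.attrs["floor"]),
                adjusted=bool(f.attrs["adjusted"]),
            )


def reject_epochs(
    epochs: EpochSet, threshold_uv: float = 90.0
) -> tuple[EpochSet, float]:
    """Drop epochs whose absolute amplitude exceeds the threshold anywhere.

    Returns the surviving set and the rejected fraction.  Raises if every
    epoch is rejected.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.samples).max(axis=(1, 2))
    keep = peak <= threshold_uv
    rate = 1.0 - keep.mean() if len(keep) else 0.0
    if not keep.any():
        raise ValueError("all epochs rejected by amplitude threshold")
    return epochs.select(keep), float(rate)


def sliding_tfr(
    epochs: EpochSet,
    window_ms: float = 500.0,
    step_ms: float = 50.0,
    taper: str = "hanning",
    pad_resolution_hz: float = 0.2,
    fmin: float = 1.0,
    fmax: float = 40.0,
    average_by: tuple[str, ...] = ("subject", "group", "sequence",
                                   "repetition"),
) -> SpectralTensor:
    """Hanning-tapered sliding-window FFT power, averaged over stimuli.

    Windows that would extend past the epoch edges are not computed, which
    truncates a -750..1150 ms epoch to power estimates centered on
    -500..900 ms.  Linear power is averaged across the epochs of each
    ``average_by`` group (the 8 stimuli of a repetition), then log10-ed.
    """
    fs = epochs.sampling_rate
    n_win = int(round(window_ms * fs / 1000.0))
    n_step = int(round(step_ms * fs / 1000.0))
    if n_step <= 0 or abs(n_step - step_ms * fs / 1000.0) > 1e-9:
        raise ValueError("step must divide evenly into the sample grid")
    n_t = epochs.samples.shape[2]
    if n_win > n_t:
        raise ValueError("window does not fit inside the epoch")

    if taper in ("hanning", "hann"):
        w = np.hanning(n_win)
    elif taper in ("boxcar", "none"):
        w = np.ones(n_win)
    else:
        raise ValueError(f"unknown taper {taper!r}")

    nfft = int(round(fs / pad_resolution_hz))
    if nfft < n_win:
        raise ValueError("pad resolution finer than the native grid required")
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    fsel = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    freqs = freqs[fsel]

    # window start indices; output time stamps are window centers, kept on
    # multiples of step_ms so the default grid is exactly -500..900 in 50 ms
    half = window_ms / 2.0
    t_first = epochs.times[0] + half
    t_last = epochs.times[-1] + 1000.0 / fs - half
    c0 = np.ceil(t_first / step_ms - 1e-9) * step_ms
    centers = np.arange(c0, t_last + 1e-9, step_ms)
    starts = np.round((centers - half - epochs.times[0]) * fs / 1000.0
                      ).astype(int)

    norm = (2.0 / w.sum()) ** 2 / 4.0

    meta_cols = [c for c in average_by if c in epochs.metadata.columns]
    groups = epochs.metadata.groupby(meta_cols, sort=True, dropna=False)
    group_meta = []
    n_groups = groups.ngroups
    out = np.empty(
        (n_groups, len(epochs.channels), len(freqs), len(centers)),
        dtype=np.float32,
    )

    for gi, (key, sub) in enumerate(groups):
        idx = sub.index.to_numpy()
        seg = epochs.samples[idx]          # [stimuli, ch, time]
        pow_acc = np.zeros((seg.shape[1], len(freqs), len(centers)))
        for ti, s in enumerate(starts):
            chunk = seg[:, :, s:s + n_win] * w
            spec = np.fft.rfft(chunk, n=nfft, axis=-1)[..., fsel]
            pow_acc[:, :, ti] = (np.abs(spec) ** 2 * norm).mean(axis=0)
        out[gi] = np.log10(pow_acc + POWER_FLOOR)
        if not isinstance(key, tuple):
            key = (key,)
        group_meta.append(dict(zip(meta_cols, key)))

    meta = pd.DataFrame(group_meta)
    return SpectralTensor(
        log_power=out, frequencies=freqs, times=centers,
        channels=list(epochs.channels), meta=meta,
        window_ms=window_ms, taper=taper,
        pad_resolution_hz=pad_resolution_hz, floor=POWER_FLOOR,
    )


def tfr_from_config(epochs: EpochSet, cfg: SpectralConfig) -> SpectralTensor:
    return sliding_tfr(
        epochs, window_ms=cfg.window_ms, step_ms=cfg.step_ms,
        taper=cfg.taper, pad_resolution_hz=cfg.pad_resolution_hz,
        fmin=cfg.fmin, fmax=cfg.fmax,
    )
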