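"""Parameterization of power spectra into aperiodic and periodic components.

A power spectrum in log10 units is modeled as a 1/f-like aperiodic curve

    L(f) = offset - exponent * log10(f)            (fixed mode)
    L(f) = offset - log10(knee + f**exponent)      (knee mode)

plus a sum of Gaussian oscillatory peaks parameterized by center frequency,
height above the aperiodic curve (log10 units), and bandwidth (2 * the
Gaussian SD).  Fitting is iterative:

1. robust initial aperiodic fit: an ordinary least-squares power-law fit,
   then a refit restricted to the frequencies whose positive residual lies
   below a low percentile, so that oscillatory peaks do not drag the curve;
2. peaks are extracted one at a time from the flattened spectrum: the
   largest maximum above both an absolute height floor and a relative
   threshold (in SD of the flattened spectrum) seeds a Gaussian whose
   width is guessed from the half-height extent, and the guess is
   subtracted before searching for the next peak;
3. all peak Gaussians are refined jointly by nonlinear least squares;
4. the aperiodic component is refit on the peak-removed spectrum;
5. the full model is reassembled and scored (R^2, RMSE).

Quality control: repetitions whose channel/time-averaged R^2 falls below a
threshold (default 0.9) are excluded from further analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import SpecParamConfig

logger = logging.getLogger(__name__)

__all__ = [
    "AperiodicFit", "PeakFit", "SpecParamModel",
    "fit_spectrum", "adjust_power", "qc_filter",
    "aperiodic_curve", "gaussian",
]


@dataclass
class AperiodicFit:
    offset: float
    exponent: float
    mode: str = "fixed"
    knee: Optional[float] = None

    def curve(self, freqs: np.ndarray) -> np.ndarray:
        return aperiodic_curve(freqs, self)


@dataclass
class PeakFit:
    center_frequency: float   # Hz
    power: float              # log10 units above the aperiodic curve
    bandwidth: float          # Hz, 2 * Gaussian SD


@dataclass
class SpecParamModel:
    aperiodic: AperiodicFit
    peaks: list[PeakFit]
    r_squared: float
    fit_error: float          # RMSE, log10 units
    frequencies: np.ndarray = field(repr=False)
    settings: SpecParamConfig = field(default_factory=SpecParamConfig,
                                      repr=False)

    def aperiodic_spectrum(self, freqs: np.ndarray | None = None):
        f = self.frequencies if freqs is None else np.asarray(freqs)
        return aperiodic_curve(f, self.aperiodic)

    def peak_spectrum(self, freqs: np.ndarray | None = None):
        f = self.frequencies if freqs is None else np.asarray(freqs)
        out = np.zeros_like(f, dtype=float)
        for p in self.peaks:
            out += gaussian(f, p.center_frequency, p.power, p.bandwidth / 2)
        return out

    def model_spectrum(self, freqs: np.ndarray | None = None):
        return self.aperiodic_spectrum(freqs) + self.peak_spectrum(freqs)


def aperiodic_curve(freqs: np.ndarray, fit: AperiodicFit) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if fit.mode == "knee":
        knee = fit.knee if fit.knee is not None else 0.0
        return fit.offset - np.log10(knee + freqs ** fit.exponent)
    return fit.offset - fit.exponent * np.log10(freqs)


def gaussian(freqs: np.ndarray, center: float, height: float, sd: float
             ) -> np.ndarray:
    return height * np.exp(-((np.asarray(freqs) - center) ** 2)
                           / (2 * sd ** 2))


def _ap_fixed(f, offset, exponent):
    return offset - exponent * np.log10(f)


def _ap_knee(f, offset, knee, exponent):
    return offset - np.log10(np.abs(knee) + f ** exponent)


def _simple_ap_fit(freqs, power, mode):
    logf = np.log10(freqs)
    if mode == "knee":
        guess = [power[0], 0.0, 2.0]
        popt, _ = curve_fit(_ap_knee, freqs, power, p0=guess, maxfev=5000)
        return np.array([popt[0], abs(popt[1]), popt[2]])
    # fixed mode: closed-form linear regression in log-log space
    slope, intercept = np.polyfit(logf, power, 1)
    return np.array([intercept, -slope])


def _robust_ap_fit(freqs, power, mode, percentile=2.5):
    """Refit the aperiodic curve ignoring points that sit above it.

    Positive residuals from an initial fit are ranked; only frequencies at
    or below the given percentile of the positive-clipped residuals are
    kept, which discards peak regions.
    """
    params = _simple_ap_fit(freqs, power, mode)
    fit0 = (_ap_knee(freqs, *params) if mode == "knee"
            else _ap_fixed(freqs, *params))
    flat = power - fit0
    flat = np.where(flat < 0, 0.0, flat)
    thresh = np.percentile(flat, percentile)
    keep = flat <= thresh
    if keep.sum() >= 3:
        f2, p2 = freqs[keep], power[keep]
        if mode == "knee":
            try:
                popt, _ = curve_fit(_ap_knee, f2, p2, p0=params, maxfev=5000)
                params = np.array([popt[0], abs(popt[1]), popt[2]])
            except RuntimeError:
                pass
        else:
            slope, intercept = np.polyfit(np.log10(f2), p2, 1)
            params = np.array([intercept, -slope])
    return params


def _guess_peaks(freqs, flat, settings: SpecParamConfig):
    """Iteratively seed Gaussians from the flattened spectrum."""
    flat = flat.copy()
    res = freqs[1] - freqs[0]
    lo_sd = settings.peak_width_limits[0] / 2.0
    hi_sd = settings.peak_width_limits[1] / 2.0
    guesses = []
    for _ in range(settings.max_n_peaks):
        i = int(np.argmax(flat))
        height = flat[i]
        if height <= settings.min_peak_height:
            break
        if height <= settings.peak_threshold * np.std(flat):
            break
        center = freqs[i]
        # half-height extent -> SD guess (FWHM = 2.355 sd)
        half = height / 2.0
        li = i
        while li > 0 and flat[li] > half:
            li -= 1
        ri = i
        while ri < len(flat) - 1 and flat[ri] > half:
            ri += 1
        fwhm = max((ri - li) * res, res)
        sd = np.clip(fwhm / 2.355, lo_sd, hi_sd)
        guesses.append((center, height, sd))
        flat -= gaussian(freqs, center, height, sd)

    # drop seeds whose center sits within one SD of the spectrum edge
    guesses = [g for g in guesses
               if freqs[0] + g[2] <= g[0] <= freqs[-1] - g[2]]
    # drop overlapping seeds (centers within 1.5 SD), keeping the taller
    guesses.sort(key=lambda g: g[0])
    keep = [True] * len(guesses)
    for i in range(len(guesses) - 1):
        c1, h1, s1 = guesses[i]
        c2, h2, s2 = guesses[i + 1]
        if c1 + 1.5 * s1 >= c2 - 1.5 * s2:
            keep[i if h1 < h2 else i + 1] = False
    return [g for g, k in zip(guesses, keep) if k]


def _fit_peaks_joint(freqs, flat, guesses, settings: SpecParamConfig):
    """Joint nonlinear refinement of all seeded Gaussians."""
    if not guesses:
        return []
    lo_sd = settings.peak_width_limits[0] / 2.0
    hi_sd = settings.peak_width_limits[1] / 2.0

    def multi_gauss(f, *params):
        out = np.zeros_like(f)
        for j in range(0, len(params), 3):
            out += gaussian(f, params[j], params[j + 1], params[j + 2])
        return out

    p0, lo, hi = [], [], []
    for c, h, s in guesses:
        p0 += [c, h, s]
        # center constrained near its seed (within 2 SD guesses), height
        # positive, SD within the configured width limits
        lo += [max(freqs[0], c - 2 * s), 0.0, lo_sd]
        hi += [min(freqs[-1], c + 2 * s), np.inf, hi_sd]
    p0 = [min(max(v, l), h) for v, l, h in zip(p0, lo, hi)]
    try:
        popt, _ = curve_fit(multi_gauss, freqs, flat, p0=p0,
                            bounds=(lo, hi), maxfev=5000)
    except RuntimeError:
        logger.warning("joint peak fit did not converge; keeping seeds")
        popt = np.array(p0)
    peaks = []
    for j in range(0, len(popt), 3):
        c, h, s = popt[j], popt[j + 1], popt[j + 2]
        if h >= settings.min_peak_height:
            peaks.append(PeakFit(center_frequency=float(c), power=float(h),
                                 bandwidth=float(2 * s)))
    peaks.sort(key=lambda p: p.center_frequency)
    return peaks


def fit_spectrum(
    frequencies: np.ndarray,
    log_power: np.ndarray,
    settings: SpecParamConfig | None = None,
) -> SpecParamModel:
    """Fit the aperiodic + Gaussian-peaks model to one log10 spectrum."""
    settings = settings or SpecParamConfig()
    freqs = np.asarray(frequencies, dtype=float)
    power = np.asarray(log_power, dtype=float)
    if freqs.ndim != 1 or len(freqs) < 10:
        raise ValueError("need at least 10 frequency points")
    if not np.all(np.diff(freqs) > 0):
        raise ValueError("frequency grid must be strictly increasing")
    if not np.all(np.isfinite(power)):
        raise ValueError("log power must be finite")

    if np.ptp(power) == 0:
        # degenerate flat spectrum: exponent 0, undefined R^2
        ap = AperiodicFit(offset=float(power[0]), exponent=0.0,
                          mode=settings.mode)
        return SpecParamModel(ap, [], float("nan"), 0.0, freqs, settings)

    ap_params = _robust_ap_fit(freqs, power, settings.mode)
    ap_fit0 = (_ap_knee(freqs, *ap_params) if settings.mode == "knee"
               else _ap_fixed(freqs, *ap_params))

    flat = power - ap_fit0
    guesses = _guess_peaks(freqs, flat, settings)
    peaks = _fit_peaks_joint(freqs, flat, guesses, settings)

    # remove fitted peaks, refit the aperiodic component on the remainder
    peak_model = np.zeros_like(power)
    for p in peaks:
        peak_model += gaussian(freqs, p.center_frequency, p.power,
                               p.bandwidth / 2)
    ap_params = _robust_ap_fit(freqs, power - peak_model, settings.mode)
    if settings.mode == "knee":
        ap = AperiodicFit(offset=float(ap_params[0]),
                          exponent=float(ap_params[2]), mode="knee",
                          knee=float(ap_params[1]))
    else:
        ap = AperiodicFit(offset=float(ap_params[0]),
                          exponent=float(ap_params[1]), mode="fixed")

    model = aperiodic_curve(freqs, ap) + peak_model
    resid = power - model
    fit_error = float(np.sqrt(np.mean(resid ** 2)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.corrcoef(power, model)[0, 1]
    r_squared = float(r ** 2) if np.isfinite(r) else float("nan")
    return SpecParamModel(ap, peaks, r_squared, fit_error, freqs, settings)


def adjust_power(
    log_power: np.ndarray,
    model: SpecParamModel,
    frequencies: np.ndarray | None = None,
) -> np.ndarray:
    """Subtract the reconstructed aperiodic curve from total log power.

    The result is log10 power relative to the aperiodic background; input
    may have extra leading axes, the last axis is frequency.
    """
    power = np.asarray(log_power, dtype=float)
    freqs = model.frequencies if frequencies is None else np.asarray(
        frequencies)
    if power.shape[-1] != len(freqs):
        raise ValueError("frequency grid mismatch between model and input")
    return power - model.aperiodic_spectrum(freqs)


def qc_filter(
    r_squared: Sequence[float] | pd.Series,
    threshold: float = 0.9,
) -> tuple[np.ndarray, int]:
    """Inclusion mask over per-repetition averaged model fits.

    ``r_squared`` holds one channel/time-averaged R^2 per sequence
    repetition; repetitions below the threshold are masked out.  Returns
    (mask, n_excluded).
    """
    r2 = np.asarray(r_squared, dtype=float)
    mask = r2 >= threshold
    return mask, int((~mask).sum())
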