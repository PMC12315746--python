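"""Spectral parameterization: recovery, identities and QC."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from prestim.config import SpecParamConfig
from prestim.specparam import (adjust_power, aperiodic_curve, fit_spectrum,
                               gaussian, qc_filter, AperiodicFit)

FREQS = np.arange(1.0, 40.0001, 0.2)


def make_spectrum(offset=1.0, exponent=1.5, peaks=(), noise_sd=0.0,
                  rng=None):
    p = offset - exponent * np.log10(FREQS)
    for cf, h, sd in peaks:
        p = p + gaussian(FREQS, cf, h, sd)
    if noise_sd:
        p = p + rng.normal(0, noise_sd, len(FREQS))
    return p


def global_fit_oracle(freqs, power, n_peaks=1):
    """Independent route: one-shot nonlinear least squares of the full
    model (power law + Gaussians), initialized from a coarse grid scan.
    Structurally different from the iterative percentile-filtered fit."""
    logf = np.log10(freqs)

    def model(f, *p):
        out = p[0] - p[1] * np.log10(f)
        for j in range(2, len(p), 3):
            out = out + gaussian(f, p[j], p[j + 1], p[j + 2])
        return out

    slope, intercept = np.polyfit(logf, power, 1)
    resid = power - (intercept + slope * logf)
    p0 = [intercept, -slope]
    lo = [-np.inf, -np.inf]
    hi = [np.inf, np.inf]
    work = resid.copy()
    for _ in range(n_peaks):
        i = int(np.argmax(work))
        p0 += [freqs[i], max(work[i], 0.05), 1.0]
        lo += [freqs[0], 0.0, 0.25]
        hi += [freqs[-1], np.inf, 5.0]
        work = work - gaussian(freqs, freqs[i], work[i], 1.0)
    popt, _ = curve_fit(model, freqs, power, p0=p0, bounds=(lo, hi),
                        maxfev=10000)
    peaks = sorted(
        [(popt[j], popt[j + 1], popt[j + 2])
         for j in range(2, len(popt), 3)], key=lambda t: -t[1])
    return popt[0], popt[1], peaks


class TestFitSpectrum:
    def test_pure_power_law_recovered_exactly(self):
        m = fit_spectrum(FREQS, make_spectrum(1.0, 1.5))
        assert m.aperiodic.offset == pytest.approx(1.0, abs=0.01)
        assert m.aperiodic.exponent == pytest.approx(1.5, abs=0.01)
        assert len(m.peaks) == 0
        assert m.r_squared >= 0.999

    def test_single_peak_recovery_with_noise(self):
        rng = np.random.default_rng(12)
        spec = make_spectrum(1.0, 1.5, peaks=[(10.0, 0.6, 1.0)],
                             noise_sd=0.02, rng=rng)
        m = fit_spectrum(FREQS, spec)
        assert m.peaks, "expected at least one fitted peak"
        main = max(m.peaks, key=lambda p: p.power)
        assert main.center_frequency == pytest.approx(10.0, abs=0.1)
        assert main.power == pytest.approx(0.6, abs=0.05)

    def test_cross_route_agreement(self):
        """The iterative fit and an independent global least-squares fit of
        the same model agree on exponent (0.05) and peak CF (0.1 Hz)."""
        rng = np.random.default_rng(30)
        for k in range(5):
            chi = rng.uniform(0.8, 2.0)
            cf = rng.uniform(8, 12)
            spec = make_spectrum(1.0, chi, peaks=[(cf, 0.7, 1.2)],
                                 noise_sd=0.03, rng=rng)
            m = fit_spectrum(FREQS, spec)
            off_o, exp_o, peaks_o = global_fit_oracle(FREQS, spec)
            assert abs(m.aperiodic.exponent - exp_o) < 0.05
            main = max(m.peaks, key=lambda p: p.power)
            assert abs(main.center_frequency - peaks_o[0][0]) < 0.1

    def test_scale_equivariance(self):
        """Adding a constant to log power shifts the offset only."""
        rng = np.random.default_rng(4)
        spec = make_spectrum(1.0, 1.2, peaks=[(10, 0.5, 1.0)],
                             noise_sd=0.02, rng=rng)
        m1 = fit_spectrum(FREQS, spec)
        m2 = fit_spectrum(FREQS, spec + 2.5)
        assert m2.aperiodic.offset - m1.aperiodic.offset == pytest.approx(
            2.5, abs=1e-8)
        assert m2.aperiodic.exponent == pytest.approx(
            m1.aperiodic.exponent, abs=1e-8)
        assert len(m1.peaks) == len(m2.peaks)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(5)
        spec = make_spectrum(0.8, 1.7, peaks=[(9, 0.6, 1.1)],
                             noise_sd=0.04, rng=rng)
        m = fit_spectrum(FREQS, spec)
        resid = spec - m.model_spectrum()
        assert np.sqrt(np.mean(resid ** 2)) == pytest.approx(m.fit_error,
                                                             abs=1e-12)

    def test_degenerate_flat_spectrum(self):
        m = fit_spectrum(FREQS, np.zeros_like(FREQS))
        assert m.aperiodic.exponent == 0.0
        assert np.isnan(m.r_squared)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_spectrum(FREQS[:5], np.zeros(5))
        with pytest.raises(ValueError, match="increasing"):
            fit_spectrum(FREQS[::-1], np.zeros_like(FREQS))
        bad = make_spectrum()
        bad[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_spectrum(FREQS, bad)

    @pytest.mark.parametrize("chi", [0.5, 1.0, 1.5, 2.0])
    def test_exponent_recovery_unbiased(self, chi):
        """Mean exponent bias below 0.05 over simulated noisy spectra."""
        rng = np.random.default_rng(int(chi * 10))
        errs = [
            fit_spectrum(FREQS, make_spectrum(1.0, chi, noise_sd=0.05,
                                              rng=rng)).aperiodic.exponent
            - chi
            for _ in range(25)
        ]
        assert abs(np.mean(errs)) < 0.05


class TestAdjustPower:
    def test_own_aperiodic_curve_maps_to_zero(self):
        m = fit_spectrum(FREQS, make_spectrum(1.0, 1.5))
        adj = adjust_power(m.aperiodic_spectrum(), m)
        assert np.allclose(adj, 0.0, atol=1e-10)

    def test_peak_survives_adjustment(self):
        spec = make_spectrum(1.0, 1.5, peaks=[(10, 0.6, 1.0)])
        m = fit_spectrum(FREQS, spec)
        adj = adjust_power(spec, m)
        truth = gaussian(FREQS, 10, 0.6, 1.0)
        assert np.abs(adj - truth).max() < 5 * max(m.fit_error, 0.01)

    def test_far_from_peak_centered_at_zero(self):
        rng = np.random.default_rng(6)
        spec = make_spectrum(1.0, 1.5, peaks=[(10, 0.6, 1.0)],
                             noise_sd=0.02, rng=rng)
        m = fit_spectrum(FREQS, spec)
        adj = adjust_power(spec, m)
        far = (FREQS > 20)
        assert abs(adj[far].mean()) < 0.03

    def test_grid_mismatch_raises(self):
        m = fit_spectrum(FREQS, make_spectrum())
        with pytest.raises(ValueError, match="grid"):
            adjust_power(np.zeros(17), m)

    def test_broadcasts_over_leading_axes(self):
        m = fit_spectrum(FREQS, make_spectrum())
        stack = np.tile(m.aperiodic_spectrum(), (3, 2, 1))
        assert np.allclose(adjust_power(stack, m), 0.0, atol=1e-10)


class TestQCFilter:
    def test_threshold_rule(self):
        mask, n = qc_filter([0.95, 0.89], 0.9)
        assert mask.tolist() == [True, False] and n == 1
        mask, n = qc_filter([0.95, 0.95, 0.99], 0.9)
        assert mask.all() and n == 0

    def test_exclusion_fraction_matches_direct_count(self):
        rng = np.random.default_rng(9)
        r2 = rng.uniform(0.8, 1.0, 100)
        mask, n = qc_filter(r2, 0.9)
        assert n == int((r2 < 0.9).sum())
        assert mask.sum() + n == 100


def test_knee_mode_fits_knee_spectrum():
    knee_true = 15.0
    spec = 1.0 - np.log10(knee_true + FREQS ** 2.0)
    m = fit_spectrum(FREQS, spec, SpecParamConfig(mode="knee"))
    assert m.aperiodic.mode == "knee"
    model = aperiodic_curve(FREQS, m.aperiodic)
    assert np.abs(model - spec).max() < 0.05
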