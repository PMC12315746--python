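"""Generator-level checks: determinism, spectral structure, path structure,
stopping rule and gaze construction."""

import numpy as np
import pandas as pd
import pytest

from prestim.config import SimConfig, default_channels
from prestim.synthgen import (generate_behavior, generate_epochs,
                              generate_gaze, generate_power_table,
                              powerlaw_noise)


def _no_oscillation_config(**kw) -> SimConfig:
    base = dict(
        n_subjects_per_group=1, groups=("young",), n_sequences=2,
        channels=default_channels(2, 2), n_frontal=2,
        alpha_base_amp_uv=0.0, theta_burst_amp_uv=0.0, theta_pre_amp_uv=0.0,
        seed=5,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenerateEpochs:
    def test_seed_determinism(self, tiny_config):
        a = generate_epochs(tiny_config, seed=3)
        b = generate_epochs(tiny_config, seed=3)
        assert np.array_equal(a.samples, b.samples)
        assert a.metadata.equals(b.metadata)

    def test_different_seed_differs(self, tiny_config):
        a = generate_epochs(tiny_config, seed=3)
        b = generate_epochs(tiny_config, seed=4)
        assert not np.array_equal(a.samples, b.samples)

    def test_metadata_indexes_epochs(self, tiny_config):
        ep = generate_epochs(tiny_config)
        assert len(ep.metadata) == ep.n_epochs
        # 2 groups x 2 subjects x 1 sequence x 8 reps x 8 stimuli
        assert ep.n_epochs == 2 * 2 * 8 * 8
        step = np.diff(ep.times)
        assert np.allclose(step, 1000.0 / tiny_config.sampling_rate)

    def test_oscillation_free_spectrum_has_no_alpha_peak(self):
        """With all oscillation amplitudes zero, the average spectrum is a
        pure power law: no detectable peak in 7-14 Hz."""
        from prestim.iaf import detect_iaf, long_segment_spectrum
        from prestim.specparam import adjust_power, fit_spectrum
        # all six sequences concatenated, as in the IAF estimation design,
        # so residual spectral ripple stays below the peak floor
        ep = generate_epochs(_no_oscillation_config(n_sequences=6))
        f, lp = long_segment_spectrum(ep, min_duration_s=10)
        model = fit_spectrum(f, lp)
        res = detect_iaf(f, adjust_power(lp, model))
        assert not res.detected

    def test_oscillation_free_loglog_slope_matches_exponent(self):
        """Log-log slope of the oscillation-free spectrum equals the
        configured aperiodic exponent within 0.1."""
        from prestim.iaf import long_segment_spectrum
        for chi in (1.0, 1.5):
            cfg = _no_oscillation_config(
                aperiodic_exponent={"young": chi}, seed=6)
            ep = generate_epochs(cfg)
            f, lp = long_segment_spectrum(ep, min_duration_s=10)
            slope = np.polyfit(np.log10(f), lp, 1)[0]
            assert abs(-slope - chi) < 0.1

    def test_injected_alpha_peak_at_true_frequency(self):
        """Single subject with IAF pinned at 10 Hz: a long FFT of the raw
        signal peaks at 10.0 Hz within the frequency resolution."""
        cfg = SimConfig(
            n_subjects_per_group=1, groups=("young",), n_sequences=1,
            channels=default_channels(1, 1), n_frontal=1,
            iaf_mean={"young": 10.0}, iaf_sd={"young": 0.0},
            alpha_base_amp_uv=30.0, seed=9,
        )
        ep = generate_epochs(cfg)
        # independent oracle: average per-epoch periodogram of the raw
        # parietal trace; resolution = 1/epoch-duration
        sig = ep.samples[:, 1, :]
        n_t = sig.shape[1]
        freqs = np.fft.rfftfreq(n_t, d=1 / cfg.sampling_rate)
        spec = (np.abs(np.fft.rfft(sig, axis=1)) ** 2).mean(axis=0)
        band = (freqs > 5) & (freqs < 20)
        peak = freqs[band][np.argmax(spec[band])]
        df = freqs[1] - freqs[0]
        assert abs(peak - 10.0) <= df + 1e-9

    def test_rejects_burst_outside_epoch(self):
        with pytest.raises(ValueError, match="burst"):
            SimConfig(theta_burst_latency=2000.0)

    def test_rejects_nonfinite_amplitude(self):
        with pytest.raises(ValueError, match="finite"):
            SimConfig(alpha_base_amp_uv=float("nan"))


class TestPowerlawNoise:
    def test_target_exponent_controls_slope(self):
        rng = np.random.default_rng(0)
        x = powerlaw_noise(rng, (200,), 2048, 500.0, 2.0, 1.0)
        freqs = np.fft.rfftfreq(2048, d=1 / 500.0)
        psd = (np.abs(np.fft.rfft(x, axis=-1)) ** 2).mean(axis=0)
        sel = (freqs >= 1) & (freqs <= 40)
        slope = np.polyfit(np.log10(freqs[sel]), np.log10(psd[sel]), 1)[0]
        assert abs(-slope - 2.0) < 0.1

    def test_rms_scaling(self):
        rng = np.random.default_rng(1)
        x = powerlaw_noise(rng, (4,), 1000, 500.0, 1.5, 7.0)
        assert np.allclose(x.std(axis=-1), 7.0)


class TestGeneratePowerTable:
    def test_all_zero_when_paths_and_noise_zero(self):
        cfg = SimConfig(path_a=0, path_b=0, path_c_prime=0,
                        subject_intercept_sd=0, residual_sd=0)
        tbl = generate_power_table(cfg, n_subjects=3)
        assert (tbl["prestim"] == 0).all()
        assert (tbl["ers_erd"] == 0).all()

    def test_deterministic_path_prestim_equals_repetition(self):
        cfg = SimConfig(path_a=1.0, subject_intercept_sd=0, residual_sd=0)
        tbl = generate_power_table(cfg, n_subjects=2)
        assert np.allclose(tbl["prestim"], tbl["repetition"])

    def test_ols_recovers_b_and_c_prime(self):
        """Closed-form OLS on a 200-subject draw recovers the outcome-path
        coefficients within 3 Monte-Carlo SEs."""
        import statsmodels.api as sm
        cfg = SimConfig(path_a=0.15, path_b=-0.6, path_c_prime=-0.1,
                        subject_intercept_sd=0.0, residual_sd=0.3,
                        groups=("young",), seed=21)
        tbl = generate_power_table(cfg, n_subjects=200)
        X = sm.add_constant(tbl[["prestim", "repetition"]])
        fit = sm.OLS(tbl["ers_erd"], X).fit()
        for col, truth in (("prestim", -0.6), ("repetition", -0.1)):
            assert abs(fit.params[col] - truth) < 3 * fit.bse[col]

    def test_product_of_coefficients_recovered_two_stage(self):
        """Two-stage OLS product a*b on a 500-subject draw lies within
        3 SEs of the configured indirect effect."""
        import statsmodels.api as sm
        cfg = SimConfig(groups=("young",), subject_intercept_sd=0.0,
                        seed=22)
        tbl = generate_power_table(cfg, n_subjects=500)
        Xm = sm.add_constant(tbl[["repetition"]])
        m = sm.OLS(tbl["prestim"], Xm).fit()
        Xy = sm.add_constant(tbl[["prestim", "repetition"]])
        y = sm.OLS(tbl["ers_erd"], Xy).fit()
        ab = m.params["repetition"] * y.params["prestim"]
        se = np.sqrt(
            (m.params["repetition"] * y.bse["prestim"]) ** 2
            + (y.params["prestim"] * m.bse["repetition"]) ** 2)
        assert abs(ab - cfg.path_a * cfg.path_b) < 3 * se

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(residual_sd=-0.1)


class TestGenerateBehavior:
    def test_certain_success_stops_after_three(self):
        cfg = SimConfig(n_subjects_per_group=2, learning_slope={"young": 100.0, "older": 100.0},
                        learning_offset={"young": -10.0, "older": -10.0})
        items = generate_behavior(cfg)
        reps = items.groupby(["subject", "sequence"])["repetition"].max()
        assert (reps == 3).all()

    def test_certain_failure_runs_eight(self):
        cfg = SimConfig(n_subjects_per_group=2, learning_slope={"young": 100.0, "older": 100.0},
                        learning_offset={"young": 100.0, "older": 100.0})
        items = generate_behavior(cfg)
        reps = items.groupby(["subject", "sequence"])["repetition"].max()
        assert (reps == 8).all()
        assert (items["correct"] == 0).all()

    def test_determinism(self, tiny_config):
        a = generate_behavior(tiny_config, seed=2)
        b = generate_behavior(tiny_config, seed=2)
        assert a.equals(b)


def markov_expected_repetitions(p_by_rep, required=3, max_reps=8,
                                n_items=8):
    """Exact expected stopping time of the 'three total correct or eight
    repetitions' rule: track the distribution of the number of
    fully-correct recalls across repetitions."""
    q = [p ** n_items for p in p_by_rep]      # P(fully correct) per rep
    dist = {0: 1.0}
    expected = 0.0
    for rep in range(1, max_reps + 1):
        nxt = {}
        stop_prob = 0.0
        for n_full, pr in dist.items():
            succ = q[rep - 1]
            if n_full + 1 >= required:
                stop_prob += pr * succ
            else:
                nxt[n_full + 1] = nxt.get(n_full + 1, 0.0) + pr * succ
            nxt[n_full] = nxt.get(n_full, 0.0) + pr * (1 - succ)
        expected += rep * stop_prob
        if rep == max_reps:
            expected += rep * sum(nxt.values())
        dist = nxt
    return expected


class TestStoppingRule:
    def test_monte_carlo_matches_markov_chain(self):
        """Empirical mean repetitions-to-completion over simulated
        sequences agrees with the exact Markov computation within 3 SEs."""
        slope, offset = 1.0, 2.5
        cfg = SimConfig(
            n_subjects_per_group=90, groups=("young",), n_sequences=2,
            learning_slope={"young": slope},
            learning_offset={"young": offset}, seed=31,
        )
        items = generate_behavior(cfg)
        reps = items.groupby(["subject", "sequence"])["repetition"].max()
        p_by_rep = [1 / (1 + np.exp(-slope * (r - offset)))
                    for r in range(1, 9)]
        exact = markov_expected_repetitions(p_by_rep)
        se = reps.std(ddof=1) / np.sqrt(len(reps))
        assert abs(reps.mean() - exact) < 3 * se


class TestGenerateGaze:
    @pytest.mark.parametrize("fraction,kept", [(1.0, True), (0.5, False),
                                               (0.9, True)])
    def test_inside_fraction_drives_classification(self, fraction, kept):
        from prestim.behavior import classify_fixation
        cfg = SimConfig()
        g = generate_gaze(cfg, inside_fraction=fraction, n_trials=1, seed=4)
        assert classify_fixation(g["x"], g["y"]) is kept
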