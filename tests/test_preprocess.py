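"""Preprocessing chain: generated-signal oracles and mask behaviour."""

import dataclasses
import logging

import numpy as np
import pytest

from olfbold.activation import tsnr_map
from olfbold.phantom import null_config, simulate_dataset
from olfbold.preprocess import (
    PreprocConfig,
    highpass_detrend,
    lowpass_filter,
    preprocess_bold,
    regress_nuisance,
    smooth_spatial,
)


@pytest.fixture()
def flat_bold(schedule):
    """All-ones small volume with a full mask, for filter oracles."""
    cfg = null_config(grid_shape=(6, 6, 4), roi_layout=(),
                      sigma_thermal=0.0, drift_amp=0.0, resp_amp=0.0)
    bold, _ = simulate_dataset(schedule, cfg, seed=0)
    bold.brain_mask[...] = True
    bold.data[...] = 100.0
    return bold


def inject(bold, series):
    out = bold.copy()
    out.data[...] = 100.0 + series
    return out


def amplitude(series):
    return (series.max() - series.min()) / 2.0


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, flat_bold, rng):
        flat_bold.data += rng.normal(size=flat_bold.data.shape)
        out = smooth_spatial(flat_bold, 0.0)
        assert np.array_equal(out.data, flat_bold.data)

    def test_constant_image_unchanged(self, flat_bold):
        out = smooth_spatial(flat_bold, 4.0)
        assert np.allclose(out.data, 100.0)

    def test_impulse_fwhm_matches_kernel(self, schedule):
        cfg = null_config(grid_shape=(21, 21, 21), roi_layout=(),
                          sigma_thermal=0.0, drift_amp=0.0, resp_amp=0.0)
        bold, _ = simulate_dataset(schedule, cfg, seed=0)
        bold.brain_mask[...] = True
        bold.data[...] = 0.0
        bold.data[10, 10, 10, :] = 1.0
        out = smooth_spatial(bold, 4.0)
        for prof in (out.data[:, 10, 10, 0], out.data[10, :, 10, 0],
                     out.data[10, 10, :, 0]):
            # width at half maximum on the voxel grid, in mm
            above = np.where(prof >= prof.max() / 2.0)[0]
            width_mm = (above[-1] - above[0] + 1) * 1.5
            assert abs(width_mm - 4.0) <= 1.5 / 2 + 1.5  # within half a voxel + grid quantization
        assert out.data[..., 0].sum() == pytest.approx(1.0)  # unit mass preserved

    def test_negative_fwhm_rejected(self, flat_bold):
        with pytest.raises(ValueError):
            smooth_spatial(flat_bold, -1.0)

    def test_mask_respected(self, flat_bold, rng):
        flat_bold.brain_mask[...] = False
        flat_bold.brain_mask[2:4, 2:4, 1:3] = True
        flat_bold.data += rng.normal(size=flat_bold.data.shape)
        out = smooth_spatial(flat_bold, 4.0)
        outside = ~flat_bold.brain_mask
        assert np.array_equal(out.data[outside], flat_bold.data[outside])


class TestHighpass:
    def test_constant_series_unchanged(self, flat_bold):
        out = highpass_detrend(flat_bold, 1 / 180.0)
        assert np.allclose(out.data, 100.0, atol=1e-9)

    def test_slow_sinusoid_attenuated(self, flat_bold, schedule):
        """Off-grid 1/360 Hz cosine: mostly removed (projection rolloff ~20%);
        an on-grid 1/300 Hz cosine is removed almost entirely."""
        t = schedule.times
        out = highpass_detrend(
            inject(flat_bold, np.cos(2 * np.pi * t / 360.0)), 1 / 180.0
        )
        assert amplitude(out.data[0, 0, 0] - 100.0) < 0.3
        n = schedule.n_volumes
        ongrid = np.cos(np.pi * 4 * (2 * np.arange(n) + 1) / (2 * n))
        out = highpass_detrend(inject(flat_bold, ongrid), 1 / 180.0)
        assert amplitude(out.data[0, 0, 0] - 100.0) < 1e-9

    def test_generator_drift_removed_exactly(self, schedule):
        """Drift emitted by the phantom lies in the projection span."""
        cfg = null_config(grid_shape=(6, 6, 4), roi_layout=(),
                          sigma_thermal=0.0, resp_amp=0.0, drift_amp=8.0)
        bold, _ = simulate_dataset(schedule, cfg, seed=7)
        bold.brain_mask[...] = True
        out = highpass_detrend(bold, 1 / 180.0)
        assert np.allclose(out.data, 1000.0, atol=1e-8)

    def test_passband_sinusoid_preserved(self, flat_bold, schedule):
        t = schedule.times
        vol = inject(flat_bold, np.sin(2 * np.pi * 0.02 * t + 0.4))
        out = highpass_detrend(vol, 1 / 180.0)
        rms_in = np.std(vol.data[0, 0, 0])
        rms_out = np.std(out.data[0, 0, 0])
        assert rms_out == pytest.approx(rms_in, rel=0.1)

    def test_mean_restored(self, flat_bold, schedule):
        t = schedule.times
        vol = inject(flat_bold, np.cos(2 * np.pi * t / 400.0))
        out = highpass_detrend(vol, 1 / 180.0)
        assert out.data[0, 0, 0].mean() == pytest.approx(vol.data[0, 0, 0].mean())

    def test_cutoff_at_nyquist_rejected(self, flat_bold):
        with pytest.raises(ValueError, match="Nyquist"):
            highpass_detrend(flat_bold, 0.25)


class TestNuisanceRegression:
    def test_zero_traces_identity(self, flat_bold, rng):
        flat_bold.data += rng.normal(size=flat_bold.data.shape)
        out = regress_nuisance(flat_bold, np.zeros((flat_bold.n_volumes, 2)))
        assert np.allclose(out.data, flat_bold.data)

    def test_exact_linear_combination_removed(self, flat_bold, rng):
        trace = rng.normal(size=flat_bold.n_volumes)
        vol = inject(flat_bold, 3.0 * trace)
        out = regress_nuisance(vol, trace)
        # residual variance ~ 0; the series mean is restored, not discarded
        assert out.data[0, 0, 0].std() == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(out.data, vol.data.mean(axis=3, keepdims=True), atol=1e-9)

    def test_collinear_columns_dropped_with_warning(self, flat_bold, rng, caplog):
        trace = rng.normal(size=flat_bold.n_volumes)
        traces = np.column_stack([trace, 2.0 * trace])
        vol = inject(flat_bold, trace)
        with caplog.at_level(logging.WARNING, logger="olfbold"):
            out = regress_nuisance(vol, traces)
        assert "collinear" in caplog.text
        assert out.data[0, 0, 0].std() == pytest.approx(0.0, abs=1e-9)

    def test_wrong_length_rejected(self, flat_bold, rng):
        with pytest.raises(ValueError, match="n_volumes"):
            regress_nuisance(flat_bold, rng.normal(size=(7, 2)))

    def test_respiratory_regression_raises_tsnr(self, schedule):
        cfg = null_config(grid_shape=(10, 10, 6), roi_layout=(), drift_amp=0.0)
        bold, truth = simulate_dataset(schedule, cfg, seed=5)
        before = np.median(tsnr_map(bold)[bold.brain_mask])
        out = regress_nuisance(bold, truth.nuisance_traces)
        after = np.median(tsnr_map(out)[bold.brain_mask])
        assert after > before


class TestLowpass:
    def test_constant_unchanged(self, flat_bold):
        out = lowpass_filter(flat_bold, 0.03)
        assert np.allclose(out.data, 100.0, atol=1e-9)

    def test_stopband_attenuated(self, flat_bold, schedule):
        t = schedule.times
        vol = inject(flat_bold, np.sin(2 * np.pi * 0.1 * t))
        out = lowpass_filter(vol, 0.03)
        interior = out.data[0, 0, 0, 20:-20] - 100.0  # skip edge transients
        assert amplitude(interior) < 0.1

    def test_passband_preserved(self, flat_bold, schedule):
        t = schedule.times
        vol = inject(flat_bold, np.sin(2 * np.pi * 0.005 * t))
        out = lowpass_filter(vol, 0.03)
        assert amplitude(out.data[0, 0, 0] - 100.0) == pytest.approx(1.0, abs=0.05)

    def test_zero_phase_no_temporal_shift(self, flat_bold, schedule):
        """Cross-correlation of filtered vs raw block response peaks at lag 0."""
        from olfbold.phantom import default_config, response_template

        r = response_template(schedule, default_config(), "+", amplitude=1.0)
        vol = inject(flat_bold, r)
        out = lowpass_filter(vol, 0.03)
        a = vol.data[0, 0, 0] - 100.0
        b = out.data[0, 0, 0] - 100.0
        lags = range(-5, 6)
        cc = [np.correlate(np.roll(b, k), a)[0] for k in lags]
        assert list(lags)[int(np.argmax(cc))] == 0

    def test_too_short_series_rejected(self, schedule):
        from olfbold.paradigm import build_paradigm

        short = build_paradigm(2, 4, 1, 6, 6, 1, 2)  # 8 volumes
        cfg = null_config(grid_shape=(4, 4, 2), roi_layout=(),
                          sigma_thermal=0.0, drift_amp=0.0, resp_amp=0.0)
        bold, _ = simulate_dataset(short, cfg, seed=0)
        with pytest.raises(ValueError, match="warm-up"):
            lowpass_filter(bold, 0.03)

    def test_cutoff_at_nyquist_rejected(self, flat_bold):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(flat_bold, 0.3)


class TestChain:
    def test_temporal_chain_idempotent_within_1pct(self, schedule, rng):
        """Running the (temporal) chain twice barely changes the result."""
        cfg = null_config(grid_shape=(8, 8, 4), roi_layout=())
        bold, truth = simulate_dataset(schedule, cfg, seed=2)
        pp = PreprocConfig(fwhm_mm=0.0, nuisance_traces=truth.nuisance_traces)
        once = preprocess_bold(bold, pp)
        twice = preprocess_bold(once, pp)
        m = once.brain_mask
        # the projections (high-pass, nuisance) are exactly idempotent; only
        # the low-pass rolloff re-shrinks near-cutoff content, so compare the
        # interior of the passband (Hann window against spectral leakage)
        freqs = np.fft.rfftfreq(schedule.n_volumes, schedule.tr_seconds)
        band = (freqs >= 0.006) & (freqs <= 0.015)
        w = np.hanning(schedule.n_volumes)
        centered = once.data[m] - once.data[m].mean(axis=1, keepdims=True)
        f_once = np.fft.rfft(centered * w)
        f_diff = np.fft.rfft((twice.data[m] - once.data[m]) * w)
        num = np.sqrt(np.mean(np.abs(f_diff[:, band]) ** 2))
        den = np.sqrt(np.mean(np.abs(f_once[:, band]) ** 2))
        # the second high-pass re-projects the low-pass's edge transients,
        # which leaves a small global residual beyond the pure rolloff
        assert num / den < 0.05

    def test_projection_stages_exactly_idempotent(self, schedule):
        cfg = null_config(grid_shape=(6, 6, 4), roi_layout=())
        bold, truth = simulate_dataset(schedule, cfg, seed=3)
        h1 = highpass_detrend(bold, 1 / 180.0)
        h2 = highpass_detrend(h1, 1 / 180.0)
        assert np.allclose(h1.data, h2.data, atol=1e-9)
        r1 = regress_nuisance(h1, truth.nuisance_traces)
        r2 = regress_nuisance(r1, truth.nuisance_traces)
        assert np.allclose(r1.data, r2.data, atol=1e-9)

    def test_invalid_cutoff_order_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            PreprocConfig(hp_cutoff_hz=0.05, lp_cutoff_hz=0.03).validate()

    def test_chain_respects_mask(self, schedule, rng):
        cfg = null_config(grid_shape=(8, 8, 4), roi_layout=())
        bold, truth = simulate_dataset(schedule, cfg, seed=2)
        pp = PreprocConfig(nuisance_traces=truth.nuisance_traces)
        out = preprocess_bold(bold, pp)
        outside = ~bold.brain_mask
        assert np.array_equal(out.data[outside], bold.data[outside])
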