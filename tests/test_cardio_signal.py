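"""Heartbeat traces, sine fitting, FFT frequency, autocorrelation."""

import numpy as np
import pytest

from zfheart.cardio_signal import (
    ChamberTrace,
    autocorrelation_score,
    extract_heartbeat_trace,
    fft_frequency,
    fit_sine,
)
from zfheart.exceptions import EmptySignalError
from zfheart.io_media import FrameStack
from zfheart.segmentation import ChamberMaskSeries, detect_heart_roi, segment_chambers
from zfheart.synthetic import HeartSimParams, default_seeds, generate_heart_video


def _trace(y, rate):
    return ChamberTrace.from_signal(np.asarray(y, dtype=float), rate)


def grid_search_freq(trace, f_lo=0.25, f_hi=6.0, step=0.001):
    """Independent dense grid-search oracle: for each frequency, the best
    achievable correlation is the R of regressing the signal on the sin/cos
    pair at that frequency (free amplitude/phase/offset)."""
    y = trace.combined_signal
    t = trace.time
    best_f, best_r = None, -np.inf
    for f in np.arange(f_lo, f_hi + step / 2, step):
        design = np.column_stack([np.sin(2 * np.pi * f * t),
                                  np.cos(2 * np.pi * f * t),
                                  np.ones_like(t)])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1 - np.sum(resid**2) / ss_tot
        if r2 > best_r:
            best_r, best_f = r2, f
    return best_f


class TestExtractTrace:
    def test_combined_signal_has_true_period(self, regular_video):
        stack, truth = regular_video
        roi = detect_heart_roi(stack)
        masks = segment_chambers(stack, roi, default_seeds(truth, roi))
        trace = extract_heartbeat_trace(stack, masks, "atrium")
        # periodogram oracle on the extracted signal
        y = trace.combined_signal - trace.combined_signal.mean()
        freqs = np.fft.rfftfreq(len(y), 1 / stack.frame_rate)
        dominant = freqs[np.abs(np.fft.rfft(y))[1:].argmax() + 1]
        assert dominant == pytest.approx(truth.freq_atrium, abs=stack.frame_rate / len(y))
        assert trace.combined_signal.min() >= 0.0
        assert trace.combined_signal.max() <= 1.0

    def test_empty_masks_raise(self, regular_video):
        stack, _ = regular_video
        empty = np.zeros((stack.n_frames,) + stack.shape, dtype=bool)
        masks = ChamberMaskSeries(atrium=empty, ventricle=empty.copy(),
                                  pixel_size=stack.pixel_size)
        with pytest.raises(EmptySignalError):
            extract_heartbeat_trace(stack, masks, "atrium")

    def test_constant_input_sets_constant_flag(self):
        frames = np.full((20, 8, 8), 50, dtype=np.uint8)
        stack = FrameStack(frames=frames, frame_rate=10.0, pixel_size=1.0)
        mask = np.zeros((20, 8, 8), dtype=bool)
        mask[:, 2:6, 2:6] = True
        masks = ChamberMaskSeries(atrium=mask, ventricle=np.zeros_like(mask), pixel_size=1.0)
        trace = extract_heartbeat_trace(stack, masks, "atrium")
        assert trace.constant
        fit = fit_sine(trace, 10.0)
        assert fit.freq is None  # downstream reports failure, no crash


class TestFitSine:
    def test_noiseless_sine_recovered(self):
        t = np.arange(180) / 30.0  # 6 s at 30 f/s
        trace = _trace(np.sin(2 * np.pi * 2.5 * t), 30.0)
        fit = fit_sine(trace, 30.0)
        assert fit.freq == pytest.approx(2.5, abs=0.05)
        assert fit.fit_score > 0.99

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        f_true = rng.uniform(0.5, 4.0)
        t = np.arange(72) / 12.0
        y = np.sin(2 * np.pi * f_true * t + rng.uniform(0, 2 * np.pi))
        trace = _trace(y, 12.0)
        fit = fit_sine(trace, 12.0)
        assert fit.freq == pytest.approx(grid_search_freq(trace), abs=0.01)

    def test_constant_trace_fails_gracefully(self):
        trace = _trace(np.ones(40), 10.0)
        fit = fit_sine(trace, 10.0)
        assert fit.freq is None
        assert not fit.ok

    def test_truncated_fit_wins_on_unstable_signal(self):
        # beats at 2 s^-1 during the first quarter, silence afterwards
        rate = 20.0
        t = np.arange(160) / rate
        y = np.where(t < 2.0, np.sin(2 * np.pi * 2.0 * t), 0.0)
        trace = _trace(y, rate)
        fit = fit_sine(trace, rate)
        assert fit.used_truncated
        assert fit.freq == pytest.approx(2.0, abs=0.1)

    def test_scale_invariance_of_frequency(self, regular_video):
        stack, truth = regular_video
        roi = detect_heart_roi(stack)
        masks = segment_chambers(stack, roi, default_seeds(truth, roi))
        trace = extract_heartbeat_trace(stack, masks, "atrium")
        scaled_stack = FrameStack(
            frames=(stack.frames.astype(np.uint16) * 3),
            frame_rate=stack.frame_rate, pixel_size=stack.pixel_size,
        )
        scaled = extract_heartbeat_trace(scaled_stack, masks, "atrium")
        fit = fit_sine(trace, stack.frame_rate)
        fit_scaled = fit_sine(scaled, stack.frame_rate)
        assert fit.freq == pytest.approx(fit_scaled.freq, abs=1e-6)
        assert fft_frequency(trace, stack.frame_rate) == fft_frequency(
            scaled, stack.frame_rate
        )


class TestFFTFrequency:
    def test_on_bin_cosine_exact(self):
        t = np.arange(36) / 6.0
        trace = _trace(np.cos(2 * np.pi * 1.0 * t), 6.0)
        assert fft_frequency(trace, 6.0) == pytest.approx(1.0)

    def test_dominant_component_wins(self):
        t = np.arange(144) / 12.0  # 12 s at 12 f/s
        y = np.sin(2 * np.pi * 2 * t) + 0.5 * np.sin(2 * np.pi * 4 * t)
        trace = _trace(y, 12.0)
        # direct DFT oracle
        spec = np.abs(np.fft.rfft(trace.combined_signal - trace.combined_signal.mean()))
        freqs = np.fft.rfftfreq(144, 1 / 12.0)
        assert freqs[spec[1:].argmax() + 1] == pytest.approx(2.0)
        assert fft_frequency(trace, 12.0) == pytest.approx(2.0)

    def test_constant_signal_returns_none(self):
        assert fft_frequency(_trace(np.full(20, 3.0), 10.0), 10.0) is None

    def test_sine_and_fft_agree_on_clean_on_bin_signal(self):
        rate, n = 12.0, 72
        t = np.arange(n) / rate
        trace = _trace(np.sin(2 * np.pi * 2.0 * t), rate)
        fit = fit_sine(trace, rate)
        fft = fft_frequency(trace, rate)
        assert abs(fit.freq - fft) <= rate / n


class TestAutocorrelation:
    def test_periodic_signal_scores_high(self):
        t = np.arange(120) / 20.0
        trace = _trace(np.sin(2 * np.pi * 1.5 * t), 20.0)
        assert autocorrelation_score(trace) > 0.95

    def test_white_noise_scores_low(self):
        low = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            trace = _trace(rng.normal(size=60), 10.0)
            if autocorrelation_score(trace) < 0.5:
                low += 1
        assert low >= 99

    def test_constant_scores_zero(self):
        assert autocorrelation_score(_trace(np.full(30, 2.0), 10.0)) == 0.0
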