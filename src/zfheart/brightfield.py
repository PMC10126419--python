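"""Fully automated heart-rate estimation from brightfield recordings.

Brightfield videos have no fluorescent label to segment, but the beating
heart is the only strongly moving structure, so the pixels with the highest
temporal standard deviation mark it.  The heart "selection" is exactly the
10 highest-SD pixels (ties broken in row-major order); their mean intensity
time series, detrended and normalized, is handed to the same sine-fit and
FFT estimators used for the fluorescence traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cardio_signal import ChamberTrace, FrequencyFit, analyze_trace
from .exceptions import InsufficientDataError, NoMotionError
from .io_media import FrameStack

#: Number of highest-temporal-SD pixels averaged into the heartbeat trace.
N_PIXELS = 10


@dataclass
class PixelTraceSet:
    """The selected high-motion pixels and their intensity traces."""

    coordinates: np.ndarray  # (k, 2) row/col of selected pixels, SD-descending
    traces: np.ndarray  # (n_frames, k) per-pixel intensity series
    averaged: np.ndarray  # (n_frames,) mean trace across the pixels


@dataclass
class BrightfieldResult:
    """Heart-rate estimates from a brightfield recording."""

    freq: Optional[float]  # s^-1, sine fit
    fft_freq: Optional[float]  # s^-1, FFT
    hr_bpm: Optional[float]  # 60 x the frame-rate-appropriate frequency
    fit: FrequencyFit
    pixels: PixelTraceSet


def bf_select_pixels(stack: FrameStack, n_pixels: int = N_PIXELS) -> PixelTraceSet:
    """Select the ``n_pixels`` pixels with the highest temporal SD.

    Ties are broken by row-major pixel order.  Raises
    :class:`~zfheart.exceptions.NoMotionError` when every pixel is constant.
    """
    if stack.n_frames < 2:
        raise InsufficientDataError("need >= 2 frames to measure temporal SD")
    sd = stack.frames.astype(float).std(axis=0)
    if sd.max() == 0:
        raise NoMotionError("no motion detected: every pixel is constant over time")
    # stable sort of -SD keeps row-major order among ties
    order = np.argsort(-sd, axis=None, kind="stable")[: min(n_pixels, sd.size)]
    coords = np.column_stack(np.unravel_index(order, sd.shape))
    traces = stack.frames[:, coords[:, 0], coords[:, 1]].astype(float)
    return PixelTraceSet(
        coordinates=coords, traces=traces, averaged=traces.mean(axis=1)
    )


def bf_heart_rate(stack: FrameStack, sine_min_rate: float = 9.0) -> BrightfieldResult:
    """Heart rate from the averaged high-SD pixel trace.

    The trace is detrended, min-max normalized, and passed through the sine
    fit and the FFT.  hr_bpm uses the FFT estimate below ``sine_min_rate``
    frames/s and the sine estimate otherwise.
    """
    pixels = bf_select_pixels(stack)
    trace = ChamberTrace.from_signal(pixels.averaged, stack.frame_rate)
    fit = analyze_trace(trace, stack.frame_rate)
    chosen = fit.best_frequency(stack.frame_rate, sine_min_rate)
    return BrightfieldResult(
        freq=fit.freq,
        fft_freq=fit.fft_freq,
        hr_bpm=None if chosen is None else 60.0 * chosen,
        fit=fit,
        pixels=pixels,
    )
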