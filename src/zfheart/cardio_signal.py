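"""Heartbeat traces and beat-frequency estimation.

Each chamber yields a :class:`ChamberTrace`: the per-frame sum of pixel
intensities inside the chamber mask and the per-frame chamber area, each
linearly detrended and min-max normalized to [0, 1], plus their mean (the
combined signal all estimators operate on).

Two frequency estimators are provided, matching their respective sweet spots:

* :func:`fit_sine` — a sine model A·sin(2πft + φ) + c refined from 30
  uniformly spaced starting frequencies, the winner chosen by the Pearson
  correlation between raw and fitted signal.  The fit is repeated on the
  first quarter of the trace (to rescue recordings where the beat destabilizes)
  and the better-scoring of the two is kept.  Preferred at frame rates
  ≥ 9 frames/s.
* :func:`fft_frequency` — the dominant non-DC bin of the discrete Fourier
  transform; robust at low frame rates such as 6 frames/s.

An :func:`autocorrelation_score` (max normalized autocorrelation over lags
of at least 2 samples) quantifies how periodic the raw signal is at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, signal as sp_signal
from scipy.stats import pearsonr

from .exceptions import EmptySignalError, InsufficientDataError
from .io_media import FrameStack
from .segmentation import ChamberMaskSeries, chamber_area_series

#: Number of sine starting frequencies swept during fitting.
N_SINE_CANDIDATES = 30
#: Lowest candidate beat frequency (s^-1); embryonic hearts beat well above it.
F_MIN = 0.25
#: Highest candidate beat frequency (s^-1) ~ 360 beats/min, capped at Nyquist.
F_MAX = 6.0
#: A winning fit scoring below this is reported as a failure.
MIN_FIT_SCORE = 0.1


@dataclass
class ChamberTrace:
    """Normalized per-chamber heartbeat signals on a common time axis."""

    time: np.ndarray  # seconds
    intensity_signal: np.ndarray  # detrended, min-max normalized to [0, 1]
    area_signal: np.ndarray  # detrended, min-max normalized to [0, 1]
    combined_signal: np.ndarray  # mean of the two
    constant: bool = False  # no variation left after detrending

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("intensity_signal", "area_signal", "combined_signal"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from time axis")

    def __len__(self) -> int:
        return len(self.time)

    @classmethod
    def from_signal(cls, y: np.ndarray, frame_rate: float) -> "ChamberTrace":
        """Build a trace from a single raw signal (used by the brightfield
        module, where there is no separate area signal)."""
        y = np.asarray(y, dtype=float)
        time = np.arange(len(y)) / frame_rate
        norm, const = _detrend_normalize(y)
        return cls(
            time=time,
            intensity_signal=norm,
            area_signal=norm.copy(),
            combined_signal=norm.copy(),
            constant=const,
        )


@dataclass
class FrequencyFit:
    """Sine-fit parameters plus companion quality metrics for one chamber.

    ``freq`` is None when the fit failed (constant signal, divergence, or a
    winning score below :data:`MIN_FIT_SCORE`).  Heart rate in beats/min is
    60 x frequency.
    """

    freq: Optional[float]  # s^-1
    amplitude: Optional[float] = None
    phase: Optional[float] = None  # radians
    offset: Optional[float] = None
    fit_score: Optional[float] = None  # Pearson r raw-vs-fit, in [-1, 1]
    fft_freq: Optional[float] = None  # s^-1, dominant non-DC harmonic
    autocorr_score: Optional[float] = None  # in [-1, 1]
    used_truncated: bool = False

    @property
    def ok(self) -> bool:
        return self.freq is not None

    @property
    def hr_bpm(self) -> Optional[float]:
        return None if self.freq is None else 60.0 * self.freq

    @property
    def hr_fft_bpm(self) -> Optional[float]:
        return None if self.fft_freq is None else 60.0 * self.fft_freq

    def best_frequency(self, frame_rate: float, sine_min_rate: float = 9.0) -> Optional[float]:
        """Frequency for downstream use: FFT below ``sine_min_rate`` frames/s
        (the sine fit may alias there), sine fit otherwise; falls back to
        whichever estimate exists."""
        prefer_fft = frame_rate < sine_min_rate
        primary, secondary = (
            (self.fft_freq, self.freq) if prefer_fft else (self.freq, self.fft_freq)
        )
        return primary if primary is not None else secondary


def _detrend_normalize(y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Remove a least-squares line, then min-max normalize to [0, 1].

    Returns the normalized signal and a constant-signal flag; a signal with
    no variation left after detrending maps to zeros with the flag set.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2 or np.ptp(y) == 0:
        return np.zeros_like(y), True
    detrended = sp_signal.detrend(y, type="linear")
    span = np.ptp(detrended)
    if span <= 0 or not np.isfinite(span):
        return np.zeros_like(detrended), True
    return (detrended - detrended.min()) / span, False


def extract_heartbeat_trace(
    stack: FrameStack, masks: ChamberMaskSeries, chamber: str
) -> ChamberTrace:
    """Per-frame masked intensity sum and chamber area, detrended and
    min-max normalized; the combined signal is their mean."""
    mask = masks.mask(chamber)
    if masks.n_frames != stack.n_frames:
        raise ValueError("mask series and stack disagree in frame count")
    if not mask.any():
        raise EmptySignalError(f"{chamber} mask is empty in every frame")
    frames = stack.frames.astype(float)
    intensity = (frames * mask).sum(axis=(1, 2))
    area = chamber_area_series(masks)[chamber]

    intensity_n, const_i = _detrend_normalize(intensity)
    area_n, const_a = _detrend_normalize(area)
    combined = (intensity_n + area_n) / 2.0
    return ChamberTrace(
        time=stack.times,
        intensity_signal=intensity_n,
        area_signal=area_n,
        combined_signal=combined,
        constant=const_i and const_a,
    )


def _sine(t: np.ndarray, amplitude: float, freq: float, phase: float, offset: float) -> np.ndarray:
    return amplitude * np.sin(2 * np.pi * freq * t + phase) + offset


def _canonical(amplitude: float, freq: float, phase: float) -> tuple[float, float, float]:
    """Normalize to amplitude >= 0 and freq >= 0 by absorbing signs into phase."""
    if freq < 0:
        # A sin(-2πft + φ) = -A sin(2πft - φ)
        freq, amplitude, phase = -freq, -amplitude, -phase
    if amplitude < 0:
        amplitude, phase = -amplitude, phase + np.pi
    return amplitude, freq, phase % (2 * np.pi)


def _fit_segment(t: np.ndarray, y: np.ndarray, frame_rate: float) -> Optional[tuple]:
    """Best sine fit over 30 starting frequencies; returns (params, score)."""
    if np.ptp(y) == 0:
        return None
    f_hi = min(F_MAX, frame_rate / 2.0)
    if f_hi <= F_MIN:
        f_hi = F_MIN * 2
    candidates = np.linspace(F_MIN, f_hi, N_SINE_CANDIDATES)
    amp0 = float(np.std(y)) * np.sqrt(2.0)
    off0 = float(np.mean(y))
    best = None
    for f0 in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _sine, t, y, p0=[amp0, f0, 0.0, off0], maxfev=400
                )
        except RuntimeError:
            continue
        fitted = _sine(t, *popt)
        if np.ptp(fitted) == 0:
            continue
        score = float(pearsonr(y, fitted)[0])
        if not np.isfinite(score):
            continue
        if best is None or score > best[1]:
            best = (popt, score)
    return best


def fit_sine(trace: ChamberTrace, frame_rate: float) -> FrequencyFit:
    """Iterative sine fit of the combined signal.

    Thirty starting frequencies uniformly spanning [0.25, min(6, Nyquist)]
    s^-1 each seed a local least-squares refinement; the refinement with the
    highest Pearson correlation between raw and fitted signal wins.  The same
    sweep runs on the first quarter of the trace, and whichever of the two
    fits scores higher on its own support is returned (ties keep the full
    fit).  A winning score below 0.1 is reported as a fit failure.
    """
    if len(trace) < 12:
        raise InsufficientDataError(f"sine fit needs >= 12 samples, got {len(trace)}")
    y = trace.combined_signal
    if trace.constant or np.ptp(y) == 0:
        return FrequencyFit(freq=None, fit_score=None, used_truncated=False)

    full = _fit_segment(trace.time, y, frame_rate)
    n_quarter = len(trace) // 4
    quarter = (
        _fit_segment(trace.time[:n_quarter], y[:n_quarter], frame_rate)
        if n_quarter >= 8
        else None
    )

    used_truncated = False
    best = full
    if quarter is not None and (best is None or quarter[1] > best[1]):
        best = quarter
        used_truncated = True
    if best is None or best[1] < MIN_FIT_SCORE:
        return FrequencyFit(
            freq=None,
            fit_score=None if best is None else best[1],
            used_truncated=used_truncated,
        )
    popt, score = best
    amplitude, freq, phase = _canonical(popt[0], popt[1], popt[2])
    return FrequencyFit(
        freq=freq,
        amplitude=amplitude,
        phase=phase,
        offset=float(popt[3]),
        fit_score=score,
        used_truncated=used_truncated,
    )


def fft_frequency(trace: ChamberTrace, frame_rate: float) -> Optional[float]:
    """Frequency of the dominant non-DC Fourier component (s^-1).

    Resolution is frame_rate / n_samples; returns None when every non-DC
    magnitude vanishes (constant signal).
    """
    if len(trace) < 8:
        raise InsufficientDataError(f"FFT needs >= 8 samples, got {len(trace)}")
    y = trace.combined_signal - trace.combined_signal.mean()
    if np.ptp(y) == 0:
        return None
    magnitudes = np.abs(np.fft.rfft(y))
    freqs = np.fft.rfftfreq(len(y), d=1.0 / frame_rate)
    magnitudes[0] = 0.0
    if np.allclose(magnitudes, 0.0):
        return None
    return float(freqs[int(np.argmax(magnitudes))])


def autocorrelation_score(trace: ChamberTrace) -> float:
    """Max normalized autocorrelation over lags in [2, n/2]; 0 for constants."""
    if len(trace) < 12:
        raise InsufficientDataError(
            f"autocorrelation needs >= 12 samples, got {len(trace)}"
        )
    y = trace.combined_signal - trace.combined_signal.mean()
    n = len(y)
    power = float(np.dot(y, y)) / n
    if power == 0:
        return 0.0
    raw = np.correlate(y, y, mode="full")[n - 1 :]
    lags = np.arange(n)
    # unbiased estimate: normalize each lag by its overlap length
    unbiased = raw / (n - lags) / power
    return float(np.clip(unbiased[2 : n // 2 + 1].max(), -1.0, 1.0))


def analyze_trace(trace: ChamberTrace, frame_rate: float) -> FrequencyFit:
    """Sine fit + FFT frequency + autocorrelation score in one record."""
    fit = fit_sine(trace, frame_rate)
    fit.fft_freq = fft_frequency(trace, frame_rate)
    fit.autocorr_score = autocorrelation_score(trace)
    return fit
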