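"""Per-fish cardiac phenotypes derived from chamber masks and beat traces.

Definitions (all areas in µm², projected 2-D chamber area):

* heart size — median of the total (atrium + ventricle) area over the first
  six frames; morphology is read early in the recording before bleaching or
  drift can bias it.
* max. dilation / max. contraction — robust extremes (95th / 5th percentile)
  of a chamber's area trace, so a single bad segmentation frame cannot
  dominate.
* absolute contractility — max. dilation − max. contraction;
  relative contractility — that difference as a percentage of max. dilation.
* ejection fraction — the fractional volume change per beat, with volume
  approximated from projected area by V ∝ A^(3/2) (isotropic scaling):
  EF = 100·(1 − (A_contr/A_dil)^(3/2)).
* arrhythmia score — coefficient of variation of the inter-beat intervals
  divided by 0.5, capped at 1; scores ≥ 0.7 are flagged arrhythmic.  The
  scale is implementation-defined (see docs/methods.md): 0 is metronomic and
  the 0.7 flag point corresponds to an interval CV of 0.35.
* conduction score — |f_atrium − f_ventricle| / max(f_atrium, f_ventricle);
  ≥ 0.5 flags a conduction defect.  The atrium:ventricle frequency ratio is
  snapped to the nearest simple ratio (1:1, 3:2, 2:1, 3:1, 4:1); a flagged
  defect at 2:1 is annotated as a Mobitz-II-like block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
from scipy import signal as sp_signal

from .cardio_signal import ChamberTrace, FrequencyFit
from .exceptions import InsufficientDataError
from .segmentation import ChamberMaskSeries, chamber_area_series

#: Arrhythmia scores at or above this are flagged arrhythmic.
ARRHYTHMIA_THRESHOLD = 0.7
#: Conduction scores at or above this are flagged as conduction defects.
CONDUCTION_THRESHOLD = 0.5
#: Robust percentiles standing in for the min/max of an area trace.
EXTREME_PERCENTILES = (5.0, 95.0)
#: Area-to-volume exponent for the ejection-fraction approximation.
EF_VOLUME_EXPONENT = 1.5
#: Candidate atrium:ventricle beat ratios and snapping tolerance (relative).
BEAT_RATIOS = {"1:1": 1.0, "3:2": 1.5, "2:1": 2.0, "3:1": 3.0, "4:1": 4.0}
BEAT_RATIO_TOLERANCE = 0.15


def heart_size(masks: ChamberMaskSeries) -> float:
    """Median over the first six frames of the total heart area (µm²)."""
    if masks.n_frames < 6:
        raise InsufficientDataError(
            f"heart size needs >= 6 frames, got {masks.n_frames}"
        )
    areas = chamber_area_series(masks)
    total = areas["atrium"] + areas["ventricle"]
    return float(np.median(total[:6]))


def chamber_extremes(area_trace: np.ndarray) -> tuple[float, float]:
    """(max_dilation, max_contraction) as the 95th/5th percentile of the trace."""
    area_trace = np.asarray(area_trace, dtype=float)
    if area_trace.size == 0:
        raise ValueError("empty area trace")
    lo, hi = EXTREME_PERCENTILES
    return (
        float(np.percentile(area_trace, hi)),
        float(np.percentile(area_trace, lo)),
    )


def contractility(max_dilation: float, max_contraction: float) -> tuple[float, float]:
    """(absolute µm², relative %) contractility from the area extremes."""
    _check_extremes(max_dilation, max_contraction)
    absolute = max_dilation - max_contraction
    return absolute, 100.0 * absolute / max_dilation


def ejection_fraction(
    max_dilation: float, max_contraction: float, exponent: float = EF_VOLUME_EXPONENT
) -> float:
    """Approximate EF (%) from projected areas via V ∝ A^exponent."""
    _check_extremes(max_dilation, max_contraction)
    return 100.0 * (1.0 - (max_contraction / max_dilation) ** exponent)


def _check_extremes(max_dilation: float, max_contraction: float) -> None:
    if max_dilation <= 0:
        raise ValueError("max_dilation must be positive")
    if not 0 <= max_contraction <= max_dilation:
        raise ValueError("need 0 <= max_contraction <= max_dilation")


def detect_beats(
    trace: ChamberTrace, frame_rate: float, freq: Optional[float] = None
) -> np.ndarray:
    """Beat times (s): peaks of the combined signal above its mid-range,
    separated by at least half the expected beat period when a frequency
    estimate is available."""
    y = trace.combined_signal
    height = (y.max() + y.min()) / 2.0
    distance = 1
    if freq is not None and freq > 0:
        distance = max(1, int(round(0.5 / freq * frame_rate)))
    peaks, _ = sp_signal.find_peaks(y, height=height, distance=distance)
    return peaks / frame_rate


def arrhythmia_score_from_intervals(intervals: np.ndarray) -> float:
    """min(1, CV/0.5) of the inter-beat intervals (population SD)."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        raise ValueError("need >= 2 inter-beat intervals")
    cv = float(np.std(intervals, ddof=0) / np.mean(intervals))
    return min(1.0, cv / 0.5)


def arrhythmia_score(
    trace: ChamberTrace, fit: FrequencyFit, frame_rate: float
) -> Optional[float]:
    """Beat-interval regularity score in [0, 1]; None with < 3 detected beats."""
    beats = detect_beats(trace, frame_rate, fit.freq if fit is not None else None)
    if len(beats) < 3:
        return None
    return arrhythmia_score_from_intervals(np.diff(beats))


@dataclass
class ConductionResult:
    """Atrium-ventricle frequency agreement."""

    score: Optional[float]  # |fa - fv| / max(fa, fv); None when a freq is missing
    beat_ratio: Optional[float]  # fa / fv
    ratio_label: Optional[str]  # snapped simple ratio or "irregular"
    defect: Optional[bool]  # score >= 0.5; None when indeterminate
    annotation: Optional[str] = None  # e.g. "2:1 block (Mobitz-II-like)"


def snap_beat_ratio(ratio: float) -> str:
    """Snap an atrium:ventricle frequency ratio to the nearest simple ratio
    within ±15% relative tolerance; otherwise "irregular".

    Ratios below one (ventricle faster than atrium) are snapped on their
    reciprocal and labelled with the chambers swapped, e.g. "1:2".
    """
    if ratio <= 0 or not np.isfinite(ratio):
        return "irregular"
    inverted = ratio < 1.0
    r = 1.0 / ratio if inverted else ratio
    best_label, best_value = min(
        BEAT_RATIOS.items(), key=lambda kv: abs(r - kv[1]) / kv[1]
    )
    if abs(r - best_value) / best_value > BEAT_RATIO_TOLERANCE:
        return "irregular"
    if inverted and best_label != "1:1":
        a, b = best_label.split(":")
        return f"{b}:{a}"
    return best_label


def conduction_score(
    fit_atrium: FrequencyFit,
    fit_ventricle: FrequencyFit,
    frame_rate: float,
    sine_min_rate: float = 9.0,
) -> ConductionResult:
    """Relative frequency mismatch between the chambers plus the snapped
    beat ratio.  The FFT estimate is preferred below ``sine_min_rate``
    frames/s, the sine-fit estimate otherwise.

    The score is |f_a − f_v| / max(f_a, f_v).  When the measured ratio snaps
    to a simple beat ratio the score is evaluated on the snapped ratio, so a
    2:1 block scores exactly 0.5 and a 1:1 rhythm exactly 0 regardless of
    estimation noise; otherwise the raw frequencies are used.  Scores at or
    above 0.5 flag a conduction defect, and a flagged 2:1 ratio is annotated
    as a Mobitz-II-like block.
    """
    f_a = fit_atrium.best_frequency(frame_rate, sine_min_rate) if fit_atrium else None
    f_v = fit_ventricle.best_frequency(frame_rate, sine_min_rate) if fit_ventricle else None
    if f_a is None or f_v is None or max(f_a, f_v) == 0:
        return ConductionResult(None, None, None, None)
    ratio = f_a / f_v if f_v > 0 else np.inf
    label = snap_beat_ratio(ratio)
    if label != "irregular":
        a, b = (float(x) for x in label.split(":"))
        score = abs(a - b) / max(a, b)
    else:
        score = abs(f_a - f_v) / max(f_a, f_v)
    defect = score >= CONDUCTION_THRESHOLD
    annotation = "2:1 block (Mobitz-II-like)" if defect and label == "2:1" else None
    return ConductionResult(score, ratio, label, defect, annotation)


@dataclass
class PhenotypeRecord:
    """One output row per fish — the CSV contract of the results sheet.

    Fields that could not be computed (failed fits, missing beats) are None
    and appear as empty cells in the sheet.
    """

    source_id: str = ""
    heart_size_um2: Optional[float] = None

    atrium_freq: Optional[float] = None  # s^-1, sine fit
    atrium_fft_freq: Optional[float] = None  # s^-1, FFT
    atrium_hr_bpm: Optional[float] = None  # 60 x sine freq
    atrium_hr_fft_bpm: Optional[float] = None  # 60 x FFT freq
    atrium_fit_score: Optional[float] = None
    atrium_autocorr_score: Optional[float] = None
    atrium_max_dilation_um2: Optional[float] = None
    atrium_max_contraction_um2: Optional[float] = None
    atrium_absolute_contractility_um2: Optional[float] = None
    atrium_relative_contractility_pct: Optional[float] = None
    atrium_ejection_fraction_pct: Optional[float] = None
    atrium_arrhythmia_score: Optional[float] = None
    atrium_arrhythmic: Optional[bool] = None

    ventricle_freq: Optional[float] = None
    ventricle_fft_freq: Optional[float] = None
    ventricle_hr_bpm: Optional[float] = None
    ventricle_hr_fft_bpm: Optional[float] = None
    ventricle_fit_score: Optional[float] = None
    ventricle_autocorr_score: Optional[float] = None
    ventricle_max_dilation_um2: Optional[float] = None
    ventricle_max_contraction_um2: Optional[float] = None
    ventricle_absolute_contractility_um2: Optional[float] = None
    ventricle_relative_contractility_pct: Optional[float] = None
    ventricle_ejection_fraction_pct: Optional[float] = None
    ventricle_arrhythmia_score: Optional[float] = None
    ventricle_arrhythmic: Optional[bool] = None

    conduction_score: Optional[float] = None
    beat_ratio: Optional[float] = None
    beat_ratio_label: Optional[str] = None
    conduction_defect: Optional[bool] = None
    conduction_annotation: Optional[str] = None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def column_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]
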