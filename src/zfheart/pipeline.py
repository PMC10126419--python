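"""End-to-end analysis of one recording: ROI → masks → traces → phenotypes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import phenotypes as ph
from .cardio_signal import ChamberTrace, FrequencyFit, analyze_trace, extract_heartbeat_trace
from .exceptions import ZfHeartError
from .io_media import FrameStack
from .segmentation import (
    CHAMBERS,
    ChamberMaskSeries,
    ChamberSeeds,
    HeartROI,
    detect_heart_roi,
    segment_chambers,
)


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters (all exposed in the CLI sidecar config)."""

    primary_threshold_quantile: float = 0.90
    secondary_threshold_quantile: float = 0.60
    roi_margin: int = 3
    rotation_angle: float = 0.0  # degrees, applied about the ROI center
    sine_min_frame_rate: float = 9.0  # below this, FFT frequencies are preferred
    ef_volume_exponent: float = ph.EF_VOLUME_EXPONENT


@dataclass
class AnalysisResult:
    """Everything one recording yields."""

    record: ph.PhenotypeRecord
    roi: HeartROI
    masks: ChamberMaskSeries
    traces: Dict[str, ChamberTrace]
    fits: Dict[str, FrequencyFit]


def analyze_stack(
    stack: FrameStack,
    seeds: ChamberSeeds,
    config: Optional[AnalysisConfig] = None,
    roi: Optional[HeartROI] = None,
) -> AnalysisResult:
    """Run the full chamber-specific pipeline on one recording.

    Fit failures in a single chamber leave that chamber's fields empty in the
    record instead of aborting the analysis.
    """
    config = config or AnalysisConfig()
    if roi is None:
        roi = detect_heart_roi(
            stack, config.primary_threshold_quantile, margin=config.roi_margin
        )
        roi.rotation_angle = config.rotation_angle
    masks = segment_chambers(stack, roi, seeds, config.secondary_threshold_quantile)

    record = ph.PhenotypeRecord(source_id=stack.source_id)
    record.heart_size_um2 = ph.heart_size(masks)

    traces: Dict[str, ChamberTrace] = {}
    fits: Dict[str, FrequencyFit] = {}
    from .segmentation import chamber_area_series

    areas = chamber_area_series(masks)
    for chamber in CHAMBERS:
        try:
            trace = extract_heartbeat_trace(stack, masks, chamber)
            fit = analyze_trace(trace, stack.frame_rate)
        except ZfHeartError:
            continue
        traces[chamber] = trace
        fits[chamber] = fit

        dilation, contraction = ph.chamber_extremes(areas[chamber])
        absolute, relative = ph.contractility(dilation, contraction)
        ef = ph.ejection_fraction(dilation, contraction, config.ef_volume_exponent)
        arrhythmia = ph.arrhythmia_score(trace, fit, stack.frame_rate)

        prefix = f"{chamber}_"
        values = {
            "freq": fit.freq,
            "fft_freq": fit.fft_freq,
            "hr_bpm": fit.hr_bpm,
            "hr_fft_bpm": fit.hr_fft_bpm,
            "fit_score": fit.fit_score,
            "autocorr_score": fit.autocorr_score,
            "max_dilation_um2": dilation,
            "max_contraction_um2": contraction,
            "absolute_contractility_um2": absolute,
            "relative_contractility_pct": relative,
            "ejection_fraction_pct": ef,
            "arrhythmia_score": arrhythmia,
            "arrhythmic": (
                None if arrhythmia is None else arrhythmia >= ph.ARRHYTHMIA_THRESHOLD
            ),
        }
        for key, value in values.items():
            setattr(record, prefix + key, value)

    if "atrium" in fits and "ventricle" in fits:
        conduction = ph.conduction_score(
            fits["atrium"], fits["ventricle"], stack.frame_rate, config.sine_min_frame_rate
        )
        record.conduction_score = conduction.score
        record.beat_ratio = conduction.beat_ratio
        record.beat_ratio_label = conduction.ratio_label
        record.conduction_defect = conduction.defect
        record.conduction_annotation = conduction.annotation

    return AnalysisResult(record=record, roi=roi, masks=masks, traces=traces, fits=fits)
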