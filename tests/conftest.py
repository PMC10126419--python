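import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from zfheart.pipeline import AnalysisConfig, analyze_stack
from zfheart.segmentation import detect_heart_roi
from zfheart.synthetic import HeartSimParams, default_seeds, generate_heart_video


@pytest.fixture
def regular_video():
    """One regular-rhythm fluorescence video at 12 f/s with ground truth."""
    params = HeartSimParams(frame_rate=12.0, seed=1)
    return generate_heart_video(params)


def analyze_synthetic(params: HeartSimParams, config: AnalysisConfig | None = None):
    """Generate a video and run the full pipeline with generator-derived seeds."""
    stack, truth = generate_heart_video(params)
    roi = detect_heart_roi(
        stack,
        (config or AnalysisConfig()).primary_threshold_quantile,
        margin=(config or AnalysisConfig()).roi_margin,
    )
    seeds = default_seeds(truth, roi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = analyze_stack(stack, seeds, config, roi=roi)
    return stack, truth, result
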