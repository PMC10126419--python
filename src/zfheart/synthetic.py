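"""Synthetic beating-heart videos with analytic ground truth.

The fluorescence renderer draws two bright ellipses (atrium and ventricle)
on a dark background, joined by a dimmer atrioventricular-canal (AVC)
bridge.  Chamber areas follow A(t) = A0 − amp·(1 + sin(2πf·t + φ))/2, so
each chamber oscillates between max. dilation A0 and max. contraction
A0 − amp; both ellipse semi-axes are scaled by √(A(t)/A0) so the area tracks
the waveform exactly.  Rhythm modes reproduce the clinically relevant beat
patterns: a regular rhythm, a 2:1 atrioventricular block (the ventricle
beats at half the atrial frequency), atrial flutter (fast atrium with low
contraction amplitude over a slower ventricle), and an irregular rhythm with
log-normally jittered inter-beat intervals.

Defaults emulate the acquisition used for real embryos — 6 s recordings at
6 frames/s — at a coarse spatial scale (4 µm/pixel, 120x160 frames, the
heart occupying a few percent of the field as in a well image) with chamber
areas in the embryonic range (6 000–8 000 µm²).

The brightfield renderer replaces fluorescence contrast with motion
contrast: a small dark disk pulsing on a bright static texture.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Set, Tuple

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse, disk as draw_disk

from .io_media import FrameStack
from .segmentation import ChamberSeeds, HeartROI

RHYTHM_MODES = ("regular", "block_2to1", "flutter", "irregular")

#: Atrial contraction-amplitude multiplier in flutter mode (shallow beats).
FLUTTER_ATRIAL_AMPLITUDE_FACTOR = 0.3


@dataclass
class HeartSimParams:
    """Parameters of a simulated heartbeat recording.

    Frequencies are in s^-1, areas and amplitudes in µm² (amplitude =
    absolute contractility, i.e. max. dilation − max. contraction).
    ``freq_ventricle=None`` resolves per rhythm mode: equal to the atrium for
    regular/irregular rhythms, half of it for a 2:1 block and for flutter.
    """

    freq_atrium: float = 2.5
    freq_ventricle: Optional[float] = None
    phase_lag: float = 0.8  # radians, ventricle lags the atrium
    atrium_area_um2: float = 6000.0
    ventricle_area_um2: float = 8000.0
    atrium_amplitude_um2: float = 2100.0
    ventricle_amplitude_um2: float = 3200.0
    avc_intensity_fraction: float = 0.5
    rhythm_mode: str = "regular"
    irregular_jitter: float = 0.2  # CV of inter-beat intervals
    noise_sd: float = 4.0  # additive Gaussian pixel noise (intensity units)
    frame_rate: float = 6.0  # frames / s
    duration: float = 6.0  # s
    pixel_size: float = 4.0  # µm / pixel
    frame_shape: Tuple[int, int] = (120, 160)
    chamber_intensity: float = 200.0
    background_intensity: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rhythm_mode not in RHYTHM_MODES:
            raise ValueError(f"rhythm_mode must be one of {RHYTHM_MODES}")
        if not 0 < self.avc_intensity_fraction < 1:
            raise ValueError("avc_intensity_fraction must lie in (0, 1)")
        for name in ("freq_atrium", "frame_rate", "duration", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("atrium", "ventricle"):
            area = getattr(self, f"{name}_area_um2")
            amp = getattr(self, f"{name}_amplitude_um2")
            if not 0 <= amp <= area:
                raise ValueError(f"{name} amplitude must lie in [0, base area]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def resolved_frequencies(self) -> tuple[float, float]:
        """(f_atrium, f_ventricle) after applying the rhythm mode."""
        f_a = self.freq_atrium
        if self.freq_ventricle is not None:
            f_v = self.freq_ventricle
        elif self.rhythm_mode in ("block_2to1", "flutter"):
            f_v = f_a / 2.0
        else:
            f_v = f_a
        if self.rhythm_mode == "block_2to1":
            f_v = f_a / 2.0  # the block fixes the ratio in ground truth
        return f_a, f_v


@dataclass
class GroundTruth:
    """Everything the generator knows about what it rendered."""

    freq_atrium: float  # s^-1
    freq_ventricle: float
    atrium_masks: Optional[np.ndarray] = None  # (n, H, W) bool
    ventricle_masks: Optional[np.ndarray] = None
    atrium_areas_um2: Optional[np.ndarray] = None  # mask pixel count x pixel_size²
    ventricle_areas_um2: Optional[np.ndarray] = None
    beat_times_atrium: Optional[np.ndarray] = None  # s, times of max. contraction
    beat_times_ventricle: Optional[np.ndarray] = None
    heart_size_um2: Optional[float] = None  # median total area, first six frames
    atrium_center: Optional[Tuple[int, int]] = None  # (row, col)
    ventricle_center: Optional[Tuple[int, int]] = None
    params: Optional[HeartSimParams] = None


def _ellipse_semiaxes(area_px: float, aspect: float = 1.25) -> tuple[float, float]:
    """(semi_row, semi_col) of an ellipse with the given pixel area; the
    column axis is ``aspect`` times the row axis."""
    semi_r = np.sqrt(area_px / (np.pi * aspect))
    return semi_r, aspect * semi_r


def _beat_warp(params: HeartSimParams, rng: np.random.Generator) -> np.ndarray:
    """Warped time τ(t) for the irregular mode: inter-beat intervals are
    log-normal with mean 1/f_atrium and CV = irregular_jitter, and τ maps the
    k-th beat back to k/f_atrium so phase = 2πfτ advances 2π per beat."""
    mean_iv = 1.0 / params.freq_atrium
    cv = params.irregular_jitter
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean_iv) - sigma**2 / 2.0
    n_beats = int(np.ceil(params.duration * params.freq_atrium * 3)) + 4
    intervals = rng.lognormal(mu, sigma, size=n_beats)
    beats = np.concatenate([[0.0], np.cumsum(intervals)])
    regular = np.arange(len(beats)) * mean_iv
    t = np.arange(params.n_frames) / params.frame_rate
    return np.interp(t, beats, regular), (beats, regular)


def _beat_times(
    freq: float, phase0: float, duration: float,
    warp: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> np.ndarray:
    """Times at which sin(2πf·τ(t) + φ) peaks (max. contraction)."""
    k = np.arange(0, int(np.ceil(duration * freq)) + 2)
    tau = ((np.pi / 2 - phase0) + 2 * np.pi * k) / (2 * np.pi * freq)
    if warp is not None:
        beats, regular = warp
        times = np.interp(tau, regular, beats)
    else:
        times = tau
    return times[(times >= 0) & (times <= duration)]


def generate_heart_video(params: HeartSimParams) -> tuple[FrameStack, GroundTruth]:
    """Render a fluorescence heartbeat video plus its ground truth."""
    rng = np.random.default_rng(params.seed)
    f_a, f_v = params.resolved_frequencies()
    nyquist = params.frame_rate / 2.0
    if f_a >= nyquist or f_v >= nyquist:
        warnings.warn(
            f"beat frequency at or above Nyquist ({nyquist:g}/s); the rendered "
            "video will alias",
            stacklevel=2,
        )

    n = params.n_frames
    t = np.arange(n) / params.frame_rate
    warp = None
    if params.rhythm_mode == "irregular":
        tau, warp = _beat_warp(params, rng)
    else:
        tau = t
    phase_a = 2 * np.pi * f_a * tau
    phase_v = 2 * np.pi * f_v * tau - params.phase_lag

    amp_a = params.atrium_amplitude_um2
    if params.rhythm_mode == "flutter":
        amp_a *= FLUTTER_ATRIAL_AMPLITUDE_FACTOR
    area_a = params.atrium_area_um2 - amp_a * (1 + np.sin(phase_a)) / 2.0
    area_v = params.ventricle_area_um2 - params.ventricle_amplitude_um2 * (
        1 + np.sin(phase_v)
    ) / 2.0

    h, w = params.frame_shape
    ps2 = params.pixel_size**2
    center_a = (h // 2, int(w * 0.33))
    center_v = (h // 2, int(w * 0.63))
    semi_a0 = _ellipse_semiaxes(params.atrium_area_um2 / ps2)
    semi_v0 = _ellipse_semiaxes(params.ventricle_area_um2 / ps2)

    # short narrow constriction between the chambers
    gap_mid = ((center_a[0] + center_v[0]) // 2, (center_a[1] + center_v[1]) // 2)
    bridge_semi = (2.5, (center_v[1] - center_a[1]) / 2.0)
    avc_value = params.avc_intensity_fraction * params.chamber_intensity

    frames = np.empty((n, h, w), dtype=np.uint8)
    masks_a = np.zeros((n, h, w), dtype=bool)
    masks_v = np.zeros((n, h, w), dtype=bool)
    for i in range(n):
        canvas = np.full((h, w), params.background_intensity, dtype=float)
        rr, cc = draw_ellipse(*gap_mid, *bridge_semi, shape=(h, w))
        canvas[rr, cc] = avc_value
        for center, semi0, area, base, mask in (
            (center_a, semi_a0, area_a[i], params.atrium_area_um2, masks_a),
            (center_v, semi_v0, area_v[i], params.ventricle_area_um2, masks_v),
        ):
            scale = np.sqrt(area / base)
            semi = (semi0[0] * scale, semi0[1] * scale)
            rr, cc = draw_ellipse(center[0], center[1], *semi, shape=(h, w))
            # mild radial falloff (bright core, dimmer rim), as in real
            # fluorescence; keeps the rim well above the AVC intensity
            radial2 = ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2
            canvas[rr, cc] = params.chamber_intensity * (1.0 - 0.25 * radial2)
            mask[i, rr, cc] = True
        canvas += rng.normal(0.0, params.noise_sd, size=(h, w))
        frames[i] = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    areas_a = masks_a.sum(axis=(1, 2)) * ps2
    areas_v = masks_v.sum(axis=(1, 2)) * ps2
    total = areas_a + areas_v
    truth = GroundTruth(
        freq_atrium=f_a,
        freq_ventricle=f_v,
        atrium_masks=masks_a,
        ventricle_masks=masks_v,
        atrium_areas_um2=areas_a,
        ventricle_areas_um2=areas_v,
        beat_times_atrium=_beat_times(f_a, 0.0, params.duration, warp),
        beat_times_ventricle=_beat_times(f_v, -params.phase_lag, params.duration, warp),
        heart_size_um2=float(np.median(total[: min(6, n)])),
        atrium_center=center_a,
        ventricle_center=center_v,
        params=params,
    )
    stack = FrameStack(
        frames=frames,
        frame_rate=params.frame_rate,
        pixel_size=params.pixel_size,
        source_id=f"synthetic-{params.rhythm_mode}-seed{params.seed}",
    )
    return stack, truth


def default_seeds(truth: GroundTruth, roi: HeartROI, half_size: int = 3) -> ChamberSeeds:
    """Square seed polygons centered on the true chamber centers, expressed
    in ROI coordinates — the stand-in for interactively drawn seeds."""

    def square(center: Tuple[int, int]) -> np.ndarray:
        r = center[0] - roi.row_start
        c = center[1] - roi.col_start
        h = half_size
        return np.array(
            [[r - h, c - h], [r - h, c + h], [r + h, c + h], [r + h, c - h]], dtype=float
        )

    return ChamberSeeds(
        atrium=square(truth.atrium_center), ventricle=square(truth.ventricle_center)
    )


def generate_bf_video(params: HeartSimParams) -> tuple[FrameStack, GroundTruth]:
    """Render a brightfield-style video: a pulsing dark disk (the heart) on a
    bright static texture, beating at the atrial frequency."""
    rng = np.random.default_rng(params.seed)
    f_a, f_v = params.resolved_frequencies()
    if f_a >= params.frame_rate / 2.0:
        warnings.warn("beat frequency at or above Nyquist; the video will alias",
                      stacklevel=2)
    n = params.n_frames
    h, w = params.frame_shape
    t = np.arange(n) / params.frame_rate
    texture = rng.uniform(120, 220, size=(h, w))
    center = (h // 2, w // 2)
    base_radius = max(4.0, min(h, w) / 10.0)
    radius = base_radius * (1.0 + 0.25 * np.sin(2 * np.pi * f_a * t))

    frames = np.empty((n, h, w), dtype=np.uint8)
    for i in range(n):
        canvas = texture.copy()
        rr, cc = draw_disk(center, radius[i], shape=(h, w))
        canvas[rr, cc] = 60.0
        canvas += rng.normal(0.0, params.noise_sd, size=(h, w))
        frames[i] = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    stack = FrameStack(
        frames=frames,
        frame_rate=params.frame_rate,
        pixel_size=params.pixel_size,
        source_id=f"synthetic-bf-seed{params.seed}",
    )
    truth = GroundTruth(
        freq_atrium=f_a,
        freq_ventricle=f_v,
        beat_times_atrium=_beat_times(f_a, 0.0, params.duration),
        params=params,
    )
    return stack, truth


def generate_screen_dataset(
    n_compounds: int,
    n_replicates: int = 3,
    hit_fraction: float = 0.05,
    effect_z: float = 3.0,
    seed: int = 0,
    n_controls: int = 24,
    control_mean_bpm: float = 160.0,
    control_sd_bpm: float = 10.0,
    experiment_id: str = "exp1",
) -> tuple[pd.DataFrame, Set[str]]:
    """Synthetic per-embryo screen table plus the set of true hit compounds.

    Control and null-compound heart rates are drawn from the same normal
    distribution; spiked compounds are shifted by ``effect_z`` control SDs
    with a random sign.
    """
    if not 0 <= hit_fraction <= 1:
        raise ValueError("hit_fraction must lie in [0, 1]")
    if n_replicates < 1 or n_controls < 1:
        raise ValueError("n_replicates and n_controls must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_controls):
        rows.append(
            {
                "embryo_id": f"ctrl_{i:03d}",
                "compound": "DMSO",
                "replicate": i,
                "experiment_id": experiment_id,
                "role": "control",
                "hr_bpm": rng.normal(control_mean_bpm, control_sd_bpm),
            }
        )
    is_hit = rng.random(n_compounds) < hit_fraction
    signs = rng.choice([-1.0, 1.0], size=n_compounds)
    hits: Set[str] = set()
    for c in range(n_compounds):
        name = f"C{c:04d}"
        shift = effect_z * control_sd_bpm * signs[c] if is_hit[c] else 0.0
        if is_hit[c]:
            hits.add(name)
        for rep in range(n_replicates):
            rows.append(
                {
                    "embryo_id": f"{name}_r{rep}",
                    "compound": name,
                    "replicate": rep,
                    "experiment_id": experiment_id,
                    "role": "compound",
                    "hr_bpm": rng.normal(control_mean_bpm + shift, control_sd_bpm),
                }
            )
    return pd.DataFrame(rows), hits
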