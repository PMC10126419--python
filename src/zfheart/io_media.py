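"""Reading heartbeat recordings and writing the three output artifacts.

A recording enters the pipeline as a :class:`FrameStack`: an ordered stack of
2-D grayscale frames together with the acquisition frame rate (frames/second)
and pixel size (µm/pixel).  Accepted sources are a directory of single-frame
TIFF/PNG files (sorted into temporal order by natural numeric filename order),
a multi-page TIFF, or a video container (GIF always; AVI/MP4 when an imageio
backend for them is installed).

Outputs are a CSV data sheet (one row per fish), an animated GIF with a
blue-to-yellow intensity lookup table and chamber outlines, and a two-panel
PNG of the per-chamber heartbeat traces with their fitted sine curves.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import imageio.v2 as iio
import matplotlib
import numpy as np
import tifffile

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .exceptions import FormatError, InsufficientDataError

if TYPE_CHECKING:  # pragma: no cover
    from .cardio_signal import ChamberTrace, FrequencyFit
    from .phenotypes import PhenotypeRecord
    from .segmentation import ChamberMaskSeries

#: Minimum number of frames any analysis needs (morphology uses the first six).
MIN_FRAMES = 6

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}
_VIDEO_SUFFIXES = {".avi", ".mp4", ".gif", ".mov"}

# Rec. 601 luma weights for color -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameStack:
    """Ordered grayscale frames plus acquisition metadata."""

    frames: np.ndarray  # (n_frames, height, width)
    frame_rate: float  # frames / second (effective, after any skipping)
    pixel_size: float  # µm / pixel
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be a (n, height, width) array, got shape {self.frames.shape}"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class AcquisitionConfig:
    """How to load a recording.

    skip_interval keeps every k-th frame (the effective frame rate becomes
    frame_rate / skip_interval); trim_seconds truncates the recording to at
    most that duration, anchored at the start.
    """

    frame_rate: float
    pixel_size: float
    skip_interval: int = 1
    trim_seconds: Optional[float] = None
    overwrite: bool = False

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.skip_interval < 1 or int(self.skip_interval) != self.skip_interval:
            raise ValueError("skip_interval must be an integer >= 1")
        if self.trim_seconds is not None and self.trim_seconds <= 0:
            raise ValueError("trim_seconds must be positive when set")

    @property
    def effective_frame_rate(self) -> float:
        return self.frame_rate / self.skip_interval


def natural_sort_key(name: str) -> tuple:
    """Sort key treating digit runs numerically: frame_2 before frame_10."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p.lower() for p in parts)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse a color frame to luminance (Rec. 601); pass grayscale through."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        lum = frame[..., :3].astype(float) @ _LUMA
        if np.issubdtype(frame.dtype, np.integer):
            return np.round(lum).astype(frame.dtype)
        return lum.astype(frame.dtype)
    raise FormatError(f"cannot interpret frame of shape {frame.shape} as an image")


def _read_image_series(directory: Path) -> tuple[list[np.ndarray], list[Path]]:
    files = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
        key=lambda p: natural_sort_key(p.name),
    )
    if not files:
        raise FormatError(f"no TIFF/PNG frames found in {directory}")
    frames = []
    for path in files:
        try:
            if path.suffix.lower() in (".tif", ".tiff"):
                img = tifffile.imread(path)
            else:
                img = iio.imread(path)
        except Exception as exc:  # noqa: BLE001 - rewrap with the filename
            raise FormatError(f"could not read frame {path}: {exc}") from exc
        frames.append(to_grayscale(img))
    return frames, files

def _read_video(path: Path) -> list[np.ndarray]:
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            data = tifffile.imread(path)
            if data.ndim == 2:
                data = data[None]
            return [to_grayscale(f) for f in data]
        reader = iio.get_reader(path)
        return [to_grayscale(np.asarray(f)) for f in reader]
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not read video {path}: {exc}") from exc


def load_frame_stack(source: str | Path, config: AcquisitionConfig) -> FrameStack:
    """Load a recording from an image-series directory or a video/stack file.

    Frame skipping is applied first (every ``skip_interval``-th frame is kept
    and the frame rate is divided accordingly), then the recording is trimmed
    to ``trim_seconds`` from the start.
    """
    source = Path(source)
    if not source.exists():
        raise FormatError(f"input {source} does not exist")

    if source.is_dir():
        frames, files = _read_image_series(source)
        shape0 = frames[0].shape
        for f, p in zip(frames, files):
            if f.shape != shape0:
                raise FormatError(
                    f"frame {p} has size {f.shape}, expected {shape0} (mixed-size series)"
                )
    else:
        if source.suffix.lower() not in _IMAGE_SUFFIXES | _VIDEO_SUFFIXES:
            raise FormatError(f"unsupported input format: {source.suffix}")
        frames = _read_video(source)
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise FormatError(f"video {source} contains mixed-size frames: {shapes}")

    stack = np.stack([np.asarray(f) for f in frames])
    stack = stack[:: config.skip_interval]
    rate = config.effective_frame_rate
    if config.trim_seconds is not None:
        n_keep = int(np.floor(config.trim_seconds * rate + 1e-9))
        stack = stack[:n_keep]
    if stack.shape[0] < MIN_FRAMES:
        raise InsufficientDataError(
            f"only {stack.shape[0]} frames after skipping/trimming; "
            f"at least {MIN_FRAMES} are required"
        )
    return FrameStack(
        frames=stack,
        frame_rate=rate,
        pixel_size=config.pixel_size,
        source_id=source.stem if source.is_file() else source.name,
    )


def write_frame_series(stack: FrameStack, directory: str | Path, fmt: str = "tif") -> list[Path]:
    """Write a stack as numbered single-frame files (round-trip helper)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(stack.frames):
        path = directory / f"frame_{i:04d}.{fmt}"
        if fmt in ("tif", "tiff"):
            tifffile.imwrite(path, frame)
        else:
            iio.imwrite(path, frame)
        paths.append(path)
    return paths


def write_results_sheet(records: Sequence["PhenotypeRecord"], path: str | Path) -> None:
    """Write one CSV row per fish; missing values become empty cells."""
    import pandas as pd

    if len(records) == 0:
        raise ValueError("no records to write")
    rows = [r.to_dict() for r in records]
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)


def blue_yellow_lut(values: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    """Map intensities through a linear blue (min) -> yellow (max) LUT.

    A degenerate range (vmax == vmin) maps everything to the midpoint color.
    """
    if vmax > vmin:
        t = np.clip((values.astype(float) - vmin) / (vmax - vmin), 0.0, 1.0)
    else:
        t = np.full(values.shape, 0.5)
    rgb = np.empty(values.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = np.round(255 * t)
    rgb[..., 1] = np.round(255 * t)
    rgb[..., 2] = np.round(255 * (1 - t))
    return rgb


def render_heartbeat_animation(
    stack: FrameStack, masks: "ChamberMaskSeries", path: str | Path
) -> None:
    """Write an animated GIF of the recording with chamber outlines.

    Intensities are scaled between the stack-wide minimum and maximum and
    mapped blue (min) to yellow (max); atrium outlines are drawn red and
    ventricle outlines white on every frame.
    """
    from skimage.segmentation import find_boundaries

    if masks.n_frames != stack.n_frames:
        raise ValueError(
            f"mask series has {masks.n_frames} frames but stack has {stack.n_frames}"
        )
    vmin = float(stack.frames.min())
    vmax = float(stack.frames.max())
    rendered = []
    for i in range(stack.n_frames):
        rgb = blue_yellow_lut(stack.frames[i], vmin, vmax)
        a_edge = find_boundaries(masks.atrium[i], mode="outer")
        v_edge = find_boundaries(masks.ventricle[i], mode="outer")
        rgb[a_edge] = (255, 60, 60)
        rgb[v_edge] = (255, 255, 255)
        rendered.append(rgb)
    iio.mimwrite(path, rendered, duration=1.0 / stack.frame_rate, loop=0)


def render_trace_plot(
    traces: Sequence["ChamberTrace"],
    fits: Sequence[Optional["FrequencyFit"]],
    path: str | Path,
    labels: Sequence[str] = ("atrium", "ventricle"),
) -> None:
    """Two-panel figure: raw combined signal per chamber with the fitted sine
    (red dotted) overlaid and the sine/FFT frequencies annotated."""
    if len(traces) != len(fits):
        raise ValueError("traces and fits must pair up")
    for trace in traces:
        if len(trace.time) == 0:
            raise ValueError("zero-length trace")

    fig, axes = plt.subplots(len(traces), 1, figsize=(8, 2.6 * len(traces)), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, trace, fit, label in zip(axes, traces, fits, labels):
        ax.plot(trace.time, trace.combined_signal, color="black", lw=1, label="raw")
        note = "fit failed"
        if fit is not None and fit.freq is not None:
            t_dense = np.linspace(trace.time[0], trace.time[-1], 512)
            y_fit = fit.amplitude * np.sin(2 * np.pi * fit.freq * t_dense + fit.phase) + fit.offset
            ax.plot(t_dense, y_fit, "r:", lw=1.5, label="sine fit")
            note = f"freq = {fit.freq:.2f}/s"
            if fit.fft_freq is not None:
                note += f"   fft_freq = {fit.fft_freq:.2f}/s"
        ax.set_title(f"{label}: {note}", fontsize=10)
        ax.set_ylabel("signal (a.u.)")
        ax.legend(loc="upper right", fontsize=8)
    axes[-1].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
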