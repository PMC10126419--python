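"""Locating the fluorescent heart and segmenting its chambers.

The heart region of interest (ROI) is found by thresholding the temporal
maximum-intensity projection at a configurable intensity quantile and taking
the bounding box of the largest connected supra-threshold component.  Within
the ROI, per-frame secondary quantile thresholds separate the bright chambers
from the dimmer atrioventricular canal (AVC); user-supplied seed polygons
(one per chamber, drawn in ROI coordinates) decide which supra-threshold
component is the atrium and which the ventricle.  Pixels claimed by both
chambers — e.g. when the AVC stays above threshold and bridges them into one
component — are assigned to the chamber whose seed centroid is nearer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as cc_label
from skimage.transform import rotate as sk_rotate

from .exceptions import NoHeartDetectedError, SegmentationFailureError
from .io_media import FrameStack

CHAMBERS = ("atrium", "ventricle")


@dataclass
class HeartROI:
    """Axis-aligned bounding box (half-open, 0-based row/col) of the heart,
    plus a rotation angle (degrees, about the ROI center) applied before
    chamber seeding."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    rotation_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("ROI must be non-empty")
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("ROI must lie within the frame")

    @property
    def height(self) -> int:
        return self.row_stop - self.row_start

    @property
    def width(self) -> int:
        return self.col_stop - self.col_start

    @property
    def center(self) -> tuple[float, float]:
        """(row, col) center of the box in frame coordinates."""
        return (
            (self.row_start + self.row_stop - 1) / 2.0,
            (self.col_start + self.col_stop - 1) / 2.0,
        )


@dataclass
class ChamberSeeds:
    """Seed polygons in (row, col) ROI coordinates, 0-based.

    Which polygon is the atrium is taken from the caller/config and never
    inferred from the image.
    """

    atrium: np.ndarray  # (n_vertices, 2)
    ventricle: np.ndarray

    def __post_init__(self) -> None:
        self.atrium = np.asarray(self.atrium, dtype=float)
        self.ventricle = np.asarray(self.ventricle, dtype=float)
        for name, poly in (("atrium", self.atrium), ("ventricle", self.ventricle)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(f"{name} seed must be a (n>=3, 2) vertex array")
            if _polygon_area(poly) <= 0:
                raise ValueError(f"{name} seed polygon is degenerate (zero area)")

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {"atrium": self.atrium, "ventricle": self.ventricle}


@dataclass
class ChamberMaskSeries:
    """Per-frame binary masks for both chambers, in frame coordinates."""

    atrium: np.ndarray  # (n_frames, height, width) bool
    ventricle: np.ndarray
    pixel_size: float  # µm / pixel

    def __post_init__(self) -> None:
        self.atrium = np.asarray(self.atrium, dtype=bool)
        self.ventricle = np.asarray(self.ventricle, dtype=bool)
        if self.atrium.shape != self.ventricle.shape:
            raise ValueError("atrium and ventricle mask series must share shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.atrium.shape[0]

    def mask(self, chamber: str) -> np.ndarray:
        if chamber not in CHAMBERS:
            raise ValueError(f"unknown chamber {chamber!r}")
        return self.atrium if chamber == "atrium" else self.ventricle


def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a polygon given as (row, col) vertices."""
    r = vertices[:, 0]
    c = vertices[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def detect_heart_roi(
    stack: FrameStack,
    primary_threshold_quantile: float = 0.90,
    margin: int = 3,
) -> HeartROI:
    """Find the heart bounding box on the temporal maximum projection.

    The threshold is the given intensity quantile of the projection; the ROI
    is the bounding box of the largest connected strictly-supra-threshold
    component, padded by ``margin`` pixels and clipped to the frame.
    """
    if not 0 < primary_threshold_quantile < 1:
        raise ValueError("primary_threshold_quantile must lie in (0, 1)")
    projection = stack.frames.max(axis=0).astype(float)
    threshold = float(np.quantile(projection, primary_threshold_quantile))
    supra = projection > threshold
    if not supra.any():
        raise NoHeartDetectedError(
            f"no pixels above the primary threshold "
            f"(quantile {primary_threshold_quantile}, value {threshold:g})"
        )
    labels = cc_label(supra, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = int(np.argmax(counts))
    rows, cols = np.nonzero(labels == biggest)
    h, w = projection.shape
    return HeartROI(
        row_start=max(0, int(rows.min()) - margin),
        row_stop=min(h, int(rows.max()) + 1 + margin),
        col_start=max(0, int(cols.min()) - margin),
        col_stop=min(w, int(cols.max()) + 1 + margin),
        rotation_angle=0.0,
    )


def _rotated_frames(stack: FrameStack, roi: HeartROI) -> np.ndarray:
    """Frames rotated about the ROI center (bilinear); identity when angle 0."""
    if roi.rotation_angle == 0.0:
        return stack.frames.astype(float)
    center_rc = roi.center
    out = np.empty(stack.frames.shape, dtype=float)
    for i, frame in enumerate(stack.frames):
        # skimage rotates about (col, row) center, counter-clockwise degrees
        out[i] = sk_rotate(
            frame.astype(float),
            roi.rotation_angle,
            center=(center_rc[1], center_rc[0]),
            preserve_range=True,
            order=1,
        )
    return out


def _seed_mask(poly_roi: np.ndarray, roi: HeartROI, frame_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a seed polygon (ROI coords) into a frame-sized boolean mask."""
    if (poly_roi[:, 0].min() < 0 or poly_roi[:, 1].min() < 0
            or poly_roi[:, 0].max() >= roi.height or poly_roi[:, 1].max() >= roi.width):
        raise ValueError("seed polygon lies outside the ROI")
    rr, cc = draw_polygon(
        poly_roi[:, 0] + roi.row_start, poly_roi[:, 1] + roi.col_start, shape=frame_shape
    )
    mask = np.zeros(frame_shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def segment_chambers(
    stack: FrameStack,
    roi: HeartROI,
    seeds: ChamberSeeds,
    secondary_threshold_quantile: float = 0.60,
    max_miss_fraction: float = 0.5,
) -> ChamberMaskSeries:
    """Per-frame chamber masks from secondary within-ROI quantile thresholds.

    For every frame, pixels inside the ROI exceeding that frame's secondary
    threshold are labeled into connected components; each chamber takes the
    component that maximally overlaps its seed polygon.  When both chambers
    land on the same component (AVC above threshold), the shared pixels are
    split by distance to the two seed centroids.
    """
    if not 0 < secondary_threshold_quantile < 1:
        raise ValueError("secondary_threshold_quantile must lie in (0, 1)")

    frames = _rotated_frames(stack, roi)
    frame_shape = frames.shape[1:]
    seed_masks = {
        name: _seed_mask(poly, roi, frame_shape) for name, poly in seeds.as_dict().items()
    }
    centroids = {}
    for name, mask in seed_masks.items():
        rows, cols = np.nonzero(mask)
        centroids[name] = (rows.mean(), cols.mean())

    rs, re_, cs, ce = roi.row_start, roi.row_stop, roi.col_start, roi.col_stop
    rr_grid, cc_grid = np.meshgrid(np.arange(rs, re_), np.arange(cs, ce), indexing="ij")
    dist = {
        name: np.hypot(rr_grid - centroids[name][0], cc_grid - centroids[name][1])
        for name in CHAMBERS
    }
    atrium_closer = dist["atrium"] <= dist["ventricle"]

    n = stack.n_frames
    out = {name: np.zeros((n,) + frame_shape, dtype=bool) for name in CHAMBERS}
    misses = {name: 0 for name in CHAMBERS}
    shared_warned = False

    for i in range(n):
        sub = frames[i, rs:re_, cs:ce]
        threshold = float(np.quantile(sub, secondary_threshold_quantile))
        supra = sub > threshold
        labels = cc_label(supra, connectivity=2)
        chosen = {}
        for name in CHAMBERS:
            seed_sub = seed_masks[name][rs:re_, cs:ce]
            overlap = np.bincount(labels[seed_sub], minlength=labels.max() + 1)
            overlap[0] = 0
            if overlap.sum() == 0:
                misses[name] += 1
                chosen[name] = 0
            else:
                chosen[name] = int(np.argmax(overlap))

        a_mask = labels == chosen["atrium"] if chosen["atrium"] else np.zeros_like(supra)
        v_mask = labels == chosen["ventricle"] if chosen["ventricle"] else np.zeros_like(supra)
        both = a_mask & v_mask
        if both.any():
            if not shared_warned:
                warnings.warn(
                    "atrium and ventricle seeds overlap the same supra-threshold "
                    "component; splitting shared pixels by seed-centroid distance",
                    stacklevel=2,
                )
                shared_warned = True
            a_mask = a_mask & (~both | atrium_closer)
            v_mask = v_mask & (~both | ~atrium_closer)
        out["atrium"][i, rs:re_, cs:ce] = a_mask
        out["ventricle"][i, rs:re_, cs:ce] = v_mask

    for name in CHAMBERS:
        if misses[name] / n > max_miss_fraction:
            raise SegmentationFailureError(name, misses[name] / n)

    return ChamberMaskSeries(
        atrium=out["atrium"], ventricle=out["ventricle"], pixel_size=stack.pixel_size
    )


def chamber_area_series(masks: ChamberMaskSeries) -> Dict[str, np.ndarray]:
    """Per-chamber area trace in µm² (pixel count x pixel_size²)."""
    factor = masks.pixel_size**2
    return {
        "atrium": masks.atrium.sum(axis=(1, 2)) * factor,
        "ventricle": masks.ventricle.sum(axis=(1, 2)) * factor,
    }
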