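"""Heart ROI detection and chamber segmentation."""

import numpy as np
import pytest
from skimage.measure import label as cc_label

from zfheart.exceptions import NoHeartDetectedError
from zfheart.io_media import FrameStack
from zfheart.segmentation import (
    ChamberMaskSeries,
    ChamberSeeds,
    HeartROI,
    chamber_area_series,
    detect_heart_roi,
    segment_chambers,
)
from zfheart.synthetic import HeartSimParams, default_seeds, generate_heart_video


def _ellipse_stack(center=(20, 30), semi=(6, 9), shape=(48, 64), n=8, value=200):
    from skimage.draw import ellipse

    frames = np.full((n,) + shape, 5, dtype=np.uint8)
    rr, cc = ellipse(*center, *semi, shape=shape)
    frames[:, rr, cc] = value
    return FrameStack(frames=frames, frame_rate=6.0, pixel_size=2.0), (rr, cc)


def _oracle_roi(stack, quantile, margin):
    """Exhaustive connected-component oracle for the ROI box."""
    proj = stack.frames.max(axis=0).astype(float)
    mask = proj > np.quantile(proj, quantile)
    labels = cc_label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    rows, cols = np.nonzero(labels == counts.argmax())
    h, w = proj.shape
    return (max(0, rows.min() - margin), min(h, rows.max() + 1 + margin),
            max(0, cols.min() - margin), min(w, cols.max() + 1 + margin))


class TestDetectHeartROI:
    def test_single_ellipse_matches_component_oracle(self):
        stack, (rr, cc) = _ellipse_stack()
        roi = detect_heart_roi(stack, 0.90, margin=3)
        assert (roi.row_start, roi.row_stop, roi.col_start, roi.col_stop) == _oracle_roi(
            stack, 0.90, 3
        )
        # ROI contains the ellipse centroid and >= 99% of its pixels
        assert roi.row_start <= 20 < roi.row_stop and roi.col_start <= 30 < roi.col_stop
        inside = (
            (rr >= roi.row_start) & (rr < roi.row_stop)
            & (cc >= roi.col_start) & (cc < roi.col_stop)
        )
        assert inside.mean() >= 0.99

    def test_all_zero_stack_raises(self):
        stack = FrameStack(
            frames=np.zeros((6, 20, 20), dtype=np.uint8), frame_rate=6.0, pixel_size=1.0
        )
        with pytest.raises(NoHeartDetectedError):
            detect_heart_roi(stack)

    def test_bridged_blobs_give_single_roi(self):
        # two bright blobs joined by a dim canal that stays above threshold
        from skimage.draw import ellipse

        frames = np.zeros((6, 40, 80), dtype=np.uint8)
        for c in (20, 60):
            rr, cc = ellipse(20, c, 6, 8, shape=(40, 80))
            frames[:, rr, cc] = 200
        frames[:, 18:23, 26:55] = 100  # bridge, above the quantile threshold
        stack = FrameStack(frames=frames, frame_rate=6.0, pixel_size=1.0)
        roi = detect_heart_roi(stack, 0.80, margin=0)
        oracle = _oracle_roi(stack, 0.80, 0)
        assert (roi.row_start, roi.row_stop, roi.col_start, roi.col_stop) == oracle
        assert roi.col_start <= 20 and roi.col_stop > 60  # spans both blob centers


class TestSegmentChambers:
    def test_avc_excluded_high_iou_every_frame(self):
        # bridge intensity below the secondary threshold -> disjoint chambers
        params = HeartSimParams(
            noise_sd=0.0, frame_rate=12.0, seed=4,
            atrium_amplitude_um2=900.0, ventricle_amplitude_um2=1200.0,
        )
        stack, truth = generate_heart_video(params)
        roi = detect_heart_roi(stack)
        masks = segment_chambers(
            stack, roi, default_seeds(truth, roi), secondary_threshold_quantile=0.63
        )
        for i in range(stack.n_frames):
            for got, want in (
                (masks.atrium[i], truth.atrium_masks[i]),
                (masks.ventricle[i], truth.ventricle_masks[i]),
            ):
                iou = (got & want).sum() / (got | want).sum()
                assert iou >= 0.9
        assert not (masks.atrium & masks.ventricle).any()

    def test_mean_iou_across_noise_grid(self):
        # SNR = (chamber - background contrast) / noise SD >= 5
        ious = []
        for noise_sd in (2.0, 19.0, 38.0):
            for seed in (5, 6):
                params = HeartSimParams(noise_sd=noise_sd, frame_rate=12.0, seed=seed)
                stack, truth = generate_heart_video(params)
                roi = detect_heart_roi(stack)
                masks = segment_chambers(
                    stack, roi, default_seeds(truth, roi),
                    secondary_threshold_quantile=0.70,
                )
                for got, want in (
                    (masks.atrium, truth.atrium_masks),
                    (masks.ventricle, truth.ventricle_masks),
                ):
                    inter = (got & want).sum(axis=(1, 2))
                    union = (got | want).sum(axis=(1, 2))
                    ious.extend(inter / union)
        assert np.mean(ious) >= 0.85

    def test_masks_always_disjoint(self, regular_video):
        stack, truth = regular_video
        roi = detect_heart_roi(stack)
        with pytest.warns(UserWarning):
            masks = segment_chambers(stack, roi, default_seeds(truth, roi),
                                     secondary_threshold_quantile=0.5)
        assert not (masks.atrium & masks.ventricle).any()

    def test_same_blob_seeds_split_by_centroid_with_warning(self):
        stack, (rr, cc) = _ellipse_stack(center=(20, 30), semi=(8, 14))
        roi = detect_heart_roi(stack, 0.85, margin=2)
        left = np.array([[10, 4], [10, 10], [16, 10], [16, 4]], dtype=float)
        right = np.array([[10, 22], [10, 28], [16, 28], [16, 22]], dtype=float)
        seeds = ChamberSeeds(atrium=left, ventricle=right)
        with pytest.warns(UserWarning, match="centroid"):
            masks = segment_chambers(stack, roi, seeds, secondary_threshold_quantile=0.3)
        assert not (masks.atrium & masks.ventricle).any()
        assert masks.atrium.any() and masks.ventricle.any()
        # every supra-threshold pixel went to the nearer seed
        a_cols = np.nonzero(masks.atrium[0])[1]
        v_cols = np.nonzero(masks.ventricle[0])[1]
        assert a_cols.max() < v_cols.min()

    def test_seed_outside_roi_rejected(self, regular_video):
        stack, truth = regular_video
        roi = detect_heart_roi(stack)
        bad = ChamberSeeds(
            atrium=np.array([[-5, 0], [-5, 4], [0, 4]], dtype=float),
            ventricle=np.array([[2, 2], [2, 6], [6, 6]], dtype=float),
        )
        with pytest.raises(ValueError, match="outside"):
            segment_chambers(stack, roi, bad)

    def test_equivariant_under_90_degree_rotation(self):
        params = HeartSimParams(noise_sd=0.0, frame_rate=12.0, seed=4, duration=1.0,
                                atrium_amplitude_um2=900.0, ventricle_amplitude_um2=1200.0)
        stack, truth = generate_heart_video(params)
        roi = detect_heart_roi(stack)
        seeds = default_seeds(truth, roi)
        masks = segment_chambers(stack, roi, seeds, secondary_threshold_quantile=0.63)

        h, w = stack.shape
        rot_frames = np.rot90(stack.frames, k=1, axes=(1, 2))
        rot_stack = FrameStack(frames=rot_frames, frame_rate=stack.frame_rate,
                               pixel_size=stack.pixel_size)
        # rot90 maps (r, c) -> (w - 1 - c, r)
        rot_roi = HeartROI(
            row_start=w - roi.col_stop, row_stop=w - roi.col_start,
            col_start=roi.row_start, col_stop=roi.row_stop,
        )

        def rot_poly(poly):
            frame_rc = poly + [roi.row_start, roi.col_start]
            rot_rc = np.column_stack([w - 1 - frame_rc[:, 1], frame_rc[:, 0]])
            return rot_rc - [rot_roi.row_start, rot_roi.col_start]

        rot_seeds = ChamberSeeds(atrium=rot_poly(seeds.atrium),
                                 ventricle=rot_poly(seeds.ventricle))
        rot_masks = segment_chambers(rot_stack, rot_roi, rot_seeds,
                                     secondary_threshold_quantile=0.63)
        np.testing.assert_array_equal(
            rot_masks.atrium, np.rot90(masks.atrium, k=1, axes=(1, 2))
        )
        np.testing.assert_array_equal(
            rot_masks.ventricle, np.rot90(masks.ventricle, k=1, axes=(1, 2))
        )


class TestChamberAreas:
    def test_area_is_count_times_pixel_size_squared(self):
        a = np.zeros((3, 10, 10), dtype=bool)
        a[:, :10, :10] = False
        a[0, :5, :5] = True  # 25 px
        a[1] = False
        v = np.zeros_like(a)
        masks = ChamberMaskSeries(atrium=a, ventricle=v, pixel_size=1.3)
        areas = chamber_area_series(masks)
        assert areas["atrium"][0] == pytest.approx(25 * 1.69)
        assert areas["atrium"][1] == 0.0
        assert np.all(areas["ventricle"] == 0.0)

    def test_hundred_pixels_at_1p3_um(self):
        a = np.zeros((1, 20, 20), dtype=bool)
        a[0, :10, :10] = True  # 100 px
        masks = ChamberMaskSeries(atrium=a, ventricle=np.zeros_like(a), pixel_size=1.3)
        assert chamber_area_series(masks)["atrium"][0] == pytest.approx(169.0)
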