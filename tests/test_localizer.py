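import math

import numpy as np
import pytest

from kneealign.geometry import Point2D, SimilarityTransform
from kneealign.localizer import (
    FrameDegenerateError,
    LocalizationError,
    OracleModel,
    ReferenceFrameSpec,
    global_search,
    localize,
    make_frame,
    resample_to_frame,
)
from kneealign.nn import ModelConfig, build_hourglass
from kneealign.phantom import PhantomRanges, generate_dataset

FRAME = ReferenceFrameSpec(crop_size=128, anchor_separation_fraction=0.165)
RANGES = PhantomRanges(atfa=(-12, 12), global_rotation=(-5, 5))


def corners_of(sample):
    lm = sample.landmarks
    return np.array(
        [
            lm.point_for("plateau_corner_left").as_array(),
            lm.point_for("plateau_corner_right").as_array(),
        ]
    )


def oracle_global(sample):
    # full-resolution oracle: the resize is then the identity, so decode
    # quantization (~0.25 px) stays within the 0.5 px recovery tolerance
    input_size = sample.image.shape[0]
    return OracleModel(corners_of(sample), input_size)


def oracle_local(sample, frame_spec=FRAME):
    # encode the ground truth in the frame the pipeline will actually build,
    # i.e. the one implied by the globally detected reference points
    r1, r2 = global_search(sample.image, oracle_global(sample))
    frame = make_frame(r1, r2, frame_spec)
    crop_xy = frame.apply_array(sample.landmarks.as_array())
    return OracleModel(crop_xy, frame_spec.crop_size)


class TestGlobalSearch:
    def test_oracle_recovers_corners(self):
        sample = generate_dataset(1, RANGES, seed=5)[0]
        p1, p2 = global_search(sample.image, oracle_global(sample))
        gt = corners_of(sample)
        assert np.hypot(p1.x - gt[0, 0], p1.y - gt[0, 1]) <= 0.5
        assert np.hypot(p2.x - gt[1, 0], p2.y - gt[1, 1]) <= 0.5

    def test_flipped_image_with_flipped_oracle_mirrors_points(self):
        sample = generate_dataset(1, RANGES, seed=6)[0]
        width = sample.image.shape[1]
        flipped = sample.image[:, ::-1]
        gt = corners_of(sample)
        mirrored = gt.copy()
        mirrored[:, 0] = width - 1 - mirrored[:, 0]
        model = OracleModel(mirrored, width)
        p1, p2 = global_search(flipped, model)
        assert p1.x == pytest.approx(mirrored[0, 0], abs=0.5)
        assert p2.x == pytest.approx(mirrored[1, 0], abs=0.5)

    def test_blank_image_with_untrained_model_degenerates_cleanly(self):
        # an untrained zero-bias model on a blank image emits constant maps;
        # both reference points decode to the map centre, which the contract
        # reports as a frame-degenerate error rather than a crash
        model = build_hourglass(ModelConfig(depth=2, width=4, n_landmarks=2, input_size=64))
        blank = np.zeros((256, 256), dtype=np.float32)
        with pytest.raises(FrameDegenerateError):
            global_search(blank, model)


class TestMakeFrame:
    def test_refs_at_anchors_give_identity(self):
        a1, a2 = FRAME.anchors
        t = make_frame(a1, a2, FRAME)
        assert t.scale == pytest.approx(1.0)
        assert t.rotation == pytest.approx(0.0, abs=1e-12)
        assert abs(t.translation.x) < 1e-9 and abs(t.translation.y) < 1e-9

    def test_rotated_refs_counter_rotate_frame(self):
        a1, a2 = FRAME.anchors
        mid = Point2D((a1.x + a2.x) / 2, (a1.y + a2.y) / 2)
        rot = SimilarityTransform(1.0, math.radians(10), Point2D(0, 0))
        r1 = rot.apply(Point2D(a1.x - mid.x, a1.y - mid.y))
        r2 = rot.apply(Point2D(a2.x - mid.x, a2.y - mid.y))
        r1 = Point2D(r1.x + mid.x, r1.y + mid.y)
        r2 = Point2D(r2.x + mid.x, r2.y + mid.y)
        t = make_frame(r1, r2, FRAME)
        assert math.degrees(t.rotation) == pytest.approx(-10.0, abs=1e-9)

    def test_doubling_separation_halves_scale(self):
        a1, a2 = FRAME.anchors
        mid_x = (a1.x + a2.x) / 2
        wide_1 = Point2D(mid_x + 2 * (a1.x - mid_x), a1.y)
        wide_2 = Point2D(mid_x + 2 * (a2.x - mid_x), a2.y)
        t = make_frame(wide_1, wide_2, FRAME)
        assert t.scale == pytest.approx(0.5)

    def test_coincident_refs_raise(self):
        p = Point2D(10, 10)
        with pytest.raises(FrameDegenerateError):
            make_frame(p, p, FRAME)

    def test_frame_round_trip_property(self, rng):
        for _ in range(100):
            r1 = Point2D(*rng.uniform(20, 230, 2))
            r2 = Point2D(*rng.uniform(20, 230, 2))
            if r1.distance_to(r2) < 1:
                continue
            t = make_frame(r1, r2, FRAME)
            pts = rng.uniform(0, 255, size=(40, 2))
            back = t.inverse().apply_array(t.apply_array(pts))
            assert np.abs(back - pts).max() <= 1e-6


class TestResample:
    def test_identity_transform_reproduces_image(self):
        sample = generate_dataset(1, RANGES, seed=7)[0]
        crop = resample_to_frame(
            sample.image, SimilarityTransform.identity(), sample.image.shape[0]
        )
        assert np.abs(crop - sample.image).max() <= 1e-6

    def test_two_x_downscale_preserves_mean_intensity(self):
        sample = generate_dataset(1, RANGES, seed=8)[0]
        # map image -> crop at scale 0.5: crop shows the top-left 128x128
        # region of image content scaled down into 64x64
        t = SimilarityTransform(0.5, 0.0, Point2D(0, 0))
        crop = resample_to_frame(sample.image, t, 64)
        region = sample.image[:128, :128]
        assert crop.mean() == pytest.approx(region.mean(), rel=0.02)

    def test_fully_out_of_bounds_is_constant_fill(self):
        sample = generate_dataset(1, RANGES, seed=9)[0]
        t = SimilarityTransform(1.0, 0.0, Point2D(-5000, -5000))
        crop = resample_to_frame(sample.image, t, 32)
        assert np.all(crop == sample.image.min())


class TestLocalize:
    def test_oracle_end_to_end_recovery(self, schema):
        samples = generate_dataset(10, RANGES, seed=11)
        for sample in samples:
            pred = localize(
                sample.image,
                oracle_global(sample),
                oracle_local(sample),
                FRAME,
                schema,
            )
            err = np.linalg.norm(
                pred.as_array() - sample.landmarks.as_array(), axis=1
            )
            assert err.max() <= 1.0

    def test_translation_equivariance_with_oracles(self, schema):
        sample = generate_dataset(1, RANGES, seed=12)[0]
        dx, dy = 7, -5
        shifted = np.roll(sample.image, (dy, dx), axis=(0, 1))
        gt_shifted = sample.landmarks.as_array() + np.array([dx, dy])

        corners = corners_of(sample) + np.array([dx, dy])
        g_model = OracleModel(corners, shifted.shape[0])
        r1, r2 = global_search(shifted, g_model)
        frame = make_frame(r1, r2, FRAME)
        l_model = OracleModel(frame.apply_array(gt_shifted), FRAME.crop_size)

        pred = localize(shifted, g_model, l_model, FRAME, schema)
        err = np.linalg.norm(pred.as_array() - gt_shifted, axis=1)
        assert err.max() <= 1.0

    def test_rotation_equivariance_with_oracles(self, schema):
        import dataclasses

        from kneealign.phantom import generate_phantom

        base = generate_dataset(1, RANGES, seed=13)[0]
        rotated = generate_phantom(
            dataclasses.replace(base.spec, global_rotation=base.spec.global_rotation + 10)
        )
        pred = localize(
            rotated.image,
            oracle_global(rotated),
            oracle_local(rotated),
            FRAME,
            schema,
        )
        err = np.linalg.norm(pred.as_array() - rotated.landmarks.as_array(), axis=1)
        assert err.max() <= 1.5

    def test_crop_size_mismatch_names_stage(self, schema):
        sample = generate_dataset(1, RANGES, seed=14)[0]
        bad_local = OracleModel(np.zeros((40, 2)) + 50, input_size=64)
        with pytest.raises(LocalizationError) as exc_info:
            localize(sample.image, oracle_global(sample), bad_local, FRAME, schema)
        assert exc_info.value.stage == "local"


class TestReferenceFrameSpec:
    def test_default_anchors_horizontal_mid_height(self):
        spec = ReferenceFrameSpec(crop_size=128)
        a1, a2 = spec.anchors
        assert a1.y == a2.y == pytest.approx(63.5)
        assert a2.x - a1.x == pytest.approx(64.0)  # half the crop width
        assert a1.x < a2.x

    def test_separation_fraction_validated(self):
        with pytest.raises(ValueError):
            ReferenceFrameSpec(anchor_separation_fraction=0.0)
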