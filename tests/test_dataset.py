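"""Sampling laws, augmentation operations and dataset assembly."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from skimage.transform import resize as sk_resize

from carmpose.dataset import (
    AugmentationConfig,
    PoseDataset,
    SamplingConfig,
    _composed_augment,
    augment_contrast,
    augment_inplane,
    augment_scale,
    augment_translation,
    build_dataset,
    minmax_normalize,
    preprocess,
    sample_coarse_poses,
    sample_fine_poses,
)
from carmpose.phantoms import make_cohort
from carmpose.projector import CArmConfig


@pytest.fixture(scope="module")
def smooth_image():
    rng = np.random.default_rng(3)
    return gaussian_filter(rng.random((96, 96)), 3)


class TestSampling:
    def test_default_coarse_grid_has_441_poses(self):
        poses = sample_coarse_poses()
        assert len(poses) == 441
        pairs = {(p.alpha, p.beta) for p in poses}
        assert (0, 0) in pairs
        for corner in [(-30, -30), (-30, 30), (30, -30), (30, 30)]:
            assert corner in pairs

    def test_grid_count_formula(self):
        for rng_, step in [(3, 3), (30, 6), (30, 3), (12, 4)]:
            poses = sample_coarse_poses(SamplingConfig(coarse_range=rng_, coarse_step=step))
            assert len(poses) == (2 * rng_ / step + 1) ** 2

    def test_step_must_divide_range(self):
        with pytest.raises(ValueError):
            SamplingConfig(coarse_range=30, coarse_step=7)

    def test_fine_sigma_derived_from_range(self):
        cfg = SamplingConfig()
        assert cfg.fine_sigma == pytest.approx(30 / 2.576)
        assert SamplingConfig(coarse_range=15).fine_sigma == pytest.approx(15 / 2.576)

    def test_fine_poses_deterministic(self):
        a = sample_fine_poses(50, SamplingConfig(seed=9))
        b = sample_fine_poses(50, SamplingConfig(seed=9))
        assert all(x == y for x, y in zip(a, b))

    def test_fine_poses_coverage_and_mean(self):
        cfg = SamplingConfig(seed=1)
        poses = sample_fine_poses(20000, cfg)
        alphas = np.array([p.alpha for p in poses])
        frac = np.mean(np.abs(alphas) <= 30)
        assert frac == pytest.approx(0.99, abs=0.005)
        assert abs(alphas.mean()) < 4 * cfg.fine_sigma / np.sqrt(len(alphas))
        assert np.abs(alphas).max() <= 3 * cfg.fine_sigma + 1e-9


class TestAugmentations:
    def test_inplane_zero_rotation_is_pure_center_crop(self, smooth_image):
        out = augment_inplane(smooth_image, 0.0)
        n, c = smooth_image.shape[0], out.shape[0]
        lo = (n - c) // 2
        np.testing.assert_allclose(out, smooth_image[lo : lo + c, lo : lo + c], atol=1e-12)

    def test_inplane_full_turn_matches_zero(self, smooth_image):
        a = augment_inplane(smooth_image, 0.0)
        b = augment_inplane(smooth_image, 360.0)
        assert np.abs(a - b).max() < 1e-6

    def test_inplane_round_trip(self, smooth_image):
        once = augment_inplane(smooth_image, 33.0)
        back = augment_inplane(once, -33.0)
        ref = augment_inplane(augment_inplane(smooth_image, 0.0), 0.0)
        span = smooth_image.max() - smooth_image.min()
        assert np.abs(back - ref).mean() < 0.02 * span

    def test_translation_zero_is_centered_crop(self, smooth_image):
        out = augment_translation(smooth_image, (0, 0), 3.125, 48)
        n = smooth_image.shape[0]
        y0 = n // 2 - 24
        np.testing.assert_allclose(out, smooth_image[y0 : y0 + 48, y0 : y0 + 48])

    def test_translation_integer_pixel_shift(self, smooth_image):
        pitch = 3.125
        out0 = augment_translation(smooth_image, (0, 0), pitch, 48)
        out3 = augment_translation(smooth_image, (3 * pitch, 0), pitch, 48)
        np.testing.assert_allclose(out3[:, :-3], out0[:, 3:])

    def test_translation_out_of_bounds_pads_with_warning(self, smooth_image):
        with pytest.warns(UserWarning, match="padding"):
            out = augment_translation(smooth_image, (200.0, 0), 3.125, 48)
        assert out.shape == (48, 48)

    def test_contrast_preserves_mean_exactly(self, smooth_image):
        for c in (0.75, 1.0, 1.25):
            out = augment_contrast(smooth_image, c)
            assert out.mean() == pytest.approx(smooth_image.mean(), abs=1e-9)
        np.testing.assert_allclose(augment_contrast(smooth_image, 1.0), smooth_image)
        flat = augment_contrast(smooth_image, 0.0)
        np.testing.assert_allclose(flat, smooth_image.mean())

    def test_scale_identity_and_bounds(self, smooth_image):
        np.testing.assert_allclose(augment_scale(smooth_image, 1.0), smooth_image)
        with pytest.raises(ValueError):
            augment_scale(smooth_image, 1.1)
        with pytest.raises(ValueError):
            AugmentationConfig(scale_range=(0.8, 1.2))

    def test_composed_matches_sequential_ops(self, smooth_image):
        """The single-warp fast path reproduces the op chain.

        Differences are limited to interpolation compounding and the fast
        path's sub-pixel translation (the op chain rounds to whole pixels),
        so the comparison uses in-bounds translations and unit scale.
        """
        pitch = 300.0 / 96
        for gamma, t in [(35.0, (10, -20)), (-120.0, (5, 8)), (170.0, (-15, 12))]:
            a = augment_inplane(smooth_image, gamma)
            w = int(round(a.shape[0] * 0.72))
            a = augment_translation(a, t, pitch, w)
            a = sk_resize(a, (64, 64), order=1, mode="edge", anti_aliasing=False)
            b = _composed_augment(smooth_image, gamma, t, pitch, 0.72, 64, 1.0)
            span = smooth_image.max() - smooth_image.min()
            assert np.abs(a - b).max() < 0.1 * span
            assert np.abs(a - b).mean() < 0.025 * span


class TestPreprocess:
    def test_constant_image_maps_to_zeros(self):
        np.testing.assert_allclose(preprocess(np.full((8, 8), 0.5)), 0.0)

    def test_two_valued_closed_form(self):
        i0 = 0.8
        img = np.array([[i0, i0 * np.exp(-1.0)]])
        np.testing.assert_allclose(preprocess(img), [[0.0, 1.0]], atol=1e-12)

    def test_range_is_unit_interval(self, rng):
        out = preprocess(rng.random((16, 16)) + 0.1)
        assert out.min() == pytest.approx(0.0)
        assert out.max() == pytest.approx(1.0)

    def test_monotone_decreasing_in_intensity(self, rng):
        img = rng.random((8, 8)) + 0.1
        out = preprocess(img)
        order = np.argsort(img.ravel())
        assert np.all(np.diff(out.ravel()[order]) <= 1e-12)

    def test_nonpositive_clamped_with_warning(self):
        img = np.array([[0.0, 0.5, 1.0]])
        with pytest.warns(UserWarning, match="clamped"):
            out = preprocess(img)
        assert np.isfinite(out).all()

    def test_minmax_constant_is_zero(self):
        np.testing.assert_allclose(minmax_normalize(np.ones((4, 4))), 0.0)


class TestBuildDataset:
    @pytest.fixture(scope="class")
    def two_subject_cohort(self):
        from carmpose.phantoms import PhantomSpec

        # 3 subjects -> 2 in the train split (60/20/20)
        return make_cohort(3, PhantomSpec(grid_shape=(32, 32, 32), spacing_mm=5.0), seed=2)

    def test_coarse_dataset_sample_count(self, two_subject_cohort, small_carm):
        ds = build_dataset(
            two_subject_cohort,
            "coarse",
            SamplingConfig(seed=0),
            carm=small_carm,
            input_size=32,
            n_augment=1,
            splits=("train",),
        )
        assert len(ds) == 2 * 441
        assert ds.stage == "coarse"

    def test_labels_in_domain_and_images_normalized(self, two_subject_cohort, small_carm):
        ds = build_dataset(
            two_subject_cohort,
            "fine",
            SamplingConfig(seed=3),
            carm=small_carm,
            input_size=32,
            fine_poses_per_subject=10,
            splits=("train",),
        )
        bound = 3 * SamplingConfig().fine_sigma
        assert np.abs(ds.labels[:, :3]).max() <= bound + 1e-9
        assert np.abs(ds.labels[:, 3:]).max() <= 50 + 1e-9
        assert ds.images.min() >= 0 and ds.images.max() <= 1

    def test_rebuild_is_bit_identical(self, two_subject_cohort, small_carm):
        kwargs = dict(
            sampling=SamplingConfig(seed=5),
            carm=small_carm,
            input_size=32,
            fine_poses_per_subject=5,
            splits=("train",),
        )
        a = build_dataset(two_subject_cohort, "fine", **kwargs)
        b = build_dataset(two_subject_cohort, "fine", **kwargs)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.images, b.images)

    def test_h5_round_trip(self, two_subject_cohort, small_carm, tmp_path):
        ds = build_dataset(
            two_subject_cohort,
            "fine",
            SamplingConfig(seed=5),
            carm=small_carm,
            input_size=32,
            fine_poses_per_subject=5,
            splits=("train",),
        )
        ds.save(tmp_path / "ds.h5")
        back = PoseDataset.load(tmp_path / "ds.h5")
        assert np.array_equal(back.images, ds.images)
        assert np.array_equal(back.labels, ds.labels)
        assert list(back.subject_ids) == list(ds.subject_ids)
        assert back.stage == "fine"
        assert back.manifest["input_size"] == 32

    def test_labels_frame(self, two_subject_cohort, small_carm):
        ds = build_dataset(
            two_subject_cohort,
            "fine",
            SamplingConfig(seed=5),
            carm=small_carm,
            input_size=32,
            fine_poses_per_subject=3,
            splits=("train",),
        )
        frame = ds.labels_frame()
        assert set(frame.columns) == {"subject_id", "split", "alpha", "beta", "gamma", "tx", "ty"}
        assert len(frame) == len(ds)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_dataset([], "coarse")


class TestRawProjectionSet:
    @pytest.fixture(scope="class")
    def raw(self, request):
        from carmpose.dataset import build_raw_dataset
        from carmpose.phantoms import PhantomSpec

        cohort = make_cohort(3, PhantomSpec(grid_shape=(32, 32, 32), spacing_mm=5.0), seed=2)
        return build_raw_dataset(
            cohort,
            "coarse",
            SamplingConfig(coarse_range=30, coarse_step=15, seed=0),
            carm=CArmConfig(sim_resolution=32),
            splits=("train",),
        )

    def test_one_projection_per_grid_pose(self, raw):
        assert len(raw) == 2 * 25  # 2 train subjects x 5x5 grid
        assert raw.images.shape[1:] == (32, 32)
        assert raw.base_offsets.shape == (len(raw), 2)

    def test_draw_batch_is_seeded_and_labeled(self, raw):
        idx = np.arange(8)
        cfg = SamplingConfig(seed=0)
        aug = AugmentationConfig()
        xa, ya = raw.draw_batch(idx, np.random.default_rng(3), cfg, aug, 32)
        xb, yb = raw.draw_batch(idx, np.random.default_rng(3), cfg, aug, 32)
        assert np.array_equal(xa, xb) and np.array_equal(ya, yb)
        np.testing.assert_allclose(ya[:, :2], raw.base_offsets[idx])
        assert xa.min() >= 0 and xa.max() <= 1
        assert np.abs(ya[:, 3:]).max() <= aug.translation_range

    def test_fit_raw_trains_and_predicts(self, raw):
        from carmpose.regressor import CoarsePoseRegressor

        reg = CoarsePoseRegressor(
            input_size=32, channels=(2, 3, 4, 4), fc=(8, 6),
            iterations=2, batches_per_iteration=2, batch_size=8, seed=0,
        )
        reg.fit_raw(raw, sampling=SamplingConfig(seed=0))
        assert reg.predict(np.zeros((1, 32, 32), dtype=np.float32)).shape == (1, 5)

    def test_stage_mismatch_rejected(self, raw):
        from carmpose.regressor import FinePoseRegressor

        with pytest.raises(ValueError, match="stage"):
            FinePoseRegressor(input_size=32).fit_raw(raw)
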