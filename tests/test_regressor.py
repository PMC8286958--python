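"""Label encoding, circular recovery, loss identities and estimator behavior."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from carmpose.geometry import Pose
from carmpose.regressor import (
    FINE_BOUND,
    TRANSLATION_WEIGHT,
    CoarsePoseRegressor,
    FinePoseRegressor,
    coarse_loss,
    decode_labels,
    encode_labels,
    fine_loss,
    recover_gamma,
)


class TestEncoding:
    def test_zero_pose_coarse(self):
        np.testing.assert_allclose(
            encode_labels(Pose(), "coarse"), [[0, 0, 1, 0, 0, 0]], atol=1e-12
        )

    def test_corner_pose_coarse(self):
        enc = encode_labels(Pose(30, -30, 90, 50, -50), "coarse")
        np.testing.assert_allclose(enc, [[1, -1, 0, 1, 1, -1]], atol=1e-12)

    def test_round_trip_coarse(self, rng):
        labels = np.stack(
            [
                rng.uniform(-30, 30, 1000),
                rng.uniform(-30, 30, 1000),
                rng.uniform(-179.99, 180, 1000),
                rng.uniform(-50, 50, 1000),
                rng.uniform(-50, 50, 1000),
            ],
            axis=1,
        )
        back = decode_labels(encode_labels(labels, "coarse"), "coarse")
        np.testing.assert_allclose(back, labels, atol=1e-9)

    def test_round_trip_fine(self, rng):
        b = FINE_BOUND
        labels = np.stack(
            [
                rng.uniform(-b, b, 1000),
                rng.uniform(-b, b, 1000),
                rng.uniform(-b, b, 1000),
                rng.uniform(-50, 50, 1000),
                rng.uniform(-50, 50, 1000),
            ],
            axis=1,
        )
        back = decode_labels(encode_labels(labels, "fine"), "fine")
        np.testing.assert_allclose(back, labels, atol=1e-9)
        assert np.abs(encode_labels(labels, "fine")).max() <= 1 + 1e-9

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            encode_labels(Pose(alpha=31), "coarse")
        with pytest.raises(ValueError):
            encode_labels(Pose(tx=60), "coarse")
        with pytest.raises(ValueError):
            encode_labels(Pose(gamma=40), "fine")


class TestRecoverGamma:
    def test_examples(self):
        assert recover_gamma(math.sin(math.radians(30)), math.cos(math.radians(30))) == pytest.approx(30)
        assert recover_gamma(0.0, -1.0) == pytest.approx(180)

    def test_scale_invariance(self, rng):
        thetas = rng.uniform(-179.99, 180, 200)
        scales = rng.uniform(0.1, 5, 200)
        got = recover_gamma(
            scales * np.sin(np.radians(thetas)), scales * np.cos(np.radians(thetas))
        )
        np.testing.assert_allclose(got, thetas, atol=1e-9)

    def test_identity_on_half_open_interval(self):
        gammas = np.linspace(-179.999, 180, 1001)
        got = recover_gamma(np.sin(np.radians(gammas)), np.cos(np.radians(gammas)))
        np.testing.assert_allclose(got, gammas, atol=1e-9)

    def test_undefined_at_origin(self):
        with pytest.raises(ValueError):
            recover_gamma(0.0, 0.0)


class TestLosses:
    def test_zero_at_target(self, rng):
        v6 = rng.normal(size=6)
        v5 = rng.normal(size=5)
        assert coarse_loss(v6, v6) == 0.0
        assert fine_loss(v5, v5) == 0.0

    def test_strictly_positive_off_target(self, rng):
        v6 = rng.normal(size=6)
        assert coarse_loss(v6 + 1e-3, v6) > 0
        v5 = rng.normal(size=5)
        assert fine_loss(v5 + 1e-3, v5) > 0

    def test_single_degree_alpha_error(self):
        t = np.zeros(6)
        o = t.copy()
        o[0] = 1.0
        assert coarse_loss(o, t) == pytest.approx(1.0)

    def test_translation_weight_is_printed_w_squared(self):
        t = np.zeros(6)
        o = t.copy()
        o[4] = 1.0  # 1 mm
        assert coarse_loss(o, t) == pytest.approx((math.pi / 180) ** 2, rel=1e-12)

    def test_fine_l1_terms(self):
        t = np.zeros(5)
        o = t.copy()
        o[0] = 2.0
        assert fine_loss(o, t) == pytest.approx(2.0)
        o = np.zeros(5)
        o[4] = 1.0
        assert fine_loss(o, t) == pytest.approx(math.pi / 180, rel=1e-12)

    def test_equal_penalty_of_rotation_and_arc_translation(self):
        """1 deg of rotation and 180/pi mm of translation cost the same."""
        t = np.zeros(6)
        rot = t.copy()
        rot[0] = 1.0
        trans = t.copy()
        trans[4] = 180 / math.pi
        assert coarse_loss(rot, t) == pytest.approx(coarse_loss(trans, t), rel=1e-12)
        assert TRANSLATION_WEIGHT == pytest.approx(math.pi / 180)


def _blob_dataset(stage, n, size=16, seed=0):
    """Images whose blob position/size encode the pose label — learnable fast."""
    rng = np.random.default_rng(seed)
    ys, xs = np.mgrid[0:size, 0:size]
    images, labels = [], []
    for _ in range(n):
        if stage == "coarse":
            a, b = rng.uniform(-30, 30, 2)
            g = rng.uniform(-179, 180)
            t = rng.uniform(-50, 50, 2)
        else:
            a, b = rng.uniform(-FINE_BOUND, FINE_BOUND, 2)
            g = rng.uniform(-FINE_BOUND, FINE_BOUND)
            t = rng.uniform(-50, 50, 2)
        cx = size / 2 + a / 30 * size / 4
        cy = size / 2 + b / 30 * size / 4
        img = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 + (g + 180) / 60))
        img += 0.3 * np.exp(-((xs - size / 2 - t[0] / 25) ** 2 + (ys - size / 2 - t[1] / 25) ** 2) / 4)
        images.append(img.astype(np.float32))
        labels.append([a, b, g, t[0], t[1]])
    return np.stack(images), np.array(labels)


class TestEstimators:
    @pytest.mark.parametrize("cls", [CoarsePoseRegressor, FinePoseRegressor])
    def test_output_shape_and_determinism(self, cls):
        X, y = _blob_dataset(cls._stage, 32)
        reg = cls(
            input_size=16, channels=(2, 3, 4, 4), fc=(8, 6),
            iterations=1, batches_per_iteration=2, batch_size=8, seed=0,
        ).fit(X, y)
        pred = reg.predict(X[:5])
        assert pred.shape == (5, 5)
        reg2 = clone(reg).fit(X, y)
        np.testing.assert_array_equal(pred, reg2.predict(X[:5]))

    def test_training_reduces_validation_loss(self):
        X, y = _blob_dataset("coarse", 256, seed=1)
        Xv, yv = _blob_dataset("coarse", 64, seed=2)
        reg = CoarsePoseRegressor(
            input_size=16, channels=(4, 8, 8, 8), fc=(16, 8),
            learning_rate=3e-3, iterations=10, batches_per_iteration=10,
            batch_size=32, seed=0,
        )
        reg.fit(X, y, Xv, yv)
        h = reg.history_
        assert h.val_loss.min() < 0.95 * h.val_loss.iloc[0]
        assert h.train_loss.iloc[-1] < 0.6 * h.train_loss.iloc[0]
        assert reg.score(Xv, yv) >= -h.val_loss.min()

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            CoarsePoseRegressor().predict(np.zeros((1, 64, 64)))

    def test_bad_image_shape_rejected(self):
        X, y = _blob_dataset("coarse", 8)
        reg = CoarsePoseRegressor(input_size=32)
        with pytest.raises(ValueError):
            reg.fit(X, y)

    def test_divergence_aborts_with_diagnostic(self):
        X, y = _blob_dataset("coarse", 16)
        reg = CoarsePoseRegressor(
            input_size=16, channels=(2, 3, 4, 4), fc=(8, 6),
            learning_rate=1e6, iterations=5, batches_per_iteration=20, seed=0,
        )
        with pytest.raises(RuntimeError, match="diverged"):
            reg.fit(X, y)

    def test_save_load_round_trip(self, tmp_path):
        X, y = _blob_dataset("fine", 16)
        reg = FinePoseRegressor(
            input_size=16, channels=(2, 3, 4, 4), fc=(8, 6),
            iterations=1, batches_per_iteration=2, batch_size=8, seed=0,
        ).fit(X, y)
        reg.save(tmp_path / "model.npz")
        back = FinePoseRegressor.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(back.predict(X), reg.predict(X))
        assert back.get_params() == reg.get_params()

    def test_sklearn_get_set_params(self):
        reg = CoarsePoseRegressor(learning_rate=5e-4)
        assert reg.get_params()["learning_rate"] == 5e-4
        reg.set_params(batch_size=32)
        assert reg.batch_size == 32
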