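"""Label encoding, circular losses and the two-stage pose regressors.

Both stages regress a 5-DoF pose update from a single preprocessed
projection.  Targets are range-normalized to [-1, 1]; the coarse stage
covers in-plane rotations over the full circle, so its gamma target is
encoded as (cos gamma, sin gamma) — giving a loss that is continuous across
the +-180 degree wrap — and recovered with atan2.  The fine stage's gamma
domain is narrow (Gaussian, sigma = 30/2.576 degrees), so it is regressed
directly.

Losses follow the weighted forms

    L_coarse = |da|^2 + |db|^2 + |dc_g|^2 + |ds_g|^2 + w^2 (|dtx|^2 + |dty|^2)
    L_fine   = |da| + |db| + |dg| + w (|dtx| + |dty|)

with w = pi/180, which penalizes a millimetre of detector translation like
a degree of rotation expressed in radians-of-arc.

The estimators follow the scikit-learn protocol: ``fit(X, y)`` on arrays of
images ``(n, S, S)`` and pose labels ``(n, 5)``, ``predict(X) -> (n, 5)``,
with fitted state in trailing-underscore attributes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .geometry import Pose, wrap_angle
from .dataset import Z_99
from .network import Adam, ModelConfig, build_model

__all__ = [
    "TRANSLATION_WEIGHT",
    "encode_labels",
    "decode_labels",
    "recover_gamma",
    "coarse_loss",
    "fine_loss",
    "CoarsePoseRegressor",
    "FinePoseRegressor",
]

#: w = pi / 180 — equal penalty for 1 degree and 1 mm-of-arc
TRANSLATION_WEIGHT = math.pi / 180.0

#: out-of-plane normalization bound, degrees (the coarse capture range)
ANGLE_BOUND = 30.0
#: detector-translation normalization bound, mm
TRANSLATION_BOUND = 50.0
#: fine-stage bound: 3 sigma of the fine Gaussian, degrees
FINE_BOUND = 3.0 * ANGLE_BOUND / Z_99


def _as_label_array(poses) -> np.ndarray:
    if isinstance(poses, Pose):
        poses = poses.as_array()[None]
    arr = np.asarray(poses, dtype=float)
    if arr.ndim == 1:
        arr = arr[None]
    if arr.shape[-1] != 5:
        raise ValueError("pose labels must have 5 components [alpha, beta, gamma, tx, ty]")
    return arr


def encode_labels(poses, stage: str) -> np.ndarray:
    """Normalize pose labels to the network target space.

    Coarse: ``[a/30, b/30, cos g, sin g, tx/50, ty/50]`` (6 values).
    Fine:   ``[a/B, b/B, g/B, tx/50, ty/50]`` with ``B`` the 3-sigma bound
    of the fine Gaussian (~34.9 deg), keeping all targets inside [-1, 1].
    Raises for labels outside the stage domain.  Invertible via
    :func:`decode_labels`.
    """
    arr = _as_label_array(poses)
    a, b, g, tx, ty = (arr[:, i] for i in range(5))
    if np.any(np.abs([tx, ty]) > TRANSLATION_BOUND + 1e-9):
        raise ValueError("translation label outside the +-50 mm domain")
    if stage == "coarse":
        if np.any(np.abs([a, b]) > ANGLE_BOUND + 1e-9):
            raise ValueError("out-of-plane label outside the coarse +-30 deg domain")
        g_rad = np.deg2rad(g)
        out = np.stack(
            [
                a / ANGLE_BOUND,
                b / ANGLE_BOUND,
                np.cos(g_rad),
                np.sin(g_rad),
                tx / TRANSLATION_BOUND,
                ty / TRANSLATION_BOUND,
            ],
            axis=1,
        )
    elif stage == "fine":
        if np.any(np.abs([a, b, g]) > FINE_BOUND + 1e-9):
            raise ValueError("rotation label outside the fine 3-sigma domain")
        out = np.stack(
            [a / FINE_BOUND, b / FINE_BOUND, g / FINE_BOUND, tx / TRANSLATION_BOUND, ty / TRANSLATION_BOUND],
            axis=1,
        )
    else:
        raise ValueError("stage must be 'coarse' or 'fine'")
    return out


def recover_gamma(s_gamma, c_gamma) -> float | np.ndarray:
    """In-plane angle from its predicted (sin, cos) channels, degrees.

    The channels are normalized to unit length before atan2, so the result
    is invariant to a positive rescaling; the angle lies in (-180, 180].
    """
    s = np.asarray(s_gamma, dtype=float)
    c = np.asarray(c_gamma, dtype=float)
    norm = np.sqrt(s * s + c * c)
    if np.any(norm == 0):
        raise ValueError("(s_gamma, c_gamma) = (0, 0) leaves the angle undefined")
    gamma = np.degrees(np.arctan2(s / norm, c / norm))
    gamma = wrap_angle(gamma)
    return float(gamma) if np.ndim(s_gamma) == 0 else gamma


def decode_labels(outputs: np.ndarray, stage: str) -> np.ndarray:
    """Invert :func:`encode_labels`; returns (n, 5) pose labels."""
    outputs = np.asarray(outputs, dtype=float)
    if outputs.ndim == 1:
        outputs = outputs[None]
    if stage == "coarse":
        if outputs.shape[-1] != 6:
            raise ValueError("coarse outputs must have 6 components")
        gamma = np.atleast_1d(recover_gamma(outputs[:, 3], outputs[:, 2]))
        return np.stack(
            [
                outputs[:, 0] * ANGLE_BOUND,
                outputs[:, 1] * ANGLE_BOUND,
                gamma,
                outputs[:, 4] * TRANSLATION_BOUND,
                outputs[:, 5] * TRANSLATION_BOUND,
            ],
            axis=1,
        )
    if stage == "fine":
        if outputs.shape[-1] != 5:
            raise ValueError("fine outputs must have 5 components")
        return np.stack(
            [
                outputs[:, 0] * FINE_BOUND,
                outputs[:, 1] * FINE_BOUND,
                outputs[:, 2] * FINE_BOUND,
                outputs[:, 3] * TRANSLATION_BOUND,
                outputs[:, 4] * TRANSLATION_BOUND,
            ],
            axis=1,
        )
    raise ValueError("stage must be 'coarse' or 'fine'")


def coarse_loss(output: np.ndarray, target: np.ndarray) -> float:
    """Weighted L2 pose loss of the coarse stage.

    ``output``/``target`` hold ``[alpha_deg, beta_deg, cos_g, sin_g, tx_mm,
    ty_mm]``.  Squared angular terms in degrees, squared sin/cos terms, and
    translation terms weighted by w^2 = (pi/180)^2.  Zero iff exact; mean
    over leading batch axes.
    """
    output = np.asarray(output, dtype=float)
    target = np.asarray(target, dtype=float)
    d = output - target
    per_sample = (
        d[..., 0] ** 2
        + d[..., 1] ** 2
        + d[..., 2] ** 2
        + d[..., 3] ** 2
        + TRANSLATION_WEIGHT**2 * (d[..., 4] ** 2 + d[..., 5] ** 2)
    )
    return float(np.mean(per_sample))


def fine_loss(output: np.ndarray, target: np.ndarray) -> float:
    """Weighted L1 pose loss of the fine stage.

    ``output``/``target`` hold ``[alpha, beta, gamma, tx, ty]`` in degrees
    and mm; translation terms weighted by w = pi/180.
    """
    output = np.asarray(output, dtype=float)
    target = np.asarray(target, dtype=float)
    d = np.abs(output - target)
    per_sample = (
        d[..., 0] + d[..., 1] + d[..., 2] + TRANSLATION_WEIGHT * (d[..., 3] + d[..., 4])
    )
    return float(np.mean(per_sample))


# ---------------------------------------------------------------------------
# training losses on normalized outputs (value + gradient)
#
# The network is optimized in the normalized target space: out-of-plane
# rotations in units of their range bound, gamma as (cos, sin) channels
# (coarse) or in units of its bound (fine), and translations carrying the
# printed weight w relative to the sin/cos terms (w * dt_mm = w * 50 * dt_norm).
# Optimizing the raw degree-scale L2 instead lets the (initially noisy)
# out-of-plane gradients swamp the shared features by a factor ~30^2 and
# stalls training; the normalized space keeps all terms O(1).

_W_TRANS = TRANSLATION_WEIGHT * TRANSLATION_BOUND  # = w * 50 mm


def _coarse_scale_vector() -> np.ndarray:
    return np.array([1.0, 1.0, 1.0, 1.0, _W_TRANS, _W_TRANS])


def _fine_scale_vector() -> np.ndarray:
    return np.array([1.0, 1.0, 1.0, _W_TRANS, _W_TRANS])


def _loss_and_grad(out_norm: np.ndarray, tgt_norm: np.ndarray, stage: str):
    """Normalized-space training loss and gradient w.r.t. the outputs."""
    n = out_norm.shape[0]
    if stage == "coarse":
        s = _coarse_scale_vector()
        d = (out_norm - tgt_norm) * s
        loss = float(np.mean(np.sum(d * d, axis=1)))
        grad = 2.0 * d * s / n
    else:
        s = _fine_scale_vector()
        d = (out_norm - tgt_norm) * s
        loss = float(np.mean(np.sum(np.abs(d), axis=1)))
        grad = np.sign(d) * s / n
    return loss, grad


class _PoseRegressorBase(RegressorMixin, BaseEstimator):
    """Shared fit/predict machinery of the two stages."""

    _stage: str = ""

    def __init__(
        self,
        input_size: int = 64,
        channels: tuple[int, int, int, int] = (8, 16, 32, 64),
        fc: tuple[int, int] = (128, 64),
        learning_rate: float = 1e-4,
        lr_decay: float = 1.0,
        batch_size: int = 64,
        iterations: int = 50,
        batches_per_iteration: int = 50,
        patience: int = 15,
        seed: int = 0,
    ):
        self.input_size = input_size
        self.channels = channels
        self.fc = fc
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.batch_size = batch_size
        self.iterations = iterations
        self.batches_per_iteration = batches_per_iteration
        self.patience = patience
        self.seed = seed

    # -- helpers -----------------------------------------------------------
    @property
    def n_outputs(self) -> int:
        return 6 if self._stage == "coarse" else 5

    def _lr_at(self, iteration: int) -> float:
        """Cosine-decayed learning rate from lr to lr * lr_decay."""
        if self.lr_decay >= 1.0 or self.iterations <= 1:
            return self.learning_rate
        frac = 0.5 * (1.0 + math.cos(math.pi * iteration / (self.iterations - 1)))
        return self.learning_rate * (self.lr_decay + (1.0 - self.lr_decay) * frac)

    def _validate_images(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            raise ValueError(
                f"X must have shape (n, {self.input_size}, {self.input_size}), got {X.shape}"
            )
        return X

    def _build(self):
        config = ModelConfig(input_size=self.input_size, channels=tuple(self.channels), fc=tuple(self.fc))
        return build_model(config, self.n_outputs, seed=self.seed), config

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train on images ``X`` (n, S, S) and pose labels ``y`` (n, 5).

        Runs ``iterations`` rounds of ``batches_per_iteration`` random
        batches of Adam updates.  With a validation set, the weights with
        the best validation loss are restored at the end and training stops
        early after ``patience`` rounds without improvement.
        """
        X = self._validate_images(X)
        y_enc = encode_labels(y, self._stage)
        if len(X) != len(y_enc):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("training set is empty")
        has_val = X_val is not None and y_val is not None and len(X_val) > 0
        if has_val:
            X_val = self._validate_images(X_val)
            yv_enc = encode_labels(y_val, self._stage)

        net, config = self._build()
        opt = Adam(net, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)
        history = []
        best_val = np.inf
        best_state = None
        stall = 0
        for it in range(self.iterations):
            opt.lr = self._lr_at(it)
            train_losses = []
            for _ in range(self.batches_per_iteration):
                idx = rng.choice(len(X), size=min(self.batch_size, len(X)), replace=False)
                out = net.forward(X[idx][:, None], train=True)
                loss, grad = _loss_and_grad(out, y_enc[idx], self._stage)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at iteration {it}: loss={loss!r} "
                        f"(lr={self.learning_rate}, batch={self.batch_size})"
                    )
                net.backward(grad.astype(np.float32))
                opt.step()
                train_losses.append(loss)
            row = {"iteration": it, "train_loss": float(np.mean(train_losses))}
            if has_val:
                val_out = self._forward_eval(net, X_val)
                val_loss, _ = _loss_and_grad(val_out, yv_enc, self._stage)
                row["val_loss"] = val_loss
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    best_state = net.state_dict()
                    stall = 0
                else:
                    stall += 1
            history.append(row)
            if has_val and stall > self.patience:
                break
        if best_state is not None:
            net.load_state_dict(best_state)
        self.net_ = net
        self.model_config_ = config
        self.history_ = pd.DataFrame(history)
        self.n_features_in_ = self.input_size * self.input_size
        return self

    def fit_raw(self, raw_train, X_val=None, y_val=None, sampling=None, augmentation=None):
        """Train with online augmentation from unaugmented projections.

        ``raw_train`` is a :class:`carmpose.dataset.RawProjectionSet`; every
        batch draws fresh in-plane rotation, translation, scale and contrast
        augmentations, so no two presentations of a projection are alike.
        Validation uses a fixed pre-augmented set, as in :meth:`fit`.
        """
        from .dataset import AugmentationConfig, SamplingConfig

        sampling = sampling or SamplingConfig()
        augmentation = augmentation or AugmentationConfig()
        if raw_train.stage != self._stage:
            raise ValueError(f"raw dataset stage {raw_train.stage!r} != {self._stage!r}")
        has_val = X_val is not None and y_val is not None and len(X_val) > 0
        if has_val:
            X_val = self._validate_images(X_val)
            yv_enc = encode_labels(y_val, self._stage)

        net, config = self._build()
        opt = Adam(net, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)
        history = []
        best_val = np.inf
        best_state = None
        stall = 0
        m = len(raw_train)
        for it in range(self.iterations):
            opt.lr = self._lr_at(it)
            train_losses = []
            for _ in range(self.batches_per_iteration):
                idx = rng.choice(m, size=min(self.batch_size, m), replace=False)
                xb, yb = raw_train.draw_batch(idx, rng, sampling, augmentation, self.input_size)
                out = net.forward(xb[:, None], train=True)
                loss, grad = _loss_and_grad(out, encode_labels(yb, self._stage), self._stage)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at iteration {it}: loss={loss!r} "
                        f"(lr={self.learning_rate}, batch={self.batch_size})"
                    )
                net.backward(grad.astype(np.float32))
                opt.step()
                train_losses.append(loss)
            row = {"iteration": it, "train_loss": float(np.mean(train_losses))}
            if has_val:
                val_out = self._forward_eval(net, X_val)
                val_loss, _ = _loss_and_grad(val_out, yv_enc, self._stage)
                row["val_loss"] = val_loss
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    best_state = net.state_dict()
                    stall = 0
                else:
                    stall += 1
            history.append(row)
            if has_val and stall > self.patience:
                break
        if best_state is not None:
            net.load_state_dict(best_state)
        self.net_ = net
        self.model_config_ = config
        self.history_ = pd.DataFrame(history)
        self.n_features_in_ = self.input_size * self.input_size
        return self

    def _forward_eval(self, net, X, chunk: int = 256) -> np.ndarray:
        outs = [net.forward(X[i : i + chunk][:, None], train=False) for i in range(0, len(X), chunk)]
        return np.concatenate(outs, axis=0)

    def predict(self, X) -> np.ndarray:
        """Predict pose updates ``(n, 5)`` = [alpha, beta, gamma, tx, ty]."""
        if not hasattr(self, "net_"):
            raise AttributeError("estimator is not fitted yet; call fit first")
        X = self._validate_images(X)
        out = self._forward_eval(self.net_, X)
        return decode_labels(out, self._stage)

    def score(self, X, y) -> float:
        """Negative mean physical-unit loss (higher is better)."""
        out = self._forward_eval(self.net_, self._validate_images(X))
        loss, _ = _loss_and_grad(out, encode_labels(y, self._stage), self._stage)
        return -loss

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        state = self.net_.state_dict()
        meta = {f"__param_{k}": v for k, v in self.get_params().items()}
        np.savez(path, __stage=self._stage, **meta, **state)

    @classmethod
    def load(cls, path):
        data = np.load(path, allow_pickle=False)
        params = {}
        for key in data.files:
            if key.startswith("__param_"):
                value = data[key]
                value = value.item() if value.ndim == 0 else tuple(int(v) for v in value)
                params[key[len("__param_"):]] = value
        est = cls(**params)
        net, config = est._build()
        net.load_state_dict({k: data[k] for k in data.files if not k.startswith("__")})
        est.net_ = net
        est.model_config_ = config
        est.history_ = pd.DataFrame()
        est.n_features_in_ = est.input_size**2
        return est


class CoarsePoseRegressor(_PoseRegressorBase):
    """Stage-1 regressor: full-circle gamma via sin/cos channels (6 outputs)."""

    _stage = "coarse"


class FinePoseRegressor(_PoseRegressorBase):
    """Stage-2 regressor: direct gamma regression in its narrow domain (5 outputs)."""

    _stage = "fine"
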