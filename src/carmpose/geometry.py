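"""C-arm pose representation, beam geometry and pose-error metrics.

The mobile C-arm is modelled with 5 degrees of freedom: two out-of-plane
rotations — the orbital rotation ``alpha`` (LAO, within the gantry plane)
and the angular rotation ``beta`` (CRA, perpendicular to it) — an in-plane
detector rotation ``gamma``, and a translation ``(tx, ty)`` of the detector
within its own plane.  Translation along the beam only changes magnification
and is deliberately not modelled.

Angles are stored in degrees throughout; translations in millimetres.
The principal-ray direction of a pose is

    nu = [sin a, -cos a * sin b, cos a * cos b]^T

which is reproduced by the third column of :func:`rotation_matrix` for the
composition order ``Rx(beta) @ Ry(alpha) @ Rz(gamma)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace

import numpy as np

__all__ = [
    "Pose",
    "PoseError",
    "beam_direction",
    "angular_error",
    "gamma_error",
    "translation_error",
    "pose_error",
    "rotation_matrix",
    "apply_pose_update",
    "mirror_pose",
    "wrap_angle",
]

#: coarse capture range of the regressors, degrees (out-of-plane rotations)
COARSE_RANGE_DEG = 30.0


def wrap_angle(angle: float | np.ndarray) -> float | np.ndarray:
    """Normalize an angle in degrees to the interval (-180, 180]."""
    wrapped = -np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) + 180.0
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class Pose:
    """A 5-DoF C-arm pose (or pose offset).

    Parameters
    ----------
    alpha, beta:
        Orbital (LAO) and angular (CRA) rotation in degrees.
    gamma:
        In-plane detector rotation in degrees, normalized to (-180, 180].
    tx, ty:
        Detector-plane translation in millimetres.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "tx", "ty"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"Pose field {name!r} must be finite, got {value!r}")
        object.__setattr__(self, "gamma", wrap_angle(self.gamma))

    # -- arithmetic in parameter space -------------------------------------
    def compose(self, offset: "Pose") -> "Pose":
        """Parameter-space composition ``self (+) offset``."""
        return Pose(
            self.alpha + offset.alpha,
            self.beta + offset.beta,
            wrap_angle(self.gamma + offset.gamma),
            self.tx + offset.tx,
            self.ty + offset.ty,
        )

    def __neg__(self) -> "Pose":
        return Pose(-self.alpha, -self.beta, wrap_angle(-self.gamma), -self.tx, -self.ty)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.tx, self.ty], dtype=float)

    @classmethod
    def from_array(cls, values) -> "Pose":
        a = np.asarray(values, dtype=float).ravel()
        if a.size != 5:
            raise ValueError(f"expected 5 pose parameters, got {a.size}")
        return cls(*a.tolist())

    def in_coarse_domain(self, range_deg: float = COARSE_RANGE_DEG) -> bool:
        return abs(self.alpha) <= range_deg and abs(self.beta) <= range_deg

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, laterality: str = "left") -> str:
        record = asdict(self)
        record["laterality"] = laterality
        return json.dumps(record)

    @classmethod
    def from_json(cls, text: str) -> tuple["Pose", str]:
        record = json.loads(text)
        laterality = record.pop("laterality", "left")
        return cls(**record), laterality


@dataclass(frozen=True)
class PoseError:
    """The five error metrics between an estimated and a reference pose.

    ``d_theta`` is the angle between the principal rays (deg), ``d_alpha`` /
    ``d_beta`` / ``d_gamma`` the absolute per-parameter rotation errors (deg,
    ``d_gamma`` circular) and ``dc`` the Euclidean detector-translation error
    in millimetres.
    """

    d_theta: float
    d_alpha: float
    d_beta: float
    d_gamma: float
    dc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_theta <= 180.0 + 1e-9):
            raise ValueError(f"d_theta out of [0, 180]: {self.d_theta}")
        if not (0.0 <= self.d_gamma <= 180.0 + 1e-9):
            raise ValueError(f"d_gamma out of [0, 180]: {self.d_gamma}")
        for name in ("d_alpha", "d_beta", "dc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _check_finite_pose(pose: Pose) -> None:
    values = pose.as_array()
    if not np.all(np.isfinite(values)):
        raise ValueError(f"pose has non-finite parameters: {pose}")


def beam_direction(pose: Pose) -> np.ndarray:
    """Unit direction of the principal ray for a pose.

    Only ``alpha`` and ``beta`` matter; the in-plane rotation and detector
    translation do not move the central ray.
    """
    _check_finite_pose(pose)
    a = math.radians(pose.alpha)
    b = math.radians(pose.beta)
    v = np.array(
        [math.sin(a), -math.cos(a) * math.sin(b), math.cos(a) * math.cos(b)],
        dtype=float,
    )
    return v


def angular_error(p: Pose, p_hat: Pose) -> float:
    """Angle in degrees between the principal rays of two poses."""
    v = beam_direction(p)
    v_hat = beam_direction(p_hat)
    dot = float(np.clip(np.dot(v, v_hat), -1.0, 1.0))
    return math.degrees(math.acos(dot))


def gamma_error(gamma_hat: float, gamma: float) -> float:
    """Circular absolute difference of two in-plane angles, in [0, 180]."""
    if not (math.isfinite(gamma_hat) and math.isfinite(gamma)):
        raise ValueError("gamma angles must be finite")
    d = abs(gamma_hat - gamma) % 360.0
    return min(d, 360.0 - d)


def translation_error(p: Pose, p_hat: Pose) -> float:
    """Euclidean distance of the detector translations, in mm."""
    _check_finite_pose(p)
    _check_finite_pose(p_hat)
    return math.hypot(p_hat.tx - p.tx, p_hat.ty - p.ty)


def pose_error(p: Pose, p_hat: Pose) -> PoseError:
    """All five error metrics between a reference pose ``p`` and estimate ``p_hat``."""
    return PoseError(
        d_theta=angular_error(p, p_hat),
        d_alpha=abs(p_hat.alpha - p.alpha),
        d_beta=abs(p_hat.beta - p.beta),
        d_gamma=gamma_error(p_hat.gamma, p.gamma),
        dc=translation_error(p, p_hat),
    )


def rotation_matrix(pose: Pose) -> np.ndarray:
    """World rotation ``Rx(beta) @ Ry(alpha) @ Rz(gamma)`` of a pose.

    The composition order is fixed so that ``R @ [0, 0, 1]`` equals
    :func:`beam_direction` for every ``gamma``; the in-plane rotation is
    applied last, about the principal ray.
    """
    _check_finite_pose(pose)
    a = math.radians(pose.alpha)
    b = math.radians(pose.beta)
    g = math.radians(pose.gamma)
    ry = np.array(
        [[math.cos(a), 0.0, math.sin(a)], [0.0, 1.0, 0.0], [-math.sin(a), 0.0, math.cos(a)]]
    )
    rx = np.array(
        [[1.0, 0.0, 0.0], [0.0, math.cos(b), -math.sin(b)], [0.0, math.sin(b), math.cos(b)]]
    )
    rz = np.array(
        [[math.cos(g), -math.sin(g), 0.0], [math.sin(g), math.cos(g), 0.0], [0.0, 0.0, 1.0]]
    )
    return rx @ ry @ rz


def mirror_pose(pose: Pose) -> Pose:
    """Laterality mirror of a pose (horizontal image flip).

    Reflecting the anatomy across the sagittal plane flips the sign of the
    orbital rotation, the in-plane rotation and the horizontal detector
    translation; ``beta`` and ``ty`` are preserved.  The map is self-inverse.
    """
    return replace(pose, alpha=-pose.alpha, gamma=wrap_angle(-pose.gamma), tx=-pose.tx)


def apply_pose_update(current: Pose, update: Pose, mirrored: bool = False) -> Pose:
    """Reposition the C-arm given a predicted pose update.

    ``update`` is the regressor's estimate of the current pose's offset from
    the standard pose, expressed in the frame the model was trained in.  The
    repositioned pose is the current pose with the update inversely applied
    (parameters subtracted); for a mirrored laterality, the update is first
    mirrored so that predictions from a horizontally flipped image apply to
    the unflipped device.
    """
    _check_finite_pose(current)
    _check_finite_pose(update)
    if mirrored:
        update = mirror_pose(update)
    return current.compose(-update)
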