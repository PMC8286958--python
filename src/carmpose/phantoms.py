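"""Parametric bone phantoms with known per-subject standard poses.

The learning problem under study is geometric: can a regressor recover the
pose offset of a projection relative to an anatomy-specific standard view?
Answering that at desk scale needs a cohort of 3D attenuation volumes whose
standard poses are known exactly and whose anatomy varies between subjects.
This module provides that cohort: femur-like phantoms (tubular shaft, angled
neck, spherical head, trochanters) and vertebra-like phantoms (elliptic body,
spinal canal, spinous and transverse processes), each embedded in a
soft-tissue ellipsoid and voxelized on a regular grid.

Inter-subject variation is emulated by randomizing sizes, attenuations and a
small rigid perturbation of each subject's standard pose; the perturbation
parameters ARE the subject's ground-truth standard pose, mimicking how a
per-patient reference view deviates from the anatomical canon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import Pose, rotation_matrix

__all__ = [
    "VolumeGrid",
    "PhantomSpec",
    "CohortSubject",
    "make_phantom",
    "make_cohort",
    "split_counts",
    "mirror_volume",
    "save_volume",
    "load_volume",
    "write_cohort_manifest",
]


@dataclass
class VolumeGrid:
    """A 3D attenuation volume on a regular grid.

    ``voxels`` is indexed ``[ix, iy, iz]`` along the world x/y/z axes and
    holds linear attenuation in 1/mm.  ``spacing`` is mm per voxel per axis
    and ``origin`` the world position (mm, relative to the isocenter) of the
    center of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if min(self.voxels.shape) < 8:
            raise ValueError("all volume dimensions must be >= 8")
        if np.any(self.voxels < 0):
            raise ValueError("attenuation values must be non-negative")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.array(self.voxels.shape) - 0.5) * self.spacing
        if np.any(lo > 0) or np.any(hi < 0):
            raise ValueError("isocenter must lie inside the volume bounding box")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.array(self.voxels.shape) * self.spacing

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.origin - 0.5 * self.spacing
        return lo, lo + self.extent_mm


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one phantom subject.

    All geometry in mm, angles in degrees, attenuation in 1/mm.  The
    ``perturb_*`` fields define the subject's standard pose: a small rigid
    rotation/offset of the anatomy relative to the canonical orientation.
    """

    anatomy: str = "femur"  # "femur" | "vertebra"
    shaft_radius: float = 10.0
    shaft_length: float = 90.0
    head_radius: float = 16.0
    neck_angle: float = 50.0  # deg from the shaft axis
    neck_length: float = 38.0
    bone_mu: float = 0.060
    soft_mu: float = 0.019
    perturb_rot_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)  # alpha, beta, gamma
    perturb_offset_mm: tuple[float, float] = (0.0, 0.0)
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.anatomy not in ("femur", "vertebra"):
            raise ValueError(f"unknown anatomy {self.anatomy!r}")
        for name in ("shaft_radius", "shaft_length", "head_radius", "neck_length", "spacing_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if max(abs(a) for a in self.perturb_rot_deg) > 10.0:
            raise ValueError("perturbation rotation must be <= 10 degrees")
        if self.bone_mu < 0 or self.soft_mu < 0:
            raise ValueError("attenuations must be non-negative")


@dataclass
class CohortSubject:
    subject_id: str
    spec: PhantomSpec
    volume: VolumeGrid
    standard_pose: Pose
    split: str  # train | val | test
    laterality: str = "left"


# ---------------------------------------------------------------------------
# implicit solids, evaluated on canonical-frame coordinates


def _cylinder(px, py, pz, p0, p1, radius):
    """Mask of a finite cylinder from p0 to p1 (both 3-vectors, mm)."""
    p0 = np.asarray(p0, float)
    axis = np.asarray(p1, float) - p0
    length = np.linalg.norm(axis)
    axis = axis / length
    dx, dy, dz = px - p0[0], py - p0[1], pz - p0[2]
    t = dx * axis[0] + dy * axis[1] + dz * axis[2]
    rx = dx - t * axis[0]
    ry = dy - t * axis[1]
    rz = dz - t * axis[2]
    return (t >= 0) & (t <= length) & (rx * rx + ry * ry + rz * rz <= radius * radius)


def _sphere(px, py, pz, center, radius):
    c = np.asarray(center, float)
    return (px - c[0]) ** 2 + (py - c[1]) ** 2 + (pz - c[2]) ** 2 <= radius * radius


def _ellipsoid(px, py, pz, center, semi):
    c = np.asarray(center, float)
    s = np.asarray(semi, float)
    return (
        ((px - c[0]) / s[0]) ** 2 + ((py - c[1]) / s[1]) ** 2 + ((pz - c[2]) / s[2]) ** 2
    ) <= 1.0


def _femur_mu(px, py, pz, spec: PhantomSpec) -> np.ndarray:
    """Attenuation field of the proximal-femur-like solid (canonical frame).

    Models the region-of-interest crop around the hip: the femoral head
    sits near the isocenter (it must stay inside the ~75 mm effective
    field of view of the cropped detector window), with the neck, both
    trochanters and the upper shaft around it; the shaft runs out of the
    field of view downward, as in real hip fluoroscopy.
    """
    s = spec
    psi = np.deg2rad(s.neck_angle)
    anteversion = np.deg2rad(18.0)  # out-of-plane neck tilt; breaks the +-alpha ambiguity
    neck_dir = np.array(
        [
            np.sin(psi) * np.cos(anteversion),
            np.cos(psi) * np.cos(anteversion),
            np.sin(anteversion),
        ]
    )
    neck_start = np.array([-14.0, -4.0, -4.0])
    head_center = neck_start + 0.8 * s.neck_length * neck_dir

    mu = np.zeros(px.shape, dtype=np.float32)
    soft = _ellipsoid(px, py, pz, (-8.0, -6.0, 0.0), (44.0, 54.0, 38.0))
    mu[soft] = s.soft_mu

    # shaft bows posteriorly; a planar phantom would project (+a, +b) and
    # (-a, -b) almost identically and make the offset sign unlearnable
    shaft_dir = np.array([-0.18, -0.96, -0.2])
    shaft_dir /= np.linalg.norm(shaft_dir)
    shaft_top = np.array([-18.0, 4.0, 2.0])
    shaft_bot = shaft_top + 0.7 * s.shaft_length * shaft_dir
    shaft = _cylinder(px, py, pz, shaft_bot, shaft_top, s.shaft_radius)
    neck = _cylinder(px, py, pz, neck_start, head_center, 0.62 * s.head_radius)
    head = _sphere(px, py, pz, head_center, s.head_radius)
    gtroch = _sphere(px, py, pz, (-26.0, 10.0, -8.0), s.shaft_radius)
    ltroch = _sphere(px, py, pz, (-20.0, -16.0, 0.9 * s.shaft_radius), 6.0)
    bone = shaft | neck | head | gtroch | ltroch
    mu[bone] = s.bone_mu

    # medullary canal: the shaft is a tube, not a solid rod
    canal = _cylinder(
        px, py, pz, shaft_bot, shaft_top + 12.0 * shaft_dir, 0.55 * s.shaft_radius
    )
    mu[canal] = s.soft_mu
    return mu


def _vertebra_mu(px, py, pz, spec: PhantomSpec) -> np.ndarray:
    """Attenuation field of the vertebra-like solid (canonical frame).

    Elliptic-cylinder body with a spinal canal, a posterior spinous process
    and two transverse processes; AP view looks along +z.
    """
    s = spec
    body_rx = 1.8 * s.shaft_radius  # reuse the size knobs for the body
    body_rz = 1.3 * s.shaft_radius
    half_h = 0.16 * s.shaft_length

    mu = np.zeros(px.shape, dtype=np.float32)
    soft = _ellipsoid(px, py, pz, (0.0, 0.0, -4.0), (40.0, 42.0, 45.0))
    mu[soft] = s.soft_mu

    body = (
        ((px / body_rx) ** 2 + ((pz - 10.0) / body_rz) ** 2 <= 1.0)
        & (np.abs(py) <= half_h)
    )
    spinous = _cylinder(px, py, pz, (0.0, 0.0, -6.0), (0.0, -5.0, -34.0), 5.0)
    trans_l = _cylinder(px, py, pz, (-8.0, 0.0, -8.0), (-30.0, 2.0, -13.0), 4.0)
    trans_r = _cylinder(px, py, pz, (8.0, 0.0, -8.0), (30.0, 2.0, -13.0), 4.0)
    ped_l = _cylinder(px, py, pz, (-11.0, 0.0, 3.0), (-9.0, 0.0, -10.0), 4.5)
    ped_r = _cylinder(px, py, pz, (11.0, 0.0, 3.0), (9.0, 0.0, -10.0), 4.5)
    bone = body | spinous | trans_l | trans_r | ped_l | ped_r
    mu[bone] = s.bone_mu

    canal = ((px / 6.5) ** 2 + ((pz + 2.0) / 5.5) ** 2 <= 1.0) & (np.abs(py) <= half_h + 2)
    mu[canal & ~spinous] = s.soft_mu
    return mu


_SOLIDS = {"femur": _femur_mu, "vertebra": _vertebra_mu}

#: detector magnification of an object at the isocenter (SDD / SID)
_DEFAULT_MAGNIFICATION = 2.0


def make_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, Pose]:
    """Voxelize a phantom and return it with its standard pose.

    The anatomy is rigidly perturbed (rotation ``perturb_rot_deg``, in-plane
    offset ``perturb_offset_mm``) relative to the canonical orientation; the
    returned standard pose holds exactly those parameters (translation
    magnified onto the detector), so projecting the volume at its standard
    pose reproduces the canonical view.  Deterministic: the spec fully
    defines the result.
    """
    shape = np.array(spec.grid_shape, dtype=int)
    spacing = np.full(3, float(spec.spacing_mm))
    origin = -(shape - 1) / 2.0 * spacing

    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    zs = origin[2] + spacing[2] * np.arange(shape[2])
    wx, wy, wz = np.meshgrid(xs, ys, zs, indexing="ij")

    # world -> canonical: undo the subject perturbation
    rot = rotation_matrix(Pose(*spec.perturb_rot_deg))
    ox, oy = spec.perturb_offset_mm
    shift = rot @ np.array([ox, oy, 0.0])
    cx = wx - shift[0]
    cy = wy - shift[1]
    cz = wz - shift[2]
    px = rot[0, 0] * cx + rot[1, 0] * cy + rot[2, 0] * cz
    py = rot[0, 1] * cx + rot[1, 1] * cy + rot[2, 1] * cz
    pz = rot[0, 2] * cx + rot[1, 2] * cy + rot[2, 2] * cz

    mu = _SOLIDS[spec.anatomy](px, py, pz, spec)

    # the phantom must lie fully inside the grid: no tissue on a boundary face
    support = mu > 0
    if (
        support[0].any() or support[-1].any()
        or support[:, 0].any() or support[:, -1].any()
        or support[:, :, 0].any() or support[:, :, -1].any()
    ):
        raise ValueError("phantom is not fully inside the volume grid")

    a, b, g = spec.perturb_rot_deg
    m = _DEFAULT_MAGNIFICATION
    standard = Pose(alpha=a, beta=b, gamma=g, tx=m * ox, ty=m * oy)
    return VolumeGrid(mu, spacing, origin), standard


def split_counts(n: int) -> tuple[int, int, int]:
    """60/20/20 train/val/test counts for a cohort of size ``n``."""
    n_train = int(round(0.6 * n))
    n_val = int(round(0.2 * n))
    n_test = n - n_train - n_val
    if n_val == 0 or n_test == 0:
        warnings.warn(
            f"cohort of size {n} leaves an empty validation or test split",
            stacklevel=2,
        )
    return n_train, n_val, n_test


def sample_specs(n: int, base_spec: PhantomSpec, seed: int) -> list[PhantomSpec]:
    """Draw ``n`` subject specs around ``base_spec`` (sizes, density, pose)."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        rot = np.clip(rng.normal(0.0, 3.0, size=3), -10.0, 10.0)
        off = rng.normal(0.0, 3.0, size=2)
        specs.append(
            replace(
                base_spec,
                shaft_radius=base_spec.shaft_radius * rng.uniform(0.85, 1.15),
                shaft_length=base_spec.shaft_length * rng.uniform(0.85, 1.15),
                head_radius=base_spec.head_radius * rng.uniform(0.85, 1.15),
                neck_angle=base_spec.neck_angle + rng.uniform(-8.0, 8.0),
                bone_mu=base_spec.bone_mu * rng.uniform(0.9, 1.1),
                soft_mu=base_spec.soft_mu * rng.uniform(0.9, 1.1),
                perturb_rot_deg=tuple(rot),
                perturb_offset_mm=tuple(off),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def make_cohort(n: int, base_spec: PhantomSpec | None = None, seed: int = 0) -> list[CohortSubject]:
    """Generate ``n`` phantom subjects with a reproducible 60/20/20 split."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if base_spec is None:
        base_spec = PhantomSpec()
    n_train, n_val, _ = split_counts(n)
    subjects = []
    for i, spec in enumerate(sample_specs(n, base_spec, seed)):
        volume, standard = make_phantom(spec)
        split = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
        subjects.append(
            CohortSubject(
                subject_id=f"{spec.anatomy}-{i:03d}",
                spec=spec,
                volume=volume,
                standard_pose=standard,
                split=split,
            )
        )
    return subjects


def mirror_volume(volume: VolumeGrid) -> VolumeGrid:
    """Reflect a volume across the sagittal (x = 0) plane.

    The grid is symmetric about the isocenter, so flipping the x axis of the
    voxel array realizes the reflection exactly.
    """
    return VolumeGrid(volume.voxels[::-1].copy(), volume.spacing.copy(), volume.origin.copy())


# ---------------------------------------------------------------------------
# I/O


def save_volume(volume: VolumeGrid, path) -> None:
    """Write a volume as NIfTI, spacing and origin carried by the affine."""
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), str(path))


def load_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    return VolumeGrid(np.asarray(img.get_fdata(), dtype=np.float32), spacing, affine[:3, 3])


def write_cohort_manifest(subjects: list[CohortSubject], path) -> pd.DataFrame:
    rows = []
    for s in subjects:
        p = s.standard_pose
        rows.append(
            {
                "subject_id": s.subject_id,
                "anatomy": s.spec.anatomy,
                "seed": s.spec.seed,
                "split": s.split,
                "laterality": s.laterality,
                "alpha": p.alpha,
                "beta": p.beta,
                "gamma": p.gamma,
                "tx": p.tx,
                "ty": p.ty,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
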