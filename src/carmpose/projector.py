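"""Ray-casting line-integral projector (digitally reconstructed radiographs).

A cone-beam geometry: point source, flat square detector, anatomy at the
isocenter (assumed midway between source and detector).  Each detector pixel
value is the line integral of linear attenuation along the source-to-pixel
ray, computed by fixed-step ray marching with trilinear interpolation.  The
projector is monoenergetic — no spectrum, scatter or detector noise — which
is sufficient for geometrically consistent, contrast-plausible images.

The hot loop is compiled with numba; the first call per process pays a
one-off JIT cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import Pose, rotation_matrix
from .phantoms import VolumeGrid

__all__ = [
    "CArmConfig",
    "ProjectionImage",
    "GeometryError",
    "project",
    "to_intensity",
    "neg_log",
]


class GeometryError(ValueError):
    """Raised for degenerate imaging geometry (e.g. source inside the volume)."""


@dataclass(frozen=True)
class CArmConfig:
    """Imaging geometry of the simulated C-arm.

    Defaults follow a Siemens Cios Spin-class device: 300 mm flat detector,
    source-detector distance 1164 mm, anatomy midway between source and
    detector (source-isocenter 582 mm).  ``sim_resolution`` is the simulated
    detector resolution per side; ``step_size`` the ray-marching step in mm
    (``None`` = half the smallest voxel spacing).
    """

    source_detector_distance: float = 1164.0
    source_isocenter_distance: float = 582.0
    detector_size: float = 300.0
    sim_resolution: int = 128
    step_size: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.source_isocenter_distance < self.source_detector_distance:
            raise ValueError("require 0 < source_isocenter_distance < source_detector_distance")
        if self.sim_resolution < 32:
            raise ValueError("sim_resolution must be >= 32")
        if self.step_size is not None and self.step_size <= 0:
            raise ValueError("step_size must be positive")

    @property
    def magnification(self) -> float:
        return self.source_detector_distance / self.source_isocenter_distance

    @property
    def pixel_pitch(self) -> float:
        """Detector mm per simulated pixel."""
        return self.detector_size / self.sim_resolution


@dataclass
class ProjectionImage:
    """A square line-integral image (dimensionless integral of mu dl)."""

    pixels: np.ndarray
    pixel_pitch: float
    pose: Pose

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("projection image must be square")
        if np.any(self.pixels < 0):
            raise ValueError("line integrals must be non-negative")


@njit(cache=True, fastmath=True)
def _raycast(vol, ox, oy, oz, sx, sy, sz, src, u_axis, v_axis, det_origin, n_pix, step):
    """Accumulate line integrals for all detector pixels (serial loop)."""
    nx, ny, nz = vol.shape
    out = np.zeros((n_pix, n_pix), dtype=np.float64)
    # interpolation support in world coordinates
    lo_x, lo_y, lo_z = ox, oy, oz
    hi_x = ox + sx * (nx - 1)
    hi_y = oy + sy * (ny - 1)
    hi_z = oz + sz * (nz - 1)
    for iv in range(n_pix):
        for iu in range(n_pix):
            px = det_origin[0] + (iu + 0.5) * u_axis[0] + (iv + 0.5) * v_axis[0]
            py = det_origin[1] + (iu + 0.5) * u_axis[1] + (iv + 0.5) * v_axis[1]
            pz = det_origin[2] + (iu + 0.5) * u_axis[2] + (iv + 0.5) * v_axis[2]
            dx = px - src[0]
            dy = py - src[1]
            dz = pz - src[2]
            norm = np.sqrt(dx * dx + dy * dy + dz * dz)
            dx /= norm
            dy /= norm
            dz /= norm
            # slab intersection with the interpolation box
            t0 = 0.0
            t1 = norm
            ok = True
            for axis in range(3):
                if axis == 0:
                    d, o, lo, hi = dx, src[0], lo_x, hi_x
                elif axis == 1:
                    d, o, lo, hi = dy, src[1], lo_y, hi_y
                else:
                    d, o, lo, hi = dz, src[2], lo_z, hi_z
                if abs(d) < 1e-12:
                    if o < lo or o > hi:
                        ok = False
                        break
                else:
                    ta = (lo - o) / d
                    tb = (hi - o) / d
                    if ta > tb:
                        ta, tb = tb, ta
                    if ta > t0:
                        t0 = ta
                    if tb < t1:
                        t1 = tb
            if not ok or t1 <= t0:
                continue
            n_steps = int((t1 - t0) / step) + 1
            acc = 0.0
            t = t0 + 0.5 * step
            for _ in range(n_steps):
                if t > t1:
                    break
                wx = src[0] + t * dx
                wy = src[1] + t * dy
                wz = src[2] + t * dz
                fx = (wx - ox) / sx
                fy = (wy - oy) / sy
                fz = (wz - oz) / sz
                if 0.0 <= fx <= nx - 1 and 0.0 <= fy <= ny - 1 and 0.0 <= fz <= nz - 1:
                    x0 = int(fx)
                    y0 = int(fy)
                    z0 = int(fz)
                    if x0 == nx - 1:
                        x0 -= 1
                    if y0 == ny - 1:
                        y0 -= 1
                    if z0 == nz - 1:
                        z0 -= 1
                    ax = fx - x0
                    ay = fy - y0
                    az = fz - z0
                    c00 = vol[x0, y0, z0] * (1 - ax) + vol[x0 + 1, y0, z0] * ax
                    c10 = vol[x0, y0 + 1, z0] * (1 - ax) + vol[x0 + 1, y0 + 1, z0] * ax
                    c01 = vol[x0, y0, z0 + 1] * (1 - ax) + vol[x0 + 1, y0, z0 + 1] * ax
                    c11 = vol[x0, y0 + 1, z0 + 1] * (1 - ax) + vol[x0 + 1, y0 + 1, z0 + 1] * ax
                    c0 = c00 * (1 - ay) + c10 * ay
                    c1 = c01 * (1 - ay) + c11 * ay
                    acc += c0 * (1 - az) + c1 * az
                t += step
            out[iv, iu] = acc * step
    return out


def project(volume: VolumeGrid, pose: Pose, config: CArmConfig | None = None) -> ProjectionImage:
    """Forward-project a volume at a pose.

    The pose rotates source and detector about the isocenter via
    :func:`carmpose.geometry.rotation_matrix`; ``tx``/``ty`` shift the
    detector within its own plane.  Image rows run along the detector v axis,
    columns along u.  Deterministic.
    """
    if config is None:
        config = CArmConfig()
    step = config.step_size
    if step is None:
        step = 0.5 * float(np.min(volume.spacing))
    if step > float(np.min(volume.spacing)) + 1e-12:
        raise ValueError("step_size must not exceed the smallest voxel spacing")

    rot = rotation_matrix(pose)
    nu = rot[:, 2]
    u_dir = rot[:, 0]
    v_dir = rot[:, 1]
    src = -config.source_isocenter_distance * nu

    lo, hi = volume.world_bounds()
    if np.all(src >= lo) and np.all(src <= hi):
        raise GeometryError("X-ray source lies inside the volume bounding box")

    det_center = (
        (config.source_detector_distance - config.source_isocenter_distance) * nu
        + pose.tx * u_dir
        + pose.ty * v_dir
    )
    pitch = config.pixel_pitch
    n = config.sim_resolution
    det_origin = det_center - 0.5 * config.detector_size * (u_dir + v_dir)
    pixels = _raycast(
        volume.voxels.astype(np.float32),
        float(volume.origin[0]),
        float(volume.origin[1]),
        float(volume.origin[2]),
        float(volume.spacing[0]),
        float(volume.spacing[1]),
        float(volume.spacing[2]),
        src.astype(np.float64),
        (pitch * u_dir).astype(np.float64),
        (pitch * v_dir).astype(np.float64),
        det_origin.astype(np.float64),
        n,
        float(step),
    )
    return ProjectionImage(np.maximum(pixels, 0.0).astype(np.float32), pitch, pose)


def to_intensity(img: ProjectionImage | np.ndarray, i0: float = 1.0) -> np.ndarray:
    """Beer-Lambert intensity image ``I0 * exp(-integral mu dl)``."""
    pixels = img.pixels if isinstance(img, ProjectionImage) else np.asarray(img)
    return i0 * np.exp(-pixels.astype(np.float64))


def neg_log(intensity: np.ndarray, i0: float = 1.0) -> np.ndarray:
    """Inverse of :func:`to_intensity`: back to the line-integral domain."""
    return -np.log(np.asarray(intensity, dtype=np.float64) / i0)
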