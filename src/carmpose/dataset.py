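"""Pose sampling, image augmentation and labeled-dataset assembly.

Training images are generated in two populations matching the two regressor
stages: a *coarse* set on a uniform grid over the out-of-plane rotations
(alpha, beta in [-30, 30] degrees, 3 degree steps around each subject's
standard pose) and a *fine* set with Gaussian rotations whose sigma =
30/2.576 covers the coarse region with 99% confidence.  The in-plane
rotation gamma and the detector translation t are cheap to apply in image
space, so they are augmented on the rendered projections rather than
re-simulated: gamma ~ U(-180, 180) (coarse) or N(0, sigma^2) (fine),
t ~ U(-50, 50)^2 mm, followed by scale (s in [0.8, 1]) and mean-preserving
contrast (c in [0.75, 1.25]) augmentation.

The full per-sample pipeline is: project at (alpha, beta) -> image rotation
by gamma -> center crop to the inscribed square -> translation crop ->
resize to the network input size -> scale augmentation -> per-image min-max
normalization -> contrast augmentation (clipped to [0, 1]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import affine_transform as _nd_affine
from skimage.transform import rotate as _sk_rotate, warp as _sk_warp
from skimage.transform import AffineTransform

from .geometry import Pose
from .phantoms import CohortSubject, VolumeGrid
from .projector import CArmConfig, project, neg_log

__all__ = [
    "SamplingConfig",
    "AugmentationConfig",
    "PoseDataset",
    "RawProjectionSet",
    "build_raw_dataset",
    "sample_coarse_poses",
    "sample_fine_poses",
    "augment_inplane",
    "augment_translation",
    "augment_scale",
    "augment_contrast",
    "preprocess",
    "minmax_normalize",
    "render_sample",
    "build_dataset",
]

#: two-sided 99% standard-normal quantile; ties the fine sigma to the coarse range
Z_99 = 2.576

#: factor of the safe center crop after rotation (inscribed square)
CENTER_CROP_FACTOR = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class SamplingConfig:
    """Pose-sampling law for dataset generation.

    ``fine_sigma`` defaults to ``coarse_range / 2.576`` so that the fine
    Gaussian covers the coarse angular region with 99% confidence; it is
    recomputed if ``coarse_range`` changes.
    """

    coarse_range: float = 30.0
    coarse_step: float = 3.0
    fine_sigma: float | None = None
    translation_range: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coarse_step <= 0 or self.coarse_range <= 0:
            raise ValueError("coarse_range and coarse_step must be positive")
        ratio = 2.0 * self.coarse_range / self.coarse_step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("coarse_step must divide 2 * coarse_range")
        if self.fine_sigma is None:
            object.__setattr__(self, "fine_sigma", self.coarse_range / Z_99)
        if self.fine_sigma <= 0:
            raise ValueError("fine_sigma must be positive")


@dataclass(frozen=True)
class AugmentationConfig:
    """Image-space augmentation laws (gamma law is selected by the stage)."""

    scale_range: tuple[float, float] = (0.8, 1.0)
    contrast_range: tuple[float, float] = (0.75, 1.25)
    translation_range: float = 50.0
    window_fraction: float = 0.72

    def __post_init__(self) -> None:
        if self.scale_range[1] > 1.0:
            raise ValueError("scale upper bound must be <= 1 (no zoom-in)")
        if not (self.contrast_range[0] <= 1.0 <= self.contrast_range[1]):
            raise ValueError("contrast range must contain 1")
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")


def sample_coarse_poses(config: SamplingConfig | None = None) -> list[Pose]:
    """Uniform grid of out-of-plane offsets around the standard direction.

    gamma and t are zero at simulation time; they are augmented in image
    space afterwards.  Defaults yield the 21 x 21 = 441 pose grid.
    """
    if config is None:
        config = SamplingConfig()
    ticks = np.arange(
        -config.coarse_range, config.coarse_range + 0.5 * config.coarse_step, config.coarse_step
    )
    return [Pose(alpha=float(a), beta=float(b)) for a in ticks for b in ticks]


def sample_fine_poses(
    n: int,
    config: SamplingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[Pose]:
    """Gaussian out-of-plane offsets for the fine stage.

    alpha, beta ~ N(0, sigma^2) i.i.d. with sigma = coarse_range / 2.576, so
    99% of draws fall inside the coarse range.  Draws are clipped at 3 sigma
    (beyond the coarse range) to keep labels inside the fine encode domain;
    the clip cannot change whether a draw lies within the coarse range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if config is None:
        config = SamplingConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    bound = 3.0 * config.fine_sigma
    ab = np.clip(rng.normal(0.0, config.fine_sigma, size=(n, 2)), -bound, bound)
    return [Pose(alpha=float(a), beta=float(b)) for a, b in ab]


# ---------------------------------------------------------------------------
# image-space augmentation


def augment_inplane(image: np.ndarray, gamma: float) -> np.ndarray:
    """Rotate an image by the in-plane angle ``gamma`` and center-crop.

    The rotation approximates a physical detector rotation by ``gamma``
    (sign convention tied to the projector's detector axes).  The crop
    retains the inscribed square (side / sqrt(2)) so that no rotation angle
    leaks border interpolation artifacts into the output.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("expected a square 2D image")
    n = image.shape[0]
    rotated = _sk_rotate(image, gamma, resize=False, order=1, mode="edge", preserve_range=True)
    crop = int(np.floor(n * CENTER_CROP_FACTOR))
    lo = (n - crop) // 2
    return rotated[lo : lo + crop, lo : lo + crop]


def augment_translation(
    image: np.ndarray,
    t_mm: tuple[float, float],
    pixel_pitch: float,
    window: int,
) -> np.ndarray:
    """Crop a ``window``-sized region whose center is offset by ``t_mm``.

    ``t_mm = (tx, ty)`` is a detector-plane translation; tx moves the crop
    center along image columns, ty along rows, converted at ``pixel_pitch``
    mm per pixel.  Windows reaching outside the image are padded with edge
    values (with a warning), mimicking a detector shifted past the simulated
    field of view.
    """
    image = np.asarray(image, dtype=np.float64)
    n = image.shape[0]
    if window > n:
        raise ValueError("crop window larger than image")
    dx = int(round(t_mm[0] / pixel_pitch))
    dy = int(round(t_mm[1] / pixel_pitch))
    cy = n // 2 + dy
    cx = n // 2 + dx
    y0 = cy - window // 2
    x0 = cx - window // 2
    pad = max(0, -y0, -x0, y0 + window - n, x0 + window - n)
    if pad > 0:
        warnings.warn("translation crop exceeds image bounds; padding with edge values")
        image = np.pad(image, pad, mode="edge")
        y0 += pad
        x0 += pad
    return image[y0 : y0 + window, x0 : x0 + window]


def augment_scale(image: np.ndarray, s: float) -> np.ndarray:
    """Scale image content by ``s`` about the center (canvas size kept).

    ``s < 1`` shrinks the anatomy, emulating a larger source-to-anatomy
    distance or smaller bone; borders are filled with edge values.
    """
    if not 0 < s <= 1:
        raise ValueError("scale factor must be in (0, 1]")
    if s == 1.0:
        return np.asarray(image, dtype=np.float64).copy()
    image = np.asarray(image, dtype=np.float64)
    center = (np.array(image.shape[::-1]) - 1) / 2.0
    tform = AffineTransform(scale=1.0 / s, translation=center * (1.0 - 1.0 / s))
    return _sk_warp(image, tform, order=1, mode="edge", preserve_range=True)


def augment_contrast(image: np.ndarray, c: float) -> np.ndarray:
    """Mean-preserving contrast change ``p -> (p - mu) * c + mu``."""
    image = np.asarray(image, dtype=np.float64)
    mu = image.mean()
    return (image - mu) * c + mu


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Per-image min-max rescale to [0, 1]; constant images map to zeros."""
    image = np.asarray(image, dtype=np.float64)
    lo = image.min()
    span = image.max() - lo
    if span <= 0:
        return np.zeros_like(image)
    return (image - lo) / span


def preprocess(intensity: np.ndarray) -> np.ndarray:
    """Convert an intensity-domain image to a normalized line-integral image.

    Applies the negative log transform (Beer-Lambert inversion) and then a
    per-image min-max rescale to [0, 1]; the output is monotone decreasing
    in intensity.  Non-positive pixels are clamped to the smallest positive
    value present (with a warning).
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if np.any(intensity <= 0):
        positive = intensity[intensity > 0]
        if positive.size == 0:
            warnings.warn("image has no positive intensities; returning zeros")
            return np.zeros_like(intensity)
        warnings.warn("non-positive intensities clamped before log transform")
        intensity = np.clip(intensity, positive.min(), None)
    return minmax_normalize(neg_log(intensity))


def _composed_augment(
    image: np.ndarray,
    gamma: float,
    t_mm: tuple[float, float],
    pixel_pitch: float,
    window_fraction: float,
    out_size: int,
    scale: float = 1.0,
) -> np.ndarray:
    """Rotation, crops, resize and scale augmentation as one resampling.

    Composes the augmentation chain (in-plane rotation, inscribed-square
    center crop, sub-pixel translation crop, resize, scale) into a single
    affine map and samples the output image with one bilinear interpolation.
    Equivalent to applying the individual operations in sequence, but with a
    single interpolation pass (and sub-pixel translation).
    """
    image = np.asarray(image, dtype=np.float64)
    n = image.shape[0]
    crop = int(np.floor(n * CENTER_CROP_FACTOR))
    window = int(round(crop * window_fraction))

    def shift(dx, dy):
        m = np.eye(3)
        m[0, 2] = dx
        m[1, 2] = dy
        return m

    # out -> in maps, (x=col, y=row) homogeneous coordinates
    c1 = (n - 1) / 2.0
    th = -np.deg2rad(gamma)
    rot = np.array([[np.cos(th), np.sin(th), 0.0], [-np.sin(th), np.cos(th), 0.0], [0, 0, 1]])
    a1 = shift(c1, c1) @ rot @ shift(-c1, -c1)
    a2 = shift((n - crop) // 2, (n - crop) // 2)
    x0 = crop // 2 + t_mm[0] / pixel_pitch - window // 2
    y0 = crop // 2 + t_mm[1] / pixel_pitch - window // 2
    a3 = shift(x0, y0)
    f = window / out_size
    a4 = shift(-0.5, -0.5) @ np.diag([f, f, 1.0]) @ shift(0.5, 0.5)
    c5 = (out_size - 1) / 2.0
    a5 = shift(c5, c5) @ np.diag([1.0 / scale, 1.0 / scale, 1.0]) @ shift(-c5, -c5)
    m_xy = a1 @ a2 @ a3 @ a4 @ a5
    # swap to (row, col) for scipy
    swap = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    m_rc = swap @ m_xy @ swap
    return _nd_affine(
        image,
        m_rc[:2, :2],
        offset=m_rc[:2, 2],
        output_shape=(out_size, out_size),
        order=1,
        mode="nearest",
    )


# ---------------------------------------------------------------------------
# rendering and dataset assembly


def render_sample(
    volume: VolumeGrid,
    base_pose: Pose,
    offset: Pose,
    carm: CArmConfig,
    input_size: int = 256,
    window_fraction: float = 0.72,
    scale: float = 1.0,
    contrast: float = 1.0,
) -> np.ndarray:
    """Render the normalized network input for ``base_pose (+) offset``.

    Out-of-plane rotations go through the projector; gamma and t of the
    absolute pose are applied in image space, exactly as during dataset
    generation, so labels and rendered images stay consistent.  Returns a
    float32 image of ``input_size**2`` values in [0, 1].
    """
    absolute = base_pose.compose(offset)
    raw = project(volume, Pose(alpha=absolute.alpha, beta=absolute.beta), carm)
    img = _composed_augment(
        raw.pixels,
        absolute.gamma,
        (absolute.tx, absolute.ty),
        raw.pixel_pitch,
        window_fraction,
        input_size,
        scale,
    )
    img = minmax_normalize(img)
    if contrast != 1.0:
        img = np.clip(augment_contrast(img, contrast), 0.0, 1.0)
    return img.astype(np.float32)


@dataclass
class RawProjectionSet:
    """Unaugmented out-of-plane projections for online augmentation.

    Holds one projection per sampled (alpha, beta) offset, at simulation
    resolution, together with each sample's subject standard-pose in-plane
    parameters.  During training, gamma/translation/scale/contrast are drawn
    fresh for every batch (online), which multiplies augmentation diversity
    without re-simulating.
    """

    images: np.ndarray  # (M, R, R) float32 line integrals at sim resolution
    base_offsets: np.ndarray  # (M, 2) alpha, beta offsets (the fixed labels)
    std_inplane: np.ndarray  # (M, 3) subject standard gamma, tx, ty
    subject_ids: np.ndarray
    splits: np.ndarray
    stage: str
    pixel_pitch: float

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, split: str) -> "RawProjectionSet":
        m = self.splits == split
        return RawProjectionSet(
            self.images[m], self.base_offsets[m], self.std_inplane[m],
            self.subject_ids[m], self.splits[m], self.stage, self.pixel_pitch,
        )

    def draw_batch(
        self,
        indices: np.ndarray,
        rng: np.random.Generator,
        sampling: "SamplingConfig",
        augmentation: "AugmentationConfig",
        input_size: int,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Render a freshly augmented batch for the given sample indices."""
        gamma_bound = 3.0 * sampling.fine_sigma
        images = np.empty((len(indices), input_size, input_size), dtype=np.float32)
        labels = np.empty((len(indices), 5))
        for row, i in enumerate(indices):
            if self.stage == "coarse":
                g = float(rng.uniform(-180.0, 180.0))
            else:
                g = float(np.clip(rng.normal(0.0, sampling.fine_sigma), -gamma_bound, gamma_bound))
            t = rng.uniform(-augmentation.translation_range, augmentation.translation_range, 2)
            s = float(rng.uniform(*augmentation.scale_range))
            c = float(rng.uniform(*augmentation.contrast_range))
            sg, stx, sty = self.std_inplane[i]
            img = _composed_augment(
                self.images[i],
                sg + g,
                (stx + t[0], sty + t[1]),
                self.pixel_pitch,
                augmentation.window_fraction,
                input_size,
                s,
            )
            img = minmax_normalize(img)
            if c != 1.0:
                img = np.clip(augment_contrast(img, c), 0.0, 1.0)
            images[row] = img
            labels[row] = (*self.base_offsets[i], g, t[0], t[1])
        return images, labels


def build_raw_dataset(
    cohort: list[CohortSubject],
    stage: str,
    sampling: SamplingConfig | None = None,
    carm: CArmConfig | None = None,
    fine_poses_per_subject: int = 100,
    splits: tuple[str, ...] = ("train", "val"),
) -> RawProjectionSet:
    """Project the out-of-plane pose samples of a cohort, without augmentation."""
    if stage not in ("coarse", "fine"):
        raise ValueError("stage must be 'coarse' or 'fine'")
    if not cohort:
        raise ValueError("cohort must be nonempty")
    sampling = sampling or SamplingConfig()
    carm = carm or CArmConfig()
    rng = np.random.default_rng(sampling.seed)
    images, offsets, inplane, sids, splits_out = [], [], [], [], []
    for subject in cohort:
        if subject.split not in splits:
            continue
        std = subject.standard_pose
        poses = (
            sample_coarse_poses(sampling)
            if stage == "coarse"
            else sample_fine_poses(fine_poses_per_subject, sampling, rng)
        )
        for pose in poses:
            raw = project(
                subject.volume,
                Pose(alpha=std.alpha + pose.alpha, beta=std.beta + pose.beta),
                carm,
            )
            images.append(raw.pixels)
            offsets.append([pose.alpha, pose.beta])
            inplane.append([std.gamma, std.tx, std.ty])
            sids.append(subject.subject_id)
            splits_out.append(subject.split)
    return RawProjectionSet(
        np.stack(images),
        np.asarray(offsets),
        np.asarray(inplane),
        np.asarray(sids),
        np.asarray(splits_out),
        stage,
        carm.pixel_pitch,
    )


@dataclass
class PoseDataset:
    """Labeled projection samples of one stage.

    ``labels`` rows are pose offsets ``[alpha, beta, gamma, tx, ty]``
    relative to each subject's standard pose.
    """

    images: np.ndarray  # (N, S, S) float32 in [0, 1]
    labels: np.ndarray  # (N, 5) float64
    subject_ids: np.ndarray  # (N,) str
    splits: np.ndarray  # (N,) str
    stage: str
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, split: str) -> "PoseDataset":
        mask = self.splits == split
        return PoseDataset(
            self.images[mask], self.labels[mask], self.subject_ids[mask], self.splits[mask],
            self.stage, self.manifest,
        )

    def labels_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.labels, columns=["alpha", "beta", "gamma", "tx", "ty"])
        frame.insert(0, "subject_id", self.subject_ids)
        frame.insert(1, "split", self.splits)
        return frame

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=self.images, compression="gzip")
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("subject_ids", data=np.asarray(self.subject_ids, dtype="S"))
            f.create_dataset("splits", data=np.asarray(self.splits, dtype="S"))
            f.attrs["stage"] = self.stage
            f.attrs["manifest"] = yaml.safe_dump(self.manifest)

    @classmethod
    def load(cls, path) -> "PoseDataset":
        with h5py.File(path, "r") as f:
            return cls(
                images=f["images"][:],
                labels=f["labels"][:],
                subject_ids=f["subject_ids"][:].astype(str),
                splits=f["splits"][:].astype(str),
                stage=str(f.attrs["stage"]),
                manifest=yaml.safe_load(f.attrs["manifest"]),
            )


def build_dataset(
    cohort: list[CohortSubject],
    stage: str,
    sampling: SamplingConfig | None = None,
    augmentation: AugmentationConfig | None = None,
    carm: CArmConfig | None = None,
    input_size: int = 256,
    n_augment: int = 1,
    fine_poses_per_subject: int = 100,
    splits: tuple[str, ...] = ("train", "val"),
) -> PoseDataset:
    """Simulate, augment and label a coarse- or fine-stage dataset.

    Per subject, pose offsets are sampled relative to that subject's
    standard pose (grid for coarse, Gaussian for fine), projected once per
    out-of-plane pose and augmented ``n_augment`` times with stage-specific
    gamma/translation draws plus scale and contrast augmentation.  All
    randomness flows through one generator seeded by ``sampling.seed``, so a
    rebuild with the same configuration is bit-identical.
    """
    if stage not in ("coarse", "fine"):
        raise ValueError("stage must be 'coarse' or 'fine'")
    if not cohort:
        raise ValueError("cohort must be nonempty")
    sampling = sampling or SamplingConfig()
    augmentation = augmentation or AugmentationConfig()
    carm = carm or CArmConfig()
    rng = np.random.default_rng(sampling.seed)

    images, labels, sids, splits_out = [], [], [], []
    gamma_bound = 3.0 * sampling.fine_sigma
    for subject in cohort:
        if subject.split not in splits:
            continue
        if stage == "coarse":
            poses = sample_coarse_poses(sampling)
        else:
            poses = sample_fine_poses(fine_poses_per_subject, sampling, rng)
        std = subject.standard_pose
        for pose in poses:
            # one projection per out-of-plane pose; gamma/t/scale/contrast are
            # augmented on the projection, as many times as requested
            raw = project(
                subject.volume,
                Pose(alpha=std.alpha + pose.alpha, beta=std.beta + pose.beta),
                carm,
            )
            for _ in range(n_augment):
                if stage == "coarse":
                    gamma = float(rng.uniform(-180.0, 180.0))
                else:
                    gamma = float(
                        np.clip(rng.normal(0.0, sampling.fine_sigma), -gamma_bound, gamma_bound)
                    )
                t = rng.uniform(
                    -augmentation.translation_range, augmentation.translation_range, size=2
                )
                s = float(rng.uniform(*augmentation.scale_range))
                c = float(rng.uniform(*augmentation.contrast_range))
                offset = Pose(pose.alpha, pose.beta, gamma, float(t[0]), float(t[1]))
                absolute = std.compose(offset)
                img = _composed_augment(
                    raw.pixels,
                    absolute.gamma,
                    (absolute.tx, absolute.ty),
                    raw.pixel_pitch,
                    augmentation.window_fraction,
                    input_size,
                    s,
                )
                img = minmax_normalize(img)
                if c != 1.0:
                    img = np.clip(augment_contrast(img, c), 0.0, 1.0)
                images.append(img.astype(np.float32))
                labels.append(offset.as_array())
                sids.append(subject.subject_id)
                splits_out.append(subject.split)

    manifest = {
        "stage": stage,
        "sampling": asdict(sampling),
        "augmentation": asdict(augmentation),
        "carm": asdict(carm),
        "input_size": input_size,
        "n_augment": n_augment,
        "fine_poses_per_subject": fine_poses_per_subject,
        "subjects": [s.subject_id for s in cohort if s.split in splits],
    }
    return PoseDataset(
        images=np.stack(images).astype(np.float32),
        labels=np.stack(labels),
        subject_ids=np.asarray(sids),
        splits=np.asarray(splits_out),
        stage=stage,
        manifest=manifest,
    )
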