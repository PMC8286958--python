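"""The desk-scale parameter-recovery study.

Generates a phantom cohort, trains both regressor stages on the training
split (online gamma/translation/scale/contrast augmentation, best-validation
weights), and evaluates the two-stage pipeline plus baselines on the
held-out test subjects.  This is the package's headline experiment: it
checks that the method recovers known pose parameters from images simulated
under its own model.

Problem sizes are chosen for a single CPU core: 30 subjects at 64^3 voxels
(2.5 mm), 96^2 simulated projections, 64^2 network inputs, a 6-degree
coarse grid and 100 fine poses per subject.  All randomness derives from
one seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from .dataset import (
    AugmentationConfig,
    SamplingConfig,
    build_dataset,
    build_raw_dataset,
)
from .phantoms import CohortSubject, PhantomSpec, make_cohort
from .pipeline import EvalConfig, EvalReport, evaluate
from .projector import CArmConfig
from .regressor import CoarsePoseRegressor, FinePoseRegressor

__all__ = ["StudyConfig", "StudyResult", "run_parameter_recovery"]


@dataclass(frozen=True)
class StudyConfig:
    """Sizes and training hyperparameters of the desk-scale study."""

    n_subjects: int = 30
    grid_voxels: int = 64
    spacing_mm: float = 2.5
    sim_resolution: int = 96
    input_size: int = 64
    coarse_step: float = 6.0
    fine_poses_per_subject: int = 100
    n_val_augment: int = 2
    channels: tuple[int, int, int, int] = (8, 16, 32, 64)
    fc: tuple[int, int] = (256, 128)
    learning_rate: float = 1e-3
    lr_decay: float = 0.1
    coarse_iterations: int = 120
    fine_iterations: int = 30
    batches_per_iteration: int = 50
    patience: int = 40
    n_eval_poses: int = 25


@dataclass
class StudyResult:
    report: EvalReport
    coarse_model: CoarsePoseRegressor
    fine_model: FinePoseRegressor
    cohort: list[CohortSubject]
    timings: dict = field(default_factory=dict)


def _train_stage(stage_cls, stage, cohort, carm, sampling, config, seed):
    train_subjects = [s for s in cohort if s.split == "train"]
    val_subjects = [s for s in cohort if s.split == "val"]
    raw = build_raw_dataset(
        train_subjects,
        stage,
        sampling,
        carm,
        fine_poses_per_subject=config.fine_poses_per_subject,
        splits=("train",),
    )
    val = build_dataset(
        val_subjects,
        stage,
        SamplingConfig(coarse_step=config.coarse_step, seed=sampling.seed + 1),
        AugmentationConfig(),
        carm,
        input_size=config.input_size,
        n_augment=config.n_val_augment,
        fine_poses_per_subject=config.fine_poses_per_subject // 2,
        splits=("val",),
    )
    iterations = config.coarse_iterations if stage == "coarse" else config.fine_iterations
    model = stage_cls(
        input_size=config.input_size,
        channels=config.channels,
        fc=config.fc,
        learning_rate=config.learning_rate,
        lr_decay=config.lr_decay,
        iterations=iterations,
        batches_per_iteration=config.batches_per_iteration,
        patience=config.patience,
        seed=seed,
    )
    model.fit_raw(raw, val.images, val.labels, sampling=sampling)
    return model


def run_parameter_recovery(seed: int = 0, config: StudyConfig | None = None) -> StudyResult:
    """Run the full cohort -> train -> evaluate study for one seed."""
    config = config or StudyConfig()
    carm = CArmConfig(sim_resolution=config.sim_resolution)
    base_spec = PhantomSpec(
        grid_shape=(config.grid_voxels,) * 3, spacing_mm=config.spacing_mm
    )
    timings: dict[str, float] = {}

    t0 = time.time()
    cohort = make_cohort(config.n_subjects, base_spec, seed=seed)
    timings["cohort_s"] = time.time() - t0

    t0 = time.time()
    coarse = _train_stage(
        CoarsePoseRegressor,
        "coarse",
        cohort,
        carm,
        SamplingConfig(coarse_step=config.coarse_step, seed=seed * 1000 + 11),
        config,
        seed=seed,
    )
    timings["coarse_train_s"] = time.time() - t0

    t0 = time.time()
    fine = _train_stage(
        FinePoseRegressor,
        "fine",
        cohort,
        carm,
        SamplingConfig(coarse_step=config.coarse_step, seed=seed * 1000 + 23),
        config,
        seed=seed + 1,
    )
    timings["fine_train_s"] = time.time() - t0

    t0 = time.time()
    test_subjects = [s for s in cohort if s.split == "test"]
    report = evaluate(
        coarse,
        fine,
        test_subjects,
        carm,
        EvalConfig(
            n_initial_poses=config.n_eval_poses,
            input_size=config.input_size,
            seed=seed * 1000 + 37,
        ),
    )
    timings["evaluate_s"] = time.time() - t0
    return StudyResult(report, coarse, fine, cohort, timings)
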