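# Methods

## Problem and model

A mobile C-arm acquires a fluoroscopic projection of a patient; surgical
quality control requires anatomy-specific *standard projections* (e.g. the
AP and lateral views of the proximal femur). `carmpose` implements a
simulation-trained, two-stage CNN regression approach to repositioning: from
one projection of a yet-unseen subject, a network predicts the 5-DoF pose
update that moves the C-arm toward the standard view; the device is
repositioned, a second image is acquired, and a second network refines the
estimate.

The pose has five degrees of freedom: the orbital rotation `alpha` (LAO),
the angular rotation `beta` (CRA), the in-plane detector rotation `gamma`,
and the detector-plane translation `(tx, ty)`. Translation along the beam
only changes magnification and is excluded; the anatomy is assumed roughly
midway between source and detector. The principal-ray direction is

    nu = [sin a, -cos a sin b, cos a cos b]^T,

realized as the third column of the rotation `Rx(beta) Ry(alpha) Rz(gamma)`
(this composition order is the unique one reproducing `nu`; `gamma` acts
last, about the ray, so it never moves `nu`).

Pose *offsets* relative to a subject's standard pose are treated additively
in parameter space: an absolute pose is `standard + offset`, labels are
offsets, and applying a predicted update means subtracting it (with the
sign flips of the laterality mirror where the anatomy was mirrored). This
matches how the training grid is defined — rotations sampled *around* the
standard direction — and makes the update exactly invertible.

## Imaging model

The projector computes monoenergetic line integrals through a voxelized
attenuation volume: a point source at `source_isocenter_distance` (582 mm)
from the isocenter, a square flat detector (300 mm, Cios-Spin-class
geometry, source-detector distance 1164 mm), fixed-step ray marching with
trilinear interpolation (default step: half the smallest voxel spacing;
zero attenuation outside the grid). Energy dependence, scatter, detector
noise and collimation are deliberately not modelled: the learning problem
needs geometrically consistent, contrast-plausible images, not dosimetric
fidelity. Beer-Lambert conversion to intensity (`I0 exp(-∫mu dl)`) and the
negative-log inverse are provided so the preprocessing contract (negative
log, then per-image min-max to [0, 1]) has an exact round trip.

Accuracy: against a dense-quadrature reference (10x finer sampling,
independent implementation) the projector agrees to well under 1% of the
dynamic range at an eighth-voxel step; the default half-voxel step trades
some of that accuracy for speed, which is irrelevant to learning because
train and test images share the discretization.

## Phantoms as the study cohort

Real CT cohorts being unavailable, the cohort is generated: parametric
femur-like and vertebra-like solids in a soft-tissue ellipsoid (bone
0.06/mm, soft tissue 0.019/mm — roughly 60 keV values), voxelized at
64^3 x 2.5 mm by default. Inter-subject variation randomizes sizes
(+-15%), neck angle (+-8 deg), attenuations (+-10%) and a rigid
perturbation of the standard pose (sigma = 3 deg per axis, clipped at
10 deg; sigma = 3 mm in-plane offset, magnified onto the detector). The
perturbation *is* the subject's ground-truth standard pose, emulating
per-patient reference variability; because the network cannot know it, it
sets an irreducible error floor of about 3 deg per axis.

Two design points matter and were fixed during development:

- **Depth asymmetry.** A quasi-planar phantom projects almost identically
  at `+alpha` and `-alpha`, making the out-of-plane offset sign
  unidentifiable — with an early planar femur the 40-degree sign flip
  changed the image no more than a 5-degree nudge, and the regressor
  could not learn `alpha`/`beta` at all. The femur therefore has an
  anteverted neck (18 deg out of plane), a posteriorly bowed shaft and a
  posterior greater trochanter, like the real bone; the vertebra's
  spinous process provides the same cue.
- **Field of view.** After rotation crop and translation crop the network
  sees about 75 mm at the isocenter. The distinctive anatomy (head, neck,
  trochanters) is centered there; the shaft runs out of view, as in real
  hip fluoroscopy.

## Training data and augmentation

Coarse stage: `alpha, beta` on a uniform grid over [-30, 30] deg around
each subject's standard pose; fine stage: Gaussian draws with
`sigma = 30/2.576` so the coarse region is covered with 99% confidence
(draws clipped at 3 sigma to keep labels encodable; the clip cannot change
the within-30-degree fraction). In-plane rotation and translation are
applied in image space — detector rotation is well approximated by image
rotation (measured: ~0.2% of dynamic range) and detector shift is exactly
image shift — with `gamma ~ U(-180, 180)` (coarse) or the same Gaussian
(fine), `t ~ U(-50, 50)^2 mm`, scale `s in [0.8, 1]` and mean-preserving
contrast `c in [0.75, 1.25]`.

The pipeline order is: projection at `(alpha, beta)` -> image rotation by
`gamma` -> center crop to the inscribed square (side/sqrt(2), so no border
artifacts at any angle) -> translation crop (window fraction 0.72 of the
crop) -> resize to the network input -> scale augmentation -> per-image
min-max normalization -> contrast augmentation, clipped to [0, 1]. During
training these steps are composed into a single affine resampling per
sample (~0.25 ms), which enables *online* augmentation: every batch draws
fresh `gamma/t/s/c`, so no two presentations of a projection are alike.
Offline pre-augmented datasets (the `build_dataset` path) are used for
validation sets and reproducible artifacts.

## Networks and losses

Both stages use the same compact CNN: four stride-2 3x3 convolutional
blocks (batch normalization after every convolution, ReLU after every
second one) and three fully connected layers. Channel widths are
configurable; the desk defaults are (8, 16, 32, 64) channels and
(256, 128) hidden FC units on 64^2 inputs. The network is implemented
directly in numpy (float32) with manual backpropagation and Adam;
gradients are verified against central finite differences in the test
suite. Everything is seeded: same seed, same weights, same batches.

Targets are range-normalized: `alpha, beta` by the 30-degree bound
(fine stage: by its 3-sigma bound of ~34.9 deg), translations by 50 mm.
The coarse in-plane rotation is encoded as `(cos gamma, sin gamma)` — a
loss continuous across the +-180 wrap — and recovered as
`atan2(s, c)` after unit normalization, which makes the recovery invariant
to positive rescaling of the two channels. The fine stage regresses its
narrow-domain `gamma` directly.

The loss *metrics* are the weighted forms

    L_coarse = da^2 + db^2 + dc_g^2 + ds_g^2 + w^2 (dtx^2 + dty^2)
    L_fine   = |da| + |db| + |dg| + w (|dtx| + |dty|)

with `w = pi/180` (a millimetre costs as much as a degree of arc).
*Optimization*, however, runs in the normalized target space: out-of-plane
terms in units of their bound, translations keeping the weight `w`
relative to the sin/cos terms (`w * dt_mm = w * 50 * dt_norm`). This is
the space the output normalization defines, and it matters in practice:
optimizing the raw degree-scale loss lets the initially-noisy out-of-plane
gradients (up to ~900 per term) swamp the shared convolutional features by
orders of magnitude, and training never beats the trivial
predict-the-mean solution; in the normalized space all terms are O(1) and
every component trains.

Training: Adam, batch 64, rounds of 50 batches; best-validation-loss
weights are restored, with early stopping; the desk configuration uses a
learning rate of 1e-3 with cosine decay to 1e-4 (the constant 1e-4
default suits much longer schedules). Divergence (non-finite loss) aborts
with a diagnostic.

## Two-stage inference and evaluation

`two_stage_predict` renders the current view, applies the coarse update
(inverse application; mirrored laterality flips `alpha`, `gamma`, `tx`),
re-renders, and applies the fine update. Evaluation runs
simulation-in-the-loop on held-out test subjects with initial poses drawn
from the coarse law (uniform out-of-plane in +-30 deg, uniform gamma,
uniform +-50 mm translation; 25 poses per subject), and reports five
metrics per stage: `d_theta` (angle between principal rays,
`arccos(nu . nu_hat)` with the dot product clamped to [-1, 1]), the
absolute parameter errors `d_alpha`, `d_beta`, the circular `d_gamma`,
and the Euclidean translation error `dc`. Two baselines are always
included: *single prediction* (the post-coarse row) and *iterated coarse*
(the coarse network applied twice with one re-projection).

Evaluation renders through the same render-then-2D-transform path as
training, so label semantics are identical; the projector's physical
`gamma`/`t` path is tied to the image-space path by property tests
(rotational symmetry of a centered sphere; detector shift equals the
magnified volume shift).

## The desk-scale parameter-recovery study

`carmpose.experiments.run_parameter_recovery` is the headline experiment:
30 phantoms (18/6/6 train/val/test), 96^2 simulated projections, 64^2
inputs, a 6-degree coarse grid (121 poses per subject; the 3-degree grid
was measured to triple projection cost without faster learning per
iteration at this scale), 100 fine poses per subject, 120 coarse / 30 fine
training rounds. It runs in roughly a quarter hour on one CPU core. The
checks: the trained coarse stage at least halves the mean initial
`d_theta` on held-out subjects, the two-stage pipeline does not lose to
the iterated-coarse baseline on `d_theta`, and the fine stage improves
`d_gamma` and `dc` without degrading `d_theta`.

## What the synthetic study does and does not show

Passing the study shows that the estimator recovers known pose parameters
from images generated under its own forward model, that the two-stage
decomposition helps, and that all geometric plumbing (labels, updates,
metrics, mirroring) is consistent. It does not show clinical performance:
the phantoms lack anatomical detail, pathology, implants and neighboring
structures; the projector lacks spectra, scatter and noise; and the domain
gap between simulation and real fluoroscopy — the central challenge the
original simulation approach addresses with realistic DRR rendering — is
absent here by construction. Accuracy numbers from this study therefore
characterize the implementation, not the clinical method.

## Numerical choices and degenerate inputs

- Dot products are clamped to [-1, 1] before `arccos`; `d_theta` near zero
  is accurate only to ~1e-5 deg (arccos conditioning).
- `gamma` is normalized to (-180, 180]; `gamma_error` wraps mod 360.
- `recover_gamma(0, 0)` raises (undefined angle).
- Constant images min-max-normalize to zeros; non-positive intensities are
  clamped to the smallest positive pixel before the log transform, with a
  warning.
- Translation crops beyond the image edge pad with edge values and warn.
- The 60/20/20 split uses rounded counts; degenerate cohorts (empty val or
  test split) warn.
- Conv biases and batch-norm shifts immediately preceding another batch
  normalization have provably zero gradient; the gradient check accounts
  for this.

## Known limitations

- The numpy CNN is CPU-bound; 256^2 inputs and paper-scale channel widths
  train impractically slowly (supported, not exercised by tests).
- The laterality mirror assumes a symmetric detector and square pixels.
- Real-CT ingestion is limited to reading volumes with spacing and origin;
  no segmentation or ROI cropping is provided.
- The fine stage's `gamma` domain (+-3 sigma) means a badly wrong coarse
  `gamma` cannot be fully corrected in one fine step.
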