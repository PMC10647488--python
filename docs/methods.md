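# Methods

This note documents the models, conventions and numerical choices behind
hydromocap, what the synthetic scene does and does not emulate, and the
known limitations.

## Camera model and conventions

A pinhole camera with Brown–Conrady distortion on normalized coordinates:
radial coefficients k1, k2, k3 and tangential p1, p2, applied between the
perspective division and the intrinsic matrix K = [[fx, s, cx], [0, fy,
cy], [0, 0, 1]]. World units are millimetres, every frame is right-handed,
pixels have their origin at the top-left corner (u right, v down,
sub-pixel continuous), and camera frames put the optical axis on +z with x
right and y down. Poses are stored world→camera only; inverses are always
derived. An equidistant-fisheye model is deliberately out of scope: at the
rig's working distance (≈1.3 m) the polynomial model reproduces the lens
well and keeps inversion simple.

**Distortion inversion** uses Newton's method on the 2-D normalized system
with the analytic Jacobian, tolerance 1e-10 normalized units, ≤50
iterations. A plain fixed-point update (`x ← x_d − δ(x)`) is *not*
contractive near the image corners for k1 = −0.25 and diverges there;
Newton converges everywhere the radial profile is monotone, which holds on
the whole image for the default coefficients.

## Intrinsic calibration

Classical planar calibration, with a staged initialization that survives
strong barrel distortion:

1. **Plumb-line seed.** Rows and columns of the checkerboard are straight,
   so their images must be straight after undistortion. Radial
   coefficients (k1, k2 in an arbitrary trial normalization) are fit by
   minimizing the perpendicular scatter of each line's corners about its
   principal axis, *normalized by the line's extent* — without that
   normalization, shrinking the whole image is a free lunch and k2
   diverges. The fit is graduated (k1 alone, then k1 + k2) and multi-start
   (barrel and pincushion seeds), because one-sided line coverage makes
   the objective multi-modal.
2. **Closed form.** Homographies are estimated from the straightened
   corners (normalized DLT) and the image of the absolute conic yields
   closed-form fx, fy, cx, cy, skew.
3. **Refinement.** Damped least squares (scipy `least_squares`, trf) over
   intrinsics + distortion + per-view poses against total squared
   reprojection error, with a block-sparse Jacobian (each residual sees
   the ~10 global parameters plus its own view's 6 pose parameters).
   Tolerances 1e-12, ≤200 iterations; the solver only accepts
   cost-decreasing steps, so refinement never worsens its initialization.
   Because planar calibration has a well-known spurious minimum trading
   focal length against board depth, the refinement is run from the
   closed-form start plus a spare focal start (a spread of typical fields
   of view when the closed form fails); starts are screened cheaply and
   the two best are polished.

k3 is only estimated with ≥10 views, otherwise fixed at zero
(ill-conditioning guard). Fronto-parallel view sets are rejected
explicitly (board normals within 3° of parallel) since the conic
constraints are then rank-deficient. Reported RMSE is per pixel
*coordinate* (so 0.5 px isotropic noise gives RMSE ≈ 0.5).

## Stereo calibration

For each matched view the board→camera poses of the two cameras compose
into a relative pose camera_a→camera_b. These are robustly averaged —
quaternion mean for rotation, componentwise median for translation — and
checked for consistency (defaults: 5° rotation spread, 150 mm translation
spread; a violation suggests mis-synchronized views and is an error). A
joint refinement then optimizes the relative pose and all board poses
against reprojection error in both cameras. Fewer than 15 paired views
logs a warning (the acquisition protocol's minimum is procedural, not
algorithmic); fewer than 3 is an error.

## Synchronization

Extinction events are onsets of luminance excursions below
`median − k·MAD` (k = 5; MAD rather than SD because a bright subject
moving through the frame corrupts the mean) that stay low for ≥3 frames —
a real extinction lasts many frames at 120 fps, while single-frame noise
can cross any percentile threshold. Onsets closer than 0.5 s to the
previous event are suppressed. Offsets are integer frames (the cameras
share a nominal 120 fps clock; sub-frame alignment is out of scope); when
more than four events appear, the first four are used, matching the
three-before/one-after protocol. Inter-event gaps must agree across
cameras within 2 frames.

## Reconstruction

Two-view homogeneous DLT via the smallest singular vector of the stacked
4×4 system, vectorized over frames. |w| < 1e-12 (point at infinity) is an
error; reprojection residuals above 5 px or negative depths are *flagged,
not dropped* — the caller decides. Only frames seen by both cameras of a
pair are reconstructed. Simultaneous >2-camera triangulation is a
non-goal: the rig is operated pairwise, and two cameras suffice as long as
the three markers of an angle come from the same pair.

Transitions between pair frames are least-squares rigid fits
(cross-covariance SVD with determinant sign correction, no scale) over
*all* (label, frame) samples reconstructed by both adjacent pairs;
duplicated samples are merged by unweighted averaging after
transformation. Collinear correspondence sets are rejected. The pool frame
takes z from the plumb lines (ball minus weight — the weights hang down),
y from the waterline direction orthogonalized against z, x = y × z;
plumb/waterline directions within 5° of parallel are rejected.

Gaps up to 12 frames (≈0.1 s at 120 fps) may be filled by linear
interpolation; longer gaps stay missing.

## Kinematics

The eight joints are marker triples from the standard six-markers-per-limb
scheme (scapular spine, shoulder, elbow, carpus, fetlock, hoof in front;
tuber coxae, hip, stifle, tarsus, fetlock, hoof behind). The angle is the
unsigned angle θ ∈ [0, 180] between the proximal and distal limb vectors
at the vertex; hyperextension (needed for the fetlocks, which extend past
180°) is detected by the sign of (v₁ × v₂)·lateral and reported as
360 − θ. The lateral (medio-lateral) axis defaults to the pool-frame x
axis — swimming is mainly sagittal-plane motion — and is configurable per
joint; the unsigned part is invariant to the choice. ROM = maximal
extension − maximal flexion = series max − min (smaller angle = more
flexed). No smoothing is applied by default; an optional zero-phase
4th-order Butterworth low-pass (6 Hz cutoff) is available for
extrema-based summaries on noisy series. Cycle boundaries are successive
extension peaks at least `min_period_s` apart (scipy `find_peaks` with a
prominence floor of 10 % of the series range).

## Synthetic scene

The generators define the study conditions; every observation is the
exact projection of emitted ground truth before seeded Gaussian pixel
noise, and everything is deterministic given (parameters, seed).

* **Rig**: six cameras at 500 mm spacing facing the motion plane at
  1300 mm, fx = fy = 800 px at 2704×1520 (wide-angle, action-camera-like),
  distortion k1 = −0.25, k2 = 0.05 so undistortion is non-trivially
  exercised. Composite coverage ≥ 2.6 m with large pairwise overlap.
* **Checkerboard**: 9×7 interior corners at 60 mm pitch — the 600×480 mm
  board whose five reference points (TL, TR, ML at (240, 240), BL, BR)
  carry the validation segments and angles. The sweep crosses the full
  field of view with incommensurate yaw/pitch/roll oscillations (±35°,
  ±25°, ±20°) so every camera's window contains a variety of board
  orientations, as the calibration protocol demands, and overshoots the
  rig by 1.2 m per side so the end cameras see the board on both sides of
  their optical axis (one-sided coverage makes their calibration
  practically unidentifiable).
* **Swim**: two five-segment limb chains (segment lengths 450/330/380/
  250/150 mm front, 400/420/430/290/150 mm hind — plausible for a
  warmblood) animated by sinusoidal joint trajectories whose means and
  amplitudes match the reported swim ranges (e.g. carpus 118.5 ± 49.5°,
  hind fetlock 156 ± 47°, hyperextending past 180°), a 1.5 s cycle, a 5°
  out-of-plane wobble to exercise genuinely 3-D code paths, constant
  forward travel across the rig and a 50 mm vertical bob.
* **Luminance**: baseline-1 series with 12-frame square dips (three
  before, one after the event window), shifted per camera by its planted
  offset.

What the generators do **not** emulate: marker appearance and tracking
failures (tracks arrive as clean pixel coordinates plus isotropic
Gaussian noise), water optics and refraction, occlusion by the body,
outliers (a uniform-outlier option exists but is off by default), and
rolling-shutter or clock-drift effects. Passing tests therefore
demonstrate the correctness and noise behaviour of the *geometry
pipeline*, not robustness to tracking pathologies.

## Accuracy experiments

`checkerboard_error_experiment` reproduces the error-estimation protocol
end to end **from the synthetic observations alone** (no ground-truth
calibration enters): intrinsics per camera from 24 sweep views, stereo per
pair from 24 paired views, triangulation of the five reference points for
every frame, unification, then per-frame absolute errors of the eight
segments and five angles with box-plot summaries (1.5·IQR whiskers),
both per segment and pooled over symmetric pairs. The acceptance script
runs the full 60 s sweep (7200 frames); the test suite uses a 12 s sweep
with 14 calibration views to keep the default run fast — same rig, same
noise, proportionally fewer data.

`swim_recovery_experiment` measures joint-angle recovery under 0.5 px
noise with the rig's known calibration. Each joint is computed from a
single camera pair — the one with the best viewing geometry (smallest mean
lateral offset of the joint from the pair's centre line, chosen without
reference to ground truth) — because switching pairs mid-series injects
transition-alignment noise, and a single pair suffices for an angle. The
6 Hz low-pass is applied before the comparison: at 120 fps the marker
noise lies two decades above the ~0.7 Hz motion band, so the filter is
part of the recovery estimator, not a cosmetic. Typical results: per-joint
RMSE 0.2–0.9°, ROM error under 2°, the fetlocks worst — their distal
segments are short, so the same millimetre-level point noise subtends a
larger angle, consistent with the field experience that fetlock angles
are the noisiest.

## Known limitations

* Stereo depth error grows with the square of distance over the 500 mm
  baseline; at 1.3 m it is ≈3–4 mm per 0.5 px of disparity noise and is
  the dominant error term. Segments oriented along the viewing direction
  (the "horizontal" board segments during oblique passes) inherit it,
  which is why their errors disperse more than the vertical ones.
* The transition between pair frames is estimated from noisy overlap
  samples; its residual rotation (≈0.1°) slightly biases angles computed
  from markers that straddle a pair boundary. Keeping all three markers
  of a joint in one pair avoids this entirely.
* No refraction modelling: cameras are assumed submerged in a uniform
  medium. A glass port or air-water interface would need a different
  projection model.
* Calibration quality drives the global scale: a 0.5 % focal error maps
  to a 0.5 % length error on every reconstructed segment. The staged
  initialization makes convergence reliable, but the variance of the
  focal estimate is set by the view geometry and noise, not by the
  optimizer.
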