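# hydromocap

Low-cost multi-camera **underwater motion capture**: camera calibration,
event-based synchronization, DLT stereo triangulation, unification of
camera-pair frames into a global pool frame, and joint-angle kinematics —
built around the six-camera rig used to film horses swimming in a
rehabilitation pool, and fully exercisable on a synthetic scene.

## Who this is for

Biomechanics groups and veterinary clinics that film large animals (or
humans) underwater with a handful of consumer action cameras and need the
whole chain from 2D marker tracks to joint ranges of motion — without an
optical mocap lab. The package consumes plain CSV files (2D tracks,
checkerboard corners, luminance series) and writes plain CSV/JSON/TRC, so
any tracker or labeling tool can sit in front of it.

## The pipeline

Six cameras (120 fps, 2.7K) along one pool wall form three stereo pairs
with overlapping fields of view (about 2.6 m × 3.0 m of coverage).

1. **Synchronization** — the pool lighting is switched off briefly several
   times (three dips before the recording, one after). Each camera's mean
   luminance series shows the dips; onsets below `median − k·MAD` (k = 5)
   give integer frame offsets between the cameras.
2. **Intrinsic calibration** — per camera, from views of an asymmetric
   checkerboard: a pose-free *plumb-line* fit straightens the board's rows
   and columns to seed the radial distortion, the image of the absolute
   conic gives closed-form intrinsics, and a damped least-squares
   refinement jointly optimizes intrinsics, Brown–Conrady distortion
   (k1, k2, k3, p1, p2) and per-view poses.
3. **Stereo calibration** — per camera pair, from ≥ 15 simultaneous board
   views: per-view relative poses are robustly averaged (quaternion mean,
   componentwise-median translation) and refined against reprojection
   error in both cameras.
4. **Triangulation** — undistorted tracks are triangulated per pair with
   the Direct Linear Transformation: for observed pixels (u, v) and
   projection matrices P, the stacked system
   `[u·p3 − p1; v·p3 − p2]` (four equations, two cameras) is solved by the
   smallest singular vector. Points land in the first camera's frame of
   each pair.
5. **Unification** — adjacent pairs see the same markers in overlapping
   regions; a least-squares rigid fit (cross-covariance SVD with
   determinant correction, the "transition matrix") chains every pair
   frame into camera 1's frame.
6. **Pool frame** — weighted plumb lines define z (up), foam delineators
   on the waterline define y, x completes the right-handed trihedron.
7. **Kinematics** — eight joint angles (shoulder, elbow, carpus, front
   fetlock, hip, stifle, tarsus, hind fetlock) as the interior angle
   θ ∈ (0, 360) at the vertex marker; the sign of `(v₁ × v₂)·lateral`
   detects hyperextension (fetlocks exceed 180°), and ROM = max − min
   (maximal extension − maximal flexion).

Accuracy is estimated with the published checkerboard protocol: five
reference points (TL, TR, ML, BL, BR) are reconstructed during a sweep and
eight segments (339.4–600.0 mm) and five angles (33.69°–101.31°) are
compared against the board's known geometry.

> **Note on the reference angles.** From the printed side lengths
> 600.0 / 432.7 / 339.4 mm, the law of cosines puts 101.31° at vertex ML,
> **45.00° at vertex TL** (angle ML-TL-TR) and **33.69° at vertex TR**
> (angle TL-TR-ML). The published angle table attaches 33.69° to TL and
> 45.00° to TR, which is inconsistent with its own side lengths; this
> package pins the angle ground truths to the geometry.

## Worked example

Generate a full synthetic session (rig config, 2D tracks of a swimming
horse with per-camera clock offsets, checkerboard observations, luminance
series, pool-frame markers) and run the pipeline:

```bash
hydromocap simulate --out demo --seed 5 --n-cycles 2
hydromocap run --rig-config demo/rig.yaml --tracks-csv demo/tracks.csv \
    --luminance-csv demo/luminance.csv --global-frame-json demo/global_frame.json \
    --out demo/results
hydromocap angles --trajectories-csv demo/results/trajectories.csv --out demo/angles
```

which prints (0.5 px observation noise, seed 5):

```
pipeline complete: 12 trajectories, 8 ROM summaries -> demo/results
shoulder: flexion 100.30 deg, extension 120.76 deg, ROM 20.46 deg
elbow: flexion 57.10 deg, extension 134.61 deg, ROM 77.52 deg
carpus: flexion 68.18 deg, extension 168.14 deg, ROM 99.96 deg
front_fetlock: flexion 126.60 deg, extension 202.87 deg, ROM 76.27 deg
hip: flexion 66.97 deg, extension 107.98 deg, ROM 41.01 deg
stifle: flexion 76.85 deg, extension 146.15 deg, ROM 69.30 deg
tarsus: flexion 61.87 deg, extension 163.47 deg, ROM 101.60 deg
hind_fetlock: flexion 106.28 deg, extension 205.06 deg, ROM 98.78 deg
```

Flexion is the series minimum, extension the maximum, ROM their
difference; the generator planted sinusoidal joint trajectories with the
swim-typical means and ranges (e.g. carpus 69–168°, ROM 99°; hind fetlock
hyperextending to 203°), and the recovered extrema sit within the noise of
the prescription. `demo/results/` also contains the unified 3D
trajectories (CSV, pool frame), the per-frame angle series, the detected
camera offsets (`sync.json`) and swim-cycle boundaries (`cycles.json`).

The library API mirrors the CLI: see `hydromocap.pipeline.run_pipeline`,
and `hydromocap.synthetic` for the scene generators.

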