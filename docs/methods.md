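# Methods

This note documents the model implemented by `tribs`, the conventions and
numerical choices it makes, what the synthetic-data generator does and does
not emulate, and the known limitations.  Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Simplified limb model

Four rigid segments (clavicle L1, humerus L2, forearm L3, third metacarpal
L4; all lengths in millimetres) carry eight rotational DOFs: 2
(sternoclavicular) + 3 (glenohumeral) + 1 (elbow) + 2 (wrist).  The local
frame follows the ISB convention with its origin at the sternoclavicular
marker P3: +Y up, the X–Y plane parallel to the sagittal plane, the Y–Z
plane parallel to the frontal plane.  In the rest pose (arm hanging, clavicle
horizontal) the clavicle points 20° anterior of the frontal plane, so the
rest acromioclavicular position is P4 = (−sin 20°·L1, 0, cos 20°·L1).  The
20° offset is an anatomical constant, configurable per subject.

The scapula is not modeled: the glenohumeral marker P8 is measured, not
chained to the clavicle, so the limb is deliberately a *discontinuous*
kinematic chain.  Plane-joint sliding, soft-tissue artifact and joint limits
are out of scope.

The right arm is implemented; `side: left` mirrors the input x coordinates.

## World → local transform

World and local frames are related by a Z-Y-X Euler rotation (α, β, γ) plus
the translation to P3.  β and γ are known from how the capture volume was
laid out (the canonical setup is β = 0°, γ = 90°, i.e. the world X–Y plane
on the ground); only the azimuth α is solved, once, from a calibration frame
with the arm near rest, using the known rest-pose local P4.  The scalar
problem is seeded with the closed-form azimuth difference of the horizontal
projections and polished by `scipy.optimize.least_squares`; the solution is
accepted when the *tangential* residual (the component a Z-rotation could
still reduce) is below 1e-6·L1.  The *irreducible* residual measures how far
the calibration posture is from the modeled rest clavicle; it is allowed up
to 15 % of L1 (≈ 8° of clavicle posture), beyond which the frame is rejected
as a calibration frame.  Configurations with |β| → 90° trigger a gimbal-lock
warning and no recovery is attempted; the remedy is re-orienting the world
frame, which every capture system supports.

In batch runs the calibration frame defaults to the first frame covered by a
full smoothing window (index `window // 2`): the filter's shrinking edge
windows smooth the leading frames less, and an unfiltered calibration frame
would pass the full marker noise into α (empirically up to ~1.7° at 2 mm
noise, versus ≲ 0.1° for a fully filtered frame).  A per-frame re-solve mode
exists behind `resolve_alpha_per_frame` for drifting setups.

## Virtual reference points

* **P1, P2 (clavicle)** are fixed in the local frame: P1 = (0, L1, 0) and
  P2 = (cos 20°·L1, 0, sin 20°·L1).  These are the unique (up to sign)
  choices that are isosceles with the clavicle and make θ1 = θ2 = 0 in the
  rest pose; the signs make θ1 positive for elevation and θ2 positive for
  forward protraction.
* **P5, P6, P7 (humerus)** sit at humerus length from P8 along +Y, +Z, +X,
  making the legs P8→P5/P6/P7 normals of the X–Z, X–Y and Y–Z planes.  The
  positive directions are fixed globally by requiring that the
  cross-product-normal angle formulas, the ψ-projection formulas and the
  signed-determinant inverse all agree; the test suite enforces this
  three-way identity on random poses.
* **P11, P12 (wrist)** each solve three constraints: perpendicular to the
  forearm through P10, one pinned coordinate (y for P11, x for P12), and
  distance l₁₀,₁₃ from P10.  The quadratic has two mirror solutions; the
  branch with positive z offset is selected (positive remaining coordinate
  at exactly zero z).  A vertical forearm (|y9 − y10| ≥ (1 − 1e-6)·l₉,₁₀)
  makes the system underdetermined and the conventional singular-pose values
  P11 = P10 + (0, 0, l), P12 = P10 + (l, 0, 0) are returned; a forearm along
  ±X likewise underdetermines P12 and the continuous-limit convention +Z is
  used.  The selected branch is continuous into the vertical singular values
  for P11 along in-plane tilt paths; for P12 the singular value is a frame
  convention (it abandons the x-pin, which is degenerate there), so no
  branch can approach it continuously — a documented discontinuity of the
  construction, harmless to the wrist angles because any perpendicular
  reference yields the same chord lengths near rest.

## Angle extraction

**Euclidean route.** θ1 = 90° − arccos(y4/y1); θ2 = 90° − arccos((x2·x4 +
z2·z4)/y1²); θ6 by the law of cosines (0° = straight arm); θ7/θ8 = 90° −
arccos(1 − l²ᵢ,₁₃/(2 l²₁₀,₁₃)) for i = 11, 12, signed: positive toward the
reference point.  The glenohumeral angles are projection-plane angles of
ψ = P8 − P9: θ3 = arccos(−ψ1/√(ψ3²+ψ1²)), θ4 = arccos(ψ2/√(ψ2²+ψ1²)),
θ5 = arccos(ψ3/√(ψ2²+ψ3²)); the equivalent cross-product-normal formulation
is also provided and both are asserted equal to ≤ 1e-8° on random poses.
With this convention θ5 = 90° in the rest pose; it is reported as-is, never
re-zeroed.  θ3 is undefined for a vertical humerus (ψ1 = ψ3 = 0); each angle
carries a validity flag (`ok`, `degenerate_denominator`, `not_requested`)
rather than a silently fabricated number.

arccos arguments are clamped to [−1, 1] when within 1e-9 (floating-point
guard), clamped with a warning up to 1e-3, and rejected as geometry errors
beyond — larger excursions mean inconsistent markers, not rounding.

**TPS route.** Signed projected areas are computed as half-determinants of
the per-plane coordinate matrices (rows ordered: reference vertex, shared
vertex i, shared vertex j — the ordering that makes the closed-form segment
column and the signed humerus determinants come out right).  Numerically the
determinants are evaluated in vertex-difference form, which is algebraically
identical to the ones-column 3×3 determinant but immune to the catastrophic
cancellation of large absolute coordinates; the literal matrices are kept
for the segment-matrix algebra.  TPS coordinates carry the area *signs*:
magnitudes alone would make the humerus inverse unable to recover direction,
so the magnitude-only reading is treated as a statement about metric length,
not a definition of the coordinates.

Isosceles defining triangles give sin(vertex angle) = 2|S|/(leg product).
`angle_from_area` is the literal sine-branch evaluator against the model
lengths (principal branch [0°, 90°] with an ambiguity flag).  The pipeline
`angles_via_tps` instead inverts against the *measured* leg lengths, for
which sin ≤ 1 holds by construction even under marker noise, and then
resolves branches: the clavicle and wrist motion angles are the complement
(90° − vertex) of the spatial vertex angle (their rest triangles have
maximal area), restricted to the sub-90° anatomical branch with an explicit
`branch_ambiguous` flag — the unsigned area cannot distinguish ±θ; the elbow
angle is disambiguated by the sign of the law-of-cosines numerator, which
extends its range to the full 0–180°; the humerus angles come through the
signed determinants and need no branch choice.

Near a branch boundary (complement angle → 0°) the arcsin argument
approaches 1 and the area route loses half the floating-point digits
(≈ 1e-5° error); away from boundaries the two routes agree to ≤ 1e-8°.
This conditioning limit is intrinsic to inverting a sine near its extremum.

**Humeral category.** Two decompositions of the 2-DOF humerus direction are
distinguished: sagittal (X–Y) and frontal (Y–Z).  The initial-stage
comparison θ4 < θ5 selects the sagittal category, otherwise the frontal
one.  In batch runs "initial stage" is made concrete
as the mean of the first 10 frames after departure from rest, where
departure is any defined angle exceeding 2° from its rest reference
(θ5 references 90°).

## Body-segment matrices and motion description

Per segment, the k triangle coordinate matrices are summed per projection
plane and squared: E_h = (ΣST_m)² + (ΣST_n)² + (ΣST_u)².  Its third column
has the closed form (2k·Σ_heads ΣP + 3k², 2k²·ΣP_i + 3k², 2k²·ΣP_j + 3k²)
with ΣP = x + y + z, verified against the brute-force matrix square to
1e-6 relative on random poses.  E^O (4×4) stacks the four third columns over
the length row (L1..L4).  Note E_h is origin-dependent (the ones-column
matrices contain absolute coordinates): E^O describes pose *in the local
frame*, which is exactly what a posture descriptor should do; triangle
areas, by contrast, are rigid-motion invariant and are asserted so.

In TPS each segment is a plane matrix through its triangle points: three
points for the humerus; two points plus the origin for the clavicle and
metacarpal; one point, its perpendicular foot on the M axis, and the origin
for the forearm; an unused segment contributes the zero matrix.  The plane
matrix's symbolic first row is a query point (M, N, U); for the numeric
descriptor it is evaluated at the TPS origin — the origin is the one
distinguished point of TPS (all degenerate triangles map there) and the
convention is applied uniformly, so descriptor comparisons remain
meaningful.  E^T (6×6) is the 2×2 block arrangement of the four plane
matrices.

Per-frame features: ‖E^O‖₂ and ‖E^T‖₂ are spectral norms ("2-norm" is read
as the operator norm; Frobenius is not used); the eigenvalue mean of E^O is
computed as trace/4 — exactly the mean of the four eigenvalues (conjugate
pairs keep it real) without a decomposition; an explicit eigendecomposition
is retained behind a diagnostics flag.  The three features differ by orders
of magnitude, so they are z-standardized before the 2-component PCA
(scikit-learn, full SVD); PC signs are fixed by making the ‖E^O‖₂ loading
non-negative so embeddings are reproducible.  Per-class 95 % confidence
ellipses come from the chi-square(2) quantile on the class score covariance;
ellipse overlap is decided numerically (boundary sampling at 720 points plus
center containment).  Class separation is scored by leave-one-out
nearest-centroid accuracy, deliberately the simplest classifier: the claim
under test is that the features separate motions, not that a strong
classifier could.

## Synthetic data generator

The generator emulates the study conditions of a marker-based recording:
six markers at 60 Hz, millimetre coordinates, a placed world frame
(β = 0°, γ = 90°, α and P3 position arbitrary), and optional i.i.d.
isotropic Gaussian marker noise (2 mm in the noisy-pipeline tests).  Angle
trajectories are waveforms (constant, ramp, sinusoid, or cosine-eased
keyframes; easing keeps commands slope-continuous, which the moving-average
filter tracks with little bias).  All randomness flows from one recorded
seed; outputs are byte-for-byte reproducible.

Construction: clavicle direction from (θ1, θ2) (feasible iff sin²θ1 +
sin²θ2 ≤ 1); P8 = P4 + a fixed shoulder offset (default (0, −50, 0) mm)
rotated with the clavicle — a generator-only rule, since extraction treats
P8 as measured; humerus direction from the category's angle pair, solved in
closed form to a unit vector; elbow flexion by rotating the forearm about
the horizontal axis perpendicular to the humerus; metacarpal direction from
the commanded wrist angles via the (generally non-orthogonal) Gram system of
the two wrist reference directions.  An uncommanded wrist angle is left
free: the two references are not orthogonal in general, so pinning both
over-constrains the hand, and jointly commanded pairs are validated against
the pose-dependent feasible set.  The (θ3, θ4) humerus pair parametrizes
every preset; the (θ3, θ5) pair is also implemented but is degenerate
exactly in the sagittal plane, so it is only usable off that plane.

Ground truth is defined as *the defining equations evaluated on the
noiseless geometry*.  For single-DOF commands this equals the command
(round-trip error < 1e-6°, measured ≈ 1e-12°); under combined commands the
projection-angle definitions couple and commanded-vs-extracted equality is
intentionally not asserted — matching the sequential-action protocol the
method is designed for.

Presets: `fig_sequence` (two 8 s cycles of humerus lift 36→80°, elbow bend
5→85°, humerus turn 10→35°, wrist snap 0→−45°, with small passive clavicle
motion; amplitudes sit inside the ranges typical of such a protocol);
`wiggle1..wiggle4` (10 s wiggling-motion classes for the description
experiment — front-of-body, side-of-body, and two classes sharing a fixed
humerus–forearm posture with elbow at 90° that differ only in the humerus
turn about the vertical axis, deliberately similar but distinct); `rest`.
The wiggle amplitudes are the package's own fixed choices, documented in
the preset source.

What the generator does **not** emulate: skin-motion artifact (noise is
white, real soft-tissue error is autocorrelated and pose-dependent), marker
occlusion/dropout patterns, camera calibration error, and subject-to-subject
anthropometric variation.  Passing the noisy-pipeline bound therefore shows
robustness to measurement noise of realistic magnitude, not performance on
real recordings.

## Filtering, calibration, I/O

Raw marker series are smoothed per coordinate by a centered moving average,
default window 25 samples (≈ 0.42 s at 60 Hz); centered (zero-lag) because
analysis is offline.  Edges use shrinking symmetric windows; missing (NaN)
samples are excluded from their windows.  Frames with a missing marker are
flagged and skipped, never interpolated — interpolation policy belongs to
the user.  Segment lengths can be calibrated as medians of the four
inter-marker distances over complete frames (≥ 10 required); medians keep
2 mm noise to < 1 mm length error.  The canonical file format is a wide CSV
(`frame,time,M3_x,...,M13_z`, mm, 9 significant digits); TRC is read-only;
binary C3D is deliberately excluded to keep the core text-only and
dependency-light.

## Validation summary (computed, not asserted from memory)

At the acceptance problem sizes: the projected-area identity holds to
~2e-16 relative (10,000 triangles); the closed-form segment column to
~5e-13 (1,000 poses × 4 segments); dual-route angle agreement to ~1e-12°
(1,000 poses); single-DOF round trips to ~1e-12° (665 sweep points); azimuth
recovery to ~3e-14° (35 grid points); the singular-pose rule is exact; the
noisy pipeline (2 mm noise, window 25) keeps every angle's RMSE under 1.1°
across seeds against a 2.5° engineering bound; the four wiggle classes
separate at 100 % leave-one-out accuracy with the similar pair's confidence
ellipses disjoint.

## Known limitations

* θ3/θ4/θ5 are projection angles with unavoidable degeneracies (vertical
  humerus, humerus along an axis); consumers must respect validity flags.
* The TPS route cannot sign θ1/θ2/θ7/θ8 (areas are unsigned); it restricts
  to the sub-90° branch and flags the ambiguity.  The Euclidean route has no
  such restriction and is the default.
* Wrist references P11/P12 coincide when the forearm lies in the X–Y plane;
  there θ7 ≡ θ8 and they cannot be commanded independently.
* E^O/E^T are origin- and frame-dependent by design; descriptor comparisons
  are only meaningful within a consistent local-frame convention.
* A maximum of 8 DOFs; no forearm pronation/supination, no hand DOFs beyond
  the third metacarpal, no kinetics.
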