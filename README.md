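# tribs — triangular body-segment kinematics for the human upper limb

`tribs` reconstructs the rotational joint angles of a simplified human upper
limb from six 3D motion-capture markers, and summarizes whole-limb motion as
small "body-segment matrices" whose norms and eigenvalues serve as features
for describing and classifying movements.  It is aimed at movement-analysis
and rehabilitation researchers who have sparse marker (or depth-camera
skeleton) data and want joint angles plus a compact per-frame motion
descriptor without a full musculoskeletal model.

## The model

The limb is four rigid segments — clavicle (length L1), humerus (L2),
forearm (L3) and third metacarpal (L4) — with eight rotational degrees of
freedom: sternoclavicular elevation θ1 and protraction θ2, glenohumeral
projection angles θ3/θ4/θ5 (about the Y, Z and X axes of a trunk-fixed
frame), elbow flexion θ6, and wrist flexion angles θ7/θ8.  The scapula is
treated as a passive link and not modeled.

Six anatomical markers are measured (point numbering 1–13 kept throughout):
sternoclavicular joint P3 (local-frame origin), acromioclavicular joint P4,
glenohumeral joint P8, elbow P9, wrist P10 and third-metacarpal end P13.
Seven reference points are constructed from them: fixed clavicle references
P1, P2; humerus references P5, P6, P7 at humerus length from P8 along the
+Y, +Z, +X axes; and wrist references P11, P12, each perpendicular to the
forearm at metacarpal distance from the wrist with one coordinate pinned.

Every DOF is characterized by one spatial triangle (e.g. Δ8,9,10 for the
elbow).  Angles can be solved two ways:

* **Euclidean route** — arc-cosines of coordinate ratios, chord lengths and
  the law of cosines, e.g. θ6 = 180° − arccos((l²₈,₉ + l²₉,₁₀ − l²₈,₁₀) /
  (2 l₈,₉ l₉,₁₀)).
* **Triangular-primitive-space (TPS) route** — each triangle maps to the 3D
  point (S_m, S_n, S_u) of its signed projected areas on the X–Y, X–Z, Y–Z
  planes; the point's norm is the triangle area, isosceles triangles give
  sin(vertex angle) = 2|S|/(leg product), and the humerus direction is
  recovered exactly (with sign) from three projected-area determinants:
  ψ₁ = −2M₃/L2, ψ₂ = −2U₄/L2, ψ₃ = 2N₅/L2.

Both routes agree to solver precision wherever both are defined; the package
verifies this per run.  Whole-limb pose is condensed into a 4×4 matrix E^O
(per-segment coordinate sums over the segment lengths) and a 6×6 matrix E^T
(TPS plane matrices of the four segments); the per-frame feature triple
(‖E^O‖₂, mean eigenvalue of E^O, ‖E^T‖₂) feeds a 2-component PCA for motion
description and clustering.

A forward-kinematics simulator (`tribs.synthetic`) generates the same six
marker trajectories at 60 Hz from commanded angle waveforms, with optional
Gaussian marker noise and exact ground truth, so the entire pipeline is
testable without capture hardware.

## Worked example

Simulate a noisy sequential-motion recording (humerus lift → elbow bend →
humerus turn → wrist snap, two cycles, 2 mm marker noise), then run the full
pipeline: moving-average filter (25 samples), world-frame azimuth
calibration, and per-frame angle extraction.

```python
import numpy as np
from tribs import default_model, generate_motion, run_pipeline
from tribs.synthetic import fig_sequence_preset

model = default_model((150.0, 300.0, 260.0, 90.0))   # segment lengths in mm
sim = generate_motion(fig_sequence_preset(noise_sd=2.0, seed=42), model)
result = run_pipeline({
    "markers": sim.markers,
    "beta_deg": 0.0, "gamma_deg": 90.0,              # world-frame placement
    "lengths_mm": {"L1": 150, "L2": 300, "L3": 260, "L4": 90},
    "filter_window": 25,
})
print("alpha_deg:", round(result.report["alpha_deg"], 3))
print("category:", result.report["humeral_category"])
for lab in ("theta3", "theta4", "theta6", "theta7"):
    truth = sim.truth[lab].to_numpy()
    est = result.angles[lab].to_numpy(dtype=float)
    ok = np.isfinite(truth) & np.isfinite(est)
    rmse = float(np.sqrt(np.mean((truth[ok] - est[ok]) ** 2)))
    print(f"{lab}: range [{truth[ok].min():7.2f}, {truth[ok].max():6.2f}] deg,"
          f" RMSE {rmse:.3f} deg")
```

Output:

```
alpha_deg: 29.916
category: sagittal_XY
theta3: range [  10.00,  35.00] deg, RMSE 0.225 deg
theta4: range [  36.00,  80.00] deg, RMSE 0.342 deg
theta6: range [   5.00,  85.00] deg, RMSE 0.502 deg
theta7: range [ -45.00,   0.00] deg, RMSE 0.874 deg
```

The solved world azimuth (29.916°) recovers the simulated 30° placement to
within the noise floor; each extracted angle tracks the noiseless ground
truth to well under one degree RMSE despite 2 mm marker noise.

The same run is available from the shell:

```bash
tribs simulate --preset fig_sequence --noise-sd 2 --seed 42 -o markers.csv --truth truth.csv
tribs extract-angles -i markers.csv --beta 0 --gamma 90 \
    --lengths 150,300,260,90 --method both -o angles.csv
tribs describe -i markers.csv --beta 0 --gamma 90 \
    --lengths 150,300,260,90 --features features.csv --pca pca.csv
```

`extract-angles --method both` adds TPS-route columns and a per-angle
discrepancy column; `describe` writes the per-frame feature triple and its
PCA embedding.  `tribs calibrate` estimates the four segment lengths from a
recording.

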