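# csvmtk

Brain MRI tissue segmentation and functional time-series registration,
built around two classical pipelines and testable end-to-end on
synthetic labeled phantoms:

1. **C-SVM segmentation** — a Chan-Vese active contour first separates
   brain tissue from background, then a Gaussian-kernel soft-margin SVM
   labels every pixel inside the contour as CSF, grey matter, or white
   matter from gray-level co-occurrence (GLCM) texture features.
2. **Rigid time-series registration** — every frame of a brain
   functional series is aligned to frame 0 by sub-block NCC matching,
   AdaBoost-weighted match reliability, and a closed-form weighted
   rigid fit, iterated with a damped refinement loop.

The package is aimed at method developers who need a fully
reproducible, dependency-light reference implementation with
ground-truth evaluation: every experiment runs on generated phantoms
with known tissue labels and known motion, so accuracy and target
registration error are exact, not estimated.

## The models

**Segmentation.** The contour stage minimizes the two-phase
piecewise-constant Mumford–Shah fitting energy

```
E(C, g0, g1) = α·Length(C) + β·Area(inside C)
             + γ1·Σ_inside |u − g0|² + γ2·Σ_outside |u − g1|²
```

with γ1 = 0.3, γ2 = 0.7, evolved as a level set with a smoothed
Heaviside and settled by exact discrete coordinate descent. Inside the
contour, pixels are classified by a one-vs-one SVM with kernel
`k(x, x′) = exp(−‖x − x′‖² / 2σ²)` (σ = 0.5, C = 1000, 1,500
stratified training pixels). Features per pixel: five GLCM statistics —
ASM, contrast, correlation, variance, entropy — over 7×7 windows at
d = 1 and θ ∈ {0°, 45°, 90°, 135°} (20 values), plus the windowed mean
and raw intensity.

**Registration.** The reference frame is tiled into 4×4 sub-blocks;
each block's displacement maximizes normalized cross-correlation over
a ±5 px search, accumulated coarse-to-fine by the recursion
`B(k) = φ·B(k−1) + d(k)`. A boosted ensemble of decision stumps scores
match reliability, and the weighted matches feed a closed-form rigid
(rotation + translation) least-squares fit, refined with a damped
(rate 0.45) fixed-point loop. A seeded mode-seeking clustering of
sampled pixels and a spherical-coordinate displacement report are
produced as per-frame diagnostics.

## Worked example

```python
from csvmtk import (PhantomSpec, RegParams, csvm_segment,
                    make_brain_phantom, make_motion_series,
                    overall_accuracy, register_time_series)

# T1-like phantom: 2% noise, 30% gray-level non-uniformity
phantom = make_brain_phantom(PhantomSpec(seed=7))
seg = csvm_segment(phantom, n_train=1500, seed=7)
m = overall_accuracy(seg.labels, phantom.labels,
                     region_mask=phantom.labels > 0)
print(f"in-brain accuracy {m.overall_accuracy:.3f}")
print({k: round(float(v), 3) for k, v in m.dice.items()})

base = make_brain_phantom(PhantomSpec(noise_fraction=0.0, seed=7))
series = make_motion_series(base, 20, max_shift_px=3, max_rot_deg=2,
                            seed=11)
reg = register_time_series(series, RegParams(seed=11))
print(f"mean TRE {reg.diagnostics['mean_tre_px']:.3f} px")
```

prints

```
in-brain accuracy 0.932
{1: 0.924, 2: 0.923, 3: 0.949}
mean TRE 0.070 px
```

i.e. 93% of brain pixels receive the correct tissue label (per-class
Dice for CSF/GM/WM in the 0.92–0.95 range), and the recovered rigid
motions land within 0.07 px of the ground truth on a probe grid.

The same pipelines are scriptable from the shell:

```
csvmtk phantom gen --size 96x96 --noise 0.02 --bias 0.30 --seed 7 \
    --out phantom.nii --labels labels.png
csvmtk segment --input phantom.nii --train-labels labels.png \
    --n-train 1500 --seed 7 --out seg.png --report report.json \
    --truth-labels labels.png
csvmtk phantom series --frames 20 --max-shift 3 --max-rot 2 --seed 11 \
    --out series.tif --truth truth.json
csvmtk register --series series.tif --seed 11 \
    --transforms transforms.json --truth truth.json --report reg.json
```

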