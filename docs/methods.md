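# Methods

This note records the models implemented in csvmtk, the choices made
where the design was genuinely open, and what the synthetic benchmarks
do and do not demonstrate.

## Synthetic phantom

The phantom emulates simulated T1-weighted brain MRI of the BrainWeb
kind: four piecewise-constant regions (background, CSF, grey matter,
white matter) arranged as nested elliptical shells whose boundaries are
perturbed by two seeded low-order sinusoids, so tissue interfaces are
curved and irregular rather than analytic circles. Intensities live on
the [0, 1] scale.

* **Tissue means** default to background 0.0, CSF 0.30, GM 0.55,
  WM 0.80 — the T1 ordering (CSF darkest tissue, WM brightest), with
  contrast ratios in the range of skull-stripped T1 slices. They are
  strictly ordered so classes are separable in the noiseless limit, and
  fully configurable.
* **Bias field** ("gray-level non-uniformity"): a sum of three seeded
  low-frequency cosine plane waves, centred to mean exactly 1 and
  rescaled so its extremes touch `1 ± fraction/2`. The default fraction
  is 0.30 (a 30% peak-to-peak non-uniformity), applied
  multiplicatively.
* **Noise**: additive zero-mean Gaussian with SD equal to
  `noise_fraction × max(tissue mean)`; default fraction 0.02. Rician
  noise, partial-volume mixing, and MR relaxation physics are out of
  scope — the phantom tests segmentation logic, not MR simulation.
* **Motion series**: frame k ≥ 1 is the base phantom resampled
  (bilinear, background-mean padding) under a seeded uniform rigid
  motion with |tx|, |ty| ≤ 3 px and |angle| ≤ 2° by default, optional
  noise added after warping. The true transforms are stored so
  registration error is measured exactly.

Everything is driven by explicit integer seeds; identical spec + seed
is bit-identical.

What passing on phantoms shows: the pipelines recover known structure
under controlled noise, bias, and motion at realistic contrasts. What
it does not show: robustness to skull/scalp clutter, pathology,
partial-volume boundaries, or non-rigid motion — real-image use should
treat the reported accuracies as upper bounds.

## Chan-Vese contour stage

Energy: `α·Length + β·Area + γ1·Σ_in(u−g0)² + γ2·Σ_out(u−g1)²` with
defaults α = 0.2, β = 0, γ1 = 0.3, γ2 = 0.7. Reported energies use a
4-neighbour boundary transition count as the discrete length (an
isolated pixel has length 4) and the inside pixel count as area.

Numerics:

* Level-set evolution with the arctan-smoothed Heaviside
  `H_ε(φ) = ½(1 + (2/π)·arctan(φ/ε))`, ε = 1. The smoothed delta is
  normalized to unit peak, so `time_step` (default 3.0) is approximately
  the contour speed in px/iteration for a unit-strength force. Region
  means are computed on the sharp mask (φ > 0); the curvature term is
  clipped to ±1 px⁻¹ (central differences; grid curvature beyond that
  is discretization noise). No reinitialization by default; periodic
  reinitialization is available behind `reinit_every`.
* Stopping: relative change of the reported energy below 1e−5 over a
  5-iteration window, cap 500 iterations.
* **Discrete polish.** After the level-set phase, checkerboard
  coordinate-descent sweeps flip pixels only when the flip strictly
  lowers the exact discrete energy at the current region means
  (simultaneously flipped pixels are never 4-adjacent, so their length
  contributions are independent). This guarantees a non-increasing
  energy trace and a final mask that is a local minimum of the discrete
  functional; a pure smoothed-Heaviside flow stalls between pixel
  flips and leaves the contour measurably short of the optimum.
* **Initialization** defaults to a centred circle of radius
  `min(H, W)/2 − 2`, i.e. a contour that *covers* the object and
  shrinks. With the asymmetric fit weights (γ1 < γ2) the CSF rim is
  energetically marginal when approached from inside — a growing
  contour stalls at the GM boundary and never collects CSF, while a
  shrinking contour retains it (the two-phase energy is hysteretic).
  A checkerboard initialization is available for objects away from the
  centre.

## Texture features

GLCMs are accumulated per orientation with the Haralick offsets at
distance d: 0° → (0, +d), 45° → (−d, +d), 90° → (−d, 0),
135° → (−d, −d), single-direction by default (a `symmetric` flag adds
reverse pairs). Images are globally quantized to Ng = 16 uniform bins
before windowing: full 256-level matrices from 7×7 windows would be
almost entirely empty, and 16 levels is standard practice. Border
windows use reflection padding.

The five statistics are ASM `Σp²`, contrast `Σp(i−j)²`, correlation
`(Σ ij·p − μxμy)/(σxσy)` (defined as 0 on flat windows where
σxσy = 0), **variance `Σ(ij − μxμy)p`**, and entropy `−Σp log p` with
`0·log 0 := 0`, base-2 by default. Note the variance statistic is the
covariance-like form written here — *not* the conventional GLCM
variance `Σ(i−μ)²p`; it equals the correlation numerator and can be
negative. It is implemented exactly as defined; downstream consumers
should not interpret it as a spread measure.

The sliding-window map is computed with per-pair-code integral images
and is verified against an independent brute-force double-loop oracle
to 1e−10 over seeded random windows.

## C-SVM tissue classification

* Feature vector per pixel: the 20 texture values (5 statistics × 4
  orientations), the 7×7 mean intensity, and the raw pixel intensity —
  22 dimensions. The raw intensity was added because all windowed
  features blur across the ~1 px band at tissue interfaces, which is
  exactly where the remaining errors concentrate; the centre pixel
  disambiguates that band (noiseless accuracy 0.98 → 0.995).
* Training pixels are sampled inside the Chan-Vese mask, stratified
  proportionally over CSF/GM/WM (largest-remainder allocation, at
  least two per class), n = 1500 by default. Features are z-scored
  with the training sample's own statistics, stored and reused at
  prediction: with the kernel width fixed at σ = 0.5, unscaled
  features would collapse the kernel.
* The SVM is a soft-margin Gaussian-kernel machine (σ = 0.5, C = 1000)
  trained one-vs-one; scikit-learn's libsvm backend solves the dual
  (SMO, tolerance 1e−3, iteration cap 1e5, non-convergence raised as
  an error). Prediction is an explicit one-vs-one majority vote with
  ties broken by the summed signed margins.
* The contour gates the classifier: pixels outside the Chan-Vese mask
  are labeled background and recorded as contour-stage provenance, so
  the SVM only ever sees in-brain pixels. (Feeding the mask as an
  extra feature was the rejected alternative — gating keeps the
  background class exact by construction.)
* At phantom scale the training labels come from the generator's
  ground truth; for real images the CLI accepts a user-supplied
  (possibly partial) label map.

## Time-series registration

Transform model: 2D rigid (rotation about the grid centre +
translation) per frame, reference = frame 0; coordinates are (row,
col), 0-based, with positive angles counter-clockwise in display
convention (x = col, y = −row).

Per frame, a damped fixed-point loop runs up to
`n_iters / iter_step = 10` rounds: warp the frame by the current
estimate, block-match against the reference, weight the matches,
rigid-fit the residual, and apply it scaled by the descent rate 0.45.
The loop stops when the residual falls below 0.02 px / 0.01°. Damping
makes each round's bias irrelevant at the fixed point: any estimator
that preserves the sign of the residual converges to the true motion.

* **Block matching.** The reference is tiled into 4×4 sub-blocks; each
  block's NCC is computed through the 12×12 context patch centred on
  it, over integer displacements within ±5 px (edge padding near the
  border), with a parabolic sub-pixel refinement of the peak (skipped
  at exact NCC = 1, where the integer peak is already exact) and an
  infinitesimal tie-break toward small displacements. The per-block
  similarity accumulates the coarse (half-resolution) and fine NCC
  peaks through `B(k) = φ·B(k−1) + d(k)`, φ = 0.5 by default.
* **Match selection.** Zero-variance blocks are excluded outright.
  A block enters the fit only if its NCC clears the acceptance floor
  0.62 *and* its context structure tensor's smallest eigenvalue is in
  the top 20% of non-flat blocks. The structure gate matters: on
  brain-like images most sub-blocks are either smooth bias gradients
  (which match anywhere) or straight tissue edges (ambiguous along the
  edge — the aperture problem); without the gate the rotation
  component of the fit collapses toward zero.
* **Boosted weighting.** An AdaBoost ensemble of 10 decision stumps
  (rounds = n_iters/iter_step) scores each selected match from its
  NCC, block gradient energy, and distance to the median displacement;
  pseudo-labels mark matches within 1 px (Chebyshev) of the median as
  inliers. Weights are the ensemble's inlier probability in [0, 1];
  degenerate cases (single pseudo-class, identical descriptors) fall
  back to uniform weights.
* **Rigid fit.** Weighted Kabsch: SVD of the weighted cross-covariance
  with a reflection guard; invariant to weight rescaling; degenerate
  (zero-spread) correspondence sets are rejected. Verified against an
  independent atan2 closed form.
* **Diagnostics** (never on the transform path): per frame, 100 seeded
  gradient-weighted pixels are sampled and clustered by seeded
  mode-seeking (below), and the recovered displacement is reported in
  spherical coordinates (radius T, inclination γ, azimuth φ) together
  with a gate flag that records whether `edge_quant_coeff − mean NCC`
  is ≤ 0. The spherical report is a faithful coordinate conversion
  kept diagnostic-only because its quantities have no geometric role
  in a 2D rigid model. When ground truth is available, per-frame
  target registration error is computed over a fixed 5×5 probe grid
  spanning the central half of the image.

### Mode-seeking clustering

A point is drawn at random from the unmarked set, shifted repeatedly
toward the mean of its neighbours within `neighborhood_radius`
(default 5 px) — each shift clipped to magnitude `m_threshold`
(default 5 px) — until the shift magnitude drops below τ (default
0.05 px). Points within the radius of the converged centre are marked
into the cluster; centres closer than `m_threshold` are merged by
count-weighted averaging (repeated until all centres are separated).
The random selection stream walks the points in lexicographic
coordinate order, so the result is stable under permutations of the
input.

## Parameters

| Parameter | Default | Role |
| --- | --- | --- |
| γ1, γ2 | 0.3, 0.7 | inside/outside misfit weights |
| α, β | 0.2, 0 | contour length / area weights |
| window, d, θ | 7, 1, {0°,45°,90°,135°} | GLCM geometry |
| Ng | 16 | gray-level quantization |
| σ, C | 0.5, 1000 | kernel width, margin penalty |
| n_train | 1500 | stratified training pixels |
| block, search | 4, ±5 px | sub-block edge, NCC search extent |
| φ | 0.5 | similarity recursion coefficient |
| n_iters, iter_step | 100, 10 | refinement/boosting budget (10 rounds) |
| descent_rate | 0.45 | damping of each residual update |
| edge_quant_coeff | 0.62 | NCC acceptance floor |
| noise, bias | 0.02, 0.30 | phantom degradation fractions |

`descent_rate` and `edge_quant_coeff` are interpretive placements of
stated constants (damping factor and acceptance floor respectively);
both are config-exposed, and the φ recursion reads `B(ε−1)` as the
previous accumulator value `B(k−1)`.

## Problem sizes

The benchmarks use 96×96 phantoms, 1,500 training pixels, and 20-frame
series — sizes at which every experiment reruns from scratch in
seconds to a couple of minutes while leaving hundreds of pixels per
tissue class and hundreds of blocks per frame, so the measured
accuracies are not small-sample artifacts.

## Known limitations

* Two-phase contour only; multi-phase level sets are delegated to the
  SVM by design.
* The GLCM variance statistic follows the covariance-like definition
  above, not the conventional spread; cross-package comparisons must
  account for this.
* Registration assumes in-plane rigid motion; deformable, 3D, and
  slice-timing effects are out of scope.
* The boosting stage's pseudo-labels assume the majority of selected
  matches move coherently; fields with >50% corrupted matches will
  mislabel inliers.
* PNG I/O quantizes intensities to 8 bits; NIfTI/TIFF round-trip
  float data losslessly.
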