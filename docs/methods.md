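# Methods

This package implements an image-based fresh-weight prediction workflow for
single plants grown on white planting boards under fixed overhead capture
(nominally a camera 80 cm above the root, 0.078 mm/pixel at full
6144×8192 resolution). It has four stages: canopy segmentation, ruler
calibration, pixel-to-area conversion, and regression benchmarking. A
synthetic scene generator with exact ground truth stands in for captured
data.

## Canopy segmentation

**Colour feature.** Vegetation is separated from the board with the excess
green index ExG = 2G − R − B, thresholded by Otsu's method. ExG is
parameter-free and well suited to green-on-white scenes; the threshold is
config-exposed (`fixed_threshold`) for unusual material. Otsu's
between-class criterion can mislocate the split when the canopy occupies a
tiny fraction of the frame (a seedling on a full board): the global optimum
may fall inside the broad background-noise mode. When the resulting class
separation is below `min_class_separation` (default 40 ExG units, matching
the generator's stress-free board/leaf margin), a second Otsu pass
restricted to the upper class recovers the true split (hierarchical Otsu).
If even then the class means are separated by less than 40 units the image
is declared plant-free — an all-board image splits only its own sensor
noise, with means a few units apart.

**Morphology.** Erosion and dilation are implemented directly from their
set definitions: the output pixel is set iff the structuring element,
translated to that pixel, is entirely contained in (erosion) or intersects
(dilation) the foreground. Cells beyond the image border count as
background by default, so the containment test fails wherever the element
hangs over the frame; `border="foreground"` is available and is what makes
the complement duality dilate(A, B) = ¬erode(¬A, B) exact for
finite-support foregrounds. Note the dual erosion uses the *same* element:
both operators here probe the translated element directly, and a reflection
only appears when dilation is rewritten as a Minkowski sum.
`refine_mask` applies a closing with a disk of radius `se_radius`
(default 5 px at working resolution), fills holes exactly (background
regions not 4-connected to the border), and keeps the largest 8-connected
component when it holds at least `min_component_fraction` (default 0.5)
of the foreground.

**Active contour.** The morphological boundary initialises a closed snake
minimising E = Eint + Eext with Eint = α|C′|² + β|C″|² and
Eext = −|∇I_σ|² along the curve (I_σ the Gaussian-smoothed grayscale,
edge map normalised to peak 1 so force amplitudes are intensity-scale
free). The Euler–Lagrange equations are integrated semi-implicitly — the
pentadiagonal circulant internal operator implicitly, the external force
explicitly — and vertices are resampled to uniform arc length every
iteration. Defaults: α = 0.2, β = 0.5, step γ = 1.0, σ = 5 px,
`max_iter` 500, `tol` 0.1 px. These were chosen to satisfy the
disk-convergence requirement (a concentric circle 10 px outside a
radius-30 disk must land on the edge within 1 px): σ = 5 provides the
capture range to pull the contour across the 10 px gap, and γ = 1 keeps
the explicit external step well inside the stability bound set by the edge
map's curvature (≈1/σ²) while converging in a few hundred iterations.
Convergence is declared when the mean net vertex displacement across a
10-iteration window falls below `tol` — a windowed criterion, because
per-iteration displacements during the slow approach phase are smaller
than the final positioning accuracy. The vertex count is set from the
initial perimeter at a target spacing of 1.2 px (clipped to [16, 1000])
so that resampled spacing stays in the contract range [0.5, 3] px for
both small disks and large canopies. The per-step energy (recorded before
the arc-length resampling, which redistributes vertices and perturbs the
discrete sum) is monotonically non-increasing on the disk fixture; tests
assert it to 1e-6 per step. There is no balloon/pressure term: the energy
has only the internal and gradient-attraction parts.

**Resolution policy.** Images whose long side exceeds
`working_long_side` (default 1024) are processed at reduced scale and the
final polygon mask is resized back by nearest neighbour; the reported
pixel count is always taken at native resolution, so counts are
comparable across images and with calibration ground truth. A snake
failure (collapsed contour, non-finite energy, empty rasterisation) falls
back to the morphological mask with a logged warning.

**Rasterisation convention.** Coordinates are 0-based (row, col); a pixel
occupies the unit square centred on its integer coordinates, and a pixel
belongs to a polygon iff its centre lies inside or on the boundary under
the even-odd rule (boundary inclusion implemented by a ±1e-9 path
expansion, which also makes the test orientation-invariant).
Self-intersecting contours are filled anyway, with a warning.

## Calibration

Repeated pixel-length measurements of a known span (ruler tick runs,
either detected from the image by darkness-weighted tick centroids or
entered as manual line readings) are cleaned with the 1.5×IQR fence —
quartiles by linear interpolation between order statistics, the common
default, stated here for reproducibility; fewer than four samples skip
cleaning with a notice. The ruler factor is k = L_recog / mean(kept runs)
in mm/pixel, and areas convert as S_recog = k²·S_pixel (mm²; reports also
carry cm² = mm²/100). Internally areas are mm² since k is mm/px. Mask
fidelity is quantified by OLS of recovered on true pixel counts (truth on
the x axis as the reference), reporting slope, intercept, R² and
residuals.

## Synthetic scenes

Each scene is one rosette on a noisy near-white board (per-channel
N(235, 5)): a central disk, 5–14 rotated ellipse leaves whose tips reach
the rosette radius (green channel ~N(140, 15), red/blue suppressed), and
thin pale petioles radiating to each leaf. Growth stages set the rosette
radius in mm — seedling 18–33, mid 42–66, mature 70–94 — so physical
sizes are preset-independent. The ground-truth mask is the exact
pixel-centre rasterisation of the analytic shape union, so truth pixel
counts carry no annotation error; a brute-force point-in-shape oracle
reproduces them exactly in tests. Stress flags emulate the documented
colour-segmentation failure modes: `pale_petiole` moves petioles to
within 10 intensity units of the board, `shadow` multiplies a smooth dark
lobe across the rosette edge, `light_margin`/`dark_margin` blend the
outer leaf ring towards white/black. The default working preset
(`desk1024`, 1024×1365 at 0.468 mm/px) is the full-resolution capture preset
(`overhead80cm`, 6144×8192 at 0.078 mm/px) scaled 6× for desk-scale
runtime; physical areas are preserved because mm/px scales inversely.

What the generator does *not* emulate: leaf texture and venation,
specular highlights, occlusion between plants, perspective and lens
distortion, and natural leaf-shape irregularity. Passing tests therefore
demonstrate correctness of the computational chain under controlled
geometry and colour statistics, not field robustness; the stress flags
probe the known colour-feature failure directions only.

## Allometric yield data

Fresh weight follows a power law with multiplicative log-normal noise:
weight = c·area^b·ε, E[ε] = 1, CV(ε) = `noise_cv`. Defaults c = 0.9 g/cm^2b,
b = 1.15, noise_cv = 0.12, n = 60 plants with areas uniform on
60–200 cm², giving weights spanning roughly 100–400 g — the scale of a
leafy brassica harvested over a 30-day cycle and consistent with
validation errors reported in tens of grams. No measured dataset ships
with the package, so these defaults are explicit, documented stand-ins.

## Model benchmarking

The registry pins 28 configurations across eight families (4 linear, 3
tree, 6 SVM, 2 efficient linear, 2 ensemble, 4 Gaussian-process, 5 neural
network, 2 kernel), mirroring a commercial regression-learner toolbox.
Pinned choices: trees with min-leaf 4/12/36; SVMs with linear, quadratic,
cubic (inhomogeneous polynomial, coef0 = 1) and Gaussian kernels at
kernel scales √P/4, √P, 4√P (P = 1 feature); efficient linear =
stochastic-gradient least squares and ε-insensitive regression; boosted
trees = 30 least-squares-boosted learners at rate 0.1; bagged trees = 30
bootstrap trees; GPR with squared-exponential, Matérn 5/2, exponential
and rational-quadratic kernels plus an optimised white-noise term, on
standardised inputs (the unit initial length scale must sit in the
optimiser's basin); fully connected ReLU networks with hidden layers
10/25/100/10-10/10-10-10 trained by L-BFGS (cap 1000 iterations) on
standardised inputs and targets; kernel models via 256 random Fourier
features feeding a linear SVM or ridge least squares. With a single
predictor the "interactions" linear variant has no interaction terms and
degenerates to the plain linear model — kept as a registry row for
structural completeness.

Validation is a single deterministic holdout split (default 25%), seeded;
cross-validation is intentionally not the default. Metrics: MAE, MAPE
(in percent), MSE, RMSE, R², prediction speed (obs/s), training time (s)
and serialized model size (bytes; pickled estimator). The three
time/size quantities are hardware-dependent: they are measured and
reported but never asserted in tests. Metric columns are min–max
normalised to [0, 1] with error metrics, training time and size inverted
so 1 is always best; constant columns map to 0. Selection takes the four
highest-R² models (ties by lower RMSE), re-normalises among those four
(this matrix is the radar-chart data), scores each by the mean of its
eight normalised metrics, and picks the highest composite (ties by
higher R²).

## Problem sizes

The fidelity benchmark runs 60 scenes (20 per growth stage) at the
desk-scale preset with working resolution 1024; the calibration study
uses 30 jittered runs plus 3 gross outliers; model comparisons use the
60-record allometric table with a 45/15 split. These sizes mirror the
study design the package emulates while keeping a full run within a few
minutes on one CPU.

## Known limitations

* Boundary fidelity degrades for seedlings at the default working
  resolution: the fixed 5 px closing radius and σ = 5 px snake smoothing
  are large relative to a 30–50 px rosette, so inter-leaf notches get
  bridged (Jaccard ≈ 0.75–0.87 versus ≥ 0.9 for mid/mature scenes).
  Pixel counts remain within a few percent, so the count regression is
  unaffected; scale-adaptive structuring elements would be the next step.
* Pale petioles sit below the ExG threshold by design; the recovered mask
  excludes parts of them while the ground truth includes them, giving a
  small systematic undercount absorbed by the regression slope.
* MAPE is dominated by the smallest plants when the benchmark spans
  seedlings (weights of a few grams); percentage metrics should be read
  jointly with MAE/RMSE on such spans.
* The duality and extensivity properties of the morphological operators
  hold away from the image border only (the containment test cannot
  succeed where the element leaves the frame); scenes keep the rosette
  clear of the frame, so this never affects the pipeline.
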