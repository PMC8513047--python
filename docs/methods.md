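# Methods

`ricemorph` classifies rice grains among 15 commercial types from color
images via nine dimensionless morpho-colorimetric descriptors and a
Bayesian-regularized feedforward network. This note documents the models,
the numerical choices, and what the synthetic test bed does and does not
establish about real images.

## Synthetic grain scenes

The real image set behind the reference statistics is proprietary, so all
image-level testing runs on rendered scenes with analytic ground truth.

**Grain model.** A grain is an ellipse with semi-axes (a, b) whose radius
is modulated by a low-order sinusoid: r(ψ) = r_ellipse(ψ)·(1 + w·sin(4ψ + φ)).
This is the simplest family that spans the bold-to-slender range of
commercial rice (aspect-ratio means 1.58–5.19) while giving the
box-counting fractal dimension non-trivial boundary structure to measure.
A pixel is foreground when its center lies inside the analytic boundary,
so the renderer and the segmentation agree on the coordinate convention
(row-major, 0-based).

**Per-class geometry.** The bundled class parameters give each of the 15
types its published aspect-ratio mean and spread. No pixel sizes are
published, so semi-major axes are derived from a common reference grain
area of 600 px² via a = sqrt(area·AR/π): slender classes render long and
narrow, bold classes short and wide, all at comparable area, with a 6%
relative spread. At this scale the narrowest class (wild rice) keeps a
minor axis of ~12 px, enough for stable moments and box counting.
Boundary waviness defaults to w = 0.04 ± 0.01 — visible roughness that
stays small against the class separation in shape space.

**Color.** Each grain samples its CIELab color from the class mean/SD and
is filled with the sRGB conversion of that color plus per-pixel Gaussian
noise of σ = 2 digital counts per channel (small against the smallest
class color separations, which are ≥ 1.5 Lab units in L). The published
per-class "±" dispersions are treated as per-grain standard deviations:
read literally as standard errors they would imply physically implausible
per-grain spreads (e.g. ~25 L units for a polished white rice).

**Background.** Uniform gray 10 (dark) or 245 (light); a class is assigned
the background opposite to its own lightness (L < 40 → light background),
mirroring how contrast is arranged at capture time. A scene's background
follows the majority polarity of the classes it contains.

**Placement.** Non-touching placement is rejection sampling of bounding
circles with a 3 px dilation margin; failure to place all grains raises an
error naming the achieved count. The touching mode places pairs at the
support-function tangency distance minus 1 px — rigid-body contact with
just enough overlap to guarantee a pixel bridge — along directions within
15° of the first grain's major axis (tip-to-flank). Flank-to-flank
parallel contacts are deliberately excluded: at tangency two flat
boundaries produce a contact seam as deep in the distance transform as the
grain interiors, which no distance-transform watershed can split; the
touching mode exists to exercise the watershed in its well-posed regime,
and the excluded configuration is a known limitation of the method itself.

**What the scenes do not model.** Real smartphone images have illumination
gradients, shadows, chalkiness and translucency, intra-grain color
texture, and camera optics. Passing the recovery suites therefore shows
the measurement chain is correct at pixel scale, not that accuracy on real
imagery will match; in particular, several rendered classes are nearly
identical by construction (the three long white types share AR ≈ 3.2–3.6
and L ≈ 59), so end-to-end synthetic accuracy understates what real
distinguishing detail could support.

## Segmentation

**Binarization.** Otsu's threshold on luminance, with the foreground taken
as the side covering the smaller pixel fraction (polarity `auto`), or as
directed by an explicit background polarity. Scenes mixing bright and dark
grain classes give a trimodal histogram in which plain Otsu merges dark
grains into a dark background; a three-level multi-Otsu mask (threshold
adjacent to the background level) is therefore computed as well and is
adopted only when it makes the background markedly more uniform — its
99.9th-percentile deviation from the background median dropping by more
than half — which is the signature of a grain mode misassigned to
background. On genuinely bimodal images the extra threshold merely splits
one mode and is ignored. A single-intensity image raises a
degenerate-threshold error; the full pipeline converts this to an empty
labeling when the polarity is stated explicitly.

**Clean-up.** Morphological opening (disk radius 1), hole filling, removal
of components below `min_area` = 50 px (rejects noise specks while keeping
the smallest rendered grains at ~600 px), optional border clearing.

**Watershed.** Markers are maxima of the Gaussian-smoothed (σ = 1)
Euclidean distance transform surviving *relative* h-maxima suppression: a
maximum seeds a marker only if its saddle toward a higher maximum lies
below (1 − h)× its own height, with h = 0.3 by default. Relative (rather
than absolute) suppression makes the rule scale-free per grain: ridge
undulation of a slender grain (≲ 10% of its own depth) is flattened, while
the neck between touching grains (typically < 50% of either depth)
survives — even when a shallow grain touches a much deeper one, the case
an absolute threshold tied to the global maximum gets wrong.
Implementation notes: relative suppression is absolute h-maxima on the log
of the distance; the image is quantized to an integer lattice because
reconstruction on floats fragments plateaus at round-off level; markers
are the regional maxima of the h-reconstruction (the raw h-maxima mask
marks only summit-level pixels and splits equal-height summits of a single
domain); and relabeling after watershed uses 4-connectivity so regions
cannot rejoin diagonally across the 1-px watershed line.

## Descriptors

* **Perimeter** is the length of the marching-squares contour polygon after
  a 5-vertex circular moving average: the raw polygon zig-zags at pixel
  scale and runs ~5% long, which would depress circularity of a perfect
  digital disk to ~0.91; after smoothing a disk measures ~0.99.
* **Circularity** 4πA/P², **aspect ratio** from the moment-equivalent
  ellipse axes, **extent** A over the axis-aligned bounding box.
* **APIdx** [(A/P) − (A/P)min]/(A/P)max is normalized within one image's
  batch of grains (the pipeline processes one image at a time), so its
  minimum is exactly 0 and its maximum strictly below 1 in every image.
* **Fractal dimension** is box counting on the *filled* silhouette: crop to
  the bounding box, pad to a 2^m square (≥ 64), count occupied boxes for
  sides 1, 2, …, 2^(m−1), and fit log N against log(1/s). On filled
  shapes at finite resolution this interpolates between the curve limit
  (1.0 for a 1-px line) and the plane-filling limit (2.0 for a solid
  square), scoring bold compact grains above slender ones — the ordering
  seen in the reference statistics. Grains under 8 px across are rejected.
* **Color** is the per-pixel sRGB → CIELab (D65, 2°) conversion averaged
  over the grain mask; **yellowness** YI = 142.86·b/L, the CIELab
  yellowness form of the colorimetric literature (the class-mean L and b
  of the reference statistics reproduce the published per-class YI within
  5%; the residual is mean-of-ratios vs ratio-of-means).

## Classifier

Architecture: 9 standardized inputs → tanh hidden layer (default 10
neurons) → logistic output per class, one-hot targets, sum-of-squares
error. "Sigmoid" is disambiguated as tanh hidden / logistic output, the
standard pattern-net pairing consistent with an MSE performance metric.

Training is Levenberg–Marquardt on F = β·E_D + α·E_W (E_D the sum of
squared output errors over all rows and classes, E_W the sum of squared
weights). After each accepted step the evidence framework re-estimates

    γ = N_w − 2α·tr(H⁻¹),  H = 2β·JᵀJ + 2α·I,
    α = γ / (2·E_W),       β = (N_t − γ) / (2·E_D),

with N_w the weight count, N_t the target-value count and J the Jacobian
of the stacked outputs. γ is clipped to [0, N_w]. No validation subset is
held out: the evidence term replaces early stopping. Stopping: gradient
∞-norm below 1e−7, LM μ above 1e10, or 300 epochs; μ starts at 0.005 with
factor 10. Initialization is Nguyen–Widrow-style scaled uniform from the
seed, making the whole trainer deterministic per seed. The objective
history records (F_before, F_after) per accepted step under that step's
(α, β), so monotone descent is checkable even though the hyperparameters
move between steps. A gradient-descent-with-momentum trainer on the same
architecture is provided as a baseline.

The 70/30 split is unstratified random (training size = floor(0.7·N)),
with a stratified option. Neuron trimming sweeps hidden sizes (default
10, 7, 5, 3) and flags configurations violating the no-overfit rule —
training MSE must not exceed testing MSE, and the train/test accuracy gap
must stay within 10 points — recommending the flag-free configuration
with the highest count-weighted overall accuracy. Retraining on a second
imaging condition trains from scratch on the union of both feature tables
and re-splits 70/30 (the union reading reproduces the published combined
sample size exactly); warm-starting from the existing weights is available
but off by default, and cannot introduce new classes.

Evaluation reports percent accuracy (argmax, ties to the lowest class id),
MSE of scores against one-hot targets, a confusion matrix, and one-vs-rest
ROC staircases anchored at (0,0) and (1,1). Prediction enforces the
nine-feature schema strictly: unknown extra columns raise rather than
being silently ignored.

## Statistics

One-way ANOVA per descriptor with Tukey–Kramer HSD: for groups i, j,
q = |m_i − m_j| / sqrt(MSE/2·(1/n_i + 1/n_j)) referred to the studentized
range with k groups and N − k degrees of freedom — the unequal-n form
matching the unbalanced class sizes. The compact letter display uses the
insert-and-absorb algorithm, guaranteeing two classes share a letter iff
their adjusted p ≥ α. PCA standardizes variables by default
(correlation-matrix PCA): on raw covariance the lightness scale would
dominate every component, incompatible with factor loadings of comparable
magnitude across descriptors; raw-covariance mode is a flag. Component
signs follow the convention that each component's largest-magnitude
loading is positive. Cluster analysis is Ward linkage on Euclidean
distances between standardized class means; linkage is configurable.

## Problem sizes

Default suites use scenes of 4–15 grains at 420–1100 px, 10 seeded scenes
per class for feature recovery, 100 seeded scenes for exact-count
recovery, and 15 × 40–100 sampled rows for classifier benchmarks. The
acceptance script's end-to-end run renders 2 training scenes and 1
deployment scene of 12 grains per class at 620 px. These sizes give
class-mean estimates with standard errors well inside the stated
tolerances while keeping a full run in minutes on one CPU.

## Known limitations

* Flank-to-flank parallel grain contacts are unsplittable by any
  distance-transform watershed and are excluded from the touching
  generator (above); real piles of aligned grains will under-count.
* The renderer's class geometry is parameterized by aspect ratio and area
  alone, so classes sharing AR and color are synthetically
  indistinguishable even where real grains differ (chalkiness, texture).
* Published per-class APIdx values include one (1.17) above the algebraic
  maximum of the batch formula, so the normalization reference used for
  the published table cannot be the whole-population batch; the formula is
  implemented as printed, and sampled feature tables simply reproduce the
  published moments.
* Box-counting FD at these grain sizes uses 6–7 octaves of box sizes; its
  absolute value is resolution-dependent and only orderings and recovered
  distributions are meaningful.
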