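# Methods

This note documents the models, parameter choices and numerical conventions
behind `saffronvision`, including the decisions made where the grading
protocol leaves the design open, and what the synthetic test bed does and
does not establish about real photographs.

## Imaging model and segmentation

The pipeline assumes bulk saffron threads photographed on a near-black
background under roughly uniform light, 8-bit RGB. "Intensity" is the
ITU-R BT.601 luma 0.299 R + 0.587 G + 0.114 B, rounded to integer; the same
definition is used as the grayscale for all texture operators, so color and
texture stages cannot disagree about brightness.

Segmentation parameters (`PreprocessParams`):

| parameter | default | meaning |
|---|---|---|
| `smoothing_kernel_size`, `smoothing_sigma` | 5 px, 1.0 px | Gaussian low-pass; the kernel is truncated to exactly 5 taps, boundaries by symmetric reflection |
| `intensity_threshold` | 20 | foreground is luma **strictly** greater than 20 |
| `min_component_area` | 3000 px | components with fewer pixels are removed (8-connectivity) |
| `structuring_radius` | 5 px | opening (erosion then dilation) with the discrete disk {x² + y² ≤ r²} |

The area and radius defaults correspond to full-resolution camera frames
(~12 Mpx); they are pixel counts and must be scaled with canvas area. All
desk-scale runs in this repository use 512×512 canvases with
`min_component_area=64` and `structuring_radius=2` (the area ratio of the
two frames is ≈ 47:1).

Choices the protocol leaves open, fixed here: the low-pass filter type
(Gaussian), the meaning of "intensity" (luma, not per-channel maxima),
component connectivity (8), and the reading of "eroded and dilated" as a
single opening with one element. Coordinates are 0-based and crop windows
half-open.

A boundary effect worth knowing: smoothing blends filament values into a
1–2 px halo of adjacent background, which then passes the threshold. The
final mask therefore hugs the material but is not a subset of the true
rendered foreground; the end-to-end test asserts instead that no retained
pixel lies farther than 3 px from true material and that the material
itself survives. Pure-background noise specks never survive the area
filter plus opening.

## Color features and composition

18 channel maps are computed per image: R, G, B; HSV hue H and saturation S
(scaled to [0, 1]); chromaticity r = R/(R+G+B); CIELAB L\*, a\*, b\* (D65);
chroma C = √(a\*² + b\*²); intensity I = (R+G+B)/3; the Euclidean norm
E = √(R²+G²+B²)/√3; BT.601 Y, Cb, Cr; and NTSC Y′, I′, Q. The list
deliberately contains two luma-like and two I-like entries under different
standards — both positions are kept so the block totals 18 means, and with
the three composition percentages, 21 color features.

Foreign matter (yellow style, white debris) is segmented on the foreground
by hue ∈ [0.045, 0.279] (closed interval), **or** by the achromatic-white
rule S < 0.1 and I > 0.8·255, since white has no stable hue. The same hue
map backs the H feature channel and the segmentation. The three
percentages are computed over foreground pixels ("total mass" = segmented
material, not the crop rectangle); if every foreground pixel is foreign,
the foreign-to-stigma ratio is reported as +inf with a warning.

## Texture features

The 99-entry registry (the protocol fixes only the total, not the
itemization; this composition is the package's own, frozen and documented):

| family | count |
|---|---|
| GLCM contrast/correlation/energy/homogeneity, 4 angles × 2 distances | 32 |
| the same 4 statistics averaged over all 8 offsets | 4 |
| 7 first-order statistics × {local-entropy map, local-STD map, LBP map} | 21 |
| 7 first-order statistics of the raw gray levels | 7 |
| 25-bin gray-level histogram | 25 |
| 10-bin rotation-invariant-uniform LBP histogram | 10 |

GLCM: gray levels quantized into 8 uniform bins of [0, 255]; distances
{1, 2}; angles 0°/45°/90°/135°; a pair is counted only when both pixels lie
in the foreground mask; the matrix is symmetrized and normalized to sum 1.
Correlation of a degenerate matrix (zero marginal deviation) is defined as
0 with a warning. The implementation is verified against a naive
pair-enumeration/double-sum oracle to 1e-10.

Local entropy: per-pixel Shannon entropy (bits) of the windowed gray-level
histogram, 9×9 window, symmetric padding, computed by one moving-average
filter per occupied level. Gray values are quantized to 32 levels first: a
9×9 window holds 81 samples, so a 256-bin window histogram is dominated by
small-sample bias, while 32 bins keep the estimator informative and the
cost proportional to occupied levels. Local STD: population standard
deviation over a 3×3 window, same padding.

LBP: the basic discrete 3×3 code — each neighbor contributes its weight
2⁰…2⁷ (clockwise from the top-left) when ≥ the center (ties count 1);
border pixels are excluded. No circular interpolation is used; the
rotation-invariant-uniform histogram is derived from the same codes by the
standard transition-count mapping.

First-order ("histogram") statistics are computed on a 256-bin histogram
over a fixed support per source — [0, 255] for gray, STD and LBP values,
[0, log₂ 32] for the entropy map — in bin-index units. A fixed support
keeps the gray-level-range feature informative; binning over the observed
range would pin it at the bin count. Histogram entropy uses log base 2.

Filter windows centered on mask pixels near the mask boundary may include
background pixels; restricting to fully-interior windows would erase thin
filaments entirely (they are narrower than the 9×9 window), so map
statistics are taken at all mask pixels and the caveat is accepted.

Feature extraction runs in ~0.2 s per 512×512 image on one CPU.

## Classifier suite

The 22 presets, frozen (the original toolbox's internals are not fully
recoverable; these are this package's documented equivalents):

- **Trees**: max leaf nodes 101 / 21 / 5 (fine / medium / coarse, i.e.
  ~100/20/4 splits).
- **Discriminants**: LDA; and a shrinkage-regularized Gaussian quadratic
  discriminant with per-class covariance (1−r)S_k + r·(tr S_k/p)·I,
  r = 10⁻³, which stays full-rank when classes have fewer samples than the
  120 features.
- **SVMs**: linear; polynomial degree 2 and 3 (coef0 = 1); Gaussian with
  kernel scale √P/4, √P, 4√P (P = feature count; gamma = 1/scale²). Always
  one-vs-one internally, C = 1.
- **KNN**: k = 1 / 10 / 100 (fine / medium / coarse); cosine metric (k=10);
  Minkowski p=3 (k=10); squared-inverse distance weights (k=10). The
  coarse preset's k is clamped to the training-fold size on small datasets.
- **Ensembles** (30 learners each): AdaBoost of 21-leaf trees (learning
  rate 0.1); bagged trees (random forest); random-subspace LDA and
  random-subspace 1-NN with ⌈P/2⌉ features per learner; RUSBoost —
  SAMME boosting with a class-balanced random undersample per round,
  implemented in-package.

Distance- and kernel-based families see z-scored features; the scaler is
fit on the training folds only (a leakage test asserts per-fold scaling is
distinguishable from global scaling). Tree-based families use raw
features. Class scores are predicted probabilities where the model defines
them, otherwise softmaxed decision values.

## Cross-validation and statistics

Fivefold stratified CV repeated 10 times; each repetition draws an
independent partition (the repetition index perturbs the seed
deterministically), and its accuracy is the pooled out-of-fold correct
fraction × 100. Mean and SD are over repetitions. The whole experiment is
bit-reproducible from the master seed, and an output manifest records a
hash of every result-affecting parameter.

Rates: TP = 100·diag/row-sum, FN = 100 − TP, PP = 100·diag/column-sum,
FD = 100 − PP; undefined rates (empty class) are NaN with a warning. Rate
tables and ROC use the pooled predictions of the first repetition
(averaging over repetitions is available but not the default). Multiclass
ROC is one-vs-rest; AUC is the trapezoid integral, equal to the
tie-corrected concordance probability; a classifier's overall AUC is the
unweighted mean of its per-class AUCs.

ANOVA is the classical one-way decomposition from explicit sums of
squares. Duncan's multiple range test compares each stretch of r adjacent
ordered means with the critical range
q(1−(1−α)^(r−1), r, df_within)·√(EMS/n), widest stretches first, never
testing inside a stretch already declared homogeneous; the letter display
assigns one letter per maximal homogeneous stretch. Under the null (all
groups from one normal), the probability of any split is exactly the
protection level of the widest stretch, 1 − (1−α)^(k−1) — for 22 groups at
α = 0.05 about 0.66 — which the Monte-Carlo test verifies.

## Synthetic scene generator

Scenes emulate the imaging protocol: a 512×512 canvas, background level 8
(safely below the threshold 20), red curved filaments rendered as disks
stamped along random quadratic Bézier spines, per-filament ±15%
multiplicative brightness jitter, an optional linear illumination gradient
(up to −30% across the frame), and i.i.d. Gaussian sensor noise (σ = 2),
clipped to [0, 255].

Grade morphology: Pushal — 15 filaments in joined triplets, length
110–170 px, 20% style at the joined end; Negin — 18 separate filaments,
140–200 px, 3% style; Sargol — 30 filaments, 40–80 px with 60% broken
shorter, no style. Widths 5–8 px throughout. Style pixels are assigned by
thresholding the spine-position map at the global quantile matching the
target fraction, so the rendered fraction tracks the target to within ~1%.
The filament pixel-scale statistics are unconstrained by any published
measurement; they were chosen once to look like bulk macro photographs at
this canvas size and to preserve the grade contrasts (Negin fragments
larger than Sargol's; Pushal carrying the most style).

What the generator does **not** emulate: specular highlights, depth-of-field
blur, filament translucency and overlap shading, camera JPEG artifacts, and
natural color variability between harvests. Synthetic classes are more
separable than real grades — several presets reach ~100% on synthetic
data — so passing tests demonstrate correctness of the machinery
(segmentation, features, CV, statistics), not field-grade accuracy.
Problem sizes in the tests and the acceptance script (90 images of 512²,
10×5-fold CV, 500 Monte-Carlo replicates) are the package's desk-scale
defaults.

## Degenerate inputs and numerical conventions

- Empty foreground after preprocessing → the sample is excluded with a
  logged reason ("no saffron found").
- GLCM with no valid pixel pair, empty value collections, single-class ROC
  input, fewer than two ANOVA groups → explicit `ValueError`s.
- A model-fit failure marks the repetition invalid and is surfaced in
  `CvResult.failures`; if every repetition fails the run raises.
- Tolerances: GLCM/AUC oracle agreement 1e-10/1e-12; ANOVA sum-of-squares
  identity 1e-9; composition recovery ±5 percentage points on synthetic
  scenes (measured ≤ 3).
- All seeds are integers below 2³¹; child seeds derive from the master
  seed via `numpy.random.SeedSequence`.
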