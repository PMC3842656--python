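# Methods

`choroidtex` quantifies the texture of the choroid — the vascular layer
beneath the retinal pigment epithelium (RPE) — in fundus OCT B-scans, and
classifies each scan into one of three imaging types associated with
retinal pathology:

* **Z1** — characteristic vertical shadow bands in the choroid cast by
  retinal lesions (neovascular AMD, exudative edema),
* **Z2** — globally reduced sub-RPE brightness (diffuse edema, ischemia of
  the inner retinal layers),
* **Z3** — a uniform choroidal texture (scarring fibrovascular tissue).

This note records the model, its assumptions, the tunable parameters, the
numerical choices, and what the synthetic phantoms do and do not show.

## Pipeline

### RPE detection and flattening

The input `L_GRAY` (M×N grey image, nominally 256×1024 at 8 bit) is median
filtered with a 3×3 mask (edge replication at borders, so no artificial
dark frame perturbs the column-maximum search). The RPE row of each column
is not the bare argmax — that is fragile against residual impulses and
saturated flat-topped bands — but the *lower median* of the candidate set
`{m : L(m,n) >= p_r · max_m L(m,n)}` with `p_r = 0.9`. Columns whose
maximum is zero have no meaningful cluster; they receive the last-row
sentinel and are flagged out of all downstream masks. With `p_r = 1` and a
unique maximum the detector reduces to the argmax.

Pixels above the contour are replaced by a `-1` sentinel (distinguishing
"outside the region" from genuinely black choroid), and each column is
shifted up so the RPE sits at row 0. Flattening is a pure per-column shift:
it preserves the multiset of valid grey values in every column.

Coordinates are 0-based `(row, col)` throughout, row 0 = shallowest tissue,
`x` = column and `y` = row for centroids.

### Brightness correction

Scanner and eye-geometry effects leave a smooth illumination field over the
choroid. The 30×30 local mean (window at least twice the largest expected
object, which is bounded by 20×20 px) is subtracted from the flattened
image. The mean is computed over *valid* pixels only, and the residual is
defined on the interior band where the window has full support (offsets
−14..+15, i.e. rows/cols 14..dim−16); the exterior band is masked out. The
residual of a constant region is 0, and an isolated impulse of amplitude A
keeps residual `A·(1 − 1/900)`.

### Multiscale conditional-morphology filter bank

The masked residual is filtered with disc structuring elements (SE) of
diameter 3, 5, 7, 9 and 11 px (an L2 ball in the i×i bounding box; diameter
3 is the 5-pixel cross). Per scale the grey image is passed through the
max-then-min composite over the SE. Applied to a residual image whose
vessels are *dark*, this composite (formally a closing) erases dark
structures smaller than the SE — which is exactly what makes the scale
ladder informative about the vessel-size distribution. A config switch
(`morphology_order="opening"`) provides the min-then-max order instead. All
neighborhood operations use a shrinking window at image borders
(out-of-image members are ignored), avoiding padding artefacts next to the
sentinel region.

Each filtered image is min–max normalized over the mask and thresholded at
0.5, keeping *dark* pixels (vessels) as foreground; a constant image
degenerates to an all-zero map with a warning.

The binary maps are then refined by *conditional* erosion and dilation —
the centrepiece of the method. With effectiveness constants
`p_we, p_wd ∈ [−1, 1]` and a threshold map `p_mn ∈ [0, 1]` (constant 0.5 by
default):

* erosion keeps the pixel where `(1 − p_we) · p_mn ≤ s_re`, otherwise takes
  the neighborhood minimum over the disc;
* dilation keeps the pixel where `(p_wd + 1) · p_mn ≥ s_rd`, otherwise
  takes the neighborhood maximum;
* `s_re` / `s_rd` are means of the normalized grey filtered image over the
  square windows shifted *forward* (+1..+i) / *backward* (−i..−1) of the
  SE's bounding box — implemented literally in that asymmetric form.

The grey image is min–max normalized to [0, 1] before the means are taken,
so the comparison against `(1 − p_we) · p_mn ∈ [0, 2]` is dimensionally
coherent. At `p_we = p_wd = 0` the operators run at maximal intensity; at
`p_we = 1` erosion is the identity; at `p_wd = 1` (with `p_mn ≡ 1`)
dilation is the identity. The defaults are `p_we = p_wd = 0`; the full
sweep grid −1.0..1.0 in steps of 0.1 is exposed. One refinement round is
dilation followed by erosion; three rounds are applied by default. After
every operation the validity mask is re-imposed, so foreground can never
leak outside the choroid.

### Features

Each refined map is decomposed into 8-connected components (border-touching
objects retained, no minimum-size filter — artefact suppression is the job
of the conditional morphology). Per scale, four statistics in the fixed
scale order 3, 5, 7, 9, 11 yield the 20-vector:

| entries | statistic |
|---|---|
| w1–w5   | object count |
| w6–w10  | mean centroid x (column) |
| w11–w15 | mean centroid y (row) |
| w16–w20 | population std of per-object mean brightness |

Brightness is sampled from the corrected residual image at object pixels.
A scale with zero objects contributes zeros for its centroid/std entries
(the classifier needs complete vectors); a single object has std 0.

### Classification

A CART tree is grown by exhaustive axis-aligned search maximizing the Gini
impurity decrease, with no minimum node size. Determinism is pinned:
candidate thresholds are midpoints between consecutive distinct sorted
values, and ties break to the lowest feature index, then the lowest
threshold (with a 1e-12 tolerance absorbing float noise between
mathematically equal scores).

Pruning is cost-complexity (weakest-link): the pruning sequence of the full
tree defines the candidate levels; each level's misclassification cost is
estimated by stratified 10-fold cross-validation (fold trees pruned at the
geometric-mean alpha of the level), and the selected level is the smallest
tree whose CV cost is within one binomial standard error of the minimum
(the 1-SE rule; level 0 = unpruned). The fold count is a documented choice;
fold assignment is seeded. On label-noise data this collapses the tree to
the root majority in roughly three quarters of random replicates — a rate
reproduced independently by an sklearn-based route with the identical
selection rule.

Evaluation is one-vs-rest per class on the 3-class confusion matrix:
`SPC = TN/(FP+TN)`, `TPR = TP/(TP+FN)`, `ACC = (TP+TN)/total`. Per-feature
ROC curves sweep all midpoint thresholds in both orientations and report
the better-oriented staircase (feature polarity is class-dependent); the
AUC equals the normalized Mann–Whitney U statistic.

The subset search enumerates all 2^k bitmasks over a feature pool, training
a full and a 1-SE-pruned tree per subset on the learning split and scoring
on the test split; declaring the full 20-feature search plans
2·2^20 = 2,097,152 trees. The exhaustive 20-feature enumeration is
supported but hours-scale; routine runs use a reduced pool (the shipped
analyses use k = 8: w1–w6, w15, w16 — counts plus the centroid/dispersion
features that dominate the trees). The empty bitmask is scored as the
training-prior majority classifier so the enumeration arithmetic stays
exact. Top-3-per-class tables (binary membership rows plus an ACC row) and
feature occurrence frequencies over the top-ranked subsets are emitted.
The 60/20/20 learning/validation/test split is stratified per class;
pruning uses CV on the learning split only, the validation split is
reserved for model selection across subsets, and the test split is touched
only for final evaluation.

## Synthetic phantoms

No clinical scans are distributed, so the generator renders phantoms
encoding exactly the qualitative markers of the three types and nothing
else: a retina background (grey ~100), a constant-brightness RPE band
(230, 4 px thick) along a gentle low-order polynomial curve, a choroid
(~150) with dark elliptical vessels (~80, radii 3–8 px so objects stay
under 20×20), class effects applied to the sub-RPE region only (Z1: 2–4
column bands attenuated to 0.45–0.6; Z2: global dimming to 0.55–0.65; Z3:
near-constant vessel contrast and a common vessel depth), and finally
salt-and-pepper noise as independent per-pixel replacement with 0 or 255 at
half the density each. Every non-RPE structure stays below 0.9×230, so on a
noise-free phantom the cluster-median detector recovers the true contour
(defined as the lower-median row of the band) exactly in every column.

Default effect sizes were fixed once from this layout arithmetic so that
the three class markers (mean sub-RPE brightness for Z2, cross-column
variance for Z1, vessel-contrast dispersion for Z3) separate the marked
class from both others by well over three pooled standard deviations at 50
images per class.

What the phantoms deliberately omit: OCT speckle statistics, depth
attenuation, A-scan physics, EDI, multi-layer retinal structure, and mixed
or ambiguous pathology. Passing the end-to-end test (pruned-tree per-class
test accuracy ≥ 0.85 on 100 phantoms per class) therefore demonstrates that
the pipeline transports the generative class markers into the feature
vector and that the classifier recovers them — not that clinical accuracy
at the published level (ACC₁ ≈ 0.76, ACC₂ ≈ 0.81, ACC₃ ≈ 0.68 for the
pruned tree) is reproduced, which is impossible without the original
~1,000 clinical images.

## Problem sizes and numerical choices

* Phantoms default to 256×1024 (the nominal acquisition geometry);
  resolution is configurable and the method is geometry-agnostic.
* The standard synthetic study is 100 images per class with a stratified
  60/20/20 split (largest-remainder apportionment per class), and the
  reduced subset search uses the 8-feature pool above (256 subsets, 512
  trees).
* Degenerate inputs: constant images binarize to all-zero with a warning;
  single-class training data yields a single-leaf tree; an empty feature
  subset is an error in `train_cart`; fewer samples than CV folds reduces
  the fold count with a warning; all-zero columns are flagged and excluded
  from masks.
* Median of an even candidate set takes the lower middle, keeping the
  result an existing row index.
* Dilation-before-erosion order within a refinement round, and re-masking
  after every conditional operation.

## Known limitations

* The phantom model is a caricature; none of the acceptance numbers
  transfer to clinical data.
* The conditional operators are implemented for disc SEs of odd diameter;
  arbitrary odd sizes are accepted but only the five canonical sizes are
  exercised.
* The exhaustive 2^20 subset search is supported by the same code path as
  the reduced search but is not run routinely.
* DICOM reading extracts the pixel payload only; acquisition metadata is
  ignored.
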