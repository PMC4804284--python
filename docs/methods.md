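# Methods

This note documents the models, parameter choices and numerical
conventions behind `nucliq`, and what the synthetic validation does and
does not demonstrate.

## Illumination correction

Confocal tissue images carry a smooth multiplicative gain (vignetting,
depth variation).  The local background is estimated as a Gaussian blur
(σ = 10 px, reflective boundary) of the **structural** channel — the
channel with spatially broad signal — and every channel is divided by it.
Division is floored: where the background falls to or below
`ε·max(B)` (ε = 10⁻³) the output is set to 0, so dead regions stay finite
and visibly flagged rather than exploding.  The correction removes gain
fields varying on scales well above σ (verified to < 2% residual away
from a 3σ border margin) but cannot distinguish staining variation from
illumination at scales comparable to σ; it also assumes the structural
channel has nonzero background everywhere tissue exists.

## Segmentation

The corrected nuclear channel is binarized with Otsu's threshold — chosen
because it is parameter-free and standard for DAPI; the binarization
method is not dictated by the correction model and could be swapped.
Components are labeled at 8-connectivity (configurable to 4) and
components with **area < 5 px** are removed ("smaller than" read
strictly: area 5 is kept).  Touching nuclei are *not* split; clump
splitting is out of scope, so a merged pair counts as one nucleus.
Coordinates are 0-based (row, col) with pixel centers at integers.

## Feature families

All free parameters live in `FeatureConfig`; defaults are sized for
nuclei of roughly 5–15 px radius at 40× magnification.

* **Fourier HOG** (orders m = 0…4, radial Gaussians σ ∈ {2, 4, 8} px).
  The gradient field is treated as a per-pixel orientation distribution;
  its order-m angular Fourier coefficient `|∇I|·e^{imθ}` is pooled with an
  isotropic Gaussian and the magnitude taken.  A global rotation
  multiplies the pooled coefficient by a unit phase, so the values are
  rotation-invariant; this is exact (to float precision) for 90°
  multiples, which are interpolation-free.
* **Haralick statistics** (window 15 px, 8 gray levels, distance-1
  offsets in 4 directions, averaged).  The per-pixel GLCM counts pairs
  (p, p+offset) with p inside the window and p+offset inside the image —
  the boundary contract is stated because sliding-window GLCMs have no
  universal convention — symmetrized and normalized.  Five statistics are
  emitted: contrast, correlation (defined as 1 for zero-variance
  windows), energy, homogeneity, entropy.  Window counting uses box
  filters with integer rounding, so counts are exact.
* **Local entropy** (window 9 px, 32 equal-width bins over the image
  range): Shannon entropy in bits of the clipped-window histogram,
  `0·log 0 := 0`.
* **Membrane saliency (CMD).** Stage 1: the smoothed Hessian (σ = 2 px,
  derivatives scale-normalized by σ²) gives the steered
  second-derivative response in closed form; bright-ridge strength is the
  eigenvalue contrast `max(0, −λmin) − max(0, −λmax)`, which is zero on
  isotropic blobs and dark lines, and the ridge orientation is
  perpendicular to the most negative curvature direction.  Stage 2:
  dense stick tensor voting at σ = 10 px.  Orientations are quantized
  into 16 bins centered at multiples of π/16 (so axis-aligned ridges bin
  robustly and quarter-turn rotations shift bins exactly); each bin's
  strength field is convolved with an analytic voting kernel
  `exp(−d²/2σ²)·cos⁴ψ` (ψ = angle between the join vector and the stick)
  carrying the bin's tensor.  This is a convolution approximation of
  classic stick voting: it omits the curvature-arc vote path of the
  original formulation, which matters for strongly curved membranes but
  not for the quasi-straight striation this pipeline targets.  Saliency
  is `λ1 − λ2` of the accumulated tensor.
* **ECS**: the structural channel's Otsu tissue mask is complemented,
  components labeled at 8-connectivity, and each extracellular pixel
  valued with its component's area (tissue pixels 0).  Large values mark
  nuclei sitting in open interstitial space rather than inside cytoplasm.

Features are computed on the nuclear and structural channels only; the
marker channel is deliberately excluded so that the quantified readout
cannot leak into classification.  Per nucleus, every map is summarized
over the nucleus pixel set and over a ring (dilation by a 15-px disk
minus the nucleus — 15 px being the same length scale used for
annotation matching) by mean, median, sample (n−1) SD and MAD: 360
descriptors.  Columns are standardized to zero mean and unit sample
variance within each image; constant columns map to 0, and images with a
single nucleus standardize to all-zeros with a warning.

## Classification

Dot annotations are matched to nuclei by Euclidean distance ≤ 15 px
(inclusive), each dot going to its nearest in-radius centroid with ties
to the smaller nucleus id.  The classifier is L2-regularized logistic
regression fitted with the liblinear solver (C = 1 by default; balanced
class weights optional, off by default).  Validation is leave-image-out:
all nuclei of one image form the held-out fold, preventing within-image
leakage, and training provenance is recorded and asserted.  PR curves
use exact integer counts at every distinct score threshold, predicting
target at score ≥ threshold; an empty prediction set has precision 1 by
convention.  The operating point maximizes precision subject to a recall
floor; among precision ties the higher-recall point is chosen because it
Pareto-dominates.  On near-separable data logistic scores saturate near
1, making thresholds in the saturated tail brittle across datasets —
operating thresholds should be chosen on (or recalibrated to) the study
they will be applied to.

## Quantification

Marker positivity: the corrected marker channel is Otsu-binarized and a
nucleus is positive when ≥ 25% of its pixels exceed the threshold — a
numeric stand-in for the perceptual "nucleus shows marker signal" rule,
robust to partial nuclear coverage; both the rule and the fraction are
configurable.  User corrections are exchanged as a CSV
(image_id, nucleus_id, accept|reject); accept forces target, reject
forces non-target, application is idempotent and row-order independent,
and unknown references fail loudly.  The report counts totals, targets,
marker-positives and co-labeled nuclei with four derived percentages;
pooled values are ratios of summed counts, not averages of per-image
percentages, matching count-ratio semantics.

## Agreement

Each rater's dots are radius-matched per nucleus (binary selection per
rater; multiple dots within radius count once).  Fleiss' kappa is
computed from the item-by-category counts with the Fleiss–Nee–Landis
large-sample standard error — the standard companion to the overall
statistic; per-category variance estimators would differ in the third
decimal at the sample sizes involved.  Verbal bands use the conventional
2-decimal cutpoints; kappa is rounded half-up to 2 decimals first so
values falling in the printed gaps (e.g. 0.205) band deterministically.
Two conditions are compared with a normal z-test on the kappa
difference.  Recomputing the published worked example from the rounded
inputs (0.695 ± 0.006 vs 0.511 ± 0.006) gives z = 21.68 against the
printed 21.72 — the residual is input rounding, within 0.5%.

## Synthetic scenes

The generator emulates the image properties the pipeline exploits:
elliptical nuclei (semi-major 3–6 px, aspect 1–2, random orientation),
bright sinusoidal striation (period 6 px — sarcomere-like banding at
40× — amplitude 0.9) in 20-px disks around target nuclei, diffuse
interstitium at intensity 0.5 with smooth ±0.1 mottle (dim but nonzero,
keeping the background estimate well-conditioned), near-black nuclear
background (off-nucleus DAPI signal comes only from the noise term, as
in real images), marker signal painted over an exactly-planted subset of
nuclei, a multiplicative gain field (none / linear ramp / radial
vignette), and clipped Gaussian noise (σ = 0.03).  The default study is
8 images of 384×384 px with 150 nuclei each (30% targets, minimum
center separation 13 px, 20% of targets and 5% of others
marker-positive) — sized so that a full multi-image study runs in
minutes on one CPU while keeping ≥ 1 000 nuclei pooled, comfortably
above the binomial sampling error the ±5-point recovery checks assume.
Simulated raters dot each true target with probability `hit_rate`
(jittered, σ = 2 px) and each non-target with probability `fp_rate`.

What passing tests show: the implementation's primitives match
independent brute-force oracles; the pipeline recovers planted classes
and fractions when the class signal is a clear texture difference; the
correction neutralizes smooth gain fields.  What they do not show:
performance on real tissue, where nuclei clump, striation is broken and
partial, staining varies within an image, and class overlap is far
larger — on such data the operating points will sit well below the
synthetic ones, as the much lower published mouse precision illustrates.

## Numerical conventions and degenerate inputs

Sample (n−1) standard deviation throughout; statistics over an empty
region (a nucleus touching all borders of a tiny image) are emitted as 0
with a warning; a constant image has no Otsu threshold and segments to
nothing; an all-zero structural channel is a hard error (no background
estimable); kappa is undefined (error) when all raters use one category
everywhere; PR curves require at least one true target.  All randomness
flows from explicit seeds; fits are deterministic given data and C.
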