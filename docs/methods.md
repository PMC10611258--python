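# Methods

## Scope and design

`somaxon` is a reference implementation of a two-compartment image-based
neurotoxicity screen. Its pipeline — weak-label tile classification of
soma-area and axon-area fluorescence images, aggregation into per-sample
toxicity probabilities, a negative-control decision line, Dunnett
comparisons against vehicle, and 2D mechanism-of-action (MoA) integration
with pairwise MANOVA — is the analysis a compartmentalized
microphysiological CIPN assay would run on real micrographs. Because no
public image set accompanies that assay class, the package ships a seeded
synthetic generator whose phenotypes emulate the reported morphologies;
every quantitative claim the tests make is therefore a claim about the
method's behavior on this generator, not about biological images (see
*Limitations*).

## Synthetic study

### Geometry and intensity model

All geometry is defined at a full-scale local image of 2304 × 2304 px and
multiplied by a `scale` factor; the default `scale = 0.25` produces
576 × 576 px images while preserving the tiling arithmetic exactly (soma:
4 segments × 36 tiles; axon: 16 tiles). Images are 16-bit grayscale with a
background of 5% of full scale, Poisson shot noise (800 photons per unit
intensity) and Gaussian read noise (SD 0.008 of full scale, configurable).
These values are implementer-chosen; they merely need to give realistic
dynamic range and severity-separable morphologies.

Soma fields contain 60 cell bodies by default (mean radius 56 px full
scale, CV 0.15, peak intensity ≈ 0.55 of full scale with a smooth radial
falloff). Axon fields contain 28 fibers drawn as smooth, predominantly
horizontal curves (Gaussian cross-section, σ = 4.8 px full scale).
Healthy fiber baselines are stratified-uniform across the channel height
rather than i.i.d.: uniform placement occasionally produces chance bundles
in damage-free images, which is not what healthy outgrowth in an open
channel looks like and would blur the healthy/damaged contrast.

### Damage phenotypes

A condition is parameterized by two abstract severities in [0, 1], mapped
linearly (the simplest monotone choice) to effect amplitudes:

| effect (at severity 1) | value | compartment |
|---|---|---|
| soma radius shrinkage | 45% | soma |
| contour irregularity (harmonics 2–5) | 0.35 × radius | soma |
| bright puncta per cell (Poisson) | 6 | soma |
| cell-body dimming | 35% | soma |
| fiber aggregation toward bundle paths | 0.8 | axon |
| per-cell fiber break probability | 0.5 | axon |

Puncta (autofluorescent debris) are scattered over the cell's *original*
footprint: a shrunken cell leaves debris where it used to be, which keeps
extreme damage detectable even when the remaining cell body is small.
Aggregation is capped at 0.8 rather than 1.0 because a totally collapsed
bundle degenerates into a single bright line that is no longer visually
distinct from a healthy sparse fiber at the classifier's input resolution.
A severity of exactly 0 forces every damage amplitude to 0 (validated).

The severity values themselves are arbitrary — the source assay describes
its phenotypes only qualitatively — and only their ordering and
compartment assignment carry meaning.

### Spontaneous background pathology

Healthy cultures are not pristine: vehicle controls in real screens score
a small but nonzero positive rate. The generator therefore adds
severity-independent heterogeneity. Each soma is drawn "stressed"
(moderate shrinkage/dimming/puncta) with probability 0.02. Each axon
image draws a small baseline aggregation (Beta(1, 4) · 0.25) and
fragmentation (Beta(1, 4) · 0.15) — treatment severities apply on top via
`max` — plus Poisson(1.5) local mini-bundle events of random strength in
which a few neighboring fibers converge over a short window.

The continuum matters: anomalies that are categorically distinct from
damage (e.g. bright blobs) can be learned as context-specific negatives,
leaving controls scoring exactly 0%; the mean + 2·SD line then collapses
to 0 and a single stray false-positive tile in a toxicant-free condition
flips an MoA call. A baseline that overlaps mild damage in appearance
leaves no separating gap, so the negative-control line takes a stable
positive value at every seed. Both generators accept `spontaneous=False`
for pure severity contrasts (used by tests that need strongly separable
classes).

### Compound panel and study design

The default panel mirrors a published CIPN screen: DMSO 0.1% (vehicle),
sucrose 10 µM (negative), oxaliplatin 10/100 µM (soma-dominant,
severities 0.6/1.0), vincristine 0.003/0.03 µM (axon-dominant, 0.6/1.0),
paclitaxel 0.1/1 µM (dual, 0.5/0.8), suramin 10/100 µM (moderate dual),
bortezomib 0.01 µM (moderate dual). The soma classifier trains on
vehicle/negative + oxaliplatin, the axon classifier on vehicle/negative +
vincristine; all compounds appear in the test split with the per-condition
image counts of the source assay's dataset tables. The high concentration
of each training toxicant is assigned severity 1.0 ("maximal damage") so
the entire severity axis lies inside the training distribution; with a
lower cap the severity-recovery sweep is not monotone at its top end.

## Tile classifier

A deliberately small CNN (4 conv blocks of 3×3 kernels with channels
8/16/32/32, three 2×2 max-pools, global average pooling, linear 2-class
head; ≈ 20k parameters) implemented in numpy with manual backpropagation.
Tiles are block-mean downsampled to a fixed 48 × 48 input and scaled to
[0, 1] by the 16-bit maximum, making the model independent of the image
scale factor. Training uses Adam (lr 1e-3), batch size 128, softmax
cross-entropy, an 80/20 seeded train/validation split, and seeded
flip/rotation augmentation in the pipeline (augmentation is off at the
library default; the pipeline enables it because the axon compartment has
only ~270 negative training tiles and unaugmented models occasionally
leave borderline healthy-tile false positives). Defaults: 8 epochs for the
soma model (~10k training tiles), 45 for the axon model (~550 tiles).

Labels are weak — every tile inherits its image's compound class — so
background tiles appear in both classes. The loss is deliberately
*unweighted*: inverse-frequency class weighting would push those
uninformative background tiles toward whichever class has more empty
tiles (damaged images have more, because cells shrink), inflating the
control false-positive rate. With unweighted loss the majority-class
prior keeps background tiles negative, which matches the screening goal.

The decision threshold is 0.5 (configurable). Everything — initialization,
batch order, augmentation draws — is derived from explicit seeds, and
training twice with the same inputs yields bit-identical weights; the
pipeline's per-stage SHA-256 content hashes make this checkable.

## Scoring and statistics

Toxicity probability is the exact percentage of positive tiles per sample
(soma sample = one quadrant segment, 36 tiles; axon sample = one local
image, 16 tiles). The decision line is the pooled per-sample mean of the
vehicle + negative-compound test samples plus twice their sample SD
(ddof = 1); exceedance is strict (a value exactly on the line does not
exceed it). Group summaries report mean ± SEM.

Dunnett's two-sided adjusted p-values are computed by deterministic
quadrature: the comparison statistics share the control mean and the
pooled SD, giving the one-factor correlation structure
ρᵢⱼ = λᵢλⱼ with λᵢ = √(nᵢ/(nᵢ+n₀)), so
P(maxⱼ |Tⱼ| ≤ t) reduces to a double integral over the shared standard
normal factor (Gauss–Hermite, 128 nodes) and the pooled-SD scale
(Gauss–Legendre on the χ quantile transform, 512 nodes). Accuracy is
≈ 5e-8 against the pooled t-test in the single-treatment case and ≈ 2e-6
against R `mvtnorm` for the classical k = 3, ν = 20 critical value
(2.5403). scipy's QMC-based implementation was not used for the p-values
because its ~1e-4 stochastic error breaks both the determinism contract
and the k = 1 equivalence check; it serves as a cross-check oracle in the
tests. The omnibus ANOVA uses `scipy.stats.f_oneway`. No correction
beyond Dunnett's built-in adjustment is applied.

MANOVA uses Wilks' Λ with Rao's F transformation (exact for the two-group
pairwise case, where it coincides with Hotelling's T²; verified against a
hand-written Hotelling oracle to 1e-9 and against statsmodels). Degenerate
inputs — e.g. two conditions whose samples are all identical — make the
total SSCP singular; the test is then restricted to the subspace with
actual variation, and if nothing varies the p-value is 1. Conditions with
fewer than 3 replicate points are excluded from the pairwise matrix with a
warning (their 2×2 within-group covariance would be rank deficient).

MoA integration pairs compartments per condition either by means (one
point per condition, used for calls) or by replicate index truncated to
the smaller compartment count (used for MANOVA); the sample unit is the
image/segment as scored, exposed in config. The four MoA categories are a
formalization of the axis-shift reading of the 2D plot; the raw
coordinates are always emitted alongside.

## Grad-CAM

Relevance is the ReLU of the gradient-weighted channel sum of the final
conv layer's activations (channel weights = spatial mean of
∂logit/∂activation, which for a GAP + linear head is uniform), upsampled
to the tile and min-max normalized; a constant raw map yields an all-zero
map with a warning. Upsampling is separable piecewise-linear interpolation
aligned to activation-cell centers (nearest-expand followed by a triangle
filter) rather than a plain bilinear resize: it preserves each
activation's exact value at its cell center, so the upsampled argmax
always falls inside the cell with maximal raw relevance — a plain resize
violates this for near-tied activations at grid edges. Overlays blend a
blue (negative-focus) or magenta (damage-focus) palette with weight equal
to the relevance. Any object exposing `feature_maps` and
`activation_gradient` can be explained, which the tests use to construct
models with known causal structure.

## Problem sizes and defaults

The default quarter-scale study comprises 233 soma and 134 axon local
images (367 total, per the design tables), ~10k soma and ~550 axon
training tiles, and runs end to end in roughly 2–3 minutes on one CPU.
The severity-recovery sweep uses 20 fresh images per severity level
{0, 0.3, 0.6, 1.0} per compartment. Null calibrations use 1000
replicates. The determinism check reruns a half-count study with reduced
epochs, which exercises every stage at lower cost.

## Limitations

- Passing tests show the analysis recovers the *generator's* ground truth;
  the generator does not model optics (PSF, vignetting), staining
  variability, focus drift, device walls or Schwann cells, so no claim
  about real micrographs follows.
- The CNN architecture, loss, epochs and augmentation are placeholders for
  an unspecified production model; the module interface is
  architecture-agnostic.
- Printed decision lines from the source assay (3.3% soma, 21.1% axon)
  are not targets: they depend on that assay's images and trained weights,
  and are not reconstructible from its printed group summaries.
- Moderate dual toxicants with similar profiles (suramin vs bortezomib)
  are not separable by design; distinguishing them would require
  endpoints (myelin, proteasome) outside the two-compartment readout.
- The mean + 2·SD line is fragile when control rates are identically
  zero; the spontaneous-pathology rate keeps it away from that regime,
  which is also where real assays operate.
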