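# Methods

## Problem setting

Cardiac function is routinely quantified from short-axis (SAX) cine MRI by
the left-ventricular end-diastolic volume (EDV), end-systolic volume (ESV)
and ejection fraction EF = (EDV − ESV)/EDV.  Training data for automatic
quantification is dominated by healthy hearts: EFs cluster around 0.55–0.60,
and regression models trained on such data degrade precisely on the low- and
high-EF cases that matter clinically.  This package implements two coupled
remedies:

1. a **mask-space synthesizer** that expands each real (ED, ES) segmentation
   pair into many new pairs with controlled, wider-ranging EF, and
2. **SFERA**, a residual-CNN + bidirectional-LSTM regression network that
   predicts (EDV, ESV) — and hence EF — directly from image stacks, without
   segmentation, plus the statistics used to evaluate such predictions.

## Mask synthesis

### Signed-distance interpolation (lower EF)

Each structure (LV blood pool, myocardium, RV) is converted to a signed
Euclidean distance transform (SDT): positive inside, negative outside,
magnitude = pixel distance to the nearest opposite-region pixel
(`scipy.ndimage.distance_transform_edt` on the mask and its complement).
Intermediate shapes between ED and ES are level sets of the convex
combination

    IM_α = (α/F)·SDT_ED + ((F−α)/F)·SDT_ES,   α = 1..F,  F = 11,

with a pixel assigned to the structure of largest positive combined SDT
(background if none).  α = F reproduces ED exactly; for concentric disks the
zero level set sits at the radius interpolated linearly in α.  Pairing the
original ED with an interpolated frame as a new ES — or an interpolated
frame as a new ED with the original ES — strictly reduces EF.  Structures
present in only one frame are skipped with a warning (they would appear or
vanish abruptly).

### Affine rescaling (higher EF)

All foreground labels of a frame are rescaled jointly by a factor γ about
the foreground centroid (inverse mapping, nearest-neighbor labels), so each
area scales by γ² up to pixelation.  ES frames use 13 γ values uniformly
spaced over [0.7, 1) and ED frames 13 values over [1, 1.2) (half-open,
left endpoint included).  Shrinking ES while growing ED raises EF:
EF′ = 1 − (γ_ES²/γ_ED²)(1 − EF) under per-slice uniform scaling.  The
default pairing is index-matched (γ_ED[i] with γ_ES[i], 13 variants per
subject); a cross-product mode is available.  With F = 11 this yields
2·(F−1) + 13 = 33 unfiltered variants per source subject.

### Filtering and rebalancing

Subject-level volumes are computed by the cardiology method of disks
(Σ per-slice area × slice spacing) at the synthetic cohort's constant 8 mm
spacing, and variants are kept when 0.10 ≤ EF ≤ 0.80 (closed interval — the
boundary convention is ours, the window is the workflow's).  The EF
histogram is then flattened by seeded per-bin subsampling: equal-width bins
over [0.10, 0.80] (default 14), up to a fixed quota drawn uniformly without
replacement per bin; deficient bins keep everything.

### Design choices in the mask half

* The interpolation weights are the convex combination above; the
  alternative reading of the interpolation formula (both weights α/F) is
  not a convex combination and fails endpoint identity, so it was rejected.
* Which of the two SDT operands is "first" is a convention; swapping ED/ES
  merely relabels α ↦ F − α.
* SDTs are combined raw (no clipping or renormalization); for the
  shapes at hand the combination is well behaved.
* The rescale center is the centroid of the union of all foreground labels,
  per frame, so the anatomy stays mutually consistent; labels are resampled
  nearest-neighbor (no fractional labels).

## Phantoms (the test bed)

Real cohorts and a learned mask-to-image renderer are emulated by an
analytic phantom: per slice, the LV blood pool is an ellipse, the myocardium
a surrounding annulus of fixed thickness, and the RV a crescent (a larger
ellipse clipped by the epicardial boundary).  ED semi-axes taper base→apex;
ES masks shrink every slice by √(1 − EF), so areas scale by 1 − EF and the
method-of-disks EF equals the target exactly — closed-form ground truth for
every operator in the package.  Cohorts draw basal semi-axes from 15–31 mm
(EDV roughly 30–130 ml at the 150 mm field of view — wide enough to emulate
the clinical spread from small to dilated ventricles within the grid),
eccentricity 0.85–1.0, wall thickness 5–8 mm, 6–9 slices, and EF from a
named law (`normal(0.57, 0.07)` for real-like imbalanced cohorts,
`uniform(0.10, 0.80)` for synthetic-style balanced ones), truncated to
(0.05, 0.90).

The procedural renderer paints per-label base intensities with bSSFP
contrast (blood pool ≈ 0.9, myocardium ≈ 0.25, RV ≈ 0.8), a smooth
low-frequency cosine background outside the heart, and additive Gaussian
noise (σ = 0.04).  It is a registered backend behind the same renderer
interface a learned mask-to-image model would use.  What it does **not**
emulate: papillary muscles and trabeculation, background anatomy, slice-to-
slice background inconsistency, imaging artefacts, or contrast variability.
Tests passing on phantoms therefore validate the machinery (operators,
training dynamics, statistics), not clinical-grade accuracy on real MRI.

## Preprocessing

Frames are bilinearly resampled to 1×1 mm, center-cropped (or symmetrically
zero-padded) to 150×150, and intensity-mapped so the 3rd/97th percentiles go
to 0/1 with clipping outside (quantiles are linear-interpolation empirical
quantiles, computed per frame; the map is invariant to positive affine
intensity transforms).  Volume targets are divided by the subject's slice
spacing and unity-normalized with per-target training-set min/max; the
inverse map restores ml exactly (round trip < 1e−9).  Out-of-range values at
inference are passed through unclipped.  Slice selection between the basal
and apical planes is an inclusive trim driven by manifest indices (no
automatic plane detection).

## The SFERA network

* **Encoder** (per slice, input 2×150×150 — ED and ES concatenated on the
  channel axis): five residual blocks; block k holds two 3×3 convolutions
  with batch normalization and ReLU, an identity shortcut (1×1 projection
  when widths differ) added before the activation, then 2×2 max pooling.
  Channels double per block from 32 (32…512); spatial side follows
  150→75→37→18→9→4.  The final map is flattened and linearly reduced to a
  128-element feature vector.
* **Aggregator**: a bidirectional LSTM (hidden 128 per direction) over the
  base→apex feature sequence; the stack embedding concatenates the final
  states of both directions.  Any stack length ≥ 1 is accepted.
* **Heads**: a linear head used for end-to-end training, and a Bayesian
  ridge pair (scikit-learn `BayesianRidge`, evidence-maximized
  regularization, one regressor per target) fitted post hoc on frozen stack
  embeddings and used at deployment.  Training end-to-end *through* a
  Bayesian ridge is not well defined, hence this two-stage reading;
  both heads are retained and selectable.
* **Loss/optimizer**: RMSE over the normalized (EDV, ESV) pairs of a batch;
  Rectified Adam (β = 0.9/0.999, rectification threshold ρ_t > 4).

The network is implemented on a small in-repo reverse-mode autodiff engine
over numpy (`_autodiff.py`: broadcasted arithmetic, matmul, im2col
convolution, 2×2 max pooling, batch normalization composed from reduction
primitives, LSTM steps from matmul/sigmoid/tanh).  Gradients of every
composite the network uses are verified against central finite differences
in the test suite; the engine is deliberately minimal and CPU-oriented.

### Reduced configuration

Full-width training at 150×150 is a GPU-scale job.  The package's
CPU-scale experiments use `reduced_config()`: a 4×4 average-pooling stem
(input 150→37), channels 6…96, 48-d features, 48-d LSTM — same depth, same
block structure, roughly 2·10⁵ parameters.  Structural contracts (five blocks,
channel doubling, 128-d features at defaults, the 150→…→4 pooling chain)
are always asserted on the full-width architecture; learning-behavior
experiments run on the reduced one.

## Experiments

Four arms mirror the training regimes of interest, all on phantom cohorts:
RSO (train on an imbalanced real-like cohort), SSO (train on a uniform-EF
synthetic cohort), RSP (SSO pretraining, then finetuning on the real-like
cohort with a fresh optimizer), RSA (two real-like cohorts combined).  A
single seed governs cohort generation, rendering, initialization and
batching; reports carry the full config echo.

## Evaluation statistics

Per quantity (EDV, ESV, EF): RMSE, MAE, Pearson r with two-sided p (t
transform), Bland–Altman bias and limits bias ± 1.96·SD (sample SD,
ddof = 1), and a percentile-bootstrap 95% CI of the MAE (1000 seeded
resamples).  Model comparison uses the Kruskal–Wallis test on the two
groups' per-subject absolute errors (squared errors via flag): a single
aggregate RMSE per model yields no sample, so the per-subject error
distribution is the tested object.  Degenerate cases are explicit: identical
constant groups return (H = 0, p = 1) with a warning; zero-variance inputs
to Pearson raise.

## Numerical and degenerate-input conventions

* SDT of an all-foreground or all-background mask is undefined (no
  boundary): a dedicated error.
* EF with EDV ≤ 0 raises; ESV > EDV warns and returns a negative EF so the
  EF filter can drop the variant.
* γ small enough to erase a structure warns (`StructureVanishedWarning`).
* Constant images normalize to zeros with a warning.
* Max pooling drops a trailing odd row/column (floor semantics), matching
  the 150→75→37→18→9→4 chain.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence.spawn`; every generator,
  renderer, sampler and training run is bit-reproducible given its seed.

## Problem sizes used in the shipped experiments

Desk-scale defaults — 200-subject uniform-EF training cohorts, 50-subject
held-out sets, the reduced encoder, tens of epochs — were chosen so a full
experiment arm completes in minutes on one CPU core while remaining large
enough for stable correlation estimates.  The full-width architecture and
cohort sizes in the tens of thousands are documented but not exercised by
the shipped experiments.

## Known limitations

* The mask synthesizer treats wall motion globally (interpolation/rescale of
  whole masks): regional wall-motion abnormalities are out of its reach.
* Through-plane (3D) interpolation is not attempted; slices are independent.
* The procedural renderer's realism gap (above) means reported phantom
  accuracies say nothing quantitative about real MRI.
* The Bayesian ridge head is used as a point predictor; its posterior
  variance is not calibrated or exposed.
* ED/ES frame identification and basal/apical plane detection are inputs,
  not outputs, of this package.
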