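# Methods

`fcbtrace` implements the computational pipeline of a provenance
(traceability) study of Fritillariae Cirrhosae Bulbus (FCB), the dried
bulbs of *Fritillaria cirrhosa*: hyperspectral reflectance spectra are
turned into synchronous correlation-spectroscopy images, which a small
residual CNN classifies into five source classes, with a PLS-DA
baseline, targeted alkaloid quantification, mineral element
determination and element–alkaloid correlation analysis alongside.
This note records the models, the parameters that matter, and the
design choices made where the method description left the design open.

## Study design emulated by the generator

Five source classes × 18 bulbs = 90 samples:

| code | provenance | practice |
|------|------------|----------|
| AH-AC | Anhong township | artificial cultivation |
| CZS-FC | Chuanzhusi town | field collection (wild) |
| BM-TC | Bamei town | tissue-culture regeneration |
| SK-FC | Seka township | field collection (wild) |
| YM-AC | Yimu township | artificial cultivation |

### Reflectance spectra

Wavelength grid: 300 equally spaced channels over 400–1000 nm
(≈ 2.01 nm spacing; the instrument's 5 nm figure is an optical FWHM,
not the grid step).  A spectrum is

    r(λ) = b(λ) − Σ_k depth[c, k] · exp(−(λ − μ_k)² / 2σ²) − dip_c(λ) + δ + ε(λ)

* `b(λ) = 0.55 + 0.10 (λ−400)/600` — a gentle upward baseline typical
  of dried plant tissue.
* Absorption bands at μ = 750, 800, 840, 970 nm (C–H overtones of
  sugars/organic acids, flavonoid-associated absorption, sugar C–H,
  and the O–H second overtone tracking moisture), shared σ = 25 nm.
* `depth[c, k]` (unitless reflectance) = base depths
  [0.10, 0.08, 0.08, 0.12] plus class offsets scaled by a single
  `effect_size` dial (default 1, giving per-band class differences of
  up to 0.04).  `effect_size` is the one knob controlling class
  separability: 1 is comfortably separable, ≈ 0.3 produces the heavy
  overlap regime in which the latent-variable baseline degrades while
  the CNN still classifies well, 0 makes all class means identical.
  SK-FC and YM-AC are deliberately the most similar pair at every
  effect size (two neighbouring Ganzi-prefecture sources).
* `dip_c` — the tissue-culture class (BM-TC) is additionally depressed
  by 0.06 over 460–750 nm (sigmoid-tapered edges, 10 nm scale),
  emulating the shorter growth period and lower pigment/saponin load
  of regenerants.
* `δ ~ U(±0.01)` — per-sample constant baseline shift (illumination /
  surface geometry); `ε ~ N(0, 0.01²)` i.i.d. per channel (sensor
  noise).  Within-class variance is not reported in the source study;
  these defaults were chosen once as plausible for ROI-averaged
  reflectance and are not fitted to anything.

The class means have a closed form (`class_mean_spectra`), so tests
can verify the sampler against the generating formula directly.

### Alkaloid and element panels

Per-class concentration ranges (µg/g for peimisine, imperialine,
peiminine, peimine; mg/kg for K, Na, Mn, Fe, Al, Cu, Mg, Zn).  The
ranges measured in the study are used verbatim (SK-FC alkaloids,
BM-TC peimine 64.13–107.42 µg/g, CZS-FC Al/Fe/Mn/Na, AH-AC
K/Mg/Cu/Zn); the unreported ranges follow the study's qualitative
profile — BM-TC highest in every element (nutrient-rich culture
media) and in most alkaloids except peimisine, SK-FC richest in
peimisine/imperialine/peiminine, peimine detectable only in BM-TC.
A (0, 0) range encodes "below the limit of detection": the value is
exactly 0 and flagged.

Cross-panel correlations use a Gaussian copula.  Every element is
configured to correlate negatively with peimisine and imperialine and
positively with peiminine and peimine.  When the requested sign
matrix factorises as `sign[i, j] = s_e[i] · s_a[j]` on its nonzero
support (true of the default), all correlated analytes load on one
shared latent factor z ~ N(0,1) with their sign; the within-range
quantile of analyte x is `Φ(√ρ · s_x · z + √(1−ρ) · ε)` with coupling
ρ = 0.8.  Non-factorisable sign matrices fall back to one latent
factor per alkaloid with sign-weighted element loadings.  Analytes
with no requested sign receive a unit-variance pure-noise latent so
every marginal stays uniform over its range.  Class-mean structure
(BM-TC high in both elements and peimine, SK-FC high in alkaloids but
low in elements) reinforces the same signs — the mechanism that
produces them in real bulbs.  Requested signs outside {−1, 0, +1} or
against an analyte whose range is degenerate in every class are
rejected as infeasible.

### What the generator does not emulate

No scattering physics, no instrument drift or wavelength
miscalibration, no spatial texture (spectra are generated at ROI-mean
level), no metabolome, and element/alkaloid values are range-uniform
rather than skewed like real concentration data.  Passing tests show
the pipeline's statistics and learning machinery behave correctly
under the assumed signal structure, not that the discrimination rates
transfer to real bulbs.

## Radiometric calibration and ROI spectra

Raw counts become reflectance against a panel of known reflectance
(20 % default): `R = (raw − dark) / (panel_mean − dark) × 0.20`, with
the dark frame optional (the vendor handles dark current internally;
the term is exposed because the formula is standard).  Non-positive
panel intensity at any channel is an error naming the channel;
calibrating twice is refused.  A sample's spectrum is the arithmetic
per-channel mean over its ROI pixels.  CSV is the canonical
interchange (wavelength column + one column per sample, labels in a
separate table); wavelength-grid mismatches are errors, never
silently interpolated.

## Synchronous 3DCOS maps

For m dynamic (reference-subtracted) spectra, the synchronous
correlation intensity is

    φ(v₁, v₂) = 1/(m−1) · S(v₁)ᵀ S(v₂)

With set-mean centering (the default reference; the standard
generalized-2DCOS convention) φ is exactly the sample covariance
matrix of the spectra — symmetric and positive semi-definite.

Per-sample images — the classifier needs one image per bulb, but the
formula defines one matrix per set — use the rank-1 specialisation
`φ = outer(s−ref, s−ref)` with `ref` the **training-set** mean.  The
mean of the per-sample maps times m/(m−1) recovers the full-set map
exactly, so the per-sample images decompose the set-level statistic;
this construction is the single biggest gap the original method
description leaves open, and the only one implementable from the
text.

Rendering maps intensities through fixed global (vmin, vmax) bounds
computed over the training maps (so the intensity scale itself is
class-informative) and resamples bilinearly to the requested pixel
size — 875×656 for display fidelity, 224×224 grayscale for training
(CPU-scale; the information in these smooth maps survives
downsampling, and a nearest-centroid probe at 128×128 is within 5
points of the raw maps).  Rendering is deterministic to the byte;
PNG is the lossless canonical export and JPEG a compatibility option
not used in tests.

## PLS-DA, VIP, PCA, split

PLS-DA: NIPALS PLS2 on one-hot class responses with X- and
Y-deflation; weights unit-norm; predictors autoscaled by default
(standard chemometrics; the original preprocessing is unstated and
the option is exposed).  Prediction is the argmax of the predicted
class responses, ties toward the lowest class index.  Constant
columns get a unit-variance guard.  VIP is Wold's definition with
per-LV explained-Y-variance weights, so Σ VIP² = p and the VIP > 1
threshold marks above-average contributors.  PCA is centred SVD with
the largest-|loading| sign convention.  The 50/25/15
train/test/external split is a seeded uniform random partition
(stratification available but off by default, matching plain random
sampling).

## The 12-layer residual network

Architecture: stem 3×3 convolution (stride 2) + batch-norm + ReLU +
average pooling, then five residual blocks — identity(16),
downsample(32), identity(32), downsample(64), identity(64) — global
average pooling, dense softmax head.  Each block is
conv–BN–ReLU–conv–BN with the additive skip `y = F(x, W) + x` and a
final ReLU; downsampling blocks stride 2 with a 1×1 projection (+BN)
on the skip path.

Counting rule (audited by `ResNet12.layer_audit`): stem (1) + 5
blocks × 2 convolutions (10) + dense head (1) = 12 weight layers; the
two projection shortcuts carry parameters but are not counted,
following the usual depth-naming convention.  Total ≈ 170 k
parameters.

Two choices departed from the obvious defaults after the obvious
defaults failed:

* **Average (not max) pooling in the stem, with an adaptive factor**
  so the first residual block sees ≈ 28 px regardless of input size.
  The correlation maps are smooth; max pooling propagates pixel
  noise peaks and the network then plateaus below perfect test
  accuracy at 224×224, whereas averaging suppresses exactly that
  noise.
* **SGD with momentum 0.9** (heavy ball), learning rate 0.01, L2
  weight decay λ = 1e−4 on convolution/dense weights (not biases or
  BN parameters).  Momentum-free SGD at this learning rate does not
  reliably converge within the epoch budget on 224×224 inputs.

Batch size 8, epoch budget 50, training stops at the first epoch
whose test accuracy is 100 % (configurable).  Everything runs in
float32 NumPy with im2col convolutions over BLAS; a fixed seed gives
bit-reproducible runs on one machine.  Per-epoch accuracy and
cross-entropy curves are recorded for train and test, with an
exponential-moving-average display smoother (α = 0.6,
`out[i] = α·out[i−1] + (1−α)·values[i]`) that never affects any
reported number.

Evaluation tallies argmax predictions into a K×K confusion matrix
(rows = truth).  Accuracy is trace/total; precision, sensitivity and
specificity are one-vs-rest per class (TP/(TP+FP), TP/(TP+FN),
TN/(TN+FP)) with unweighted macro averages; 0/0 ratios are reported
as NaN and flagged rather than coerced.

## Quantification and correlation track

Calibration curves are unweighted OLS lines signal = a·conc + b on
≥3 standards (≥2 distinct levels); R² is reported and a negative
slope warns.  Tissue content converts as
`conc_solution × extract_volume × dilution / mass` with defaults
1.2 mL and 0.1 g; inverted concentrations ≤ 0 report 0 µg/g with a
below-LOD flag, and out-of-range inversions are flagged rather than
refused.  The dilution multiple is user-supplied (the described
water-dilution step implies but does not state one).

Mineral content follows the national-standard digest formula
`X = (C − C0)·V·1000·f / (m·1000)` mg/kg; a blank exceeding the
sample yields a flagged negative value, never a silent clip.

Element–alkaloid association is pairwise Pearson (default; Spearman
available) with two-sided p-values and the conventional significance
stars; Benjamini–Hochberg adjustment is available but off by default,
mirroring the unadjusted-stars convention of the original analysis.

## Problem sizes and numerical choices

The shipped configuration trains on 50 images of 224×224 in well
under a minute per run on one CPU core and reaches 100 % test
accuracy in 9–42 epochs across seeds; the statistical calibration
suites use 1000 null simulations at n = 90 and 100 generator seeds.
Symmetry of synchronous maps is enforced to 1e−9 (float round-off is
symmetrised away); NIPALS convergence tolerance is 1e−12 on the
score vector; BN ε = 1e−5.  Degenerate inputs (m < 2 spectra, empty
ROI masks, single-class fits, zero-variance correlation columns,
all-identical standards) raise named errors rather than propagating
NaNs.

## Known limitations

* The residual network is a compact NumPy implementation: single
  device, no data augmentation, no GPU path — adequate for the
  90-sample study scale it targets, not for large imaging corpora.
* Per-sample 3DCOS images are rank-1 by construction; if the original
  study built them from repeated scans per bulb, absolute image
  content differs (only the deviation construction is derivable from
  the published text).
* ENVI cube files are not parsed; calibration and ROI extraction
  operate on in-memory arrays, with CSV as the interchange format.
* The generator's uniform-within-range concentrations and Gaussian
  band shapes are conveniences, not fitted models of bulb chemistry.
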