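# Methods

## Wavelet stage

A two-level separable 2-D discrete wavelet transform (PyWavelets filter
banks) decomposes each image; the seven retained subbands are the level-1
details LH1, HL1, HH1 and all four level-2 bands LL2, LH2, HL2, HH2 (the
level-1 approximation is decomposed and discarded). Orientation follows
the standard separable convention (LH = horizontal detail, HL = vertical,
HH = diagonal).

The mother wavelet is configurable; the default is Haar — the simplest
orthonormal choice, with exact rational arithmetic in the oracle tests.
Boundary handling defaults to periodization, under which subband sizes are
exactly half the input per level and the orthonormal transform conserves
energy (coefficient energy equals pixel energy to 1e-6 relative — a
standing test). Odd dimensions are symmetric-padded to even before each
level; padding is recorded in the subband metadata and cropped on
reconstruction. Perfect reconstruction to 1e-8 is asserted for Haar, db2
and sym4 on even and odd shapes.

## Descriptor stage

Each subband is flattened row-major and entries with |v| ≤ `zero_tolerance`
(default 0: exact zeros only — image background and padding produce exact
zeros, and the phantom generator guarantees some) are removed; survivor
order is preserved. Row-major flattening is an arbitrary but fixed choice:
m0 is order-invariant while m2/m4 are not, so fixing the order makes
results reproducible.

Root-squared moments use plain forward differences (non-circular; lengths
N−1 and N−2). The square root is applied to each moment sum — the
"root-squared" convention — and the frequency-domain identities are tested
in that form: m0_raw² equals the DFT power sum of the series, and m2_raw²
the power sum of the differenced series (Parseval).

The power transform m = m_raw^λ/λ uses **λ = 0.1** by default. A λ of
exactly 0 makes the expression undefined; λ ≤ 0 is rejected at
configuration time. λ is recorded in every output artifact.

Guards (all with ε = 1e-12, each firing a named flag carried in a
companion table):

* any log with argument ≤ 0 → log(|arg| + ε). This matters for f2–f4
  (m0 ≥ m2 is not guaranteed after the power transform) and for f7 on
  signals whose Teager sum vanishes (e.g. constants);
* f5 with m0·m4 = 0 → 0;
* f6 divides by |mean| floored at ε (wavelet detail coefficients are
  near-zero-mean by construction, so this guard fires routinely on detail
  bands — the flag, not the value, is the signal there). f6 itself is
  implemented as log(population std / |mean|) of the series, the
  coefficient-of-variation reading of a garbled printed formula.
* A subband that is entirely zero, or leaves fewer than 3 survivors,
  yields the all-zero sentinel row for its seven features and is listed in
  `sentinel_bands`; it never aborts the image.

Optional `normalize_m0` divides each band's m0_raw by the cohort-free sum
of all bands' m0_raw of the same image before the transform (off by
default; cross-band normalization is hinted at but not specified by the
antecedent literature).

## Reduction

PCA (scikit-learn, full SVD) on the 49 features, z-scored by default since
the descriptors mix log and ratio scales; constant columns get a
unit-variance substitute and a flag. Seven components are kept by default;
a cumulative-variance threshold rule is available in the CLI. Component
signs are fixed (largest-magnitude loading positive) for determinism. In
the cross-validated experiment the scaler and PCA are refit inside every
training fold and applied frozen to its test fold; a cohort-level fit is
produced only for the scree report. A resubstitution ("paper mode")
switch trains and evaluates on the full set and emits an information-leak
warning.

## Classifiers

Defaults where the choice was open: KNN k=5 Euclidean; SVM RBF with C=1,
gamma = 1/(p·var); LDA (SVD solver); decision tree with Gini, no depth
limit; CNN with 8 conv filters of kernel 3 (valid padding), one ReLU, two
600-wide fully-connected layers, a 3-way softmax, Adam at 1e-3, 200
epochs, batch 32. The CNN is implemented directly on NumPy arrays with
explicit backpropagation — the input is only 7 values wide, so training is
seconds on one CPU — and z-scores its inputs with training-set statistics
so Adam sees comparably scaled channels regardless of the spread of the
incoming principal components. All stochastic elements (weight init, batch
shuffling, tree tie-breaking, fold shuffling) are seeded; a fixed seed
reproduces every report bit for bit.

ROC scores per family: vote fractions (KNN), leaf class frequencies (DT),
one-vs-rest decision values (SVM, LDA), softmax probabilities (CNN).
AUC is the trapezoid integral of the one-vs-rest step curve; a constant
score column degenerates to the chance diagonal (AUC 0.5, flagged). The
AUC agrees with the Mann–Whitney U statistic divided by n₁n₀ (a standing
test). Class coding is fixed everywhere as HC=1, AD=2, MCI=3.

Evaluation metrics are computed from the pooled cross-validation confusion
matrix: sensitivity_c = 100·C[c,c]/rowsum, precision_c = 100·C[c,c]/colsum
(0 with a flag when the column is empty), accuracy = 100·trace/total.

## Synthetic cohorts

The ring phantom emulates a *spatially normalized* axial slice: an
elliptical brain of roughly uniform tissue (intensity 150) with a brighter
cortical rim (190), small jitter in position and outer size (σ = 0.5%),
and a central dark cavity standing in for the ventricles. The cavity
radius is (0.05 + 0.05·class_signal·rank)·image_size with rank HC=0,
MCI=1, AD=2 and 5% multiplicative jitter — so at `class_signal=1` the
cavity-area ordering HC < MCI < AD holds essentially always, and at 0 the
three classes are draws from one distribution. Gaussian noise (σ = 5
intensity units) is added inside the brain mask only; background and
cavity stay exactly 0, which keeps exact zeros in the level-1 subbands and
exercises the zero-removal path on every run. Images are quantized to
8 bits before use, matching the PNG input format. The texture phantom
instead fills the mask with a sinusoidal grating whose dominant frequency
shifts with class rank.

What the phantom does **not** emulate: anatomy, partial-volume effects,
bias fields, Rician noise, registration error. Passing tests therefore
demonstrate that the pipeline recovers a morphological class signal of
realistic size against realistic within-class variation — not performance
on clinical MRI.

## Problem sizes and tolerances

The acceptance-grade end-to-end checks use cohorts of 200 images per
class at 256×256 — the size of the motivating study design — for both the
separated (`class_signal=1`; decision tree and CNN must reach ≥ 90%
cross-validated accuracy) and the signal-free cohort (all five
classifiers within 33.3% ± 6 points, the 3-class chance band at n = 600).
Unit and property tests run on 16–256 px images and series of length
8–1024; numeric tolerances are 1e-8 for reconstruction/Parseval
identities, 1e-6 for energy conservation and eigenvalue identities, 1e-10
for the scale invariance of f5, and 2% for the sinusoid Teager-energy
closed form at N = 1024.

## Known limitations

* Published headline accuracies on the original MRI cohort are not
  reproducible here because that dataset is not packaged; the worked
  examples recompute the metrics implied by its printed confusion counts.
* The sparseness feature is implemented exactly as printed (no square
  root around the moment ratio, unlike some antecedent descriptor sets).
* KNN distance ties follow scikit-learn's neighbor ordering.
* With λ small, m^λ/λ compresses moments toward a narrow range; f2–f4 can
  sit near their log guards for short series. Flags make this visible.
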