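# Methods

`seedspec` implements a spectra-only workflow for identifying crop-seed
varieties from near-infrared (NIR) hyperspectral images, aimed at the
hard case of hybrid varieties whose seeds look alike: calibration of
raw cubes to reflectance, per-seed mean spectra, chemometric
pretreatment, hybrid wavelength selection (SPA ∪ CARS), and a compact
convolutional classifier that consumes the selected bands through a
learned high-dimensional mapping.  This note records the models, the
defaults and the numerical choices, and what the synthetic benchmark
does and does not demonstrate.

## Reflectance calibration and ROI spectra

Raw digital numbers are converted to relative reflectance with white
(~99% reflectance board) and dark (lens cap) reference frames:

    R = (I_raw − I_dark) / (I_white − I_dark)

applied per pixel and band.  Pixels with |white − dark| below
`1e−6 · max(white)` are dead sensor elements; they are set to 0 with a
warning rather than producing unbounded ratios.  Calibration is
invariant to affine sensor transforms `I → a·I + b` (a > 0), which the
tests check to 1e−12.

Seeds are imaged embryo-up on black paper, so a single NIR band
(default: the band nearest 1100 nm, where seed/background contrast is
high) suffices for segmentation: Otsu threshold, connected components,
discard components under `min_area = 30` px, keep the `n_expected`
largest.  Each seed's region of interest is the central rectangle
covering 60% of its component's bounding box — a fixed stand-in for
"the largest rectangle comfortably inside the seed" that avoids
edge-pixel spectra, which mix seed and background.  Masks are ordered
row-major by centroid so seed-to-label assignment is deterministic.
The seed's spectrum is the arithmetic mean over its ROI pixels.

Both ends of the acquired range (224 bands, 935.61–1720.23 nm) have
poor signal-to-noise; analysis uses the closed interval
949.43–1709.49 nm.  Crop bounds are inclusive because they are
themselves band centres; on the default 224-band grid (step ≈ 3.52 nm)
216 bands survive — the crop never assumes a surviving-band count but
computes it from the grid.

## Pretreatment

1. **Savitzky–Golay smoothing**, window 3, polynomial order 1.  With a
   3-point window an order-2 SG fit reproduces the input exactly, so
   order 1 — equivalent to a 3-point moving average — is the only
   order at which a 3-point window smooths at all.  Edges are
   mirror-padded by one point so all B bands survive.
2. **Maximum normalization (MN)**: each spectrum is divided by its own
   maximum, mapping it into [0, 1].  MN is per-sample because its
   purpose is removing multiplicative scatter differences *between*
   seeds; it is idempotent and scale-invariant, and it is applied
   after smoothing (smoothing a normalized spectrum would shift its
   maximum below 1).

## Wavelength selection

Both selectors treat the q-class task PLS-DA style: labels are one-hot
coded into q response columns, and RMSE/RMSECV pools the squared error
over all q columns.

**SPA** (successive projections algorithm).  A chain is grown from
every possible start band; at each step the band with the largest
residual norm after projection onto the orthogonal complement of the
chain so far is appended (computed on column-mean-centred training
spectra; ties go to the lowest band index).  For each subset size
k ≤ 20 the best chain prefix is the one minimizing validation RMSE of
an intercept-augmented least-squares fit on the one-hot labels; the
criterion curve is this best-RMSE-per-k.  The chosen size is the
smallest k within 5% of the curve's global minimum — the point where
the RMSE "no longer decreases significantly".  Validation uses a
held-out stratified third of the samples (the same 2:1 design used for
model evaluation).

**CARS** (competitive adaptive reweighted sampling), N = 50 Monte
Carlo runs.  Run i fits a PLS regression (up to 10 components,
clipped to the retained-band count with a warning) on a random 80% row
subsample restricted to the currently retained bands, weights each
band by the sum of absolute PLS regression coefficients over the q
responses, and retains the top ⌈r_i · p⌉ bands, where the
exponentially decreasing function

    r_i = a·e^(−k·i),  a = (p/2)^(1/(N−1)),  k = ln(p/2)/(N−1)

falls from r_1 = 1 to r_N = 2/p.  The adaptive reweighted draw is
taken *without replacement* at the full retention count, which makes
it equivalent to the forced top-k selection; the competitive
randomness between runs comes from the row subsampling.  Each run's
subset is scored by pooled 5-fold RMSECV of a PLS model on the full
sample set (folds fixed across runs so scores are comparable); the
minimal-RMSECV subset wins, earliest run on ties.  Because run 1
retains every band, the winner can never be worse than the full-band
model on the same folds.

**Union.**  The final feature set is the sorted set-union of the SPA
and CARS selections — the two methods miss different information, and
the union trades a few extra bands for completeness.

All selector randomness flows from one integer seed recorded in the
result; results carry nm wavelengths so band sets survive re-gridding.

## The classifier

CNNs cannot consume a length-F band vector directly, so the model
first applies a *learned affine map* F → D (D ∈ {192, 768, 3072}) and
reshapes the result — channel-major — into a 3-channel square image
(8×8×3, 16×16×3, 32×32×3).  The affine-map reading of the
"high-dimensional feature mapping" is forced by the parameter
accounting: the printed parameter difference between the D = 768 and
D = 192 variants equals (F + 1)·(768 − 192) with F = 56, exactly an
affine map with bias and nothing else D-dependent.  Five 3×3
convolutions follow (padding 1; stride 1 except stride 2 at layer 3,
so only layer 3 halves the spatial size), each followed by ReLU; then
adaptive max pooling to 1×1 and a single affine layer to q logits with
softmax.  Channel widths are (16, 32, 64, 32, 16) scaled by a depth
factor d ∈ {0.75, 1.0, 1.25} — a raise-then-reduce profile.  There is
no batch normalization and no activation on the mapping layer: the
simplest architecture consistent with the published layer table, and
one that keeps the parameter count in closed form,

    params = (F·D + D) + Σ_l (9·c_in·c_out + c_out) + (c_5·q + q),

which the tests require to match the built network exactly for all
nine (d, D) variants.  MACs (multiply–accumulates per forward pass)
are counted analogously; for (d = 1.0, D = 768, F = 56, q = 7) the
closed forms give 90,567 parameters and 3,987,568 MACs.  Published
figures for this configuration round to 90.73k and 4.05M under a
counting convention we could not reconstruct from any bias/
normalization combination (~0.2% and ~1.5% apart); internal
consistency between formula and network is therefore the contract
this package tests.

### Training

The network is a from-scratch NumPy implementation (im2col
convolutions backed by BLAS; gradient correctness is tested against
central finite differences).  Initialization is uniform
±1/√fan_in per tensor from a single integer seed; optimization is SGD
with momentum 0.9, weight decay 0, initial learning rate 0.01 under
polynomial decay lr(t) = lr0·(1 − t/T)^0.9 — a standard choice for a
"LambdaLR-style" schedule.  The default training length is T = 300
epochs with minibatches of 64: at desk scale, 300 *full-batch* steps
at lr0 = 0.01 measurably stall at chance level (the original regime
paired this learning rate with 10,000 epochs), whereas 64-sample
minibatches give ~2,300 steps and converge; batch size is otherwise a
free parameter and full-batch remains available
(`TrainConfig(batch_size=None)`).  Runs are exactly reproducible for
a fixed seed.

### Evaluation

Stratified k-fold cross-validation assigns each class's shuffled
members round-robin to folds, so 7 × 105 samples under 3 folds give
exactly 35 per class per fold: 245-sample test sides and 490-sample
training sides, the 2:1 design.  Reports contain train/test accuracy,
the q×q confusion matrix (rows = truth), macro one-vs-rest precision
and recall (a class never predicted contributes precision 0, with a
warning), and the analytic parameter/MAC counts.

## The synthetic benchmark

The raw seed images behind the original study are not deposited, so
the package ships a generator that emulates the study design: 7
classes × 105 seeds, 224 bands over 935.61–1720.23 nm.  Each class's
profile is a shared smooth quadratic baseline (reflectance ~0.4–0.9)
minus Gaussian absorption dips (FWHM 40 nm) at class-specific centres;
the centre pool staggers 8 wavelengths over 1000–1630 nm and
consecutive classes share one centre with different depths
(0.10–0.30), emulating the similarity of half-parent hybrids.  Samples
are `scatter · profile + noise` with multiplicative scatter uniform in
[0.8, 1.2] — applied *before* the additive noise (σ = 0.005) so that
MN, not smoothing, is what removes it.  A miniature cube generator
places elliptical "seeds" over a near-dark background and builds raw
digital numbers from the very reference frames the caller will
calibrate with, so the full image path (calibrate → segment → mean
spectra) is testable end to end.

What passing the synthetic benchmark shows: every stage is wired
correctly, the selectors find planted informative bands (≥80% of dip
centres within ±3 bands of the union set across seeds), and the
classifier separates classes whose differences are localized
absorption features under scatter and noise.  What it does not show:
performance on real seeds, whose class differences are broader,
weaker and chemically confounded — the generator has no detector
drift, no spatial non-uniformity, no wavelength-correlated noise, and
its classes are more cleanly separable than real varieties (the CNN
reaches ~100% test accuracy at desk scale, where the original study
reports 96.65%; the benchmark requires ≥95% and that the D = 3072
mapping not beat D = 768, and equality is an accepted outcome on data
this separable).

## Problem sizes and numerical choices

* Desk-scale training: 300 epochs, minibatch 64.  The D = 768 model
  is cross-validated over all 3 folds; the D = 3072 comparison model
  is trained at equal epochs on fold 1 only (one 300-epoch D = 3072
  fold costs several minutes of single-threaded BLAS; its role is the
  qualitative does-not-beat comparison, not a CV estimate).
* All tie-breaks are deterministic: lowest band index (SPA picks,
  CARS weight ranking), earliest step (RMSE/RMSECV minima), first
  maximum (argmax pooling).
* Degenerate inputs raise rather than propagate: empty ROI masks,
  non-positive rows under MN, zero probability at the true class
  (clamped at 1e−12 with a warning), selector sizes exceeding the
  rank-feasible bound.
* Model checkpoints use NumPy's `.npz` container; they are portable
  across platforms but not guaranteed bit-identical across NumPy
  versions.
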