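# Methods

`cottonvit` implements a hyperspectral chemometrics workflow for
predicting seed vitality (seedling height, cm) from plate images of
cottonseeds, together with a synthetic plate generator that stands in
for the unavailable laboratory data.  This note documents the models,
the defaults and why they were chosen, and what the synthetic study
does and does not demonstrate.

## The synthetic plate study

The generator emulates a push-broom VNIR acquisition: 8 plates of 25
seeds on a 5×5 grid (200 seeds), 520 bands from 391 nm at a 1.254 nm
step (last band ≈ 1042 nm).  Seeds are ellipses (semi-axes ≈ 6.5 × 4.5
px with 10% jitter and small rotation) on a dark plate background
(reflectance ≈ 0.06); plates are 118 × 118 px.

**Spectral model.**  Each seed *i* has noise-free reflectance

    r_i(λ) = B(λ) · (1 − Σ_k α_k(g_i) · exp(−(λ − μ_k)² / 2σ_k²))

with a smooth continuum `B(λ) = 0.45 + 0.18·tanh((λ−730)/120)` and
three Gaussian absorption features whose depths are affine in the
seed's spectral driver `g_i`: `α_k = 0.22 + s_k (g_i − 10)`.  Defaults
place the centers at 550, 711 and 970 nm (σ = 6, 6, 7 nm; slopes
0.014, 0.018, 0.012 per cm) — a visible pigment feature, the red edge,
and the NIR water band.  The observed mean spectrum is
`a_i·r_i(λ) + b_i + ε` with multiplicative scatter `a_i ~ N(1, 0.05²)`,
offset `b_i ~ N(0, 0.01²)`, and band noise `ε ~ N(0, 0.004²)` that is
shared across the seed's pixels (so region-of-interest averaging does
not cancel it); independent per-pixel shot noise of the same sd is
added on top.  Raw captures are synthesized by inverting the two-point
reflectance correction against a smooth lamp profile (≈3000–3600
counts) and a flat dark frame (60 counts), stored as float32, so the
correction recovers the planted reflectance to ≈2·10⁻⁸.

**Vitality and texture.**  Vitality is `v ~ N(10, 2²)` cm, truncated
positive.  Each seed also carries a texture latent `t`.  In the
default mode spectra are driven by `v` itself and `t = ρ·z + √(1−ρ²)·u`
with coupling ρ = 0.6 to the spectral latent `z`.  In
`fusion_sensitive` mode `v = 10 + 2·(0.70·z + 0.65·t + 0.296·e)` with
`t ⊥ z`, so image texture carries vitality information the spectra
alone cannot supply — the regime in which feature fusion should help.

The texture latent is expressed as spatial *roughness*: each seed's
intra-seed intensity field is a unit-variance mix of a coarse
(Gaussian-smoothed, σ = 1.2 px) and a fine (pixel-scale) noise
component, orthonormalized over the seed mask, with fine fraction
`0.15 + 0.7·logistic(t)`, applied multiplicatively at 6% amplitude.
Amplitude itself cannot carry the signal because GLCM quantization
spans each patch's own range and is therefore amplitude-invariant;
spatial frequency content survives quantization.  With the defaults,
mean GLCM contrast across the three planted bands tracks the latent at
Spearman ρ ≈ 0.82.

**Choice of magnitudes.**  The laboratory values (absorption
positions, widths, noise levels) are not published; the defaults were
fixed once so that the planted signal is strong but not trivial:
ordinary least squares on the three planted bands reaches R ≈ 0.99,
band-level SNR is ≈4–5, and wavelength selection is genuinely needed
before regression.  All magnitudes are `SimConfig` fields.

**What the simulation does not capture.**  Real seed coats have
structured (non-Gaussian) texture, specular highlights, and
wavelength-dependent texture; real spectra have correlated band noise,
water-vapor artifacts and instrument drift; seed shapes are not
ellipses.  Passing results here demonstrate that the pipeline's
machinery is correct and that it recovers signals of the planted form
— not that the specific R/RMSE levels transfer to laboratory data.

## Pipeline stages

**Calibration.**  `S = (O − Y)/(X − Y)` elementwise.  White/dark
frames are averaged along the scan axis by default (references are
captured once and carry shot noise).  Pixels with `X = Y` are set to 0
and counted in a warning rather than propagating NaN.

**Partitioning (SPXY).**  Joint distance
`d = d_X/max d_X + d_y/max d_y` (Euclidean on spectra, absolute on
vitality); the mutually farthest pair seeds the training fold, then
greedy max–min selection to ⌊0.7·n⌋ = 140 train / 60 test.  The split
is computed once on raw spectra and shared by every grid cell so that
pretreatments and models are compared on identical folds.  Ties break
to the smallest index; the procedure is deterministic.

**Pretreatments.**  SNV (per-row standardization, sample sd, ddof=1
repo-wide), MSC (per-row affine regression against the training-mean
reference, frozen at fit time), SG (Savitzky–Golay, window 11, order
2, edge windows evaluated from the terminal polynomial fits).  Window
and order are unpublished for the original study; 11/2 is common NIR
practice and is config-exposed.  Everything follows a fit-on-train /
apply-to-test contract even where the operation is row-local.

**SPA.**  For every candidate start column a greedy chain is grown by
maximal norm after projection onto the orthogonal complement of the
chosen columns; every chain prefix is scored by MLR RMSE on an
internal validation fold (an SPXY 80/20 split of the training fold),
and the global (start, size) minimum wins, up to 30 variables.  One QR
factorization per chain serves all prefixes.  Near-zero projected
norms (relative tolerance 1e-12) terminate a chain, which handles
exact collinearity.

**CARS.**  100 Monte-Carlo iterations, each fitting a 3-component PLS
on an 80% row subsample of the retained variables; weights are
normalized |coefficients|.  The enforced retention ratio follows the
exponentially decreasing schedule with endpoints r₁ = 1 and
r_N = 2/p (the constants are uniquely determined by those endpoints);
after the top-ratio cut, adaptive reweighted sampling (weighted draw
with replacement, duplicates collapsed) picks the working set, and
5-fold RMSECV of that set is recorded.  The `retained_path` diagnostic
reports the enforced (schedule) count, which starts at p and is
non-increasing; the returned set is the working set at the RMSECV
minimum.  Runs are bit-reproducible for a fixed seed.

**Segmentation.**  Otsu threshold → 8-connected components → area
floor (20 px) → labels renumbered row-major by centroid (rows grouped
within 0.6 × median component height).  This deterministic stage
replaces a learned segmenter, which would need annotated real plates;
the evaluation contract is retained: pixel accuracy and mean IoU on
the 2-class problem, in percent.  The printed mean-IoU convention is
the mean over the classes observed in either mask; a class absent from
both is excluded (0/0 is undefined), which is the standard definition.

**GLCM texture.**  Patches are the masked bounding boxes of each seed;
gray levels are quantized to 16 bins spanning the masked range (hence
offset-invariant); offset distance 1, angle 0°, symmetric matrix.
Pairs touching background are dropped so plate pixels never enter the
statistics.  Features per (seed, band): contrast, correlation, energy
(Σp², in (0,1]), entropy (bits, 0·log0 = 0); degenerate marginals
yield correlation 0 with a warning.  Quantization depth, offset, and
angle averaging are unpublished for the original study; the defaults
are conventional and config-exposed.  Full-spectrum extraction gives
520 × 4 = 2080 features per seed.

**Fusion.**  The selected-wavelength block is concatenated with the
texture block of the same bands (4 texture columns per band), so
fused width = 5 × spectral width (e.g. 10 → 50, 45 → 225).

**Models.**
- *PLSR*: autoscaled PLS1, 3 components.  Autoscaling (rather than
  centering only) is deliberate: fused blocks mix reflectance
  (variance ~1e-4) with GLCM features (variance ~1e1), and centered
  PLS lets the high-variance block drown the other — measured on
  fusion-sensitive data, fusion *hurts* under centering-only and helps
  under autoscaling.  Components are capped at the cell's feature
  count; requesting more than the rank is an error.
- *SVR*: RBF kernel, C = 10, ε = 0.1, γ = 1/(VN·var), features
  standardized with training statistics; a small validation-grid
  utility over (C, ε) is provided.
- *1D-CNN*: conv(64, k=3, same) → avg-pool(2) → conv(128, k=3, same) →
  avg-pool(2) → fc(256) → fc(1), ReLU, plain SGD at lr 1e-4, batch 4,
  50 epochs, MSE loss, implemented in numpy with backprop verified
  against central differences.  Inputs *and targets* are standardized
  with training statistics and predictions mapped back: at lr 1e-4 a
  zero-initialized output bias cannot traverse a ~10 cm target scale
  in 50 epochs, so optimization is performed on unit-scale data.  The
  recorded loss curve is on the standardized scale.  Kernel size,
  activation, padding and pooling width are unpublished; the defaults
  (3 / ReLU / same / 2) are conventional and config-exposed.  Inputs
  shorter than 4 (two pool-2 stages) are rejected.
- *Evaluation*: R is the Pearson correlation between predictions and
  observations; RMSE = √(Σ(ŷ−y)²/n).  A printed formula in the source
  literature for R equals a residual-to-total ratio (which approaches
  0, not 1, for good fits); Pearson R is the evident intent and is
  what is implemented.

**Grid orchestration.**  `pipeline.run` executes pretreatment ×
selector × mode × model over the one shared split, logs every stage,
caches texture matrices by band set, and emits one report row per
cell; a failed cell (e.g. CNN on a 3-band selection) is logged and
reported with NaN metrics without aborting the grid.  Per-cell seeds
are derived deterministically from the run seed, so PLSR/SVR rows are
byte-reproducible and CNN loss curves reproduce exactly on one
machine.

## Problem sizes used in tests

The test suite exercises two study sizes: the full default study
(8 × 25 × 520) for the count arithmetic, segmentation, signal-recovery
and fusion checks, and a small study (2 plates × 9 seeds × 60 bands
over the same wavelength span, broader 30 nm features) for the
grid-plumbing, determinism and leakage checks, where the full study
would add nothing but runtime.  Repeat-based claims (CARS recovery,
fusion benefit) use 10 seeded studies each.

## Known limitations

- The Otsu segmenter assumes bright seeds on a dark background and
  will not survive uneven illumination; its near-perfect scores on
  synthetic plates say nothing about real-plate difficulty.
- CARS diagnostics on very clean data can place the RMSECV minimum at
  (or near) the full spectrum, selecting many bands; the planted
  centers are still retained.
- SPA sizes the model by a single validation fold; on small studies
  the chosen subset size is variable.
- GLCM features are computed at one offset/angle; angle averaging is a
  config change away but untested surface.
- The CNN is a faithful small-scale implementation, not an optimized
  one; wide fused inputs (~1000 features) train slowly on one CPU.
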