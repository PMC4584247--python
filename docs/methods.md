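# Methods

This note documents the models, algorithms and numerical choices behind
`hsitss`, and what the synthetic data generator does and does not emulate.

## The measurement model

A push-broom hyperspectral camera records digital counts per pixel and
band. Counts are converted to reflectance with white (~99 % reflectance
panel) and dark (shutter closed) reference frames:

    I = (I_raw − I_dark) / (I_white − I_dark).

Calibrated values are deliberately **not clipped** to [0, 1]: values above 1
betray specular highlights or saturation and are flagged downstream, never
silently altered. A pixel/band where white equals dark is a degenerate
reference and raises an error rather than producing ±inf.

Background is removed by a two-band difference: dark fruit is much brighter
at 893 nm (NIR plateau) than at 569 nm (visible, pigment-absorbed), while a
spectrally flat background has near-equal reflectance at both. Pixels with
`I(893) − I(569) ≥ 0.4` are foreground. Wavelengths are resolved to the
nearest grid band, since real instrument grids rarely contain a named
wavelength exactly. Analysis is restricted to the 420–1000 nm window
(closed interval) to drop the noisy grid edges; on a linear 512-point
380–1030 nm grid this keeps 456 bands.

Each fruit's sample spectrum is the arithmetic mean over its masked pixels.

## Synthetic captures

Because no public capture data exist for this workflow, the generator is a
first-class, tested module. Fruit reflectance is a sum of Gaussian shape
components `(amp_i + sens_i · tss) · exp(−(λ−c_i)²/2w_i²)` with defaults:

| component | center (nm) | width (nm) | amplitude | TSS coupling (refl./°Brix) |
|---|---|---|---|---|
| visible floor | 715 | 500 | 0.05 | 0 |
| NIR peak | 850 | 80 | 0.45 | 0 |
| long-λ shoulder | 1010 | 100 | 0.15 | 0 |
| O–H valley | 970 | 18 | −0.05 | −0.010 |

This reproduces the phenomenology of mature dark berries: visible
reflectance < 10 %, a global maximum within 800–900 nm, and a 960–980 nm
absorption valley whose depth increases linearly with TSS (the valley is
the O–H combination band of water and carbohydrates, so deeper absorption
at higher sugar content is the physically expected sign). The linear
TSS→spectrum coupling is intentional: it is the statistical structure a
linear calibration (PLSR) assumes, so recovery tests have a known truth.

TSS values are drawn from a normal truncated to the observed fruit
population (mean 6.75, SD 1.55, range 3.21–10.99 °Brix). Raw counts are
synthesized as `dark + (white − dark) · R · scatter · noise`, clipped to the
sensor full scale of 1.0 (white-normalized counts), so noise-free captures
calibrate back to `R` exactly — the generator and the calibration are exact
inverses, which the tests exploit. Imperfections:

- **noise_sd = 0.01** — multiplicative per-pixel-per-band sensor noise;
- **scatter_sd = 0.03** — per-pixel multiplicative factor constant across
  bands, emulating the bumpy-surface scatter of an uneven fruit;
- **saturation_rate = 0.005** — fraction of fruit pixels forced to full
  scale at all bands, emulating blooming highlights; flagged as saturated.
- background reflectance is flat 0.25, so its two-band difference is ~0,
  far below the 0.4 mask threshold, while fruit sits at ~0.46.

Not emulated: illumination spectra and their spatial non-uniformity beyond
a smooth band-dependent gain, pigment chemistry (the visible floor is one
wide component rather than anthocyanin/chlorophyll bands), camera PSF, and
inter-fruit shape variability (circular footprints). Consequently, passing
recovery tests show the *pipeline machinery* is correct under the stated
noise model; they do not certify performance on real fruit, where scatter
is structured and the TSS–spectrum link is only approximately linear.

## SPXY partitioning

Calibration/prediction splitting uses joint x–y distances:
`d(i,j) = d_x(i,j)/max d_x + d_y(i,j)/max d_y` with Euclidean `d_x` on
spectra and `|y_i − y_j|` on TSS, then Kennard–Stone maximin selection:
seed with the most distant pair, repeatedly add the sample whose minimum
distance to the selected set is largest. The algorithm is deterministic;
ties break toward the smallest original index (row-major argmax), which
makes the selected *identities* invariant to input permutation. If all
spectra (or all responses) are identical, the degenerate distance block is
dropped and the other distance is used alone. The study ratio is 3:1
(235:75 at the full 310-sample scale).

## Random Frog

Parameters: `T` iterations (10 000 at study scale; a few hundred suffice on
synthetic data and are used in tests), initial subset size `Q = 50`,
variance factor `θ = 0.3`, candidate-pool multiplier `ω = 3`, acceptance
ceiling `η = 0.1`. Each iteration, a candidate size
`Q* ~ round(N(Q_cur, θ·Q_cur))` is clamped to [1, n_bands]. The candidate
subset is built by coefficient ranking:

- `Q* > Q_cur`: draw `ω·(Q*−Q_cur)` random bands from the complement, fit a
  PLS sub-model on the union, keep the `Q*` bands with largest |coefficient|;
- `Q* < Q_cur`: fit PLS on the current subset, keep the `Q*` strongest;
- `Q* = Q_cur`: keep the current subset.

Fitness is 5-fold cross-validated RMSE of a PLS sub-model with latent
variables `min(n_lv_max, |V|, n_train − 1)` (n_lv_max = 5 by default);
leave-one-out inside tens of thousands of sub-fits would be needlessly
expensive, and contiguous folds keep the fitness deterministic. A candidate
no worse than the incumbent is accepted outright; a worse one with
probability `min(η, η·fit_cur/fit_cand)` — η as the ceiling of the
acceptance probability. SP(band) = (iterations whose retained subset
contains the band)/T; selection takes all bands with SP ≥ a cut-off (0.7
and 0.85 in the study), ordered by descending SP, ties by ascending
wavelength. All randomness flows from one seeded generator, so runs are
bit-reproducible.

Note on null behaviour: within one run the retained subsets form a strongly
autocorrelated chain, so even with an uninformative response the per-band
inclusion counts are far more dispersed than a binomial reference; the
meaningful null property is exchangeability across bands, which the test
suite checks with a permutation test over independent seeded runs.

## Calibration models

**PLSR (NIPALS, PLS1).** X and y are mean-centered, not variance-scaled
(reflectance bands share units). Components are extracted sequentially —
weight `w ∝ X_d′y_d`, score `t = X_d w`, loadings `p = X_d′t/t′t`,
`q = y_d′t/t′t`, deflation `X_d ← X_d − t p′` — and the model is collapsed
to `B = W(P′W)⁻¹q` (P′W upper triangular by construction) plus an
intercept. With as many components as the rank of centered X, PLSR
reproduces ordinary least squares, which the tests verify against a
normal-equations oracle and scikit-learn's independent NIPALS. Extraction
stops early if the residual covariance underflows (rank exhaustion); the
LV count is chosen by minimum leave-one-out RMSECV over 1..lv_max,
smallest count on ties.

**LS-SVM.** Dual coefficients and bias solve the KKT system
`[[0, 1′], [1, K + I/γ]] [b; α] = [0; y]`; the first row enforces
`Σα_k = 0`, which every fit satisfies to ~1e−16 and the tests assert. The
RBF kernel uses the convention `exp(−d²/σ²)` — **σ² is the full
denominator, no factor 2** — matching the LS-SVM literature where σ² is
called the bandwidth; note many other libraries use `exp(−d²/2σ²)`, so σ²
values are not directly portable. The system's condition number is checked
(error beyond 1e14) before a dense solve. Hyperparameters come from an
exhaustive grid search (defaults γ ∈ 10^0..10^9, 13 points; σ² ∈
10^−2..10^6, 17 points) under leave-one-out CV, ties to the smallest γ then
σ²; the σ² grid is ignored for the linear kernel, which has no bandwidth.

Metrics are Pearson R and RMSE on calibration, leave-one-out CV, and
SPXY-held-out prediction sets. Model comparisons use the signed percent
change `100·(new − ref)/ref`, reported to 3 significant figures. A constant
prediction vector is reported as R = 0 rather than NaN.

## Pixel-wise chemical maps

A calibrated cube is unfolded row-major into a pixels × bands matrix, the
model predicts every foreground pixel, and the vector is folded back —
`fold(unfold(·))` is the identity, bit-exactly. Model wavelengths are
resolved to nearest grid bands; a mismatch beyond half the grid step is an
error. Both PLSR and LS-SVM families run through this one unfold → predict
→ fold path. For any *linear* model, the footprint mean of the per-pixel
map equals the model applied to the footprint-mean spectrum — the algebraic
bridge between sample-level calibration and pixel-level maps, asserted at
1e−8 in the tests.

Optional denoising applies a 5×5 median filter (reflection padding) to each
needed band image *before* prediction; filtering the final TSS map instead
is available to callers via `median_filter_image` since the equally
defensible alternative order changes little for linear models. Background
pixels carry NaN (never 0 °Brix, a legal concentration). Saturated pixels —
raw counts at sensor full scale in any model wavelength — are flagged and
excluded from map statistics. Maps render on a linear blue→cyan→green→
yellow→red ramp with pure blue/red endpoints at the chosen °Brix range and
neutral gray background.

The published 23-wavelength multilinear model ships as `data/eq12.json`
(intercept 16.207 °Brix; its wavelengths concentrate on the 400–550 and
800–1000 nm regions). Its coefficients belong to the original instrument
and fruit population, so on synthetic captures it yields plausible but not
truth-matching values; it is bundled for evaluating on real 23-band
reflectance vectors and for pinning worked values in tests.

## Scale choices

Test and analysis runs use reduced, stated sizes chosen as the package's
own defaults for desk-scale work: 60-sample analyses (10 captures of 6
fruit), Random Frog at T = 400–500, and a 310 × 456 table where the full
study scale matters (SPXY sizes, full-band PLSR recovery). The study-scale
T = 10 000 is a config value away and changes SP resolution, not mechanics.

## Known limitations

- The Random Frog candidate scheme (coefficient-ranked add/drop with the ω
  pool) is one documented reconstruction of the algorithm family; published
  variants differ in details the original description leaves open, and SP
  values differ in detail across variants while the ranking is robust.
- LS-SVM training is dense O(n³); fine for hundreds of calibration samples,
  not for thousands.
- ENVI I/O covers BIL/BSQ/BIP with little-endian IEEE types and
  wavelength-bearing ASCII headers — the subset this pipeline exchanges —
  not the full ENVI format zoo.
- The synthetic generator's linear TSS coupling makes full-band and
  reduced-band models near-perfect at default noise; it validates
  correctness, not field performance (see above).
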