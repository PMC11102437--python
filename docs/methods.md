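# Methods

## Model and estimation

The package assumes each trial's multichannel signal is generated, to a
useful approximation, by a *linear* time-invariant dynamical system
observed at a fixed sampling interval Δt: x(t + Δt) = **A** x(t).
Exact DMD estimates **A**'s spectral decomposition without ever forming
**A**: with snapshot matrices X = [x₁ … x_{L−1}], X′ = [x₂ … x_L] and a
rank-K truncated SVD X ≈ U S V*, the reduced operator Ã = U* X′ V S⁻¹ is
diagonalised (Ã W = W Λ) and the modes are read off as Φ = X′ V S⁻¹ W.
Each eigenvalue λₖ yields a frequency fₖ = arg(λₖ)/2πΔt (bounded by
Nyquist), a per-second amplitude multiplier rₖ = |λₖ|^(1/Δt) and a
continuous rate ωₖ = ln(λₖ)/Δt (principal branch). Amplitudes solve the
least-squares initial condition b = Φ⁺ x(0) *on the stacked state space*,
because the channel-truncated modes are not a basis for the stacked
state.

### Hankel stacking

Exact DMD expects tall snapshot matrices (dimension ≫ snapshots);
neural data are the opposite (P channels ≪ L samples). The signal is
therefore delay-embedded: h time-shifted copies are stacked row-wise,
giving hP × (L−h) snapshot matrices, with h the smallest integer
satisfying h ≥ (L+1)/(P+1) (and at least 1). Of each hP-dimensional mode,
the first P coordinates (the first delay block) are kept, so the mode
matrix is P × K and the sDM feature matrix is P × P. We read "the first P
coordinates" rather than "the first P mode vectors" because the feature
construction requires exactly a P × P channel-by-channel matrix; the
alternative reading would not produce one.

### Numerical choices

- **Singular-value floor.** Before inverting S, components with
  sᵢ ≤ max(hP, L−h)·ε·s₁ (ε = double-precision machine epsilon) are
  discarded and the effective rank reported; this prevents S⁻¹ blow-up on
  numerically rank-deficient data. A fully zero signal raises a
  numerical-rank error.
- **Dead modes.** Eigenvalues with |λ| ≤ 1e−12·max|λ| have no frequency
  or rate (ln 0); they are dropped with a warning.
- **Mode ordering.** Eigensolvers return eigenpairs in arbitrary order,
  so a canonical deterministic order is imposed: ascending |fₖ|, ties
  broken by the sign of fₖ (negative first), then by descending |bₖ|.
- **Conjugate closure.** Real input makes Ã real, so the eigenvalue
  multiset is conjugation-closed; this is property-tested at tolerance
  1e−8 relative, and the sDM layer *asserts* it by rejecting mode sets
  whose Φ Φ† has an imaginary residue above 1e−8 of the largest real
  entry (configurable).
- **Normalization.** Mode columns are L2-normalized *after* truncation to
  the P coordinates (normalizing before would not yield unit-norm rows of
  the truncated matrix); removed scales are recorded and the stacked
  modes left untouched so reconstruction is unaffected. Zero-norm
  columns are dropped with a warning.
- **Reconstruction** evaluates Σₖ φ̃ₖ e^{ωₖt} bₖ on the stacked modes and
  keeps the first P rows; a horizon with max|Re ω|·t > 700 would overflow
  exp and raises instead.

## Feature layer

sDM features are Re(Φ Φ†) built from unit-norm, conjugation-closed
modes; the matrix is symmetrized against rounding residue (½(M + Mᵀ)),
which is exact for closed mode sets. The feature map ψ is the
column-major vectorization — any fixed order works for inner products;
column-major is fixed for file compatibility. snDM is the diagonal, seDM
the strict upper triangle in row-major channel order (again, any fixed
documented order is valid).

Frequency filtering assigns mode k to the band containing |fₖ| —
conjugate partners always share a band — with half-open [low, high)
intervals and the last band closed at its upper edge, so a partition
reaching Nyquist covers every admissible frequency. Band edges default
to the conventional 0–1, 1–4, 4–8, 8–13, 13–30, 30–80, 80–150,
150–500 Hz ladder. Empty bands yield zero matrices; filtered features
are *not* re-normalized per band, which preserves exact additivity:
Σ_bands Φ Φ†|_band = Φ Φ†.

The PSD baseline is a single Hamming-windowed periodogram zero-padded to
512 FFT points (one-sided, 257-point grid to Nyquist); trials longer than
512 samples are rejected in this mode rather than silently Welch-averaged.
Band power is the mean PSD over bins in [low, high).

## Decoding harness

- **Splits.** Stratified shuffled k-fold (per-fold class imbalance
  minimized) seeded per repeat; contiguous sequential blocks for
  time-series regression targets (deterministic, so repeats collapse).
  Inner folds are built only from outer-training trials; fold
  partitioning is property-tested.
- **Hyperparameters.** Cost grid 10⁻¹…10⁸ (10 values), ridge λ grid
  10⁻⁸…10⁸ (17 values), rank grid defaulting to {25, 50, 100, 200, 300}
  clipped to the data plus the maximum available rank. Rank and
  cost/λ are searched *jointly* in the inner CV (the selection metric is
  balanced accuracy for classification — the same metric used for
  reporting — and MSE for regression); ties resolve to the smallest rank,
  then the smallest cost/λ, deterministically.
- **Class imbalance.** Before every fit, minority-class training indices
  are repeated by deterministic cycling until all classes match the
  largest; all original indices are retained. Scoring uses balanced
  accuracy throughout.
- **Solvers.** The model kinds are contracts, not library mandates:
  any L2-SVC supporting precomputed kernels, any L1-logistic solver and
  closed-form ridge qualify. Here: sklearn `SVC` with precomputed or
  linear kernel (identical C parameterization, so kernel-vs-linear runs
  are comparable cost-for-cost), `LogisticRegression(l1_ratio=1,
  solver="liblinear")` wrapped one-vs-rest (liblinear's classic
  multiclass scheme), and `Ridge` with intercept (training-fold
  centering). libsvm can spin effectively forever at very large costs on
  non-separable data, so SVC fits carry a 10⁵-iteration cap; converging
  fits stop far below it. No feature scaling is applied before the SVMs;
  the kernel/feature-map duality makes the kernel and linear routes
  produce label-for-label identical predictions (tolerance only where a
  decision value sits within solver precision of 0).
- **Regression scoring.** Per target dimension and outer fold, the
  Pearson correlation between predicted and true values is Fisher-z
  transformed (atanh, |r| clipped at 1 − 1e−12 to stay finite) and
  averaged over folds and dimensions; constant target dimensions are
  skipped with a warning.

### Descriptive statistics

The ANOVA F map applies the classical one-way F per feature component,
vectorized; zero within-group variance maps to +inf (warned) when group
means differ and to 0 when they do not, edge cases a generic
implementation leaves as NaN. No multiple-testing correction is applied —
the maps are descriptive. Reproducibility is the mean Fisher-z Pearson
correlation over all same-label trial pairs; the snDM–PSD profile
correlates concatenated (trial, channel) feature values against each PSD
bin. All three are validated against their nulls on simulated data
(mean F ≈ df_W/(df_W − 2); mean z ≈ 0).

## Synthetic generators

The generators produce exactly the structure the method assumes —
low-rank oscillatory dynamics plus residual — and deliberately nothing
more. The worked example is the closed-form two-component signal
(13 Hz decaying ×0.25/s and 8 Hz growing ×2/s, sech spatial bumps at
positions ∓3 on an 81-point grid, 0.5 s at 1 kHz), for which every DMD
quantity is known analytically. Labelled trial sets default to a
three-class motor-task-like block: 40 trials per class, 16 channels,
500 samples at 1 kHz; every class shares a sustained broad 10-Hz rhythm
while a 110-Hz (high-gamma-range) component sits at a class-specific
spatial position, with per-trial uniform random phases and white
Gaussian channel noise of sd 0.2 against unit component amplitude —
class identity therefore lives purely in the *spatial amplitude pattern*
of a fast component, the situation somatotopic cortical activations
present. Phase-shuffled surrogates randomize per-channel Fourier phases
(DC and Nyquist untouched), preserving periodograms exactly while
destroying the cross-channel coherence low-rank dynamics require.

What passing tests therefore show: the estimator, feature algebra and
harness are correct on data obeying the model. What they do not show:
performance on real ECoG, which adds 1/f background, nonstationarity,
artifacts, volume conduction and electrode idiosyncrasies that no test
here emulates.

## Problem sizes

Tests and the acceptance script run the study-scale generator defaults
(120 trials of 16 × 500) for the headline decoding checks, with a reduced
cross-validation layout (5-fold outer × 1 repeat, 3-fold inner × 1
repeat and a {4, 8} rank grid) as the package's default demonstration
size; the `CVScheme` defaults remain the full 10 × 10 × 10 × 10 layout
for real analyses. Unit tests use smaller geometries (≤ 8 channels,
≤ 200 samples) where the property under test does not depend on scale.

## Known limitations

- Single-trial DMD only: no streaming/online updates, total-least-squares
  or optimized DMD variants, and no multi-trial joint decomposition.
- The stacking rule ties h to (P, L); extremely short trials (L < 3) or
  single-sample windows are rejected rather than padded.
- The PSD module is a single-window estimator by design; long recordings
  need external epoching first.
- `reproducibility` is O(pairs · features); very large trial counts may
  warrant a blocked implementation.
- Band assignment uses |fₖ| only; a mode at exactly a band edge belongs
  to the upper band (half-open convention) — the edge inclusivity is a
  convention, not an estimate.
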