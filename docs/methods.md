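# Methods

## Problem and signal model

Motor imagery — mentally rehearsing a movement without executing it —
modulates the power of the sensorimotor µ (8–13 Hz) and β (14–26 Hz) rhythms:
the cortical patch controlling the imagined body part desynchronizes (ERD)
while the contralateral patch synchronizes (ERS). A brain–computer interface
turns this into a K-class decoding problem: each imagined movement is a
class, each trial a multichannel EEG epoch, and the discriminative signal is
the *spatial distribution of band-limited variance*, not the mean waveform.

The toolkit implements the classical decoding chain for this signal:

1. **Preprocessing** — 50 Hz notch, 8–26 Hz bandpass, spatial re-referencing
   (common average reference or small Laplacian).
2. **Feature extraction** — common spatial patterns (CSP) for classification;
   periodogram, short-time Fourier PSD and Mallat wavelet sub-band energies
   as inspection/auxiliary features.
3. **Classification** — soft-margin RBF SVMs with (C, g) chosen by stratified
   K-fold grid search, combined into four multi-class topologies: one-vs-rest
   (OVR), one-vs-one voting (OVO), Platt's decision DAG, and a two-layer
   decision tree over class groups.

## Preprocessing

CAR subtracts the instantaneous cross-channel mean; its output is exactly
rank-deficient (channel sums are zero), which matters downstream (see CSP
regularization). The small Laplacian subtracts a weighted neighbor average,
either the plain mean of exactly four neighbors or inverse-distance weights
g_ij = (1/d_ij)/Σ_j (1/d_ij), which sum to one per channel. Neighbor lists
and distances are user-supplied montage metadata; nothing is inferred from
channel names. Channels with missing or wrong-sized neighbor sets raise
errors rather than silently degrading the filter.

Frequency filtering defaults to a 4th-order Butterworth IIR bandpass applied
forward-backward (zero phase, squared magnitude response) and an IIR notch of
quality 30 at 50 Hz. Zero-phase filtering requires epochs longer than three
times the filter order; shorter epochs are rejected. FIR designs (Hamming
window) are available where linear phase in a single pass is preferred.
Filter stability is validated at construction (all poles strictly inside the
unit circle).

## Spectral features

* Periodogram: |DFT|²/N, returned one-sided with interior bins doubled so the
  one-sided sum equals the signal energy (Parseval).
* STFT PSD: Hanning-windowed frames, |frame DFT|²/(2π), default 1 s window
  with 50 % hop — a standard resolution trade-off for 8–26 Hz rhythms. The
  1/(2π) scale is a convention; every classifier-facing use is
  scale-invariant.
* Discrete wavelet transform: PyWavelets' pyramidal (Mallat) filter bank with
  symmetric padding, default family `db4`, configurable. L levels split
  [0, fs/2] into L+1 dyadic sub-bands A_L: [0, fs/2^(L+1)] and
  D_j: [fs/2^(j+1), fs/2^j]; per-component energies and relative energies are
  exposed as features. Note the dyadic band edges are nominal: a db4 filter
  bank has wide transition bands, so a pure tone centered in a sub-band keeps
  roughly three quarters of its energy there, with the rest leaking into the
  adjacent bands; longer filters (db8+) concentrate above 80 %. Decomposition
  is allowed down to signal length ≥ 2^L (perfect reconstruction holds
  regardless), which is more permissive than PyWavelets' recommended maximum
  level.

## Common spatial patterns

For classes A and B, each epoch's spatial covariance is trace-normalized
(R = XXᵀ/tr XXᵀ, making features amplitude-invariant) and averaged per class
with equal epoch weight. The summed covariance R̄_A + R̄_B is eigendecomposed
to form the whitening matrix P = Σ^(−1/2)Uᵀ; the whitened class-A covariance
P R̄_A Pᵀ is then diagonalized, and the filter matrix SF = U_Aᵀ P
simultaneously diagonalizes both classes with complementary eigenvalue
diagonals (λ_A + λ_B = 1). Filters are sorted by descending λ_A, the first
and last m retained, and an epoch is reduced to the 2m features
f_p = log₁₀(var(Z_p)/Σᵢ var(Zᵢ)) of its filtered rows. Log base 10 is a
fixed convention; any base only rescales the features.

Numerical choices:

* Eigenvector signs are fixed by making each filter's largest-magnitude
  coefficient positive, so fits are reproducible bit-for-bit.
* A singular summed covariance raises an error rather than silently
  pseudo-inverting. Optional ridge regularization (R̄ + εI per class, default
  ε = 0) handles rank-deficient inputs; the CLI enables ε = 1e−9 by default
  because its default chain ends in CAR, which guarantees one zero
  eigenvalue. The ridge places the null direction mid-spectrum (λ_A ≈ 0.5),
  where it is never selected.
* Default m = 2 (4 features per pairing), requiring 2m ≤ channels.

Multi-class feature extraction is pairing-specific: OVR-CSP fits one model
per class against the pooled rest; OVO-CSP one per unordered pair, in
lexicographic order. Nodes never share a feature space.

## SVM training and model selection

The binary soft-margin dual (maximize Σα − ½ΣΣ α_i α_j y_i y_j K(x_i,x_j)
s.t. Σα_i y_i = 0, 0 ≤ α_i ≤ C) is solved by libsvm via scikit-learn with a
tight tolerance (1e−8); the box and equality constraints are re-validated on
every returned model, and the dual objective is exposed so the solution can
be checked against an exhaustive QP solve. Kernels: linear, polynomial
(xᵀy+1)^q, RBF exp(−g‖x−y‖²) with g = 1/σ², and sigmoid tanh(βxᵀy+γ).

(C, g) selection: stratified, seeded K-fold cross-validation (default K = 5)
over a row-major grid (C outer), default C, g ∈ {2^−10 … 2^10}. The winner is
the highest mean CV accuracy; ties prefer the smallest C (larger penalties
over-fit more readily), then the first g in grid order — a fully
deterministic protocol. Feature standardization (zero mean, unit variance) is
fit on training folds only, and refit on the full training set for the final
model.

## Multi-class topologies

Every node = its own CSP model + standardizer + grid-searched RBF SVM.

* **OVR** (K nodes): exactly one positive decision names the class
  unambiguously; zero or multiple positives fall back to the maximal decision
  value and set an ambiguity flag.
* **OVO** (K(K−1)/2 nodes): each pair votes; ties are broken by the summed
  signed decision values accumulated toward each tied class, then by the
  smallest class id.
* **DAG** (same nodes as OVO): repeatedly evaluate smallest-id vs largest-id
  of the surviving classes and eliminate the loser — exactly K−1 evaluations.
  Cheap at test time, but a root mistake is unrecoverable (error
  accumulation, demonstrated in the test suite).
* **Two-layer** (3 nodes for K = 4): layer 1 separates a configurable
  bipartition of the classes (default {1,2} vs {3,4}) using CSP fitted on the
  pooled groups; layer 2 holds one pairwise node per non-singleton group.
  Two evaluations per prediction. The grouping is surfaced as configuration
  because no single bipartition is canonical; group-pooled CSP at layer 1 is
  this package's design choice.

## Synthetic data generator

Each class k is defined by a row of a K × channels variance table: latent
sources are white Gaussian noise band-passed to 8–26 Hz (with the package's
own bandpass design, so generator and analyzer agree on the band), rescaled
to the class-k variances, mixed to channels by a full-rank (default random
orthogonal) matrix drawn once per dataset, and summed with broadband sensor
noise. This reproduces exactly the statistical structure CSP assumes —
class-dependent second moments under a fixed linear forward model — and
deliberately omits what it does not test: time-locked ERD transients within
the epoch, non-stationarity across trials, 1/f background spectra, volume
conduction geometry, and artifacts (blinks, EMG). Passing the end-to-end
suite therefore demonstrates correctness of the pipeline's mathematics, not
expected accuracy on recorded EEG.

Presets (4 classes, 8 channels, 250 Hz, 4 s epochs, 40 epochs per class;
class k boosts source k):

* **easy**: 4:1 variance contrast, noise σ = 0.2 µV against unit-variance
  sources (≈ +14 dB channel SNR) — every topology should recover ≥ 90 % test
  accuracy, and in practice reaches 100 %.
* **hard**: 2:1 contrast, noise σ = 3.0 µV (≈ −9.5 dB). Whole-epoch variance
  features over 4 s are extremely robust, so mild noise barely dents
  accuracy; σ = 3.0 was chosen as the regime where the pipeline degrades
  visibly (OVO ≈ 79 %) while staying well above the 25 % chance level.

Train and test sets are independent draws sharing one mixing matrix; the
test stream is seeded with seed+1. Given a seed, output is byte-identical
across runs.

## Problem sizes

The test suite and the reproduction script run the full pipeline at the easy
preset's native size (160 train / 160 test epochs of 8 × 1000 samples) for
the four-topology end-to-end check, and smaller 64-sample/12-epoch problems
for structural tests, which keeps the complete suite under a couple of
minutes on one core.

## Known limitations

* The EDF writer emits a minimal single-record, 16-bit file — sufficient for
  fixtures and synthetic exports, not a general-purpose EDF+ exporter
  (no annotations, no multi-record segmenting).
* No artifact rejection, resampling, filter-bank CSP, shrinkage covariance
  estimators, probability calibration, or online adaptation.
* The all-at-once multi-class SVM formulation (a single joint optimization
  over K hyperplanes) is intentionally not implemented; all topologies are
  combinations of binary machines.
* Chance-level and accuracy claims are specific to the synthetic generator's
  stationary-source model; see above.
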