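# Methods

This note documents the models, estimators and numerical choices behind
`fractalconn`, in the order data flows through the package.

## Signal model

Channels are modeled as unit-variance fractional Gaussian noise (fGn,
stationary, Hurst exponent H ∈ (0,1)) or fractional Brownian motion (fBm,
the running sum of fGn increments, B_H(0)=0).  A connected pair is the
time-reversible correlated bivariate fGn: autocovariances γ_H1, γ_H2 with

    γ_H(k) = (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) / 2,

cross-covariance ρ·γ_H̄(k), H̄ = (H1+H2)/2, so the lag-0 correlation is
exactly ρ.  A delay Δ (integer samples) is imposed *after* correlating:
the pair is generated with n+Δ samples, channel 2 is shifted, both are
cropped.  fBm channels are cumulative sums taken after the shift.  This
correlate-then-delay order matches the simulation design the estimator
claims rest on; the (H1, H2, ρ) triples that admit no positive-semidefinite
joint covariance are rejected with an explicit error, never approximated.

**Synthesis** is by circulant embedding of the 2×2 covariance sequence
(Chan–Wood / Helgason-style): the embedding eigen-sequences are computed by
FFT, each per-frequency 2×2 matrix is factorized by its symmetric square
root, and complex Gaussian draws are transformed back.  Eigenvalues below
−10⁻⁹ (relative) abort synthesis; small negative rounding is clipped.  One
draw yields two independent realizations (real and imaginary parts), which
the Monte-Carlo layer exploits.  Sample autocovariances and cross-covariances
match the closed forms to Monte-Carlo error (tested).

**Trends.**  Additive per-channel trends are scaled so the trend SD equals
`amplitude` × channel SD: random polynomials (degree ≤ 3), sinusoids, or an
independent slow fBm path (H=0.2 by default, the configuration used in the
trend-robustness scenario).  Because the description of the trend
scenario is ambiguous — an additive contaminant versus an fBm *component* —
both are available: `TrendSpec(trend_kind="fbm", ...)` and the benchmark
presets `fig5-trend` / `fig5-mixed`; neither is presumed.

## Dual-tree complex wavelet transform

Two parallel orthonormal DWTs whose mother wavelets form an approximate
Hilbert pair.  Levels ≥ 2 use an even-length conjugate-quadrature pair with
a half-sample delay offset (the q-shift property), **designed at import
time** by the common-factor method: h0 = q(z)(1+z⁻¹)^K d(z) against
q(z)(1+z⁻¹)^K d̃(z), where d is the order-L maximally-flat (Thiran)
half-sample-delay factor and q comes from solving the half-band condition
linearly and spectrally factorizing.  Defaults K = L = 4 (16-tap filters,
4 vanishing moments).  Level 1 uses a Daubechies-8 pair with a one-sample
decimation offset between trees.  Design invariants (orthonormality to
10⁻¹⁰, shared autocorrelation, −πf phase offset, vanishing moments) are
unit-tested rather than assumed.

The sign s in d = d_a + i·s·d_b and the mother center frequency f₀ are
*measured* from the filter bank (from the conjugated equivalent-filter
response, matching the correlation-based implementation), not hard-coded;
the default bank measures f₀ = 0.6875 cycles/sample and s = −1, with
negative-frequency leakage below 0.5 % at every analysis level.  Octave j
maps to f₀·fs/2ʲ Hz; at fs = 448 Hz octaves 8–12 span ≈ 0.075–1.20 Hz, the
infraslow regime.

Boundaries use symmetric extension; the margin of coefficients whose
support touches an extension is tracked per octave
(m′ = ⌈(m + Lf − 1)/2⌉ through each filtering) and those coefficients are
excluded from every spectral sum.  An octave entirely inside the margin is
still computed but flagged, and flagged octaves are skipped by band
averages.  Non-power-of-two inputs are truncated to a multiple of 2^J with
a logged warning — never zero-padded, which would inject trend-like edges.

## Connectivity indices

The wavelet cross-spectrum conjugates the second channel,
S_ab(j) = mean_k d_a d_b*; hence Im S_ab encodes the lead/lag direction of
channel b relative to a, W-ICOH and W-wPLI negate under argument swap, and
|W-COH| is swap-invariant (all exact, tested without tolerance).  The wPLI
0/0 case (e.g. a channel with itself, where the products are real up to
rounding) is defined as 0 and flagged; "rounding level" means the imaginary
mass is below 10⁻¹² of the total product mass.  Band averages are means of
|index| over unflagged octaves — the absolute value follows the prose
definition of the band index (the displayed formula omits it, an
ambiguity resolved in favor of the [0,1] scalar).

The Fourier side has two dialects.  The generic Welch machinery
(`fourier_frames`/`fourier_indices`) keeps per-frame short-time coefficients
on the rfft grid, with the Gabor density condition T₀·ν₀ ≤ 1 enforced (at
50 % overlap T₀·ν₀ = ½).  The simulation-comparison dialect
(`fourier_octave_profile`) uses one Hanning window per octave, length
2^(j+2), 50 % overlap, demodulated directly at the octave center frequency
f₀/2ʲ — generically off the DFT grid, exactly as a Gabor transform at
frequencies ℓν₀ is — with no detrending.  All indices are ratios, so the
frame-averaging normalization cancels.

## Hurst estimation

Weighted least squares of log₂ S(j) on j over a declared octave band,
weights n_j, no small-sample log-bias correction; H = (ζ+1)/2 for the fGn
class, (ζ−1)/2 for fBm.  The class is declared by the caller, not inferred.
Recovery is within ±0.05 for H ∈ {0.5, 0.7, 0.8} at n = 2¹⁴ (tested).

## Monte-Carlo benchmarking and reference values

`run_grid` simulates N pairs per (ρ, Δ) cell and records per-octave and
band estimates for any subset of the six estimators.  Per-cell seeds derive
from (master seed, ρ, Δ) — not from grid position — so cells are
exchangeable under axis reordering and any cell is reproducible in
isolation; a synthesis failure marks the cell failed and the run continues.

Ground truth for COH/ICOH integrates the exact model spectra against the
squared analytic-wavelet response per octave.  The fGn density uses the
classical alias-sum form (truncated at ±200 terms with an integral tail
correction; it integrates to the unit variance to ~10⁻⁶), the cross-density
is ρ·S_H̄(f)·e^{i2πfΔ}, and each fBm channel contributes the discrete
integrator 1/(1−e^{−i2πf}).  The integral reference reproduces long-run
empirical estimates within Monte-Carlo error (cross-validated in the
tests).  The wPLI expectation is not a spectral ratio, so its reference is
a long-run empirical mean (defaults n = 2¹⁶–2¹⁸, with its SE attached).
The Fourier estimators are judged against the same per-octave truth as the
wavelet ones; within-octave resolution differences are second-order
relative to the effects being measured.

`summarize` reports, per cell/estimator/octave (plus band): mean, SD, 95 %
CI, bias, and **two RMSE readings**: `rmse`, the per-realization
root-mean-square error, and `rmse_mc_mean` = √(bias² + SE²), the error of
the Monte-Carlo mean itself.  The per-realization reading is floored by the
estimator's single-realization noise (≈ 0.04 for a band-averaged index at
n = 2¹⁴), which masks pure-bias failures; the mean-error reading is
bias-dominated at large N and is the appropriate scale for estimator
*consistency* comparisons.  The headline Fourier-vs-wavelet degradation on
fBm uses the mean-error reading per octave with the ratio averaged over
octaves 3–7: on delayed fBm the windowed-Fourier coefficients are dominated
by leakage from the local random trend — a coherent, effectively zero-lag,
*real-valued* contamination — which collapses F-ICOH toward 0 regardless of
the true coupling, while the wavelet's vanishing moments annihilate the
local polynomial behavior and leave W-ICOH unbiased (its per-octave means
match the model reference to ~0.003).  The resulting ratio is 14–20 at
ρ = 0.1 across seeds at N = 200.  For stationary fGn the two estimators are
comparable (ratios near 1), as expected.

## Network statistics

Pairwise matrices hold band-averaged |index| values (diagonal undefined).
Efficiency-cost-optimization filtering sweeps densities {2/M, 4/M, …, ≤ ½},
binarizes by keeping the strongest edges, scores
J(d) = (E_global + E_local)/d with unweighted efficiencies (networkx), and
takes the maximizing density, ties toward sparsity (the sweep ascends and a
later candidate must win strictly).  On unstructured input the selected
mean degree concentrates near 2–4, the known operating point of the
criterion.  Because the normalization behind sub-1 "average
degree" values quoted for comparable analyses is not defined, `average_degree` returns the plain mean
degree 2E/M and `degree_summary` adds the density 2E/(M(M−1)); both are
labeled.  Group contrasts are edge-wise paired t-tests (condition B − A)
with Benjamini–Hochberg FDR across all M(M−1)/2 edges at α = 0.01 by
default; zero-variance edges are flagged and excluded from the correction.
Filtering is intended for group-mean matrices (per-condition mean across
subjects, then ECO), mirroring group-level thresholding.

## What the synthetic data does and does not emulate

The generator reproduces the second-order structure the estimators are
designed for: per-channel scale-free spectra (fGn H ≈ 0.6–1, fBm H ∈ (0,1)),
exact pairwise correlation with sample delays, slow additive trends, and
disjoint-pair network structure (each channel in at most one edge — the
full multivariate selfsimilar model with mixing matrices is out of scope).
It does not emulate multifractality, oscillatory rhythms, measurement noise
spectra, or realistic sensor cross-talk; passing tests therefore certify
estimator behavior under the stated model, not performance on recorded
MEG/EEG data, whose richer structure (see the known gap between wPLI and
ICOH on real recordings) is deliberately outside the simulator.

## Problem sizes and defaults

Simulation experiments default to n = 2¹⁴ samples and N = 200 realizations
per condition (the benchmark CLI's `--full` flag restores N = 1000 and the
full delay grid {0, 1, 2, 4, 8, 16, 32, 64}); ρ presets span 0–0.9 in steps
of 0.1.  The acceptance script runs the three headline experiments in
roughly 15 s on one CPU; the full test suite, including the Monte-Carlo
acceptance checks, in a few minutes.

## Known limitations

* Filter taps differ from the classical tabulated q-shift coefficients (the
  pair is designed, not tabulated); per-octave values shift at the third
  decimal with filter choice, band averages less.
* The delay applies to whole samples only; sub-sample delays require the
  (out-of-scope) operator-fractional model.
* The Fourier octave dialect is one defensible reading of "windows matched
  to the wavelet bands"; absolute Fourier RMSE values (not the wavelet
  ones, nor the qualitative ratios) depend on that choice.
* ECO filtering assumes a connected-enough graph for local efficiency to be
  informative; on an all-zero matrix it returns an empty network with a
  warning.
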