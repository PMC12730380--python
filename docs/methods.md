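# Methods

## Model and measures

All analyses treat each channel pair as a jointly stationary bivariate
process. The directed measures are prediction-error variance *ratios*:

* one-step: I = var(ε)/var(γ), where ε is the innovation of the univariate
  autoregressive representation of the target and γ that of the joint
  representation including the source;
* L-step: I^L = var(ε^L)/var(γ^L), the same ratio when predicting L samples
  ahead. The predictors condition on samples up to and including the
  current time (lags k ≥ 0); a flag (`include_current=False`) switches to
  the strictly earlier past, which shifts each variance to one more
  unpredictable innovation term. The ratio, not its logarithm, is the
  primary statistic; ln I is provided as a derived column for users who
  expect the Geweke log form.

I^L ≥ 1 holds exactly for analytic spectra of causal models (the univariate
predictor can never beat the joint one), with equality iff nothing flows
into the target; on estimated spectra, sampling noise can push values
slightly below 1. I^L → 1 as L → ∞ for any stationary pair, since both
error variances converge to the target's total variance.

Only pairwise GC is implemented. Conditional/multivariate GC, spectral
(frequency-decomposed) GC, and transfer entropy are out of scope.

## Spectral conventions

One convention is used everywhere: two-sided discrete-time spectra on the
grid f_j = j/N (cycles/sample), normalized so that the grid mean
(1/N)·Σ_j S(f_j) equals the lag-0 covariance. Physical Hz appear only at
the reporting layer (f_Hz = f_j · fs; lag_ms = L · 1000/fs, so a 500 Hz
analysis rate yields a 2 ms step). Analytic factors use
Ψ(f) = Σ_{k≥0} A_k e^(−i2πfk); "causal/analytic" always means nonnegative
Fourier indices under this sign convention. With this normalization the
zeroth factor coefficient is directly the innovation square root
(Σ = A₀A₀\*), with no sampling-interval bookkeeping inside factorization.

### Multitaper estimation

DPSS tapers with unit energy make each eigenspectrum unbiased for the
convention above. Defaults NW = 4, K = 7 are field-standard and explicit
configuration, with admissibility K ≤ 2NW − 1 enforced. Per-trial,
per-channel mean removal is the only detrending (segments are short and
typically already high-pass filtered). Eigenspectra are averaged over
tapers and trials into a single matrix per condition (one GC curve per
epoch); the effective degrees of freedom 2·K·trials are recorded. FFT
length is the next power of two ≥ max(requested grid, trial length).
Adaptive (Thomson-weighted) combining is not implemented.

## Factorization backends

Both backends return S(f) = Ψ(f)Ψ(f)\* with Ψ analytic and outer. Every
returned factor is checked against three quantitative contracts:
reconstruction residual (max relative Frobenius error per bin), analyticity
defect (negative-index Fourier energy fraction of the grid values), and the
Szegő/Kolmogorov outerness identity det(A₀A₀\*) = exp(mean log det S). The
factor is unique up to a constant right-unitary; `canonicalize` fixes the
representative with lower-triangular A₀ and positive real diagonal, which
is how cross-backend agreement is asserted. GC is invariant under that
rotation, so backend choice cannot affect the science.

**Scalar (cepstral/Kolmogorov) route.** For a positive scalar spectrum, the
cepstrum c = IFFT(log psd) is projected onto nonnegative indices (indices 0
and N/2 halved) and exponentiated; |s⁺|² then reconstructs the input
exactly at the grid points. Non-positive bins are rejected — the log does
not exist — and flooring is an explicit caller decision, never silent.

**Wilson.** The Newton-type fixed point Ψ ← Ψ·[Ψ⁻¹SΨ⁻\* + I]₊, with the
causal projection halving the k = 0 (and k = N/2) coefficient, initialized
at the Cholesky factor of the grid-mean spectrum. Quadratically convergent;
stops at relative factor change < 1e-9 or 100 iterations, with the
per-iteration reconstruction residual logged in `info["residuals"]`.

**Triangular-plus-unitary (Janashia–Lagvilava-style), channel pairs.**
Stage one is a pointwise lower-triangular pre-factorization from nested
scalar factorizations: M₁₁ = s⁺(S₁₁), M₂₁ = S₂₁/conj(M₁₁), and
M₂₂ = s⁺(det S/S₁₁) — the Schur complement — so S = MM\* on the grid while
M₂₁ is generally non-causal. Stage two right-multiplies by a unitary-valued
U(f) = [[a, b], [−conj(b), conj(a)]] with a, b causal polynomials of degree
d, determined (up to the constant-unitary ambiguity) by the linear
least-squares system that annihilates the strictly negative Fourier
coefficients of the corrected second row; the smallest right singular
vector of that system is the solution. At an exact solution |a|² + |b|² is
automatically constant (it equals a causal function that is also real,
hence anticausal, hence constant), which justifies the final pointwise row
normalization: that normalization makes U *exactly* unitary with det 1, so
the reconstruction Ψ = MU is exact to rounding and the finite polynomial
degree appears only in the measured analyticity defect. The degree starts
at N/8 and doubles while the defect improves, capped at 3N/8 to keep the
system overdetermined. Smooth (analytic-model) spectra converge to
~machine-precision defects; rough estimated spectra bottom out at a defect
set by their own irregularity (the same is true of Wilson's last
multiplication step, at a similar level), so the hard failure gate is a
separate `analyt_tol` (default 1e-3 energy fraction) while contract-level
assertions for smooth spectra use the far tighter values above. Spectra
with more than two channels are directed to the Wilson backend; the
pairwise setting is the one the GC measures are defined for here.

**Near-singular spectra.** Band-passing leaves near-zero power out of band,
making broadband spectra numerically singular. Bins with minimum eigenvalue
below 1e-12 of the global maximum are *rejected*, not silently regularized;
callers who accept the bias may pass an explicit ridge (adds ridge·I).
This keeps an important numerical decision in the caller's hands.

## Exact oracles

The synthetic module makes every stage testable without data:

* **Spectrum**: S(f) = A(f)⁻¹ Σ_w A(f)⁻\* from the VAR coefficients; its
  grid mean is checked against the companion-form Lyapunov covariance.
* **Joint L-step variance**: partial sums of [B_k Σ_w B_kᵀ] with B_k the
  top-left blocks of companion-matrix powers (the Wold expansion).
* **Univariate L-step variance**: the exact marginal autocovariance
  sequence is pushed through a high-order Yule–Walker/Levinson fit
  (`scipy.linalg.solve_toeplitz`), whose AR polynomial is expanded to its
  moving-average form; the order doubles from 200 until the variances move
  < 1e-10, realizing the infimum over finite predictors as a converged
  limit.

The canonical fixture is the bivariate VAR(1) X_n = 0.5X_{n−1} + 0.4Y_{n−1}
+ ε_n, Y_n = 0.7Y_{n−1} + η_n with unit independent innovations: coupling
is strictly Y→X, the companion matrix is triangular (stationarity is
immediate), and the exact one-step ratio is 1.26161.

## Simulation study conditions

The generator draws Gaussian innovations, initializes at zero, and discards
a 1000-sample burn-in; trials use independent child streams of one seeded
generator, so runs are reproducible bit-for-bit. Defaults mirror the
intended application scale: 1 kHz sampling, 1 s analysis segments split
into sub-windows for trial averaging.

* Direction recovery: 100 seeded runs of 40 trials × 1000 samples,
  multitaper (NW = 4, K = 7, 256-point grid), Wilson factorization, call at
  L = 1.
* Surrogate calibration and power: 8 trials × 500 samples (4000 samples
  total), 99 circular-shift surrogates per repetition (p resolution 0.01 at
  the 0.05 level), 100 repetitions per condition. Circular shifts are
  uniform over offsets at least a quarter window from either end;
  trial-shuffle surrogates re-pair source and target trials by a
  fixed-point-free permutation. Surrogates rerun the identical estimation
  settings, re-using cached tapered FFTs where the resampling allows it.
  The surrogate machinery is an optional add-on to the core estimation
  chain, not part of it.

What these synthetic benchmarks establish: the estimation chain is
consistent, directionally accurate, and calibrated *under the generative
assumptions* — linear stationary dynamics, Gaussian innovations, no
common-input confounds. What they do not establish: robustness to volume
conduction and shared reference (which can create spurious zero-lag
coupling between scalp channels), nonstationarity within an epoch, artifact
contamination, or the adequacy of any particular clinical epoch choice.
Cleaning (e.g. ICA-based artifact removal) is assumed done upstream.

## Epoching and filtering conventions

Seconds and 0-based samples, half-open windows [start, end), so adjacent
epochs share no samples and lose none. The reference point (e.g. visually
marked seizure onset) is a user-supplied annotation. Band-pass filtering is
a 4th-order Butterworth applied forward–backward (zero-phase, effective
8th order): a causal filter's frequency-dependent group delay would shift
channels relative to each other and could fabricate lead–lag structure —
fatal for a direction-sensitive measure — so zero-phase filtering is fixed,
not configurable. A band edge at exactly Nyquist is clipped to 0.99·Nyquist
with a logged warning. An analysis window "one second before" a reference
defaults to the interpretation [−2, −1) s (the window *ends* one second
before the reference); both readings are expressible through `EpochSpec`.
Decimation (zero-phase, via `scipy.signal.decimate`) is an explicit option
and never applied by default.

The minimal EDF writer (16-bit, one record per second) exists for fixtures
and round-trip tests; reading goes through mne. CSV uses an optional
leading `time_s` column from which the sampling rate is inferred.

## Known limitations

* The triangular-plus-unitary backend covers one- and two-channel spectra;
  general n would require the row-recursive extension.
* Near-unit-root sources (|d| → 1) inflate the burn-in needed for
  approximate stationarity; the burn-in is a parameter, not adaptive.
* Surrogate p-values inherit the usual conservatism of the +1 empirical
  estimator; n_surrogates < 19 is rejected outright.
* GC on band-limited spectra requires an explicit ridge decision; no
  default regularization is applied, so naive broadband use after an
  aggressive band-pass will (correctly) fail the positive-definiteness
  gate.
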