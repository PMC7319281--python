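# Methods

## Model and statistic

The package tests H0: B = B0 in the functional linear model
Y(t) = alpha(t) + ∫ beta(t, s) X(s) ds + eps(t) on L²[0, 1] (and the scalar
analogue Y = alpha + ∫ X beta + eps).  Curves are represented by their
loadings on orthonormal bases: X_i on {phi_k}_{k≤K}, Y_i and eps_i on
{eta_l}_{l≤L}, the surface beta by the L×K matrix of double integrals
against both bases.  Orthonormality makes every L² inner product a Euclidean
dot product of loading rows; all statistics below are computed in that
coefficient space.  Raw supports [a, b] are affinely rescaled to [0, 1].
Curves observed on a dense common grid are projected onto the basis by
unpenalized least squares.

The test statistic T_n averages, over all C(n, 4) subject quadruples and the
three pairings of each quadruple, the kernel
¼ ⟨X_i1 − X_i2, X_i3 − X_i4⟩ ⟨R_i1 − R_i2, R_i3 − R_i4⟩, where
R_i = Y_i − B0(X_i).  Working with differences makes T_n exactly invariant
to adding any fixed curve to all X_i and any fixed curve to all Y_i, so
neither the intercept nor the predictor mean needs to be estimated.
E[T_n] = ‖C(beta − beta0)‖² with C the covariance operator of X: the
statistic measures the discrepancy B − B0 *after* transformation by C,
which is what lets the test avoid estimating (or inverting) C.

### Closed-form reduction

The quadruple average is never enumerated.  Writing A and B for the n×n
predictor and residual Gram matrices, expanding the kernel product and
counting index coincidences over ordered distinct 4-tuples gives the exact
identity

    T_n = S1/P(n,2) − 2·S2/P(n,3) + S3/P(n,4),

with P(n,m) the falling factorial and, on the diagonal-zeroed Grams,
S1 = Σ_{i≠j} A_ij B_ij, S2 = Σ_{i≠j≠k} A_ij B_jk (computed as
1'AB1 − S1), S3 = Σ over four distinct indices of A_ij B_kl (computed by
inclusion–exclusion as (1'A1)(1'B1) − 2 S1 − 4 S2).  This is O(n²), which is
what makes 1000-replicate Monte-Carlo grids cheap.  The literal O(n⁴)
enumeration (`flute_statistic_naive`) is retained as the definition of
record, and the test suite certifies the reduction against it to 1e-10
relative error across hundreds of random instances.

### Variance plug-in and rejection rule

Under H0 the first-order projection of the U-statistic vanishes (T_n is
degenerate) and n T_n / √(2 tr(Λ²) tr(Σ²)) → N(0, 1), with Σ = var(xi) and
Λ = var(residual loadings).  Both traces are estimated by the pairwise
inner-product plug-in tr(Σ²)^ = R1 − 2 R2 + R3 over distinct index tuples —
algebraically the *same* trilinear form as T_n with A = B = Gram, so the
implementation shares one core routine (each public operation keeps its own
enumeration oracle).  Because with A = B every kernel term is a squared
contrast, the plug-in is provably nonnegative on any PSD Gram; the `clip`
option only guards the zero boundary against float rounding, and a zero
denominator raises a `CalibrationError` rather than producing NaN.

The plug-in formula is written for mean-zero data, so the implementation
mean-centers the loading rows before forming the plug-in Grams (the
statistic itself needs no centering); this keeps the whole standardized test
shift-invariant end-to-end.  A `center=False` switch exposes the uncentered
variant; at the study's sample sizes the difference is numerically
negligible.

The test is one-sided: reject at level alpha when
z = n T_n / √(2 tr(Λ²)^ tr(Σ²)^) ≥ z_alpha, p-value = 1 − Phi(z).  For
scalar responses the residual Gram is the outer product of the scalar
residuals r_i = y_i − ⟨X_i, beta0⟩ and the denominator is
σ̂² √(2 tr(Σ²)^), with σ̂² the sample variance of the centered residuals —
consistent under the null and local alternatives; the estimator is
pluggable.

### Asymptotic power

Under local alternatives the power is Phi(−z_alpha + r_n) with signal-to-
noise ratio r_n = n ‖C(beta − beta0)‖² / √(2 tr(Λ²) tr(Σ²)): exactly alpha
at zero effect, monotone in effect and n, tending to one for any fixed
positive effect.  `asymptotic_power` evaluates this formula.

## Synthetic-data generator

The generator reproduces a standard simulation design for this problem
class, directly in coefficient space (exact under orthonormal bases):

- **Predictor loadings** follow a moving-average factor model
  xi_ik = Σ_{t=1..T} rho_t N_{i,k+t−1} with N_i ~ N(0, I_{K+T−1}) and
  rho_t ~ U(0, 1).  The implied loading covariance is banded with bandwidth
  T − 1 (entry (k, l) equals Σ_t rho_t rho_{t+|k−l|} for |k−l| < T), so T
  controls the range of dependence.  By default the rho vector is redrawn
  for every replicate dataset (`rho_policy="per_replicate"`), treating the
  dependence weights as part of the random design; `"fixed_per_cell"` draws
  once per Monte-Carlo cell.  Defaults: T = 5; T = 11 gives the strongly
  correlated variant.
- **Regression surface** beta(t, s) = |beta|² · exp{(t² + s²)/2}.  The
  surface is separable, so its coefficient matrix is rank one.  Note the
  amplitude convention: |beta|² multiplies the exponential shape directly
  and is *not* the surface's L² norm (the shape's squared norm is ≈ 2.14).
  `normalize_beta=True` instead rescales so the squared L² norm equals
  |beta|², which is the convention the scalar design uses.
- **Scalar coefficients** beta_k = √(|beta|²/K) for all k, so
  Σ beta_k² = |beta|² exactly.
- **Errors**: loadings eps_i ~ N(0, Σ_eps) with Σ_eps = I_L
  (homoscedastic) or diag(1/l) (heteroscedastic); scalar errors N(0, 1).
- Defaults n = 40, K = L = 5, 1000 replicates per cell mirror the
  small-sample regime the test targets; the study grid varies n ∈ {40, 100}
  and K = L ∈ {5, 11}.

What the generator does *not* emulate: non-Gaussian factor distributions,
sparse or irregular sampling of curves, measurement error on the grid, and
per-subject observation grids.  Passing tests therefore speak to the
coefficient-space behavior of the statistic under Gaussian factor designs,
not to smoothing-induced errors in sparse real data.

## Monte-Carlo study and seeding

`flute.study` runs preset grids (functional size/power at two truncations
and two sample sizes; weak vs strong loading correlation; heteroscedastic
errors; scalar response; pure-noise response) and attaches binomial
standard errors √(p̂(1−p̂)/reps) to every rejection rate.  Seeding is
counter-based: replicate r of cell c uses
`SeedSequence(master_seed, spawn_key=(c, r))`, so any cell is bitwise
reproducible in isolation and results are independent of execution order or
parallelism.  Calibration failures are counted and excluded from the
denominator, never silently dropped.  The bundled acceptance script runs
the headline cells at 1000 replicates; the test suite uses 200-replicate
versions with correspondingly widened (±3 SE) bands.

## Numerical choices

- Quadrature: trapezoid rule; basis Grams on a 2001-point grid are identity
  to 1e-6 for Fourier truncations up to 25; surface coefficients use a
  2001-point (1-D, exploiting separability, equivalent to ≥ 401² in 2-D)
  grid.
- Fourier ordering: 1, √2 sin(2πs), √2 cos(2πs), √2 sin(4πs), … — the
  orthonormal forms, required for the coefficient-space inner-product
  shortcut.
- Least-squares projection rejects rank-deficient designs (fewer grid
  points than basis functions) instead of regularizing.
- Degenerate inputs: n < 4 subjects, asymmetric Grams, zero-variance
  residuals and zero trace plug-ins all raise typed errors.
- The weather demo smooths rainfall onto the basis first and takes logs of
  the fitted curve clipped below at 0.05 (raw daily rainfall contains
  zeros); the day grid is rescaled to [0, 1].  All preprocessing choices are
  echoed in the report manifest since none of them is canonical.

## Known limitations

- **Normal calibration needs large truncations.**  The N(0, 1) null limit
  holds as K, L → ∞ with n.  At fixed small truncation the standardized
  null statistic converges instead to a weighted centered chi-square
  mixture with ~K·L terms, which is visibly right-skewed: at K = L = 5 the
  limiting skewness is ≈ 1.0 (and the empirical null skewness at n = 200
  matches), decaying roughly like 1/√(KL) (≈ 0.4 at K = L = 11, ≈ 0.2 at
  K = L = 25).  Consequences: the one-sided test over-rejects somewhat at
  small K, L (empirical size ≈ 0.06–0.08 at nominal 0.05 in the study
  grid), and a high-resolution goodness-of-fit test of z against N(0, 1)
  will reject at these truncations even for large n.  Users wanting exact
  small-truncation calibration should compare against the weighted
  chi-square form or a resampling reference rather than the normal.
- Only dense, commonly-gridded curves are supported; sparse-design
  smoothing is out of scope.
- The statistic tests B = B0; it does not estimate beta or provide
  confidence bands.
- p-values come from the asymptotic normal; there is no permutation or
  bootstrap p-value fallback (the bootstrap utility visualizes the
  statistic's sampling distribution, it does not calibrate the test).
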