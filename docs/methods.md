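# Methods

## Signal model and assumptions

The package models the powder-averaged (direction-free) diffusion-weighted
signal as arising from sub-diffusive water motion described by a
time-fractional diffusion equation. Its solution gives the normalised
signal

    S(q, Δ̄) = S0 · E_β(−D_β q² Δ̄^β),   Δ̄ = Δ − δ/3,

with `E_β` the single-parameter Mittag-Leffler function,
`β ∈ (0, 1]` the fractional order (β = 1 recovers Gaussian,
mono-exponential diffusion) and `D_β` the anomalous diffusion coefficient
in mm²/s^β. Equivalent b-space form: `S(b) = S0·E_β(−b·D_SUB)` with
`b = q²Δ̄` and `D_SUB = D_β Δ̄^(β−1)`. Expanding `log S` at small b links
the model to the conventional quadratic kurtosis representation and yields
the closed forms

    D* = D_SUB / Γ(1+β),    K* = 6 Γ²(1+β)/Γ(1+2β) − 3.

Assumptions worth stating explicitly:

* **Powder averaging first.** Only the geometric mean over
  diffusion-encoding directions is modelled; directional (tensorial)
  kurtosis is out of scope.
* **Gaussian noise on the powder average.** Real-valued reconstructed
  data are assumed, so the per-shell averaged signal carries additive
  zero-mean Gaussian noise of SD σ = 1/(SNR·√N_DIR). Rician/non-central-χ
  magnitude statistics are not modelled.
* **(D_β, β) constant per voxel across diffusion times.** This is what
  lets one joint objective pool observations from any number of Δ blocks:

      min over (D_β, β) of Σ_ij [S_ij − E_β(−D_β q_j² Δ̄_i^β)]²

* **K\* is diffusion-time independent**; apparent DKI metrics fitted to
  sub-diffusive data are not, which the DKI time-dependence experiment
  quantifies.

## Mittag-Leffler numerics

`E_β(z)` is needed on the negative real axis for every forward-model
evaluation inside the fit loop, so accuracy across the whole
(β, z) box reachable by the solver matters. Two branches:

* **Taylor series** of the defining sum with `lgamma`-based terms,
  used for |z| ≤ 2 when β ≥ 0.4 (and |z| ≤ 0.5 for any β, where
  convergence is geometric). Truncation stops when a term falls below
  the tolerance times the partial sum; a hard 500-term cap raises rather
  than returning a silently wrong value. Beyond |z| ≈ 2 at β ≈ 0.5 the
  alternating series loses digits to cancellation (peak term ≫ result),
  which is why the series is also only an *oracle* in tests at small |z|.
* **Spectral-integral quadrature** elsewhere. On the negative axis
  `E_β(−x)` is completely monotone with an explicit spectral density;
  substituting `u = r^β` and then an arctangent map turns the
  Lorentzian-like kernel into a bounded integrand on a finite interval
  that remains well-conditioned as β → 1 (where the kernel degenerates to
  a point mass at u = 1). For large x the integrand is a boundary layer of
  known scale `u ~ 30^β/x`; breakpoints at that scale are passed to the
  adaptive quadrature so the layer cannot be stepped over. Exponents are
  evaluated in log space to avoid overflow at extreme (β, x).

β = 1 is special-cased to `exp(z)`. Validation: `E_1 = exp` to 1e-12;
`E_½(−x) = exp(x²)·erfc(x)` to better than 1e-10 from x = 0 to 4000;
agreement with the truncated series where the series is well-conditioned;
agreement with the large-argument asymptotic expansion
`Σ (−1)^(k+1) x^(−k)/Γ(1−βk)` at x ≥ 200. Complete monotonicity
(0 < E ≤ 1, strictly decreasing in |z|) is property-tested.

## Fitting

Bounded trust-region-reflective least squares
(`scipy.optimize.least_squares`) with objective tolerance 1e-4 and step
tolerance 1e-6. Parameter boxes: D_β ∈ [1e-6, 5e-2] mm²/s^β,
β ∈ [1e-3, 1]; DKI comparator D ∈ [1e-6, 5e-2] mm²/s, K ∈ (0, 3], with
b ≤ 2500 s/mm² enforced (the quadratic model's validity range) and a
single diffusion time per DKI fit. Initial values are mid-range
(D_β = 5e-4, β = 0.8; D = 1e-3, K = 1); the estimates are insensitive to
the start, and an optional multi-start restart exists for non-converged
voxels. When a b = 0 volume is present the data are divided by its
powder-averaged value and S0 is fixed at 1; otherwise S0 is a free bounded
parameter. Powder averaging floors real-valued data at 1e-6 of the voxel's
b = 0 level before taking logs, since measured voxels can be non-positive.
Noiseless round trips recover (D_β, β) to better than 1e-4 relative on the
two-diffusion-time scheme.

## Synthetic study conditions

The generator emulates the two-diffusion-time Connectome-style protocol:
Δ = 19/49 ms, δ = 8 ms, nominal b-tables {50…6000} and {200…17800} s/mm²
(8 shells per Δ), up to 64 directions per shell. Supplied nominal b-values
are authoritative; the pulse formula `(γδG)²(Δ−δ/3)` with the published
gradient ladder gives ≈72 s/mm² where the nominal table says 50, and no
reconciliation is attempted. Arbitrary-Δ schemes for the simulation
experiments are synthesised from the 8-step gradient ladder
(31…290 mT/m) through the pulse formula.

Noise: σ = 1/(SNR·√N_DIR) with N_DIR = 64 throughout, i.e.
σ = 0.0250/0.0125/0.00625 at SNR 5/10/20 (the reference human data sit
near SNR 23, σ ≈ 0.0054). Noise is added to every DW observation of the
normalised signal; b = 0 anchors stay at exactly 1, so no separate b = 0
noise is simulated.

Truth parameters: either the fixed idealised tissue pairs — white matter
(3·10⁻⁴ mm²/s^0.75, β = 0.75, K* = 0.8125) and grey matter
(5·10⁻⁴ mm²/s^0.85, β = 0.85, K* = 0.4733) — or independent uniform draws
D_β ~ U[1e-4, 1e-3], β ~ U[0.5, 1] (K* ∈ [0, 1.7124]), matching the ranges
observed in brain tissue. The uniform draws are independent because no
joint law is established; seed-controlled throughout.

Experiment-specific choices:

* **Diffusion-time count**: per replicate, n ∈ 1…5 diffusion times drawn
  from [δ, δ+50] ms with enforced minimum pairwise separation 30/(n−1) ms
  (rejection sampling); the `2′` control uses two coincident Δs so the
  doubled single-Δ sampling has the same observation count as two distinct
  Δs. 1000 replicates by default; the packaged comparisons use 250 per
  condition, where the observed CV differences (roughly a factor of two
  between one and two diffusion times) dwarf Monte-Carlo error.
* **Δ1/Δ2 grid**: one truth draw per replicate per cell, 500–1000
  replicates; R² of fitted vs true K* per cell with a block-split
  Monte-Carlo standard error.
* **b-subset search**: all C(16, k) subsets for k = 2/3/4 (120/560/1820).
  Each replicate's noise realisation of the full 16-entry table is shared
  across subsets so rankings are not confounded by independent noise; a
  noiseless b = 0 anchor is always included in the subset fits. R² can be
  negative for poor subsets and is reported unclamped.
* **DKI time dependence**: b = {0, 1000, 1400, 2500} s/mm², 21-point
  linear Δ̄ grid on [10, 110] ms for the noisy panel (SNR 20, 95%
  percentile bands over replicates) plus a log-spaced noiseless extension
  for long-time behaviour. One nuance found and kept: with the GM truth
  the noiseless K̂_DKI rises by ~0.3% relative over Δ̄ ∈ [10, ~25] ms
  before its monotone decline toward K*; the effect is invisible at plot
  scale but real, so the packaged checks assert the decline from 30 ms on
  and the long-time convergence of both tissues to K*.

Scaling note: the packaged acceptance computations use 500 replicates per
stochastic benchmark, which puts the Monte-Carlo standard error of the
reported R² near 0.005–0.01; these are the problem sizes the repository's
scripts and tests run at.

## Reproducibility statistics

* **R²** about the mean of the *simulated* (true) kurtosis values.
* **Region pooling**: voxel-count-weighted mean; within-subject pooled SD
  with weights n−1 (between-subject mean differences deliberately do not
  inflate the pooled SD); CV in percent.
* **Tissue contrast** `|μ_WM − μ_GM|/√(σ_WM² + σ_GM²)`.
* **ICC** per voxel across subjects:
  s²_intra = meanᵢ ½[(scanᵢ−m̄ᵢ)² + (rescanᵢ−m̄ᵢ)²],
  s²_inter = varᵢ(m̄ᵢ) with population normalisation (switchable to
  sample), ICC = s²_inter/(s²_intra+s²_inter). Inputs must already be
  co-registered; registration is out of scope.
* The scan–rescan generator draws per-voxel subject effects of SD
  `between_sd` and paired scan/rescan deviations ±e with e of SD
  `within_sd`. The paired (antithetic) construction makes the subject
  mean exact, so the estimator above recovers the nominal
  between²/(between²+within²) exactly in expectation; with independent
  deviations the same estimator would converge to
  (between²+within²/2)/(between²+within²) because half the within
  variance leaks into the inter-subject term. The generator is synthetic
  plumbing for exercising the decomposition, not a model of scanner
  physics.

## What the synthetic conditions do not capture

Passing these benchmarks demonstrates correctness of the numerics,
estimator and experiment logic under the stated noise model — not
performance on real scans. Not emulated: Rician/magnitude noise floors,
echo-time-dependent SNR loss as Δ2 grows, partial-volume mixing,
spatially correlated physiological noise, motion/eddy/Gibbs artefacts,
registration error in scan–rescan comparisons, and anatomically realistic
parameter spatial structure (the phantom is a two-value checkerboard).
Human-data region statistics therefore cannot be reproduced here and are
explicitly outside the test surface.

## Known limitations

* The Mittag-Leffler evaluator handles real z ≤ 0 (plus small positive z
  via the series); complex arguments and the two-parameter function are
  out of scope.
* The fitter clamps β within [1e-3, 1]; flat (no-decay) voxels pin D_β at
  its lower bound and are flagged rather than rejected.
* Direction downsampling uses greedy max-min-angle selection on antipodal
  axes — adequate for SNR bookkeeping (measurement counts), but not an
  optimal spherical code.
* Equal per-observation weighting across Δ blocks in the joint objective;
  shells with different direction counts are not variance-weighted.
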