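# Methods

## Mixture descriptor

A sigma profile is the unnormalized histogram of a molecule's COSMO
screened surface charge density: bin k holds P(σ_k)·A, the surface area
(Å²) with charge density σ_k, so the bins sum to the molecule's total
COSMO surface area. Profiles are consumed as data; computing them
(DFT/COSMO and the averaging/binning into histograms) is out of scope.
The grid is the standard COSMOtherm discretization of 61 bins at 0.001
e·Å⁻² steps; 61 bins at this step size pin the range to −0.030 … +0.030
e·Å⁻², the only convention consistent with a 61-entry vector.

A mixture of up to three components is the concatenation of the
components' profiles, each scaled by its mole fraction — 3 × 61 = 183
entries. Unary and binary mixtures zero-fill the unused slots
(equivalent to x = 0), so all systems share one feature space. The
original slot-assignment rule is not recoverable from the method's
description, so slots are ordered canonically: descending mole fraction,
ties broken lexicographically by compound id. This makes featurization
deterministic and invariant to the order components are listed in. Note
a consequence of concatenation: a 1:1 pair of two compounds with
identical profiles gives [½SP, ½SP, 0], which is *not* the pure
compound's [SP, 0, 0] — slots are positional, not additive. For density
and viscosity the system temperature (K, raw) is appended as entry 184;
melting temperature is composition-only.

## Gaussian-process regression

Labels are modelled as zero-mean jointly Gaussian with covariance from
one of three stationary kernels of the Euclidean feature distance d:

- RBF: σ² exp(−d²/2ℓ²)
- Rational quadratic: σ² (1 + d²/2αℓ²)^(−α), which tends to the RBF as
  α → ∞
- Matérn 3/2: σ² (1 + √3 d/ℓ) exp(−√3 d/ℓ)

always plus a White term σ_W²·δ(i,j) for observation noise. A single
shared length scale is used across all dimensions; normalization is what
makes heterogeneous dimensions (sigma bins, temperature) commensurable.
The zero-mean assumption is satisfied by normalizing labels.

Normalization modes are none, standardization (z−⟨z⟩)/s_z, and
log-standardization (log z − ⟨log z⟩)/s_log z with a fixed 10⁻³ buffer
added inside the logarithm so zero-valued bins stay finite. Moments use
the sample standard deviation (divisor n−1; immaterial at realistic n
but fixed for reproducibility); constant dimensions would give s = 0 and
are assigned s = 1 so they map to zero. Normalizers are fitted on the
training split only — validation and test rows never touch the moments
(verified by a poisoning test).

Hyperparameters maximize the log marginal likelihood
−½YᵀK⁻¹Y − ½log|K| − (n/2)log 2π via L-BFGS-B on log-hyperparameters
with analytic gradients, bounds [10⁻⁶, 10⁶] per parameter, one
deterministic start (σ² = 1, ℓ = median pairwise distance of the
normalized inputs, α = 1, σ_W² = 0.1) plus 5 seeded log-uniform restarts
(two decades around the start); the best final likelihood wins, so the
result is deterministic given the seed and never worse than its start.
Cholesky factorization adds jitter starting at 10⁻⁸ × mean diagonal,
escalating ×10 (logged) to at most 10⁻²; the factorization is cached on
the model for prediction.

Predictive variance includes σ_W² (it predicts an observation, not the
latent function); a flag reverses this. Back-transform under label
log-standardization reports the predictive median exp(μ_log) − 10⁻³ as
the point prediction, a 95% multiplicative band
[exp(μ_log ± 1.96 s_log)], and a delta-method variance — the uncertainty
convention on the log scale is this package's own.

Prediction reductions (the query-kernel dot products) are computed
row-contiguously per query, which makes batched and one-at-a-time
predictions agree bit-for-bit; BLAS matrix-path reductions vary with
batch shape and, amplified through near-singular K⁻¹Y weights, were
observed at ~10⁻⁹ relative.

Model persistence is a single JSON archive (kernel, normalizers,
training matrices, factorization, format version); doubles survive the
JSON round trip exactly, so reloaded models predict bit-identically.

## Datasets, splitting, metrics, benchmark

Datasets are CSV tables (`comp1..3, x1..3, temperature_K, label`);
malformed rows go to a rejection report with reasons, never silently
dropped. The three-way hold-out is 70/20/10 with stratified sampling:
labels are cut into 10 equal-frequency bins, each bin is shuffled by the
seed and allotted by largest remainder, making global fractions exact to
±1 row per stratum and the three label distributions mutually consistent
(KS-checked in tests). The original work's stratum count and allocation
rule are unstated, so its exact 2797/789/399 density split cannot be
replicated; 10 quantile bins is this package's choice.

Metrics: R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², MAE, and for viscosity MALE =
mean |log₁₀ y − log₁₀ ŷ| (base 10 chosen; the base is not specified in
the method's description). Zero label variance yields R² = NaN with a
warning.

The benchmark grid fits one GP per kernel × label-normalization cell
(9 cells; feature normalization fixed to log-standardization, the
selected setting — a 27-cell extended grid varies it too) on the
training split and scores validation R². Viscosity is scored on the
log₁₀ scale throughout, matching how multi-decade viscosity data are
analyzed; a model whose predictions go nonpositive scores NaN. Failed
fits become `failed` rows, not aborts. Rows sort by validation R², ties
by kernel name.

## Screening

All C(n,2) unordered 1:1 pairs are enumerated (for the database's 342
precursors: 58,311), featurized at x = (½, ½) with T = 298 K for
density/viscosity and no temperature for melting, and predicted in one
batch. Gates are hard thresholds on the predicted melting mean: < 275 K
(low mode) or < 300 K (high mode); a conservative option gates on
mean + 1.96 sd. The bi-objective ranking (minimize or maximize both
density and viscosity) uses the rank-sum of within-gate ranks with
viscosity ranked on the log scale — scale-free over viscosity's ~9
decades — with deterministic pair-id tie-breaks; a Pareto-front mode is
available. How the original selection jointly ranked the two objectives
is unstated; rank-sum is this package's choice.

## Chemical-space maps (PPCA)

Probabilistic PCA (x = mean + Wz + ε, ε ~ N(0, σ²I)) is fitted to the
183-entry descriptors (never the temperature) by the closed-form
maximum-likelihood solution: W spans the top-2 principal subspace scaled
by (λ_k − σ²)^½ and σ² is the mean discarded eigenvalue. An EM route is
kept as an independent check (its likelihood is non-decreasing and
converges to the closed-form optimum). Component signs are pinned by
making each component's largest-magnitude loading positive. Projection
returns posterior-mean latent positions rescaled per axis to data units
— the shrunken scores ((λ−σ²)/λ)·Uᵀ(x−mean) — which converge to
classical PCA scores as σ² → 0 and map the training mean to the origin.
Property surfaces over the 2-D map use inverse-distance-weighted
interpolation on a regular grid spanning the coordinates' bounding box,
with exact values at coincident nodes.

## Synthetic data

The generator stands in for the experimental database and commercial
sigma profiles, which cannot ship with the package. Profiles are sums of
Gaussian bumps on the 61-bin grid — one dominant bump near σ = 0 plus
smaller wings, the qualitative shape of real profiles — rescaled to a
total area drawn from 60–250 Å² (typical small-molecule COSMO areas).
Datasets draw 2 components (80%) or 3 (20%), Dirichlet(2) mole
fractions, and uniform temperatures in 278–368 K where applicable.

Labels come from a documented latent function of the descriptor:
"linear-in-moments" (default) is linear in three low-order moments of
log(v + 10⁻³) — property surfaces over profile space are smoothest on
the log scale, the same reason log feature standardization performs best
on real data — and "smooth-RBF-mixture" is a 6-anchor RBF expansion. The
latent is standardized against a fixed 256-mixture reference sample of
its own library, so label distributions are stable across library sizes
and seeds. Property maps: density 1.3 + 0.17z − 5·10⁻⁴(T−298) g/mL
(≈0.8–1.8, like real data), melting 330 + 90z K clipped to 60–650,
viscosity log₁₀η = 1.8 + (decades/6)z − 0.012(T−298), log-normal and
centered at the geometric center of real viscosity data (~4·10⁻³–9·10⁵
cP), spanning ≥ 4 decades at the default `viscosity_decades = 5`. Noise
is additive: label units for density/melting, log₁₀ units for viscosity
(default sd 0.05). All randomness flows from the single spec seed
through named generators.

What passing synthetic tests shows: the machinery — featurization,
leakage-free splitting, likelihood optimization, posterior algebra,
gating, projection — is correct, and the pipeline recovers known smooth
structure at realistic noise. What it does not show: that real DES
property surfaces are as smooth or as low-dimensional as the latent
functions, so accuracy figures on synthetic data do not transfer to real
databases.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small instances — libraries of
12–40 compounds, datasets of 80–500 rows, benchmark fits with 2
restarts — chosen so the whole suite completes in well under a minute
while still exercising every code path at full feature dimensionality
(183/184). The M32 parameter-recovery simulation uses a
jittered-replicate design (25 base points × 4 replicates, jitter sd
0.02) because the noise variance is not identifiable from i.i.d. scattered
inputs at n = 100 — replicated measurements are also how real property
data make noise estimable. The end-to-end viscosity figure is reported
as R² on the log₁₀ scale, as is standard for labels spanning many
decades.

## Known limitations

- No sparse/inducing-point approximations: training is O(n³) and
  comfortable to a few thousand points.
- Single shared length scale (no automatic relevance determination).
- The log-label variance is a delta-method approximation; use the
  multiplicative band for honest uncertainty.
- Screening gates on predictive means by default; enable the
  conservative mode when false liquids are costly.
- IDW surfaces are for visualization, not interpolation-quality
  estimates.
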