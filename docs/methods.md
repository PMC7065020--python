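# Methods

## The estimands

All selection analyses are phenotype-level OLS regressions on standardized
traits `z` (mean 0, sample SD 1; n−1 denominator) and relative fitness
`w = W / W̄` (W = total flower count). The differential `S_j` is the slope
of `w` on `z_j` alone; the directional gradient vector `β` comes from the
linear-terms-only multiple regression; the nonlinear gradient matrix `γ`
from the full second-order model, with pure quadratic coefficients (and
their standard errors) doubled and cross-product coefficients taken as-is.
This is the Stinchcombe bookkeeping: the fitted surface is
`ŵ = a + b'z + z'Hz` and `γ = 2H` elementwise matches doubling only the
diagonal because each off-diagonal pair `z_i z_j` appears once in the
design. p-values for `β` come from the linear model and for `γ` from the
full model (two-model convention); for the doubled diagonal both the
doubled estimate and the underlying coefficient test are reported — they
carry the same t statistic, so no information is lost.

Default standardization/relativization scope is pooled across the two
treatments, with `within_treatment` kept as a sensitivity option. Pooled
scope keeps one z scale, so between-treatment slope differences are slope
differences, not scale artifacts; the heterogeneity ANCOVA therefore always
runs on pooled-scope data. `S`, `β` and `P` (the phenotypic correlation
matrix) satisfy `S = Pβ` exactly when computed on one complete-case set
restandardized within that set; `selection_decomposition` does exactly
this, making the direct-vs-indirect decomposition an algebraic identity
rather than an approximation.

Missing data are handled by listwise deletion per fitted model, with each
result reporting its own `n_used`. Different models therefore run on
different complete-case sets — deliberate, mirroring how such greenhouse
datasets are analysed in practice, and the reason reported df vary across
models.

## Heterogeneous-selection tests

Treatment is coded 0/1 (reference = second declared level, "simple" in the
default design), so each interaction coefficient is the first-minus-second
difference in the corresponding selection coefficient, and its 1-df F test
(squared t) equals the incremental residual-sum-of-squares F for that term.
The implied per-group slopes are algebraically the within-group OLS slopes.
No multiple-testing correction is applied to the primary p-values (matching
standard practice for these designs); a Holm-adjusted column is emitted
alongside for transparency.

## Variance partition

Per trait: `y = Xb + Z_g u_g + Z_gt u_gt + e` with treatment fixed,
genotype and genotype×treatment random, fitted by REML. The restricted
likelihood is profiled over the variance ratios `φ = σ²/σ²_e` (L-BFGS-B on
the non-negative orthant, ftol 1e-12, restarts from a moment-style start,
near-zero, and perturbed points), with `σ²_e` solved in closed form. The
marginal covariance is handled through the Woodbury identity on the
random-effect space (q ≤ 3 × n_genotypes), so each evaluation costs
O(n q²); no sparse machinery is needed at desk scale. Convergence is
declared on optimizer success or a projected-gradient norm < 1e-4 (the
profiled criterion is evaluated with numeric gradients, which bounds the
achievable precision; balanced-design fits agree with closed-form ANOVA
estimators to better than 1e-6).

Random terms are tested by the REML likelihood-ratio χ² against χ²(1).
This reference ignores the boundary problem and is conservative (simulated
type-I error ≈ 2–3% at nominal 5%); the 50:50 χ²(0):χ²(1) mixture is
available behind a flag. The treatment F uses Satterthwaite df:
`df2 = 2 Var̂(c'b)² / Var[Var̂(c'b)]`, with the gradient of the contrast
variance over the variance components by central differences (relative step
1e-5) and the observed REML information by a finite-difference Hessian.
Components estimated at the zero boundary are excluded from the delta
method — this makes the no-random-effects limit collapse exactly to the OLS
residual df — and df2 is capped at the residual df. Exact parity with any
particular external Satterthwaite implementation is not promised; the
agreement target is the approximation family, verified through its limiting
cases. Flowering day is fitted on the square-root scale in the mixed-model
stage only (left-skewed residuals); selection analyses use the raw scale by
default, with a switch.

## Fitness surfaces

Two-trait thin-plate splines: `f(x) = d₀ + d'x + Σ c_i η(|x − x_i|)`,
`η(r) = r² log r`, warp coefficients constrained orthogonal to the affine
null space, solved densely via the bordered (m+3) system. Duplicate
coordinates are collapsed to weighted pseudo-observations (weight =
multiplicity, response = within-location mean); the smoother trace — and
hence GCV — is unchanged by this collapse, while the kernel matrix stays
nonsingular. The smoothing parameter minimizes
`GCV(λ) = n·RSS/(n − tr A(λ))²` over 40 log-spaced values of λ relative to
a data-dependent scale (the mean |K| entry, normalizing for n and
coordinate spread) spanning [1e-8, 1e3], refined by a bounded local search
around the grid minimum. λ → 0 interpolates distinct points; λ → ∞
approaches the affine fit (effective df → 3; edf is monotone in λ). Plain
GCV occasionally undersmooths on pure noise (it selects maximal smoothing
in roughly two-thirds of pure-noise replicates, not always) — a known
property of the criterion, inherited deliberately rather than patched with
an inflation factor. Grid evaluation masks cells outside the convex hull of
the data, because a TPS extrapolates wildly beyond support.

## The synthetic generator

Traits: `trait = mean + g_i + δ·1[complex] + (g×t)_ij + e` with Gaussian
genotype and G×E effects and residuals drawn jointly across traits through
a correlation matrix R. Fitness: expected relative fitness
`1 + β'z + ½ z'γz` on the *population-standardized* traits, scaled by a
per-treatment baseline flower count, plus additive Gaussian noise on the
count scale, floored at 0 and rounded (a Poisson option exists). Evaluating
the surface on standardized traits makes the generating `β`/`γ` directly
comparable to estimated standardized gradients.

The default configuration encodes the reference greenhouse scenario:
20 genotypes × 2 treatments × 6 replicates (N = 240); trait means/treatment
effects near the published trait table (flowering ≈ 44.3 d + 0.6 d in
complex soil; size ≈ 40.7 + 4.8; growth ≈ 3.41 + 0.22); genotypic variances
σ²_G = 30 (flowering), 35 (size), 0 (growth) against residual variances 91,
130, 1.0 — chosen so the per-treatment SEs and the pattern of significant
genotype χ² match the published table — and σ²_GxE = 0 (no G×E was
detected there). Residual trait correlations (−0.2 flowering–size, −0.1
flowering–growth, +0.5 size–growth) give the indirect-selection channel a
realistic magnitude. Fitness baselines are 67.08/58.16 flowers with
β = (−0.28, 0.18, −0.084) in complex and (−0.13, 0.14, −0.10) in simple
soil (the published gradient values), correlational γ(flowering, growth) =
+0.23 / −0.31, and a stabilizing γ(flowering²) = −0.20 in both — the
published quadratic value is not printed in the main tables, so −0.20 is
the package's choice of a clearly-detectable stabilizing strength at this
sample size. Count noise SD is 30 flowers, back-calculated from the
published flower-count SEs after subtracting the surface-driven variance.
Per-trait missingness (0.15 flowering, 0.08 size, 0.04 growth) lands
complete-case model sizes in the ~160–200 range seen in greenhouse data of
this size. Mortality is modeled as independent uniform thinning per trait,
which understates any structured (e.g. treatment-correlated) missingness in
real experiments.

What passing tests show — and don't: recovery and calibration results hold
under Gaussian random effects, a quadratic log-free fitness surface, and
independent missingness. Real data can violate all three (overdispersed
counts, non-Gaussian line effects, informative mortality); the estimators
are standard OLS/REML and inherit their usual robustness, but the
simulation results should be read as verifying the implementation, not as
guarantees about any particular field system.

## Known limitations and deliberate scope cuts

- Per-treatment directional gradients estimated by the linear-only model
  are *not* consistent for the generating β when γ ≠ 0 and the treatments
  shift trait means under pooled standardization (the omitted quadratic
  terms correlate with z through the group mean; bias ≈ Σγμ, up to ~0.04
  at the default settings). The parameter-recovery check therefore uses
  purely directional generating surfaces and group-baseline relativization,
  the regime in which the estimand equals the truth. Count flooring adds a
  further small attenuation (a few hundredths on γ) at the default noise
  level — visible in the generator's own oracle runs and accepted as part
  of a realistic observation model.
- Selection models are phenotype-level OLS on relative fitness, as is
  conventional; no genotype-aware selection ANCOVA, no Poisson/GLM fitness
  models, no canonical rotation of γ.
- The mixed model fits homoscedastic residuals and no Kenward–Roger
  correction; only two treatment levels are supported throughout.
- Replication against the archived original dataset requires the user to
  supply the deposit CSV; the package ships the published reference values
  and tolerances (±0.02 for S/β/γ, ±0.3 for F and χ², ±0.05 for means) and
  the comparison machinery, which the test suite exercises on synthetic
  data of the same schema.

## Problem sizes used in the test and acceptance runs

Identity checks run at the experiment's own scale (N = 240); recovery at
N = 10,000 (250 replicates per genotype×treatment cell); calibration at
500 null replicates (type-I error) and 200 replicates (sign recovery);
LRT calibration at 100–200 REML replicates; surface-shape properties at
40–100 replicates with 31–61 point grids.
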