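# Methods

## Scope and data model

`isodiet` analyses bulk stable-isotope measurements (δ13C, δ15N, C:N)
of a consumer population and candidate prey sources. The atomic record
is one sample's δ13C/δ15N pair with optional C:N, sex and year labels;
group-level inputs (sources, DTDFs) are means ± SD. All δ values are
plain per-mil floats; isotope ratios appear only in the δ-notation
conversion at ingestion.

## Lipid normalization

Lipids are depleted in ¹³C, so lipid-rich tissue biases δ13C low. The
arithmetic correction δ13C_LN = δ13C_bulk + 7.95 (C:N − 3.8)/C:N uses
the C:N ratio as a lipid proxy. Two decisions matter:

- **Trigger.** Normalization is applied to a group only when its *mean*
  C:N strictly exceeds 3.5 (manta muscle at C:N ≈ 3.3 is left
  untouched; zooplankton at 4.3 is corrected). Exactly 3.5 does not
  trigger. Threshold, slope and reference ratio are configurable in
  `LipidNormParams`.
- **Per sample, then average.** The correction is nonlinear (convex) in
  C:N, so applying it per sample and averaging is not the same as
  applying it once to the group means: at the zooplankton moments
  (−20.5 ± 0.6 ‰, C:N 4.3 ± 0.5) the per-tow route averages ≈ −19.7 ‰
  while the one-shot route gives −19.58 ‰. Per-sample application is
  the default and only route in the pipeline; the one-shot number is
  reproducible by calling `lipid_normalize` on the means directly.

The correction magnitude is bounded by the slope (7.95 ‰) only for
C:N > 1.9 (half the reference ratio); below that the formula
extrapolates far outside its calibration range and should not be used.

## Trophic position

T_L = (δ15N_consumer − δ15N_base)/Δ15N + 2.5, with baseline 7 ‰ and a
base level of 2.5 because the baseline pool mixes primary and secondary
consumers. Two elasmobranch Δ15N values (3.7 ‰ and 2.3 ‰) bracket the
uncertainty in discrimination. At the consumer mean of 10.6 ‰ the
formula gives 3.47 (Δ15N = 3.7) and 4.07 (Δ15N = 2.3). Published
point estimates for this system (≈3.4 and 3.7) are not both recoverable
from these inputs by direct arithmetic — the 2.3-DTDF figure would
require a different (higher) baseline — so the package asserts only the
formula's algebra (base-level at the baseline, linearity with slope
1/Δ15N), not those printed values.

## Mixing model

For isotope j ∈ {δ13C, δ15N} and consumer i,

    y_ij ~ Normal( Σ_k p_k (μ_kj + c_kj),
                   Σ_k p_k² (ω_kj² + τ_kj²) + ε_j² )

where μ, ω are source means/SDs, c, τ the DTDF means/SDs (independent
errors convolve, hence the variance sum), p the diet proportions and
ε_j a per-isotope residual SD. This is the standard mass-balance
convention with p²-weighted dispersion. With two isotopes at most three
sources are identifiable (n + 1 rule); the configuration layer enforces
K ∈ [2, 3]. Concentration dependence and elemental-flux weighting are
deliberately not modelled and the API has no hook for them.

**Priors.** p ~ Dirichlet(1) (uniform on the simplex); ε_j ~
Uniform(0, 10 ‰) by default (configurable upper bound). Consumers enter
the likelihood individually, never as a group mean.

**Sampler.** Adaptive random-walk Metropolis-within-Gibbs. The simplex
is reparameterized by additive log-ratios z_k = log(p_k/p_K), whose
Jacobian Π_k p_k makes the z-space target density ∝ Σ_k log p_k under
Dirichlet(1); unconstrained-space proposals mix far better than
simplex-constrained ones. One joint z-update and one update per ε_j per
iteration; proposal scales adapt toward ~30% acceptance during burn-in
only, so the post-burn kernel is fixed and valid. All chains advance in
lock-step as vectorized array operations. Defaults: 4 chains × 10,000
iterations, 1,000 burn-in, thin 1. Convergence is monitored with
split-R̂ and effective sample size (via `arviz`); any R̂ > 1.1 flags the
run as non-converged in the summary and manifest, never silently.

Validation baked into the test suite: the sampler reproduces
Dirichlet(1) moments when the likelihood is disabled; with all SDs at
10⁻⁴ it matches the exact linear mass-balance inversion to < 0.01; the
likelihood matches a term-by-term normal-density oracle; and forward
simulation → fit recovers known proportions with ≥ 85% nominal 95%
coverage.

**Four-model batch.** Models 1–4 cross zooplankton treatment
(lipid-normalized / bulk) with DTDF set (large pelagic sharks
0.9 ± 0.33 / 2.29 ± 0.22 ‰; leopard shark 1.7 ± 0.5 / 3.7 ± 0.4 ‰).
The across-model summary is the arithmetic mean and sample SD of the
four per-model posterior means, per source. Sources are always reported
in input order.

**Reconstituting consumers from printed moments.** When only group
means and SDs are available, individuals are simulated as independent
normals at those moments. For reproduction runs the draw is
standardized so the sample mean and SD equal the stated values exactly
(`match_moments=True`): the printed moments are summary statistics of
the actual sample, and re-simulating them would inject noise (SE ≈
0.13 ‰ on a 75-sample δ13C mean) into precisely the statistics the
model fits. Recovery and property tests use raw (unmatched) draws.

## Isotopic-niche ellipses

SEA = π√det(S) for the sample covariance S of a group's (δ13C, δ15N)
cloud; SEAc = SEA·(n−1)/(n−2). The Bayesian counterpart uses a
conjugate normal–inverse-Wishart model with prior df = 3 (dimensions
+ 1), prior scale = identity, and negligible prior weight on the
location (κ₀ = 10⁻³ centred on the sample mean), giving a closed-form
inverse-Wishart covariance posterior sampled directly — no MCMC. SEA is
computed per draw and summarized by 2.5/50/97.5% quantiles.

Overlap between two groups is computed on the 1-SD standard ellipse
(contour level configurable): uniform rejection sampling inside the
smaller ellipse (200,000 seeded draws by default; sampling the smaller
one makes the estimate symmetric in its arguments), with a 600×600 grid
integrator as a deterministic fallback. Monte-Carlo error at the
default draw count is ≈ 0.2% of the sampled area; tests verify 2%
agreement with closed-form circle–circle intersections.

## Cohort statistics

Two-way fixed-effects ANOVA with sequential (Type-I) sums of squares in
the declared term order, fit by OLS (`statsmodels`). With unbalanced
groups the SS type and order matter; the order is explicit and swapping
the factors is the supported sensitivity check (balanced designs are
order-invariant, and the tests assert this only there). Empty cells
make the interaction inestimable and raise a design error rather than
silently dropping the term. Tukey HSD uses the studentized-range
distribution evaluated numerically (no table lookup); with exactly two
groups it reduces to the pooled t-test via q = t√2.

## Synthetic data

Generators are pure functions of (spec, seed), with the package default
seed 20161130. Consumer simulation draws from the mixing likelihood
itself (so recovery tests are well-posed); isotopes are independent
within a consumer by default, matching the likelihood, with a
correlation knob defaulting to 0. Tow simulation draws independent
normals for δ13C, δ15N and C:N, truncating C:N below at 1. Community
simulation draws labelled bivariate-normal clouds for ellipse tests.

What the generators do *not* emulate: temporal baseline shifts, El Niño
variability, within-individual tissue-turnover dynamics, δ13C–δ15N
correlation induced by shared baselines, and non-normal zooplankton
composition. Passing tests therefore demonstrate internal consistency
of the estimators under the stated distributional assumptions, not
robustness to these real-data features.

## Problem sizes and numerical choices

Reproduction runs use 75 consumers, 35 tows, 4 chains × 10,000
iterations per model (a full four-model suite takes a few seconds);
unit tests use 2 × 3,000 chains, and the recovery study uses 20
replicates of n = 50 consumers at 2 × 3,000. Simplex membership is
checked to 1e-8; covariance degeneracy to det ≤ 1e-12; reported ‰
values are rounded to one decimal in reports (two decimals for
proportions) with full precision retained internally and in manifests.

## Known limitations

- Two isotopes cap the model at three sources; the co-occurring-species
  comparison is therefore external to the mixing model.
- DTDFs for large planktivorous elasmobranchs are borrowed from other
  taxa; the four-model batch brackets, but cannot resolve, that
  uncertainty.
- The residual SD absorbs unmodelled consumer heterogeneity (movement,
  turnover); posterior proportions are sensitive to the DTDF means at
  the ~0.1 level, which is why the model average is reported.
- Ellipse overlap is a geometric statement about 1-SD contours, not a
  probability of shared resource use.
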