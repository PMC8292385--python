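# Methods

## Generative model

An individual's disease liability is

    L = A + R + e,      R = β_LEV · G_LEV,

where `A` is the common-variant polygenic burden with variance
`h²_PB`, `G_LEV ~ Binomial(2, f)` is the large-effect-variant genotype
(Hardy–Weinberg), `β_LEV = sqrt(h²_LEV · var(y) / 2f(1−f))`, and
`e ~ N(0, 1 − h²_PB − h²_LEV)` (minus the interaction variance when an
interaction term is on).  `A` is realized as a weighted sum of
simulated genotypes, not drawn directly: per cohort, `N_PB` causal
variants are resampled from a MAF/LD panel, effects are drawn from the
chosen architecture, and dosages are simulated as independent binomial
counts — the post-LD-pruning idealization.

**Case assignment.**  Under the liability-threshold model a subject is
a case iff `L > t`.  We calibrate `t` by root-finding so the
*population case rate equals K exactly* under the LEV-mixture liability
(`Σ_g P_HWE(g) Φ((βg − t)/sqrt(1 − h²_LEV)) = K`).  With no LEV effect
this reduces to the textbook `t = Φ⁻¹(1−K)`; with a strong rare LEV the
textbook threshold would inflate the case rate by up to ~20% because
the liability is a right-skewed mixture, not a standard normal.  The
prevalence-defining convention `K = E[p]` is applied symmetrically to
the logit model, whose intercept `u₀` is solved by Gauss–Hermite
quadrature plus Brent root-finding (`|E[p] − K| < 1e−6`).  A
`threshold_mode="nominal"` switch restores `Φ⁻¹(1−K)` for comparison.
The conditional-risk identity `P(case | G=g) = Φ((gβ − t)/sqrt(1 −
h²_LEV))` holds for either threshold and is used as the closed-form
oracle in the tests.

**Robustness variants.**  Disease subtypes scale the PB of a random
Bernoulli(minor-proportion) subset by `(1+λ)` without re-normalizing
the liability (the model as usually written; var(L) then exceeds 1 by
design).  The interaction variant adds the standardized product of the
largest-effect common variant's dosage and the LEV genotype, scaled by
`sqrt(h²_interaction)`; the product is not orthogonalized against the
main effects, so total variance carries a small covariance term.  The
dependence variant places the LEV on the haplotypes of the
largest-effect common variant (conditional frequency `f/f_partner`),
realizing D′ = 1.

## Genetic architectures

Effects on standardized genotypes are `β_i ~ N(0, C·s_i)` with
`s_i = 1` (polygenic), `s_i = [f_i(1−f_i)]^(1+α)` (negative selection,
α = −0.37), or `s_i = [f_i(1−f_i)]^(1+α) / (1+l_i)` (LDAK, α = −0.25,
`l_i` the LD score).  `C = h²_PB / Σ s_i` is computed, never sampled,
so calibration is exact.  The LDAK weight is applied inside the effect
variance, which is variance-equivalent to scoring `sqrt(w)`-weighted
genotypes.  Note the direction: relative to the equal-share α = −1
baseline, α = −0.37 gives high-heterozygosity variants *larger*
variance shares; rare variants have larger per-allele effects than
under neutrality but smaller shares than under α = −1.

## The estimated score (PGS) and π₀

Real scores include noncausal variants.  Two contamination mechanisms
are implemented for a noncausal fraction π₀:

- `weighted_nulls` — the scored set keeps the causal-set size;
  `round((1−π₀)·N_PB)` causal variants keep their true weights and the
  rest are replaced by null variants carrying fresh architecture-drawn
  weights.  Covariance algebra gives corr(PGS, PB) = 1−π₀.
- `dropped_causals` (default) — the score is the retained causal subset
  only; corr(PGS, PB) = sqrt(1−π₀).

The published power curve these modes are compared against implies an
attenuation *between* the two (≈ π₁^(2/3)); no construction stated in
the source text reproduces it exactly.  `dropped_causals` matches the
curve closely for π₀ ≤ 0.5 and is therefore the default; at π₀ ≥ 0.7 it
over-predicts power (67% and 30% at π₀ = 0.7/0.9 versus the reference
48.0% and 14.8%), while `weighted_nulls` under-predicts throughout.
Both modes are exposed and property-tested against their attenuation
laws.

## Statistics

- **PB-LEV test**: among cases only, one-sided Wilcoxon rank-sum of the
  PGS of carriers (dosage ≥ 1, dominant coding) vs noncarriers.  Exact
  enumeration when the smaller group has ≤ 8 untied values (the normal
  approximation is conservative there — with 1–3 carriers it rejects at
  ~3% instead of 5%); otherwise the tie/continuity-corrected normal
  approximation.
- **Utility / power**: the fraction of replicates with P < 0.05.
  Replicates with no carriers (or no noncarriers) among cases are
  *untestable* and counted as non-significant — the inability to find a
  carrier is part of the operating characteristic and reproduces the
  utility collapse at f < 0.001.  Consequence: with an inert LEV at
  f = 0.005, K = 0.01, N = 10⁴, ~36% of replicates are untestable and
  the null "utility" is ≈ 5% × 64% ≈ 3.2%, below the naive 5%.
- **Odds ratios**: 2×2 ORs (LEV carriers, or top-q PGS tail, as the
  exposed group) use the Haldane–Anscombe 0.5 correction on zero cells
  and Woolf confidence intervals; per-SD ORs come from within-stratum
  logistic regression on the cohort-standardized score (statsmodels),
  with separation reported as an untestable sentinel.
- **Screening table**: cases ranked by PGS are split into 10 equal bins
  (remainder spread from the lowest bin); the statistic is carriers per
  1000 cases per bin, mean ± sd across replicates, plus the carrier
  proportion below/above the case-score median.
- **QQ pairs**: sorted observed p-values against uniform order-statistic
  means i/(n+1).

## Numerical engine

Per-variant dosages are generated from two 16-bit integer comparisons
per individual (allele present iff a fresh uint16 falls below
`round(maf·2¹⁶)`); a numba kernel fuses generation with the PB/PGS
inner products so a 10,000 × 3,000 cohort replicate costs ~0.1 s
without materializing the matrix.  The materializing path consumes the
random stream in the identical order, and the two are equivalence-tested
on the same seed.  MAFs are effectively quantized to 1/2¹⁶ (relative
error < 0.2% at the 0.01 panel floor); standardization on the hot path
uses the population moments of the quantized frequency, making the
score weights exactly consistent with the generated columns.  The LEV
genotype is drawn from float64 uniforms (no quantization; frequencies
down to 10⁻⁴ matter) and is never resampled when carriers are absent.
All randomness in a replicate flows from one `default_rng(base_seed+r)`;
results are bit-reproducible given the base seed.

## Problem sizes

The reference analyses used 95,593 LD-pruned causal variants and
biobank cohorts up to 361,194 subjects with 500 replicates.  Because
the PB is a variance-calibrated sum, its distribution — and every
downstream statistic — depends on `h²_PB`, not the variant count
(central limit theorem); an equivalence test verifies score moments at
different panel sizes.  Package defaults therefore use 2,000 scored
variants, 200–500 replicates, and cohorts of 10⁴–10⁵ (screening runs
scale biobank n down to 50,000; the yield statistic is a proportion, so
scaling changes only its Monte-Carlo error — also tested).

## Synthetic data: what it does and does not emulate

The built-in panel draws MAF ~ Uniform(0.01, 0.5) (or a 1/f "sfs"
spectrum) and LD scores ~ 1 + Gamma(1.5, 20) (mean ≈ 31, right-skewed,
a plausible pruned-panel profile).  Genotypes are fully independent:
no residual LD, no population structure, no relatedness, no genotyping
error.  Passing tests therefore validate the liability/architecture
machinery, not robustness to real-data confounding.  Two consequences
are documented and deliberate:

- The negative-selection vs polygenic contrast in the significance
  distribution of the PB-LEV test is essentially absent here: with
  variance-calibrated independent variants, the case-stratum PB is
  Gaussian to CLT accuracy under every architecture.  The published
  contrast most plausibly rides on real-genotype LD structure, which is
  out of scope (only the single D′ = 1 pair is modeled).
- The biobank screening demo ships *synthetic* trait rows (labelled
  `_synthetic`): per-trait heritability/prevalence inputs of the
  reference analysis are not distributed with the package, and the
  probit R² conversion of a large odds ratio (e.g. OR = 5.1 at
  f = 0.0013) implies a carrier enrichment among cases several-fold
  above `OR` itself, so absolute per-decile yields exceed the reference
  figures even though the lowest/highest-decile *ratio* matches.
  Treat the screening output as a relative prioritization signal unless
  `h²_LEV` is supplied from a direct case-by-carrier table.

## Other conventions

- OR → `h²_LEV` conversion: `v/(v+1)` (probit) with
  `v = (ln OR)²·2f(1−f)`, paired with the liability-threshold model;
  `v/(v+3.29)` (logit) with the logit model.
- LEV heterogeneity: a candidate list of (effect, frequency) pairs is
  reduced to the single variant maximizing `β²f(1−f)` (ties to the
  lowest frequency); the resulting `h²_LEV` is a lower bound.
- Grid runs checkpoint per combination (hash of parameters + seed) and
  resume without recomputation; invalid parameter combinations are
  emitted with `status=invalid_parameters`, never dropped.
- Monomorphic simulated columns are resampled once and then flagged;
  readers never coerce silently (imputed/dropped/rejected records are
  counted and reported).
- `u₁` (logit slope) defaults to 1: the genetic score enters the
  log-odds directly; the implied heritability scale of the logit model
  is otherwise unidentified.
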