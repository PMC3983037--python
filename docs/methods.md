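# Methods

## Model and estimands

Phenotypes of N nominally unrelated individuals follow the mixed model
y = g + e with cov(g) = σ²_g **A**, where **A** is the SNP-derived genetic
relationship matrix (GRM). The estimands are the SNP heritability
h² = σ²_g/(σ²_g + σ²_e) and, for two traits, the genetic correlation
r_G = σ_g12/√(σ²_g1 σ²_g2). Among unrelated individuals the off-diagonal
relatedness A_jk is centred near zero with variance var_π; for genome-wide
common SNPs in human populations var_π ≈ 2×10⁻⁵ (a function of effective
population size), and for m *independent* loci var_π = 1/m.

## Sampling-variance approximations

REML estimation in this regime is asymptotically equivalent to OLS of
pairwise phenotype products on pairwise relatedness (Haseman–Elston). The
slope of that regression has variance `var(residual) / (n_pairs · var(A_jk))`;
with standardized phenotypes and tiny relatedness the residual variance is
≈ 1 and n_pairs ≈ N²/2, giving

    var(ĥ²) ≈ 2 / (N² · var_π)

independent of h². For the genetic correlation, a second-order delta-method
expansion of r̂_G = ĉ/√(ĥ²₁ĥ²₂) around the true values combines the
component variances var(ĉ) = 1/(N₁N₂ var_π) (cross-set regression over
N₁·N₂ contrasts) and var(ĥ²_k) = 2/(N_k² var_π):

    different samples:
      var(r̂_G) ≈ (1/var_π)[ 1/(h²₁h²₂N₁N₂) + r_G²/(2h²₁²N₁²) + r_G²/(2h²₂²N₂²) ]

    same sample:
      var(r̂_G) ≈ [ (1 − r_G r_P)² + (r_G − r_P)² ] / (N² var_π h²₁ h²₂)

The same-sample form requires the phenotypic correlation r_P and has no
default for it — the two parameters are logically independent. Unlike the
classical Reeve/Robertson pedigree approximations it does not collapse to 0
as r_G → 1 except in the genuinely degenerate limit r_G = r_P = 1. Both
forms were validated three ways: against the published predicted-SE columns
for eight case-control studies and ten psychiatric disease pairs (all within
one unit of the last printed decimal; the two non-targeted pairs that
deviate by ~0.0011–0.0013 before rounding do so because the published
observed-scale h² inputs are themselves rounded to two decimals), against a
10⁶-draw Monte-Carlo oracle on the delta-method components, and against full
replicate simulations (below).

## Case-control studies and the liability scale

Disease status analysed as a 0/1 trait obeys the same formulas on the
observed scale with N = cases + controls. Population-scale interpretation
uses the liability-threshold model: prevalence K fixes the threshold
t = Φ⁻¹(1−K), z = φ(t), selection intensity i = z/K, and with case
proportion v the linear conversion h²_liab = c · h²_obs,

    c(K, v) = K²(1−K)² / (z² · v(1−v)) = (1−K)² / (i² · v(1−v)).

Standard errors scale by the same c, so the Wald NCP — and hence power — is
scale-invariant. Two properties worth emphasizing because they are easy to
get backwards: c(K=v=0.5) = π/2, and c **decreases** as the disease gets
rarer at fixed v = 0.5 (c(0.01, 0.5) ≈ 0.552). Strong ascertainment
concentrates liability-scale information, so a balanced case-control sample
of a rare disease has a *smaller* liability-scale SE and *more* power than a
common-disease design of equal size. This is the standard ascertainment
transformation and is consistent with well-known published conversions
(e.g. observed 0.41 → liability 0.23 for schizophrenia at K = 0.01).
Prevalences outside (10⁻⁶, 1−10⁻⁶) are rejected rather than extrapolated:
z/K is numerically fragile there and outside the regime the theory was
developed for.

## Power and minimum sample size

The test of θ ∈ {h², r_G} is the two-sided Wald χ²₁ test: power =
P[χ²₁(λ) > q_{1−α}] with λ = θ²/var(θ̂) (no one-sided boundary correction —
this plain-χ²₁ convention, λ ≈ 7.849 for 80% at α = 0.05, is what reproduces
the published minimum sizes). Minimum N is found by integer bisection
(power is monotone in N) and reported both unrounded and rounded up to the
next multiple of 100, the convention behind the published values
8900/4500/3000/2300 for h² = 0.1–0.4; two-sample designs hold the N₂:N₁
ratio fixed and scale both.

## GRM construction and var_π

The Yang-style estimator with per-SNP standardization:
A_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i)), allele
frequencies taken from the sample by default (external frequencies accepted).
Missing genotypes are handled per-pair complete-case with the per-pair SNP
count recorded. Text I/O uses the GCTA whitespace-triplet dialect (lower
triangle + id file, optional gzip). `empirical_var_pi` prunes pairs above a
relatedness cutoff (default 0.025, the conventional cryptic-relatedness
threshold) before taking the variance. Note the cutoff is calibrated for
real-data relatedness spreads (sd ≈ 0.0045); the simulation harness disables
it because at simulation scale (sd = 1/√m ≈ 0.01–0.02) it would truncate the
genuine distribution of unrelated pairs and bias var_π downward. With
in-sample allele frequencies the off-diagonal mean is −1/(N−1) rather than
exactly 0 (centering constrains each row); this is immaterial for variances.

## Haseman–Elston implementation

All three pairwise regressions (univariate products over j<k, symmetrized
same-sample cross products, all N₁×N₂ cross-set products) are computed from
closed-form sufficient statistics — sums, sums of squares and quadratic
forms like yᵀ**A**y — in O(N²) per fit without materializing pair-level
vectors. The result is exactly OLS (verified against a naive pair-loop
oracle to 1e-10). Contrasts sharing an individual are correlated; no
reweighting is applied, matching the asymptotic-equivalence regime the
approximation assumes. The symmetrized product (y1_j y2_k + y1_k y2_j)/2 is
used for the same-sample covariance as the minimum-variance unbiased
combination of the two orderings. Phenotypes are standardized with the
sample mean/SD of the analysed individuals. Non-positive heritability
estimates leave r̂_G undefined (NaN, with a warning) rather than clipped.

## Synthetic data and the verification harness

The generator draws allele frequencies uniformly on (0.05, 0.5), genotypes
Binomial(2, p) per individual (HWE, linkage equilibrium), standard-normal
causal effects at n_causal loci (default: all loci), rescales genetic values
to realized variance h² and residuals to 1−h², and induces a genetic
correlation either by drawing effect pairs from a bivariate normal
(`correlated_effects`, any r_G) or by giving a fraction r_G of causal loci
the same effect in both traits (`shared_fraction`; a fraction that is not a
multiple of 1/n_causal raises with a pointer to the other mechanism).
Same-sample residual pairs are correlated r_e, so
r_P = r_G√(h²₁h²₂) + r_e√((1−h²₁)(1−h²₂)). Case-control samples are
ascertained from an oversampled pool (default multiplier max(5, 2v/K)) by
thresholding liability at Φ⁻¹(1−K).

`run_replicates` draws genotypes once (a fixed genotyped cohort) and redraws
effects/residuals/ascertainment each replicate; all randomness flows from a
single seed through `SeedSequence.spawn`, so runs are bit-reproducible and
each replicate is independently reconstructible. For each replicate it
records the HE estimate and its per-fit SE, and summarizes the mean
estimate, the SD across replicates, and the theory SE computed with both the
empirical var_π of the simulated GRM and the idealized 1/m.

Verification scale is n = 2000 individuals, m = 10000 SNPs, 100 replicates
per condition — chosen so the whole battery (univariate h² ∈ {0.2, 0.5, 0.8},
same-sample r_G ∈ {0, 0.4, 0.8} at h² = 0.5, different-samples
r_G ∈ {0, 0.4} with 2000+2000) runs in minutes on one CPU. At this scale the
acceptance checks require unbiasedness within 3 standard errors of the mean
and SD/theory-SE ratios within 20–25%; with 100 replicates the Monte-Carlo
uncertainty of the SD itself is ~7%, so observed ratios of ~1.0–1.2 are
consistent with the approximation holding. The generator reproduces the
theory's assumptions exactly (no LD, no stratification, no cryptic
relatedness, no non-additive variance); passing tests show the formulas are
correct *under those assumptions*, not that real data meet them — on real
genomes var_π must come from the data or from effective-population-size
theory, and LD weighting or added relatives change it materially.

## Monte-Carlo oracle scale

The delta-method closed forms are additionally checked against a 10⁶-draw
oracle that samples (ĥ²₁, ĥ²₂, ĉ) from normals with the component variances
and forms r̂_G directly. The check runs at N₁ = N₂ = 50000, where the
component coefficients of variation (~1–2%) keep the second-order truncation
error of the closed form well inside 3 Monte-Carlo standard errors of the
oracle; at much smaller N the comparison would measure truncation error, not
implementation correctness. Independent-normal components cannot represent
the same-sample covariance structure (r_P couples them), so the oracle is
applied to the same-sample formula only at r_G = r_P = 0 where independence
holds; general (r_G, r_P) values are covered by the full replicate
simulation and the published worked values.

## Numerical choices and limitations

Normal, χ² and non-central χ² quantities come from scipy's double-precision
implementations; no bespoke series. λ = 0 returns power = α exactly.
h² = 0 is rejected for r_G variances (division by h²) and h² < 10⁻³ warns.
GRM text output rounds to 6 decimals. Not implemented, by design: REML
itself (the HE regression is the estimator of record here), LD-aware or
haplotype GRMs, rare-variant architectures, multi-threshold liability
models, LRT power with mixture nulls, and the historical Reeve–Robertson /
Koots–Gibson approximations (their pathological r_G → 1 behaviour is the
motivation for the delta-method form, not a supported method).
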