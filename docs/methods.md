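# Methods

## The estimation problem

A child's polygenic score (PGS) predicts their phenotype through two
routes: the causal effect of the alleles the child carries (the *direct*
effect, δ) and the association induced by the rearing environment that
genetically disposed parents provide (*genetic nurture*, η). In
parent–offspring trios the two can be separated because each parent
transmits exactly one of their two alleles per locus: the transmitted
alleles form the child's own score (PGS_T), while the non-transmitted
alleles can be assembled into a "pseudo-control" score (PGS_NT) that shares
the family environment but not the child's genome. Under random mating an
association between PGS_NT and the child's outcome indexes nurture;
an association of PGS_T reflects direct effect plus nurture.

## Generative model

The simulator produces trio cohorts with known δ and η so every stage of
the pipeline can be validated by parameter recovery.

**Founders.** `n_snps` independent biallelic SNPs with allele frequencies
Uniform over `maf_range` (default 0.05–0.5); founder genotypes are
Binomial(2, p) (Hardy–Weinberg). Causal weights are standard normal, with
a `weight_sparsity` fraction nonzero (default all). LD is *not* simulated:
the analyses operate on scores, which do not require LD structure to
validate the design; this is a known limitation for any question about
individual loci.

**Mating.** Non-consanguineous couples are formed by Gaussian-copula rank
matching on the true score: mothers' score ranks are mapped to normal
scores u, a target v = r·u + √(1−r²)·e is drawn with e orthogonalized
in-sample against u, and fathers are assigned by the rank of v. This hits
the target cross-mate correlation `r_am` to within rank-mapping error
(~±0.01 at n = 5000). A `consang_fraction` of couples is instead generated
from explicit mini-pedigrees: first cousins (shared grandparental couple;
expected genome-wide IBD proportion 0.125) for degree 3, first cousins
once removed (one further meiosis; 0.0625) for degree 4.

**Transmission.** One allele is sampled uniformly and independently from
each parent per SNP; the simulator records which, giving phase-level
ground truth against which the resolver is checked.

**Phenotypes.** Per age a ∈ {3, 5, 7, 11, 14, 17}, the liability is

    L_a = δ_a·Z(S_child) + η_a·(Z(S_mother) + Z(S_father))
          + β_sex·I(female) + β_SES·SES + ε_a,

with ε scaled so Var(L_a) = 1 in the cohort. η multiplies the *sum of the
two z-scored parental scores* (one η per SD of each parent's score): with
this parameterization the joint trio model's per-parent coefficient equals
η, and — because cov(Z_m + Z_f, Z_NT) = 1 under random mating — the
univariate PGS_NT slope on the liability also equals η, while the PGS_T
slope equals δ + η. These identities are what the recovery tests assert.
Age-specific liabilities are conditionally independent given the genetic
terms (no autoregressive structure); longitudinal correlation is induced
only through the shared scores, matching a cross-sectional per-age
analysis.

Symptom scores are generated by a liability-threshold item model: each
item's liability loads √0.5 on a rater-specific liability (itself loading
√0.7 on L_a, the `rater_reliability`), plus an independent uniqueness, and
is cut into ordinal categories. SDQ-E uses five 0–2 items (total 0–10) for
the parent rater at all ages and the self rater from age 11; SMFQ (13
items, 0–2; age 14) and KMH (6 items, 0–4; age 17) use the same
construction. `emotional_disorder` = 1 iff any SDQ-E total ≥ 7. Item
thresholds (0.9/1.7 on the unit-normal item scale) were chosen once to
give a right-skewed symptom distribution with a meaningful ≥7 tail.

**Attrition.** P(trio complete) = σ(logit(p₀) − β_att·L̄ + γ·SES), with L̄
the child's mean liability across ages; p₀ defaults to 0.43 (a realistic
trio-complete fraction for a large birth cohort), β_att = 0.5, γ = 0.3.
This reproduces the qualitative pattern that complete trios are healthier
and higher-SES than the full sample. Defaults for the effect sizes: δ
rising from 0.05 (age 3) to 0.20 (age 17) on the liability scale
(per-SD associations of roughly OR 1.1–1.2 after thresholding), η = 0,
sex effect 0.5 (higher female liability), SES effect −0.15, r_am = 0,
no consanguinity. The generator emits only non-complementary ref/alt pairs
unless `include_palindromic` is set, so causal SNPs survive default
palindromic filtering.

**What the simulator does not emulate.** LD, genotyping/imputation error,
survey design weights, ancestry structure (PCs are pure noise covariates),
rater-specific biases beyond a single reliability knob, and sibling
structure. Passing recovery tests therefore show the *estimators* are
correct under the stated model, not that real-cohort estimates are
unconfounded.

## Transmission resolution

For hard-call dosages the transmitted pair (t_m, t_f) is determined by
enumerating each parent's possible transmitted allele and intersecting
with the child dosage. Every Mendelian-consistent triple resolves uniquely
except child = mother = father = heterozygous, which is AMBIGUOUS;
inconsistent triples are MENDEL_ERROR; any missing member gives MISSING.
The implementation is a precomputed 4×4×4 lookup; tests check it against
an independent brute-force haplotype enumeration over all 27 triples.
Ambiguous sites default to `set_missing` (avoids injecting noise into NT
scores); `random_split` draws the maternal transmitted allele fairly —
note the pseudo-control *dosage* at a triple-het site is 1 under either
true phase, so NT scores are exact under both policies. Mendelian-error
sites are set missing for the whole trio at that variant; a per-variant
error-rate filter (default 1%) is available. Fractional (imputed) dosages
are rejected: transmission is undefined for them. At every resolved site
child + pseudo-control = mother + father dosages, exactly; this identity
propagates to the scores and is asserted to 1e-10.

## Scoring

Weights use the PRS-CS output layout (CHR SNP BP A1 A2 BETA, A1 = effect
allele). Alignment handles exact matches, allele swaps (folded into an
alt-dosage weight plus additive constant, making scoring exactly invariant
to file representation after standardization), and strand flips;
palindromic A/T, C/G SNPs are dropped by default with no frequency-based
rescue (error-prone and unnecessary for simulated data). Missing dosages
are mean-imputed with 2p̂ estimated in the scoring cohort (the
pseudo-control uses the child-cohort frequencies so T and NT share a
scale). Scores are z-scored within cohort — all effect sizes are per SD —
and residualized on 10 PCs + intercept by least squares; residual–PC
correlations are zero to 1e-8 by construction.

## Association models and FDR

Logistic regression for disorder status, OLS for symptom scores, both
co-varying for 10 PCs (sex/SES opt-in); Wald CIs (estimate ± 1.96·SE,
exponentiated for ORs) and complete-case Ns, matching how such results are
conventionally reported. Linear models report ΔR² over the
covariates-only model. Perfect separation raises an explicit error rather
than diverging silently. The sex-interaction model reports the product
term plus sex-stratified fits; the joint trio model fits child, mother and
father scores together; the multivariable model fits all score sets
jointly with a condition-number guard. Benjamini–Hochberg adjustment
(step-up, capped at 1) is applied within configurable families, by default
per transmission class × outcome family; it is implemented in-package and
cross-checked against a brute-force oracle and statsmodels.

## Relatedness and mating diagnostics

pi-hat uses the frequency-standardized method-of-moments estimator
Σ(x−2p)(y−2p)/(2p(1−p))/m over SNPs with frequency in [0.05, 0.95] — a
standardized-genotype kinship × 2, chosen over the three-state P(IBS|IBD)
model for transparency; it approximates PLINK's PI_HAT and is unbiased on
simulated pedigrees (mean within ±0.01 of the degree expectation at 200
pairs × 20,000 SNPs). Degree bins are geometric midpoints between adjacent
expectations (powers of 1/√2): 3rd degree = (0.0884, 0.177], 4th =
(0.0442, 0.0884], etc. MAF < 0.05 SNPs are excluded to bound estimator
variance. Mate and T/NT correlations are Pearson r on residualized scores
with Fisher-z CIs; under assortative mating with cross-mate score
correlation r, corr(T, NT) = (r/2)/(1 + r/2) (≈ 0.130 at r = 0.3), which
the diagnostics recover within sampling error.

## Numerical and design notes

- Determinism: one config seed drives founders → mating → transmission →
  phenotypes → attrition sequentially from a single Generator; identical
  config + seed reproduce byte-identical output files (no timestamps
  written).
- Genotypes are drawn as two Bernoulli haplotypes rather than a
  vector-p binomial call (identical distribution, much faster).
- Recovery experiments use the latent liability as the linear outcome so
  estimates sit on the scale of δ and η; observable symptom totals
  attenuate all coefficients by the item-model loading and are used for
  the qualitative (direction/significance) checks instead.
- Problem sizes: estimand recovery runs 20 replicates of 5000 trios × 500
  SNPs; null calibration 500 replicates × 200 SNPs; T/NT-correlation
  checks 10,000 trios × 300 SNPs; relatedness checks 200 pairs × 20,000
  SNPs. Score-scale quantities are insensitive to SNP count beyond a few
  hundred because only score correlations enter.
- Degenerate inputs: zero-width maf_range is allowed; frequencies of 0 or
  > 0.5 are rejected; an all-consanguineous cohort needs no founder pool;
  zero scored variants yield constant (offset) scores; empty FDR families
  and single-sex interaction data raise.

## Known limitations

No LD, no X chromosome, no multi-sibling families, single ancestry group
per simulated cohort, Wald (not likelihood-ratio) inference, no
survey weighting or mixed models for the repeated measures. The estimand
identity PGS_T slope = δ + η holds under random mating; under assortative
mating or consanguinity both T and NT slopes are inflated by the T/NT
correlation — that inflation is exactly what the mating diagnostics are
for.
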