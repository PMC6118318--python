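# Methods

This note documents the statistical models implemented in `triovar`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## Study design assumed

The pipeline targets a case–parent trio design: affected children (some
with both parents sequenced, some without), unrelated unaffected adult
controls, and a targeted panel over one or more candidate genes. The
default parameters mirror a pediatric Crohn's disease cohort: 205
affected children of whom 179 form complete trios, 200 controls, and a
NOD2-like locus carrying three common risk alleles (MAF 1.4–3.5%,
per-allele relative risk 2.2–3.8), eight rare risk alleles (MAF < 0.5%,
RR 3–15) and neutral variants, at a disease prevalence of
34.7 per 100,000 children.

## Genotype model and quality filtering

Genotypes are diploid alt-allele counts {0, 1, 2} with explicit
missingness. Multi-allelic VCF records are split into biallelic records
on read (one record per alternate allele, counting copies of that allele
only, so per-site alt totals are conserved); phase separators in input
files are ignored because phase is re-derived from parents. Variant
identity is the 1-based `(chrom, pos, ref, alt)` key throughout.
Half-calls and non-diploid calls are rejected rather than coerced.

The only site-level quality filter is the missingness filter: a variant
is removed when its missing-call fraction is **≥ threshold (default
10%) in cases or in controls**, with the boundary inclusive. Parents do
not count toward either rate — they enter only the phasing and de novo
stages, and the filter is defined on the case/control contrast the
association tests use. Upstream caller-level filtering (VQSR and the
like) is out of scope; inputs are assumed already called.

## Phasing and carrier encodings

Phase for a double-heterozygous variant pair is derived purely from
parental genotypes by gamete enumeration: every maternal × paternal
transmitted-gamete combination compatible with the parents' unphased
genotypes (a missing parental call contributes both alleles) is checked
against the child's genotype. The call is *trans* (compound
heterozygote) or *cis* only when every compatible combination forces
that configuration, *ambiguous* when both remain possible (e.g. all
three members double-heterozygous), *unphasable* when no parental data
exist, and a Mendelian-error flag with no phase call when no combination
explains the child.

Two covariate encodings feed the effect-size models:

- **Model 1** (what a genotyping study without parents would see): one
  heterozygote indicator per common risk variant plus an any-homozygote
  indicator. Het indicators may overlap each other; homozygotes carry
  only the homozygote flag.
- **Model 2** (what trio sequencing adds): mutually exclusive
  non-reference categories with precedence **homozygote >
  compound heterozygote > single common het > rare het**. The precedence
  order is a design choice inferred from the mutually exclusive category
  counts such models publish; double heterozygotes whose phase is
  ambiguous or unphasable are conservatively *not* counted as compound —
  this biases the compound-heterozygote effect toward the null rather
  than inflating it — and fall through to the heterozygote categories.
  Cases without sequenced parents are treated the same way (unphasable).
  A homozygote at a rare panel variant is classified as a compound
  carrier (two risk alleles in trans trivially); with rare-variant
  frequencies below 0.5% this category is essentially never populated.

## De novo mutations

A de novo candidate requires a complete trio with the child
heterozygous and **both parents confidently homozygous reference**; a
missing parental call suppresses the candidate (preventing
missingness-driven false calls). Candidates are then excluded if the
variant's minor-allele frequency exceeds 0.5% in any reference
population (absent variants count as frequency 0) or if carriers among
cases and controls jointly number two or more — carriers of the
genotype, not allele copies, counted over cases and controls only.

The de novo burden test is an upper-tail Poisson test with mean
λ = 2 · n_trios · gene_length · (μ_SNV + μ_indel), the factor 2 because
the rates (defaults 1.2×10⁻⁸ and 4×10⁻¹⁰ per generation) are per
haploid base. It is deliberately a mutation-rate-only test: it does not
reproduce functional-prioritisation de novo association methods
(VARPRISM), which weight mutations by predicted impact, and its p-values
are labelled accordingly.

## Association statistics

- **Fisher exact tests** use the hypergeometric distribution
  (scipy); one-sided tests (case enrichment) are used for the
  single-marker and burden tests, matching the arithmetic of the
  minimum-copy filter. The test suite checks them against an
  independent exact-rational enumeration of the 2×2 support.
- **Single-marker tests** for rare variants (internal-control MAF < 1%)
  compare case alt-allele counts against internal control alleles pooled
  with a reference population's counts; odds ratios use the Haldane
  +0.5 correction when a cell is zero, with Woolf log-scale CIs.
- The **minimum-allele-copy filter** computes the smallest copy count
  m* for which a one-sided Fisher test with all m copies in cases
  (allele denominators 2·n_cases vs 2·n_controls) reaches p < α, and
  retains genes with at least m* copies. For 205 cases, 200 controls,
  α = 0.05, m* = 5.
- The **carrier-collapsing burden test** collapses a gene's variants
  with combined-sample MAF ≤ 5% (monomorphic sites excluded) to a
  carrier indicator and applies a one-sided Fisher test. It is a labelled
  stand-in for composite-likelihood burden frameworks (VAAST): simpler,
  with no functional priors, and its outputs always carry a
  `burden_stand_in` flag so the two are never confused.
- **Logistic regression** is Newton–Raphson on the binomial
  log-likelihood (`ml`) or on the Jeffreys-penalized likelihood
  (`firth`), the penalized score adding h_i(½ − p_i) to each residual
  (h_i the hat values of the weighted design). Firth estimates stay
  finite under the quasi-separation rare variants create; on a 2×2
  design the Firth estimate coincides with the Haldane add-0.5 odds
  ratio, which the tests assert to 1e-6 relative. CIs are Wald on the
  (penalized) information — consistent with log-symmetric published
  intervals — not profile-penalized-likelihood.
- **Tjur's R²** is the coefficient of discrimination: mean fitted
  probability among cases minus mean among controls.

Numerical choices: convergence at max |score| < 1e-8 within 50
iterations, non-convergence flagged and never silent; step-halving
requires the objective to improve, or — once the objective has plateaued
at float precision — the score norm to shrink, which prevents
oscillation around flat penalized optima; a pseudoinverse substitutes
for the information inverse only when a Newton overshoot makes it
transiently singular.

## Meta-analysis

DerSimonian–Laird random effects on Woolf log odds ratios:
y = log(ad/bc), v = 1/a+1/b+1/c+1/d, with 0.5 added to every cell of a
study containing a zero cell (only then). Fixed-effect weights w = 1/v
give Q = Σw(y−ȳ)²; τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw)); pooling uses
w* = 1/(v+τ²) with a Wald CI. τ² = 0 reduces exactly to the
inverse-variance fixed-effect estimate; k = 1 returns the study
unchanged. Reproducing any particular published pooled estimate
requires the corresponding study-level tables, supplied as a TSV;
the module ships the estimator, not the literature corpus.
Hartung–Knapp, REML/Paule–Mandel τ² and publication-bias diagnostics
are out of scope.

## Risk attribution

Odds ratios convert to relative risks by RR = OR/(1−P₀+P₀·OR) at
prevalence P₀ (for a rare disease RR ≈ OR, and RR ≤ OR whenever
OR ≥ 1). The exposure proportion Pe is the risk-allele frequency,
entering through Hardy–Weinberg genotype terms; homozygote risk follows
the multiplicative model RR_BB = RR_Bb². Per-variant PAR is

PAR = [2Pe(1−Pe)(RR_Bb−1) + Pe²(RR_BB−1)] / [1 + 2Pe(1−Pe)(RR_Bb−1) + Pe²(RR_BB−1)],

and per-variant PARs combine across a locus multiplicatively,
1 − ∏(1−PAR_i), which never exceeds the additive sum ("conserved" PAR).
The locus-PAR confidence interval is parametric Monte Carlo: each log OR
drawn Normal(log OR, SE²), the locus PAR recomputed per draw, 2.5/97.5
percentiles reported; seeded and deterministic. The propagation method
is a design choice — no closed form exists for the multiplicative
combination.

Heritability explained uses the liability-threshold model: disease
occurs when a standard-normal liability exceeds T = Φ⁻¹(1−P₀); genotype
penetrances are the relative risks normalised so the population risk is
P₀; each genotype's mean liability is T − Φ⁻¹(1−K_g); the variance of
these means (total liability variance 1) is h². Per-variant h² combine
additively. This implements the standard single-locus liability-scale
framework; exact parity with any particular web calculator is not
claimed. A genotype penetrance reaching 1 is an error (the threshold
model is undefined there).

In the pipeline stage, locus-wide attribution is restricted to variants
whose estimated OR exceeds 1: the locus PAR is defined for risk
variants, and chance-protective estimates would contribute negative
terms.

## The synthetic cohort generator

Parents' haplotypes are drawn independently per variant from the
configured allele frequencies (Hardy–Weinberg and linkage equilibrium —
no LD, recombination maps, population structure or sequencing-error
model). Children receive one allele per variant from each parent
independently; compound heterozygosity therefore arises naturally from
independent transmission, and the generating phase is recorded in the
truth table. Disease risk is multiplicative across the two alleles of a
variant and across variants, with the baseline genotype risk calibrated
so the population prevalence equals the configured value; risks are
clipped at 1, and a configuration is rejected if clipping would distort
the calibrated prevalence by more than 0.1% relative (checked by exact
enumeration of the genotype-risk distribution). Affected children are
ascertained by rejection sampling (acceptance probability equals the
prevalence by construction; below 1e-8 it is refused as unattainable);
controls are adults sampled conditional on being unaffected. De novo
events are injected per trio child as Poisson(2·L·μ) per mutation
class, as new neutral singleton variants; genotypes are then masked
completely at random at the configured missingness rate (no informative
missingness mechanism is modelled). Output is deterministic given the
seed, byte-identical across runs.

For large power and calibration studies, `sample_case_control_genotypes`
draws case genotypes directly from the exact conditional law the
rejection sampler targets (P(g | case) ∝ HWE(g)·RR^g per variant, valid
because the multiplicative model factorises under linkage equilibrium),
avoiding millions of rejected draws at realistic prevalences.

Because the generator matches the analysis assumptions by construction,
passing tests demonstrate internal consistency, estimator calibration
and parameter recovery — not robustness to LD, population
stratification, differential missingness or genotyping error, none of
which the simulator produces.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to make the statistical
assertions sharp: null calibration of the single-marker test at 2,000
cases/controls with a 0.5%-frequency variant (where the exact test's
discreteness is negligible at KS resolution); burden power and type-I
error at 2,000/2,000 over 200 and 2,000 replicates via the conditional
sampler; Wald-CI coverage of generating log relative risks over 100
replicates of 2,000 ascertained cases vs 2,000 controls on a
three-common-variant panel; phase-versus-truth concordance over ≥10,000
simulated double heterozygotes; PAR consistency at 50,000 per group.

## Known limitations

- The burden and de novo tests are frequency-only stand-ins; methods
  with functional priors will rank variants differently.
- Wald intervals on penalized fits can undercover for extremely sparse
  categories; profile-penalized-likelihood intervals are not
  implemented.
- The simulator's linkage-equilibrium assumption makes compound-het
  frequency a direct product of carrier frequencies; real loci with LD
  between risk alleles will differ.
- Ancestry adjustment (PCA covariates, genomic control) is out of
  scope; inputs are assumed ancestry-matched upstream.
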