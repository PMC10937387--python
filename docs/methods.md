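# Methods

## Two-locus pedigree likelihood

The engine computes the exact probability of a family's phenotype and
genotype data under a two-locus model: an X-linked locus with a rare
deleterious allele S and an unlinked autosomal locus with a truncating
allele T. Joint genotypes are counts of mutant alleles, enumerated
`x_count * 3 + a_count`; males have 6 joint states, females 9. The loci
are physically unlinked (an X-linked kinase gene versus an autosomal gene
on another chromosome), so transmission factorises into independent
per-locus Mendelian terms with no recombination parameter: sons receive no
paternal X; daughters receive the father's X allele with certainty and one
maternal draw; autosomal alleles are one draw from each parent. Founders
follow Hardy–Weinberg priors at `q_s` and `q_t`.

Defaults are taken from printed population counts: `q_s = 6/76702`
(hemizygous loss-of-function males in a reference population of 76,702)
and `q_t = 0.01`, giving a diploid truncating-carrier fraction of
`1-(1-q_t)^2 ≈ 2%`. The reference population reports carriers rather than
allele counts, so where an operation needs the ~1% figure as a *carrier*
fraction directly (the co-occurrence expectation) a flag says so. Both are
configurable.

Genotype observations are hard indicators (study genotypes were
Sanger-confirmed; no genotyping-error parameter). The observation alphabet
for the autosomal locus is {unknown, hom wt, het}; a homozygous-mutant
individual is not encodable and is recorded as unknown by the simulator —
at the default frequencies the probability of producing one is of order
`q_t^2` and negligible. The same applies to homozygous-S females.

### Penetrance models

Five inheritance-model families map (genotype, sex, X-inactivation) to a
probability of affection:

| family | at-risk set | free parameters |
|---|---|---|
| `null_model` | nobody | `eps` |
| `monogenic_x` | ≥1 S allele | `f_m, f_f_skewed, f_f_random, eps` |
| `monogenic_a` | ≥1 T allele (sex-shared) | `f_m, eps` |
| `heterogeneity_or` | either locus | `f_m, f_f_skewed, f_f_random, f_a, eps` |
| `digenic_and` | ≥1 S **and** ≥1 T | `f_m, f_f_skewed, f_f_random, eps` |

At-risk males penetrate with `f_m`; at-risk females are gated by the
X-inactivation covariate: `f_f_skewed` when the mutant X is predominantly
active, `f_f_random` under random X-inactivation, and the phenocopy floor
`eps` when the mutant X is silenced (the unaffected carrier whose fully
inactivated X carries the deleterious allele is the motivating case).
Unknown X-inactivation is treated as random — the conservative choice,
since observed random-inactivation carrier females are unaffected.
Everyone outside the at-risk set is affected with the phenocopy rate
`eps` (default upper bound 0.1 during fitting: phenocopies of a severe
early-onset myopathy are rare; configurable).

The locus-heterogeneity family gives the autosomal branch its own carrier
penetrance `f_a` and takes the *strongest applicable cause*, floored by
the phenocopy rate: `p = max(v_x, v_a, eps)`. Setting one branch's
penetrance to zero then reproduces the corresponding monogenic model
exactly, so the heterogeneity optimum can never fall below a monogenic
optimum — except in the corner where a monogenic fit places a penetrance
*below* `eps`, which no monotone combination can mimic; the test suite
allows a small slack for that corner. An independent-causes combination
(`1-(1-v_x)(1-v_a)`) was considered and rejected because it loses this
exact nesting.

### Computation

Likelihoods are computed by Elston–Stewart peeling formulated as
sum–product message passing on the bipartite tree of nuclear-family units
and individuals. Loop-free pedigrees keep this exact; pedigrees with
inbreeding or marriage loops are rejected rather than approximated
(loop-breaking is out of scope, and the study pedigrees are loop-free).
Peeling order is deterministic (units and members sorted by id), making
results bit-reproducible. Arithmetic is linear-space per family with the
logarithm taken at the end — family likelihoods stay far above the
double-precision floor at realistic sizes — and a zero likelihood is
reported as −inf with a diagnostic naming the first individual whose
observations admit no genotype state, or the family when only the joint
configuration is impossible.

A brute-force oracle enumerates every observation-consistent genotype
assignment (guarded to ≤12 members and ~4×10⁶ configurations) through a
code path independent of the peeling implementation; peeling and
enumeration agree to <10⁻¹⁰ log-units across random pedigrees and all
model families.

### Ascertainment

Families entered the study through an affected proband, so likelihood
comparisons of ascertained cohorts default to conditioning each family on
the marginal probability of its proband's affection status (classical
single-proband correction). Under Hardy–Weinberg founders and random
mating every individual's marginal genotype is the Hardy–Weinberg product,
so the denominator needs no peeling; the engine also exposes the
stripped-pedigree computation and the two are property-tested equal. Both
conditioned and unconditioned modes are available and flagged in results.

## Model fitting and comparison

Each family is fitted by maximizing the summed per-family log-likelihood
over its free parameters: a coarse grid (step 0.05 per parameter; the
phenocopy axis spans [0, 0.1]) followed by bounded L-BFGS-B refinement
from the three best grid points. Because the phenotype part of a family's
likelihood is a mixture of monomials in the penetrance parameters, each
family is summarised once per model family (enumerating
observation-consistent genotype configurations, capped at 20,000 with a
peeling fallback) and the whole grid is evaluated with array arithmetic;
the summary is property-tested equal to the peeling likelihood. The
heterogeneity family is fitted last, with the fitted monogenic optima
added as refinement starts so the nesting inequality holds by
construction. Ties at machine precision break toward the family with
fewer free parameters. Likelihood ratios are reported in log10.

## Enrichment statistics

Carrier counts are compared with a two-sided Fisher exact test under the
minimum-likelihood rule: the p-value sums point hypergeometric
probabilities of all tables with the observed margins that are no more
probable than the observed table, with a `1+1e-7` relative tolerance
absorbing floating-point ties (matching mainstream exact-test
implementations). Following Agresti and Coull, two successes and two
failures are added to each group before testing; the adjusted procedure is
the shipped default and is the one that reproduces the published cohort
p-values (the raw tables give visibly different values — an order of
magnitude smaller). Tables are built exactly as the counts are printed,
family-level cases against per-patient controls, rather than homogenised.
The affected-versus-unaffected comparison of truncating-variant carriage
among hemizygous loss-of-function males takes its group counts as inputs:
the published tabulation lives in supplementary material that is not
machine-readable, so the package does not hard-code it.

## Synthetic cohort generator

The generator emulates the study design: families of 2–3 generations
(three generations with probability 0.5), sibships uniform on 1–4 (second
generation) and 1–3 (third), each second-generation child marrying in a
spouse with probability 0.5. Founders draw genotypes from Hardy–Weinberg
priors; with probability `founder_carrier_boost` (default 1) the founding
mother is made an S carrier and a random member of the founding couple a T
carrier — without the boost, digenic families are astronomically rare at
`q_s ≈ 8×10⁻⁵` and rejection sampling is hopeless. The boost alters only
the generator's founder draws, never the likelihood used in analysis.

Carrier females draw a latent mutant-X-active cell fraction from a
Beta(2, 2) distribution, dichotomised at threshold 0.6 into the
categorical calls the likelihood consumes (≥0.6 mutant-active skew, ≤0.4
mutant-silenced skew, otherwise random); the threshold is consistent with
80:20 and 65:35 ratios being called skewed. Affection is Bernoulli with
the model penetrance; the generative default is the digenic family with
`f_m = 0.95`, `f_f_skewed = 0.9`, `f_f_random = eps = 0.01` — male
penetrance near one with a small phenocopy allowance. Ascertainment
(default: at least one affected male, who becomes the proband) is by
rejection sampling, chosen over importance weighting for transparency;
the rejected-family count is recorded.

What the generator does *not* emulate: genotyping dropout and untested
relatives (every member's carrier status is observed), de novo mutation
(none was seen in the study), variable expressivity beyond the binary
affection code, population structure, and the exact sibship distribution
of the real 25 families, which is only recoverable from the published
figure. Passing tests therefore demonstrate correctness and calibration of
the machinery under the stated study-like conditions, not exact
reproduction of the real cohort's likelihood ratio, which would require
the genuine pedigrees. The packaged reconstruction of families M, Y and Z
(`study_families_MYZ_synthetic.ped`) carries every member named in the
study text with their published genotype, phenotype and X-inactivation
status, but the connecting structure is inferred — it is labelled a
synthetic stand-in accordingly.

## Experiment sizes

The shipped experiments use desk-scale sizes chosen to give stable
statistics: parameter recovery fits 20 replicate cohorts of 200
informative families (simulated unascertained with the founder boost, so
the maximum-likelihood estimate is a clean binomial estimate of `f_m`;
ascertained-and-conditioned recovery carries the known single-versus-
complete ascertainment bias and is not used for calibration); model
selection uses 20 replicates of 25 ascertained families to mirror the
study's cohort size; the Fisher oracle enumerates all 2×2 tables with
total ≤60; the peeling oracle uses 100 random pedigrees of ≤8 members
with the genotype space capped so enumeration stays exact.

## Known limitations

- No loop-breaking: consanguineous pedigrees are rejected.
- No linkage/marker data: the engine models the two causal loci only,
  not flanking markers, so LOD-style multipoint analyses are out of scope.
- The observation alphabet cannot represent homozygous-mutant autosomal
  genotypes or homozygous-S females (recorded as unknown; negligible at
  study frequencies).
- Single-proband ascertainment correction is approximate when families
  were in truth ascertained through "at least one affected" with several
  independent entry points.
- The phenocopy bound (0.1) and grid step (0.05) are pragmatic defaults;
  profile-likelihood confidence intervals are not implemented.
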