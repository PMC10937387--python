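# digenic

Statistical-genetic analysis of **digenic inheritance between an X-linked
and an autosomal locus**, built around the SRPK3/TTN skeletal myopathy: a
rare deleterious allele of the X-linked muscle kinase gene *SRPK3* causes
disease only when co-inherited with a heterozygous truncating variant
(TTNtv) in the giant sarcomeric gene *TTN*. Carrier females express the
phenotype only when skewed X-inactivation leaves the mutant X
predominantly active.

The package provides, as importable library code:

- **`digenic.variants`** — variant cohort tables, classification of
  consequences into truncating (stop gain, frameshift, essential splice)
  vs non-truncating classes, per-family carrier tallies. The 25-family
  cohort table ships as a fixture.
- **`digenic.pedigree`** — pedigree data model and an extended
  PED/LINKAGE-style format carrying two-locus observations and
  X-inactivation status.
- **`digenic.likelihood`** — exact two-locus pedigree likelihoods by
  Elston–Stewart peeling over the joint genotype space of an X-linked
  locus × an unlinked autosomal locus, with a brute-force enumeration
  oracle.
- **`digenic.inference`** — maximum-likelihood fitting of five
  inheritance-model families and likelihood-ratio model comparison.
- **`digenic.enrichment`** — two-sided Fisher exact tests with the
  Agresti–Coull add-two adjustment, and population co-occurrence
  expectations.
- **`digenic.simulate`** — gene-dropping simulation of study-like families
  with ascertainment and Beta-distributed X-inactivation skewing.

A CLI (`digenic classify|enrich|likelihood|compare|simulate|pipeline`)
wraps the library, and the numbered scripts under `analysis/` run the full
study analysis, writing tables to `results/`.

## The model

For each family the likelihood of the observed phenotypes **Y** and
genotype observations **G** under penetrance model *M* is the exact sum
over joint genotype assignments *g*:

```
L(M) = Σ_g  Π_founders P_HWE(g_i)  ×  Π_non-founders P_Mendel(g_i | g_fa, g_mo)
          ×  Π_i P(G_i | g_i) P(Y_i | g_i, sex_i, xi_i, M)
```

computed by peeling over the tree of nuclear families. Genotypes are
`x ∈ {0,1}` (males) or `{0,1,2}` (females) copies of the X-linked allele S
times `a ∈ {0,1,2}` copies of the autosomal allele T; founders follow
Hardy–Weinberg priors at frequencies `q_s` (default 6/76,702 ≈ 7.8×10⁻⁵)
and `q_t` (default 0.01). Penetrance families: *null* (phenocopies only),
*monogenic X*, *monogenic autosomal*, *locus heterogeneity* (either locus
sufficient) and *digenic AND* (both required). In males the at-risk
genotype penetrates with `f_m`; carrier females are gated by
X-inactivation: `f_f_skewed` when the mutant X is predominantly active,
`f_f_random` under random/unknown X-inactivation, and the phenocopy rate
`eps` when the mutant X is silenced. Ascertained families can be
conditioned on the proband's affection status (classical
single-ascertainment correction). Model fits maximize the summed family
log-likelihood (grid step 0.05 plus bounded local refinement) and models
are ranked by log10 likelihood ratio.

Cohort enrichment uses the exact two-sided Fisher test (minimum-likelihood
rule) after adding two successes and two failures to each group, following
Agresti and Coull.

## Worked example

```
$ digenic classify src/digenic/data/srpk3_ttn_cohort.tsv --out-dir out
21 of 25 families carry a truncating TTN variant (84%)

$ digenic enrich --case 21/25 --control 5/170
raw table: (21, 4, 5, 165)  p = 9.421e-20
adjusted table: (23, 6, 7, 167)  p = 6.133e-19
odds ratio (adjusted): 91.5
```

84% of cohort families carry a TTNtv against 2.94% of the 170 LGMD-R1
patients; the adjusted exact test puts the chance of such an imbalance
under equal carriage at 6.13×10⁻¹⁹. Simulating 25 study-like ascertained
families and comparing inheritance models:

```
$ digenic simulate --seed 1 --n-families 25 --out cohort.ped
$ digenic compare cohort.ped --seed 1
best-fitting family: digenic_and
log10 LR vs next best: 40.55
```

i.e. the simulated cohort's data are ~10⁴⁰ times more likely under digenic
inheritance than under the best single-gene reduced-penetrance
alternative — comfortably past the 10¹⁰ scale reported for the real
families. The analysis scripts print the same numbers:
`python analysis/04_model_comparison.py --seed 1`.

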