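# prioriseq

Genetic risk prediction for sequencing study design: use the common
risk loci a disease already has (typically from GWAS) to decide **who
to sequence next** when hunting for undiscovered low-frequency and
rare risk alleles.

The premise: individuals or families whose disease status is *poorly
explained* by their known-locus genetic risk are the most likely to
carry risk factors nobody has found yet. `prioriseq` implements that
idea end to end:

- **Risk scoring** — linear (quantitative) and logistic (binary)
  prediction from a panel of known loci, ŷⱼ = μ + σ Σᵢ βᵢ(gᵢⱼ −
  2fᵢ)/√(2fᵢ(1−fᵢ)) and ŷⱼ = expit(α + Σᵢ bᵢgᵢⱼ) with the intercept α
  calibrated so the population-average risk equals the prevalence K;
  residuals Δy = y − ŷ define "super cases" (affected, low predicted
  risk) and "super controls" (screened unaffected, high predicted
  risk).
- **Selection theory** — on the liability-threshold scale
  (liability = s + r + δ(g − 2f), s ~ N(0, V), r ~ N(0, 1 − V),
  disease when liability > T = Φ⁻¹(1 − K)), closed-form/quadrature
  computation of the allele frequency an undiscovered variant attains
  in residual-selected cases and controls, the inflated *apparent odds
  ratio* this induces, and Cochran–Armitage trend-test power for
  prioritised versus random designs.
- **Pedigree inference** — PLINK PED ingestion, validation to a rooted
  tree of nuclear-family units, kinship matrices, and an
  inside-outside algorithm giving *exact* per-locus genotype
  posteriors and conditional genotype sampling in partially genotyped
  pedigrees (linear time; 1,000-member pedigrees in seconds).
- **Family burden statistic** — P(Y ≥ y_obs | observed genotypes), the
  probability of a family's affected count given the risk its members
  are known to carry, evaluated by exact Poisson-binomial tails and,
  where genotypes are missing, averaged over conditional genotype
  replicates. Small tails = unexplained burden = sequence this family.
- **Simulators** — liability-model cohorts and ascertained nuclear
  families (optional dominant mutation with calibrated carrier
  penetrance), used both as study-design experiments and as
  Monte-Carlo oracles for the analytic theory.

Intended users: statistical geneticists designing targeted or
whole-genome sequencing studies from large genotyped cohorts or
multiplex family collections.

## Worked example

Rank two three-affected families for sequencing (see
`examples/family_burden_ranking.py`; the ungenotyped mother in
LOWRISK is integrated out by conditional genotype sampling):

```
population prevalence K = 0.05, calibrated intercept = -4.103

rank  family    y_obs  P(Y>=y|G)   mc_se    E[affected|G]
   1  LOWRISK      3   1.664e-05  5.6e-08   0.083
   2  HIGHRISK     3   2.233e-02  0.0e+00   0.862
```

Both families have three affected members, but HIGHRISK carries many
risk alleles (expected affected 0.86, tail 0.022 — largely explained),
while LOWRISK carries few (expected 0.08, tail 1.7 × 10⁻⁵): its burden
is unexplained by known loci, so it is ranked first.

Other narrative scripts in `examples/`: residual-extreme selection in
a cohort (`score_and_select.py`), apparent odds ratios and power
curves (`selection_theory_power.py`), exact pedigree posteriors
(`pedigree_genotype_sampling.py`) and the mutation-detection AUC grid
(`mutation_detection_grid.py`). A thin CLI (`prioriseq predict|power|
select-theory|pedigree-sample|burden|simulate-families|simulate-cohort`)
wraps the same library calls for shell use.

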