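# Methods

This note records the models implemented in `prioriseq`, their
assumptions, the parameters that matter, and the numerical and design
choices made where more than one reasonable option existed.

## Risk scoring (`prioriseq.risk_model`)

Quantitative traits are predicted by a linear model on standardized
genotypes,

    yhat_j = mu + sigma * sum_i beta_i (g_ij - 2 f_i) / sqrt(2 f_i (1 - f_i)),

where f_i is the effect-allele frequency and beta_i the effect in
trait SD per standardized allele. Centring by 2f and dividing by the
Hardy–Weinberg genotype SD makes each beta a per-standardized-allele
effect, so on the standardized trait scale the score's explained
variance is exactly sum(beta_i^2) — the convention that lets the
selection theory below speak of "variance explained" without extra
bookkeeping.

Binary traits use a logistic model, yhat_j = expit(alpha + sum_i b_i
g_ij) with b_i the per-allele log odds ratios. The intercept alpha is
chosen so that the *population mean* predicted risk equals the
prevalence K under Hardy–Weinberg, independent loci. For panels of up
to 25 loci the genotype-score distribution sum_i b_i g_i is computed
by exact convolution collapsed onto a 4,096-bin grid (mass between
grid points is split linearly between neighbours, making the
discretization error second-order in the bin width); larger panels
fall back to a fixed-seed 100,000-draw Monte-Carlo sample of scores.
The one-dimensional root for alpha is then solved by Brent's method on
[-50, 50] to a residual below 1e-10.

Missing dosages are mean-imputed to 2f for unrelated-individual
scoring (unbiased under Hardy–Weinberg); pedigree-aware treatment of
missingness is done properly, by conditional sampling, in the family
modules. Residual-extreme selection breaks ties by input order so
selections are reproducible. Loci are treated as independent
throughout (panels are assumed LD-pruned); no shrinkage or
re-estimation of the supplied effects is attempted.

## Selection theory (`prioriseq.selection_theory`)

Everything is parametrised on the liability (probit) scale: disease
occurs when l > T = Phi^-1(1 - K); the known risk score contributes
s ~ Normal(0, V), the residual r ~ Normal(0, 1 - V), and an
undiscovered test variant adds delta * (g - 2 f_v) with g ~
Binomial(2, f_v). The probit composition keeps the score's explained
variance exactly V, matching how predictive power is usually quoted.
The per-allele liability shift delta is not a free parameter: it is
root-found (Brent, tolerance well below 1e-6 on the odds-ratio scale)
so that the variant's marginal *allele-based* odds ratio —
odds(f_case)/odds(f_control) computed from the three closed-form
genotype penetrances Phi(delta (g - 2 f_v) - T) — equals the stated
odds ratio in unselected individuals. The variant's own variance
contribution is deliberately not removed from the residual (it is
below 1e-3 liability units for the designs of interest).

Selection on predicted risk is modelled as selection on s: the
prediction is a monotone function of s, so tail fractions agree.
"Super cases" are cases in the lowest fraction q of s among cases;
"super controls" are screened non-cases in the highest fraction q of
s among non-cases. Their allele frequencies are ratios of integrals
of the form

    integral phi(s; V) * Phi((s + delta (g - 2 f_v) - T)/sqrt(1 - V)) ds

accumulated per genotype class, evaluated by adaptive quadrature
(absolute tolerance 1e-12) over +-12 score SDs, with the in-case score
quantile found by Brent root-finding to 1e-10. Unscreened
(general-population) controls keep the population frequency f_v
regardless of selection. Two degenerate limits short-circuit
analytically: q = 1 (no selection) and V = 0 (a flat score selects at
random); both reduce to the unselected case/control frequencies.

For a quantitative trait the residual after removing the score is
Normal(beta_v (g - 2 f_v), 1 - V) given g; tail cutoffs are solved on
the three-component genotype mixture and tail frequencies follow in
closed form. Setting V = 0 recovers selection on the raw trait, which
is also the baseline the power comparison uses: the "random" design
for quantitative extreme sampling compares the two tails of the raw
trait, the prioritised design the two tails of the residual. For
case-control designs the baseline is a random draw from the case and
control pools.

Power uses the allelic trend test under additivity, i.e. the
two-proportion z-test on 2N alleles per group. Convention, held fixed
by tests: the rejection threshold uses the pooled null variance and
the alternative the unpooled variance, so the null power equals the
significance level exactly; power is two-sided with both rejection
directions summed.

Correctness of the analytic machinery is anchored to simulation: the
acceptance suite requires agreement with 10^7-individual seeded cohort
simulations within 3 binomial SE over the full grid OR in {1.2, 2, 4}
x V in {0.05, 0.25, 0.5} x q in {0.01, 0.1, 0.5} x K in {0.01, 0.1}.

## Pedigrees and inside-outside inference (`prioriseq.pedigree`, `prioriseq.inside_outside`)

Pedigrees are decomposed into a rooted tree of nuclear-family units
(a couple plus its children). Only loop-free pedigrees are supported,
and the declared structural contract is: a single connected component,
nobody their own ancestor, parent sexes consistent with their roles,
exactly one founder couple as the root (first in file order, a
deterministic choice), and every other married-in spouse a founder.
Violations abort with an error naming the offending union — the
inference engine is exact only on trees, and a silently approximate
answer would be worse than none. Affection codes 0 and -9 both map to
unknown (PLINK dialects differ). Kinship matrices use the standard
recursion phi(i,i) = (1 + phi(father, mother))/2, phi(i,j) =
(phi(father_i, j) + phi(mother_i, j))/2 in a parents-first ordering.

Genotypes are effect-allele dosages at biallelic loci, so all tables
are 3-state; loci are unlinked and in linkage equilibrium (the model
multiplies per-locus terms); founders draw from Hardy–Weinberg priors
at supplied population frequencies; transmission is the exact
Mendelian table; observation factors are hard 0/1 indicators (no
genotyping-error model — observed genotypes are conditioned on
exactly).

The inside pass runs leaf-to-root over the unit tree: an individual's
inside vector is their observation factor times, for each union they
anchor, the spouse-summed product of the children's transmission-
weighted inside vectors. The outside pass runs root-to-leaf,
combining the anchoring parent's outside-and-other-unions factor with
the spouse's prior-weighted inside vector and sibling
leave-one-out products (computed by prefix/suffix products, never by
division, so Mendelian zeros cannot produce 0/0). Marginals are the
normalized inside-outside products; the data log-likelihood comes
from the root contraction. Rather than switching to log-space
arithmetic on large pedigrees, every message is renormalized per
locus as it is formed and the constants are folded into a log-
likelihood accumulator — equivalent protection against underflow with
cheaper inner loops, since all messages are vectorized across loci.
A zero normalizer is a Mendelian impossibility and raises an error
naming the locus.

Sampling draws complete genotype configurations top-down: the root
from prior x inside (its exact marginal), each married-in spouse
conditional on the partner's sampled genotype (weighted by prior, own
inside vector and the children's messages), each child conditional on
both sampled parents times its inside vector. Traversal is a fixed
pre-order and the generator is seeded, so replicates are reproducible;
loci are sampled independently in one vectorized pass, and observed
entries are reproduced exactly because their factors are point masses.
The binding correctness contract is enumeration: on random pedigrees
of up to 6 members, likelihoods and marginals must match brute-force
3^N sums to 1e-12 and sampled frequencies must pass chi-square
goodness-of-fit against the exact marginals. Complexity is linear in
members x loci: a 1,000-member, 100-locus pedigree completes
posteriors plus 1,000 replicates in roughly ten seconds on one CPU
(the test suite enforces under sixty).

## Family burden statistic (`prioriseq.family_burden`)

A family with members carrying disease probabilities p_j (from the
logistic risk model) and y_obs affected members is scored by
P(Y >= y_obs), with Y the Poisson-binomial sum of independent
Bernoulli(p_j); the tail is evaluated exactly by O(N^2) dynamic-
programming convolution. The closed tail (">=") is chosen so that
y_obs = 0 always yields 1. Member phenotypes are conditionally
independent given genotypes in the base statistic — that is what
makes the exact tail available.

With missing genotypes the tail is averaged over R conditional
genotype replicates drawn by the inside-outside sampler, with the
Monte-Carlo SE reported; fully genotyped families skip sampling
entirely and return a deterministic tail with zero SE. Genotype
sampling conditions only on observed genotypes, not on phenotypes:
ascertainment-corrected sampling (families are in the collection
*because* they are multiply affected) is a known approximation gap,
recorded here deliberately.

An optional polygenic residual models risk at loci nobody has typed:
a multivariate-normal liability term with covariance 2 * kinship *
residual_variance, folded into member probabilities on the probit
scale via the threshold-equivalent bridge T_j = Phi^-1(1 - p_j),
p_j' = 1 - Phi(T_j - r_j) — the logistic probability is mapped to the
liability threshold that reproduces it, shifted by the sampled
residual, and mapped back. With residual_variance = 0 this reproduces
the base statistic exactly. Families are ranked by ascending tail
probability; ties break by smaller expected affected count (the more
surprising family first), then input order.

## Family and cohort simulators (`prioriseq.family_sim`)

The family generator follows the infinitesimal liability model.
Liability is the sum of a known-score component s (variance V), a
residual genetic component (variance h2 - V) and an environment
component (variance 1 - h2); offspring inherit each heritable
component as the parental midpoint plus a segregation deviate of half
the component variance, which conserves the component variance across
generations. Families are ascertained by rejection sampling to an
exact affected count (default: exactly 3 affected among parents and
offspring, the stated design of the experiments this reproduces); the
sampler runs in vectorized batches and aborts if the acceptance rate
falls below 1e-6 after 10^7 attempts.

A dominant mutation is modelled as one heterozygous carrier parent
plus Mendelian (probability 1/2) transmission to each offspring.
Carriers receive a fixed liability increment T - Phi^-1(1 - gamma),
which makes the marginal carrier penetrance P(affected | carrier)
exactly gamma. A mechanism in which the mutation acts as an
independent Bernoulli(gamma) cause OR-ed with polygenic affection was
evaluated and rejected: it decouples carrier affection from polygenic
liability, which materially overstates how distinguishable low-
penetrance mutation families are from polygenic-only families under
ascertainment (small-family, penetrance-0.10 detection AUC ~0.71
versus ~0.62 for the liability increment), and its marginal carrier
penetrance is 1-(1-gamma)(1-K) rather than gamma. The liability-
increment form is both the cleaner reading of "a dominant mutation
with penetrance gamma" and the one consistent with the detection
performance this package's experiments are designed to reproduce.

The mutation-detection experiment ranks mutation against non-mutation
families by the burden tail computed from member *scores*: given s_j,
the member's disease probability is 1 - Phi((T - s_j)/sqrt(1 - V)),
and the family tail is the exact Poisson-binomial evaluated at the
ascertained affected count. Scores rather than explicit loci are
simulated because the experiment is parametrised by variance captured,
not by locus counts (explicit-locus pipelines are available through
the risk-model and pedigree modules and are exercised by integration
tests). Shared residual-genetic covariance is *not* folded into the
tail statistic (conditional independence given scores); the polygenic
extension in the burden module is available for sensitivity analysis.
Discrimination is summarised as the Mann-Whitney AUC with smaller
tails ranked as more mutation-like and ties counted half. Canonical
experiment conditions: prevalence 1%, heritability 50%, score
variance 12.5% (a predictor capturing a quarter of heritability),
2-8 offspring, penetrance 0.10-1.00, exactly 3 affected, 5,000
families per arm and cell — at those sizes the two headline cells run
in roughly twenty and five seconds respectively.

The cohort simulators draw the same liability decomposition for
unrelated individuals (with the test variant's calibrated liability
shift, or its quantitative beta) and serve as the Monte-Carlo oracles
for the analytic selection theory; their own calibration (realized
prevalence, realized odds ratio) is covered by tests.

What the simulators deliberately do not emulate: linkage and LD
between loci, genotyping error, gene-gene interaction, assortative
mating, shared environment, variable ascertainment schemes, and
phenotype-conditioned genotype distributions within ascertained
families. Tests passing on these simulations therefore validate the
*methods* under their stated model, not the model's fidelity to any
particular disease.

## Limitations

- Pedigrees with loops (consanguinity, double marriages into the same
  lineage) are rejected, not approximated.
- The burden statistic ignores ascertainment when integrating over
  missing genotypes (see above).
- Effects are taken as given; winner's-curse shrinkage of GWAS
  estimates is out of scope.
- The trend-test power formula is asymptotic; for very rare alleles
  and small samples an exact test would differ.
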