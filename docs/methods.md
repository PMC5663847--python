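# Methods

This note documents the models, estimators, priors and numerical choices the
package implements, and what its synthetic-data validation does and does not
establish.

## Data model and filtering

Microsatellite alleles are stored in repeat units; base-pair input is divided
by the locus motif length, with a hard error on non-integral division (the M
ratio and the stepwise mutation model operate on repeat counts, and silent
rounding would corrupt both). A genotype is typed or missing as a pair —
missing is never encoded as a size-0 allele inside a computation. Individuals
present only in the mtDNA alignment are legal and enter sequence statistics
only.

The inclusion filter keeps an individual iff it is typed at ≥6 of the 11
microsatellite loci, or at ≥5 loci while also carrying the mtDNA sequence
(at least half of the twelve loci available, counting the mtDNA as one). The
filter is idempotent and reports each removal with its reason.

Alignment columns containing gaps or ambiguity codes are excluded listwise
from every sequence statistic and distance.

## Diversity statistics

* He = 1 − Σp² per locus without small-sample correction (the default of the
  desktop tools commonly used for such tables); the Nei unbiased variant is
  available behind a flag. Ho is the fraction of heterozygous typed
  individuals.
* F_IS uses Weir & Cockerham's within-population variance components
  (b and c summed over alleles and loci, f = 1 − Σc/Σ(b+c)); a simple
  1 − ΣHo/ΣHe variant is provided (`method="nei"`) because published tables
  of this kind are often produced that way. Significance: 10⁴ permutations of
  gene copies among individuals within the population (enforcing
  Hardy–Weinberg while preserving allele frequencies and the missing
  pattern), two-tailed.
* Pairwise F_ST is the multilocus Weir–Cockerham θ as a ratio of summed
  components; 95% CIs by bootstrap over loci (the source tables do not state
  bootstrap vs jackknife; bootstrap chosen and documented), p-values by
  permuting individuals between the pair, Bonferroni-corrected across pairs
  in pipeline reports.
* Rarefied allelic richness uses the exact hypergeometric form
  `A_r = Σ_i [1 − C(N−N_i, g)/C(N, g)]` on gene copies; private allelic
  richness multiplies the focal presence probability by the absence
  probability in every other population. The rarefaction unit is gene
  copies. The published table's "26 individuals" cannot be 52 copies for
  groups of 16–17 diploids, so the pipeline default rarefies at the largest
  gene-copy count feasible in every population and locus, capped at 52; the
  private-allele rarefaction default is 6 copies. Both are configurable.
* M ratio: per locus M = k/(r+1) with k distinct alleles and r the size
  range; loci monomorphic within a population contribute M = 1 by default
  (exclusion available). Its significance is the fraction of constant-size
  coalescent simulations (Ne uniform on [10, 20000], μ log-uniform on
  [10⁻⁴, 10⁻³], GSM parameter uniform on [0, 0.3]), matched to the
  population's sample size and locus count, that fall below the observed
  value. The null distribution is reusable across populations with the same
  configuration.
* Sequence side: S with singleton/shared decomposition (a site is a
  singleton when exactly one sequence deviates), haplotype diversity
  n/(n−1)(1 − Σp²), π as mean pairwise difference per clean site, θ_W =
  S/(a₁L). Tajima's D uses the standard variance constants; monomorphic or
  n<4 samples report D = 0 with a degeneracy flag. Its p-value comes from
  10⁴ constant-size coalescent replicates conditioned on n and the Watterson
  estimate of θ (per locus), two-tailed; the null simulator is a vectorised
  infinite-sites coalescent written for this purpose.
* Hudson F_ST = 1 − H_w/H_b with H_w the unweighted mean of the two
  within-population mean pairwise differences and H_b the mean
  between-population difference; reciprocally monomorphic distinct samples
  give exactly 1. Because within-population pairs are sampled without
  replacement, single realizations carry an O(1/n) negative bias around 0 —
  the estimator is unbiased only in expectation. Significance comes from the
  Snn permutation test: each sequence's nearest neighbours (minimum Hamming
  distance, ties sharing weight equally) are computed once, so label
  permutations only re-score membership.

## Coalescent simulator

Genealogies come from msprime's continuous-time coalescent (adequate for
deme sizes ≥ ~10; no recombination, migration or selection — the shipped
scenarios are isolation models). Deme sizes are diploid individuals; nuclear
lineages coalesce at rate 1/(2N). The mtDNA locus is haploid and maternal:
with an even sex ratio its effective copy number is N/2, implemented as a
haploid deme of size N/2, giving pairwise rate 2/N and a mean TMRCA one
quarter of the nuclear value (asserted by test). The corresponding Watterson
scale is θ_mt = N·μ·L.

Microsatellite mutations are dropped on the simulated trees by a generalized
stepwise model written here: Poisson counts at μ per locus per generation
along each branch; step magnitudes geometric with parameter P_GSM (P_GSM = 0
is the strict stepwise model), signs symmetric; a contiguous allele range of
40 states with reflecting boundaries by default (unbounded available — used
by the closed-form variance test E[(Δsize)²] = 2μt(1+P)/(1−P)²); the root
allele sits at the range midpoint, which is inconsequential because every
statistic used is translation-invariant. The mtDNA locus mutates under
finite-sites HKY (default κ = 10) via msprime.

Times in scenario files are years, converted with a generation time of 10
years (the collapse window "last five generations" equals 50 years under
this convention).

## Scenario sets and priors

Scenarios are declarative: parameter declarations (uniform or log-uniform),
deme-size expressions, split/resize event templates referencing parameters,
and inequality conditions enforced by rejection resampling (error after 10⁵
failed draws). Sets serialise to YAML with full fidelity.

Shipped sets (all on the three distinct populations XCSS/PY/TL):

1. **Branching order (10):** the trichotomy; the three rooted bifurcations;
   and six serial-colonization chains in which each daughter was founded
   from another daughter. Chains were chosen over admixture templates
   because they need no admixture-proportion parameter and stay inside the
   split/resize DSL; the set is configurable, so alternative topologies can
   be supplied as YAML without code changes.
2. **Size change (6):** constant; daughter decline; ancestral founder
   bottleneck (N_anc2 → N_founder for a duration DB → expansion to N_exp2 at
   T_exp2, split at T_isol2); simple ancestral change; daughter expansion;
   change in both. Forcing N_anc2 = N_founder = N_exp2 in the founder
   scenario recovers the constant scenario (nesting, asserted by a
   Kolmogorov–Smirnov test on simulated statistics).
3. **Recent collapse (2):** the founder history with daughters constant
   since the split, versus the same history plus an independent collapse in
   every daughter at a shared time within the last 5 generations, remnant
   fractions log-uniform on [0.001, 1].

Default priors: population sizes uniform [10, 20000] individuals; split
times uniform [100, 5000] years; the expansion time uniform
[1000, 50000] years; bottleneck duration uniform [10, 500] years; collapse
time uniform [1, 50] years. Mutation priors: μ_mic log-uniform
[10⁻⁴, 10⁻³] per locus per generation, P_GSM uniform [0, 0.3], μ_mt
log-uniform [10⁻⁸, 10⁻⁶] per site per generation, κ fixed at 10. These are
consistent with the scale of the posterior estimates the analysis is meant
to explore; all are overridable per scenario set.

## ABC engine

Summary statistics per dataset: per population — mean allele count, mean He,
mean allele-size variance, mean M ratio, mtDNA S, haplotype diversity, π and
Tajima's D; per pair — Weir–Cockerham θ, shared-allele distance, Goldstein's
(δμ)² and Hudson's mtDNA F_ST. Non-finite values (Tajima's D of a
monomorphic sample) are imputed as 0 with a 0/1 degeneracy indicator
appended, so monomorphism itself remains informative.

Rejection standardises statistics by the reference-table median absolute
deviation, falling back to the standard deviation for columns whose MAD is
zero but variance is not (statistics that vanish in most PODs, e.g. mtDNA S
under small sizes, would otherwise be discarded); columns constant
everywhere are dropped with a warning. Ties in distance break by row index
for determinism.

Model choice: (a) ABC-LDA — linear discriminant projection of the accepted
statistics, multinomial logistic regression on the axes, probabilities
evaluated at the observed point, delta-method CIs from the
observed-information covariance of a baseline-category Newton fit (omitted
under separation); a scenario absent from the accepted rows receives
probability 0 with a warning. (b) ABC-RF — a classification forest (default
500 trees) on the raw statistics plus LDA axes; the prior error rate is the
out-of-bag misclassification rate; the posterior probability of the selected
scenario is a regression forest trained on out-of-bag correctness, its
spread across trees reported as an SD. Error calibration classifies fresh
held-out PODs per scenario into a row-normalised confusion matrix with
type-I (1 − diagonal) and type-II (false-assignment) rates.

Parameter estimation: local-linear regression of each parameter
(logit-transformed within its prior bounds) on the MAD-standardised
deviation of the statistics from the observed point, Epanechnikov weights in
distance; the fitted trend is removed and the intercept retained, then
back-transformed — adjusted draws therefore respect the prior bounds by
construction. Point summaries: weighted KDE mode, weighted mean and
quantiles (2.5/5/50/95/97.5%). The regression needs clearly more accepted
rows than statistics (p ≈ 55 here): with fewer than 50 rows the function
refuses, and the pipeline widens the estimation tolerance until at least
max(100, 2 × dim) rows are accepted. At the package defaults
(10⁴ PODs/scenario, 1% tolerance) this is automatic.

Posterior predictive checks resample posterior draws, re-simulate, and
locate each observed statistic by a two-tailed empirical tail probability
with the +1 continuity correction; p < 0.05 flags a misfit.

The three analysis steps run sequentially, each conditioning on the previous
winner (winners are never revisited), mirroring the nested design of the
original workflow.

## LD-Ne

Burrows Δ̂ from unphased genotype dosages with the S/(S−1) correction,
r² = Δ̂²/(p(1−p)q(1−q)), inter-locus allele pairs only, both allele
frequencies > P_crit (default 0.02). The S-weighted mean r² minus the
random-mating sampling expectation (1/S + 3.19/S² for S ≥ 30, else
0.0018 + 0.907/S + 4.44/S²) enters the published quadratic solution for Ne;
non-positive r²′ reports infinity. Two CI flavours are emitted: jackknife
over loci (the reported default — its 95% interval covers a known simulated
Ne = 50 about 90% of the time in the validation experiment) and a parametric
χ² interval on the number of comparisons, which is markedly anticonservative
because allele-pair comparisons are far from independent — it is provided
for comparability, not inference. The sampling-expectation formulas are
empirical fits accurate to a few percent of their own value; the panmixia
validation therefore allows a 3%-of-expectation margin on top of Monte-Carlo
error. Random mating only; monogamy variants are out of scope.

## Synthetic data and what the tests show

The generator reproduces the study design — 58/17/17/53/3 diploids in five
groups (the three differentiated populations, the admixed group, and the
tiny river-mouth group as a fifth deme of the split), 11 loci, 129 of 148
individuals with a 597-bp mtDNA sequence, 5% missing genotypes at random —
under an explicit truth: ancestral size 18 700, founder size 60 at 3 400
years with a 100-year bottleneck, expansion to 5 660, five-way split at
1 030 years into daughters of 2 000, and (in the collapse variant) a
collapse 50 years ago to a 2% remnant. A discrete Wright–Fisher forward
simulator (no mutation, ~30 generations from linkage-equilibrium standing
variation) provides genotypes whose inter-locus LD reflects a known Ne for
the LD-Ne validation.

What passing tests establish: the estimators agree with closed forms, exact
enumeration and independent hand computations; the simulator matches
coalescent expectations; scenario choice is calibrated (coin-flip on
identical scenarios, near-certain on separable ones) and recovers a planted
collapse; posteriors of the identifiable parameters cover their truths at
close to nominal rates. What they do not establish: robustness to real-data
pathologies the generator omits — genotyping error, null alleles, gaps and
ambiguities beyond random missingness, departures from the isolation model
(migration during divergence), or uncertainty in the cluster assignment
itself, which the pipeline takes as given.

## Problem sizes and numerical defaults

Library defaults target the full-scale analysis (10⁴–10⁶ PODs per scenario,
10⁴ permutations/bootstraps, 10⁴ null simulations). The shipped tests and
the acceptance script run the same code at desk scale — reference tables of
2 500–5 000 rows per scenario set, 100-replicate recovery experiments,
10⁴-replicate coalescent analytics, reduced permutation counts — sizes
chosen so the whole validation runs on a laptop while keeping Monte-Carlo
error within the stated tolerances. Every stochastic component accepts a
seed and is reproducible bit-for-bit under it.

## Known limitations

* The founder-phase population size is not separately identifiable from the
  bottleneck duration (only their intensity ratio matters for coalescence);
  its posteriors are prior-dominated and its interval coverage is poor —
  deliberately excluded from the headline-parameter validation.
* The logistic-regression CIs are asymptotic; under near-separation they are
  omitted rather than reported unreliably.
* Hudson F_ST single realizations around 0 are biased low by O(1/n).
* The six non-trichotomy, non-bifurcation topologies are serial-colonization
  approximations of admixture-type alternatives; replace them via YAML if an
  admixture parameterisation is required.
* The exact composition of the admixed group in the original study cannot be
  recovered from locality labels alone; reproducing the published per-group
  numbers requires the original assignment file.
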