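# rpabc

Population-genetic inference for endangered riverine porpoise populations —
and, more generally, for any small, recently fragmented population sampled
with microsatellites and a maternally inherited sequence locus.

The package addresses a conservation-genetics question: given diploid
microsatellite genotypes and mtDNA control-region sequences from a handful of
populations, how diverse and differentiated are they, how many breeding
individuals do they effectively contain, and what demographic history —
founder events, splits, recent collapses — best explains the data?

It provides, as one coherent library:

* **Diversity and differentiation statistics** — observed/expected
  heterozygosity, Weir & Cockerham F_IS and pairwise θ (F_ST) from variance
  components with permutation tests and bootstrap CIs, rarefied (private)
  allelic richness, the Garza–Williamson M ratio `M = k/(r+1)` with a
  coalescent-simulation significance test, and for sequences S, haplotype
  diversity, π, Watterson's θ_W, Tajima's D with a coalescent null, Hudson's
  F_ST `1 − H_w/H_b` and the Snn nearest-neighbour permutation test.
* **LD-based contemporary Ne** — Burrows composite disequilibrium Δ̂ across
  inter-locus allele pairs (rare alleles screened at P_crit), the
  bias-corrected random-mating estimator
  `N̂e = (1/3 + √(1/9 − 2.76 r̂²′)) / (2 r̂²′)` with `r̂²′ = r̂² − E[r²_sample]`,
  and jackknife plus parametric confidence intervals.
* **A coalescent simulator** (msprime-backed) for multi-population histories
  with piecewise-constant sizes, splits and bottlenecks; microsatellites
  mutate under a generalized stepwise model (geometric step sizes, reflecting
  allele-range bound) and the mtDNA locus under finite-sites HKY at one
  quarter of the nuclear effective size.
* **A nested ABC workflow** — a declarative scenario DSL shipping three
  scenario sets (10 branching orders → 6 size-change scenarios → constancy
  vs recent collapse), reference-table simulation, rejection on
  MAD-standardised Euclidean distance, model choice by multinomial logistic
  regression on LDA axes (ABC-LDA) and by random forest with out-of-bag
  posterior estimation (ABC-RF), type-I/type-II error calibration, local
  linear-regression parameter posteriors, and posterior predictive checks.
* **A synthetic-data generator** that emulates the study design (148
  diploids in 5 groups, 11 loci, 129 × 597 bp mtDNA, ~5% missing genotypes)
  under a known truth, so every stage is testable end to end.

## Worked example

`examples/01_diversity_statistics.py` generates a synthetic study-like
dataset under the fitted demographic history and prints the diversity table:

```
dataset: 148 diploids x 11 loci, 129 mtDNA sequences of 597 bp

per-population microsatellite diversity:
   pop     He     Ho    A_r   M_GW      M p
    PY  0.755  0.770   2.86  0.611   0.0000
    TL  0.736  0.737   2.87  0.509   0.0000
  XCSS  0.752  0.776   2.92  0.580   0.0000
 Admix  0.768  0.810   2.90  0.613   0.0000
    SH  0.681  0.909   3.17  0.473   0.1380

mtDNA (all 129 sequences): S=3, Hd=0.652, pi=0.196% per site, Tajima's D=1.92
```

`He` is expected heterozygosity (1 − Σp²) averaged over loci; `M_GW` is the
mean ratio of allele count to allele-size range — values near 0.5 with
simulation p-values of ~0 are the footprint of the planted bottleneck and
collapse. The pairwise θ values (~0.06–0.09 between groups) match the weak
but significant differentiation expected a few hundred generations after a
split.

The other examples cover LD-Ne recovery on a Wright–Fisher simulation
(`02`), the M-ratio bottleneck footprint (`03`), and the final ABC collapse
test with remnant-fraction posteriors (`04`). The `rpabc` command-line tool
(`rpabc simulate | stats | abc | ldne`) exposes the same pipeline for file
inputs (GenePop/CSV genotypes, FASTA alignments, CSV partitions).

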