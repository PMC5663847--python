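"""Diversity and differentiation statistics on a study-like dataset.

Generates a synthetic microsatellite + mtDNA dataset whose demographic truth
mirrors the fitted history of the riverine porpoise populations (founder
bottleneck, simultaneous split, recent collapse), then computes the per-
population diversity table and pairwise differentiation.
"""

from rpabc.pipeline import AnalysisConfig, run_stats
from rpabc.synthetic import TruthConfig, generate_study_like

geno, mt, partition, truth = generate_study_like(TruthConfig(seed=42))
print(f"dataset: {geno.n_individuals} diploids x {geno.n_loci} loci, "
      f"{mt.n_sequences} mtDNA sequences of {mt.length} bp")

config = AnalysisConfig(seed=1, n_perm=1000, n_boot=1000, snn_perm=500,
                        mgw_sims=500, tajima_sims=2000)
report = run_stats(geno, mt, partition, config)

print("\nper-population microsatellite diversity:")
print(f"{'pop':>6} {'He':>6} {'Ho':>6} {'A_r':>6} {'M_GW':>6} {'M p':>8}")
for pop, rec in report["microsat_diversity"].items():
    print(f"{pop:>6} {rec['he_mean']:6.3f} {rec['ho_mean']:6.3f} "
          f"{rec['ar_mean']:6.2f} {rec['m_gw']:6.3f} {rec['m_gw_p']:8.4f}")

total = report["mtdna_diversity"]["Total"]
print(f"\nmtDNA (all {total['n']} sequences): S={total['s']}, "
      f"Hd={total['hd']:.3f}, pi={100 * total['pi_per_site']:.3f}% per site, "
      f"Tajima's D={total['tajima_d']:.2f}")

print("\npairwise microsatellite F_ST (Weir-Cockerham theta):")
for rec in report["pairwise_fst"]["microsatellite"]:
    a, b = rec["pair"]
    print(f"  {a:>6} vs {b:<6} theta={rec['fst']:6.3f}  {rec['stars']}")

print("\nA small M ratio (<<1) with a small simulation p-value is the "
      "bottleneck footprint: allele counts drop faster than the allele-size "
      "range. He near the empirical 0.6-0.7 and low F_ST between recently "
      "split groups mirror the study system.")
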