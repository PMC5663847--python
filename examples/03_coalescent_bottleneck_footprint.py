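"""Coalescent simulation: the M-ratio footprint of a bottleneck.

Simulates microsatellite datasets under a constant-size history and under a
sharp recent bottleneck, and contrasts the Garza-Williamson M ratio, the
statistic the demographic analysis leans on to detect collapses.
"""

import numpy as np

from rpabc.coalsim import (MutationModel, RealizedDemography, ResizeEvent,
                           SamplingDesign, ScenarioDraw, simulate_dataset)

design = SamplingDesign(n_diploid={"P": 20}, n_mt={"P": 0},
                        n_loci=11, mt_length=0)
model = MutationModel(mu_mic=5e-4, p_gsm=0.2)
constant = RealizedDemography(populations={"P": 5000.0})
bottleneck = RealizedDemography(populations={"P": 50.0},
                                events=[ResizeEvent(50.0, "P", 5000.0)])

def mean_m(dem, seed):
    geno, _ = simulate_dataset(ScenarioDraw({}, dem, model), design, seed)
    ms = []
    for l in range(geno.n_loci):
        s = geno.alleles[:, l, :].ravel()
        ms.append(len(np.unique(s)) / (np.ptp(s) + 1))
    return float(np.mean(ms))

m_const = [mean_m(constant, 100 + k) for k in range(40)]
m_bott = [mean_m(bottleneck, 500 + k) for k in range(40)]
print(f"constant N=5000          : mean M = {np.mean(m_const):.3f}")
print(f"bottleneck 5000->50,     : mean M = {np.mean(m_bott):.3f}")
print( "50 generations ago")
print("\nA bottleneck removes alleles faster than it shrinks the allele-size "
      "range, so M = k/(range+1) drops well below its constant-size value; "
      "this one-sided shift is what the simulation-based M test detects.")
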