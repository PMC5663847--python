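"""Contemporary effective population size from linkage disequilibrium.

For every pair of alleles at different loci, the Burrows composite
disequilibrium is estimated from unphased diploid genotypes,

    Delta_AB = (1/S) * [2 n_AABB + n_AABb + n_AaBB + n_AaBb / 2] - 2 p_A p_B ,

scaled by S/(S-1) and squared into r^2 = Delta^2 / (p_A(1-p_A) p_B(1-p_B)).
Rare alleles with frequency <= p_crit (0.02 by default, following standard
practice for LD-Ne estimation) are screened out.  The weighted mean r^2 across
allele pairs (weights = pair sample size S) is corrected for the sampling
contribution expected under random mating,

    S >= 30:  E[r^2_sample] = 1/S + 3.19/S^2
    S <  30:  E[r^2_sample] = 0.0018 + 0.907/S + 4.44/S^2

and Ne follows from the bias-corrected random-mating solution

    S >= 30:  Ne = (1/3 + sqrt(1/9 - 2.76 r2'))   / (2 r2')
    S <  30:  Ne = (0.308 + sqrt(0.308^2 - 2.08 r2')) / (2 r2')

with r2' = r^2 - E[r^2_sample]; r2' <= 0 (or a negative discriminant) reports
an infinite estimate.  Confidence intervals are emitted both by jackknife over
loci and parametrically (chi-squared on the effective number of independent
allele-pair comparisons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import chi2

from .popdata import MISSING, GenotypeTable


class LdNeError(ValueError):
    pass


@dataclass
class LdNeConfig:
    p_crit: float = 0.02
    mating: str = "random"

    def __post_init__(self) -> None:
        if not (0 <= self.p_crit < 0.5):
            raise LdNeError("p_crit must be in [0, 0.5)")
        if self.mating != "random":
            raise LdNeError("only the random-mating model is implemented")


@dataclass
class AllelePairR2:
    locus_a: int
    locus_b: int
    allele_a: int
    allele_b: int
    r2: float
    sample_size: int  # individuals typed at both loci


@dataclass
class NeEstimate:
    ne_point: float  # may be math.inf
    ci95_jackknife: tuple[float, float]
    ci95_parametric: tuple[float, float]
    mean_r2: float
    expected_sample_r2: float
    n_comparisons: int
    harmonic_mean_s: float


def _burrows_delta(ga: np.ndarray, gb: np.ndarray, allele_a: int,
                   allele_b: int) -> tuple[float, float, float, int]:
    """(Delta, p_A, p_B, S) for one allele pair from unphased genotype columns.

    ``ga``/``gb`` are (n, 2) allele-size arrays restricted to individuals
    typed at both loci.
    """
    s = len(ga)
    da = (ga == allele_a).sum(axis=1)  # copies of A per individual: 0/1/2
    db = (gb == allele_b).sum(axis=1)
    p_a = da.mean() / 2
    p_b = db.mean() / 2
    joint = np.mean(da * db) / 2
    delta = joint - 2 * p_a * p_b
    delta *= s / (s - 1)
    return float(delta), float(p_a), float(p_b), s


def burrows_r2(geno: GenotypeTable, p_crit: float = 0.02) -> list[AllelePairR2]:
    """r^2 for every screened inter-locus allele pair.

    Allele frequencies for screening are computed among individuals typed at
    the locus; both alleles of a pair must exceed ``p_crit``.  Loci are never
    paired with themselves.
    """
    if geno.n_loci < 2:
        raise LdNeError("need >= 2 loci")
    # per-locus screened alleles
    screened: list[list[int]] = []
    for l in range(geno.n_loci):
        col = geno.alleles[:, l, :]
        col = col[col[:, 0] != MISSING]
        if len(col) == 0:
            screened.append([])
            continue
        vals, counts = np.unique(col.ravel(), return_counts=True)
        freqs = counts / counts.sum()
        keep = [int(v) for v, f in zip(vals, freqs)
                if f > p_crit and f < 1.0 - 1e-12]
        # a locus with a single surviving allele carries no LD information
        screened.append(keep if len(keep) >= 1 and len(vals) >= 2 else [])
    pairs: list[AllelePairR2] = []
    typed = geno.typed_mask()
    for la, lb in combinations(range(geno.n_loci), 2):
        both = typed[:, la] & typed[:, lb]
        s = int(both.sum())
        if s < 3:
            continue
        ga = geno.alleles[both, la, :]
        gb = geno.alleles[both, lb, :]
        for a in screened[la]:
            for b in screened[lb]:
                delta, p_a, p_b, s = _burrows_delta(ga, gb, a, b)
                denom = p_a * (1 - p_a) * p_b * (1 - p_b)
                if denom <= 0:
                    continue
                pairs.append(AllelePairR2(la, lb, a, b, delta ** 2 / denom, s))
    if len(pairs) < 2:
        raise LdNeError("fewer than 2 usable allele pairs after screening")
    return pairs


def expected_sample_r2(s: float) -> float:
    """Sampling contribution to r^2 under random mating (Waples correction)."""
    if s >= 30:
        return 1.0 / s + 3.19 / s ** 2
    return 0.0018 + 0.907 / s + 4.44 / s ** 2


def _ne_from_r2prime(r2p: float, s: float) -> float:
    if r2p <= 0:
        return math.inf
    if s >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2p
        if disc < 0:
            return math.inf
        ne = (1.0 / 3.0 + math.sqrt(disc)) / (2 * r2p)
    else:
        disc = 0.308 ** 2 - 2.08 * r2p
        if disc < 0:
            return math.inf
        ne = (0.308 + math.sqrt(disc)) / (2 * r2p)
    return ne if ne > 0 else math.inf


def _point_estimate(pairs: list[AllelePairR2]) -> tuple[float, float, float, float]:
    w = np.array([p.sample_size for p in pairs], dtype=float)
    r2 = np.array([p.r2 for p in pairs])
    mean_r2 = float(np.average(r2, weights=w))
    s_harm = float(len(w) / np.sum(1.0 / w))
    exp_r2 = expected_sample_r2(s_harm)
    ne = _ne_from_r2prime(mean_r2 - exp_r2, s_harm)
    return ne, mean_r2, exp_r2, s_harm


def ldne_estimate(geno: GenotypeTable, config: LdNeConfig | None = None
                  ) -> NeEstimate:
    """LD-based contemporary Ne of one population sample.

    Point estimate from the S-weighted mean r^2 minus its sampling
    expectation; jackknife-over-loci CI (delete one locus, re-estimate, normal
    interval on r2') and a parametric chi-squared CI on the effective degrees
    of freedom (number of independent comparisons).
    """
    config = config or LdNeConfig()
    pairs = burrows_r2(geno, config.p_crit)
    ne, mean_r2, exp_r2, s_harm = _point_estimate(pairs)
    n_comp = len(pairs)

    # jackknife over loci
    loci = sorted({p.locus_a for p in pairs} | {p.locus_b for p in pairs})
    jack_r2p = []
    for drop in loci:
        rest = [p for p in pairs if drop not in (p.locus_a, p.locus_b)]
        if len(rest) < 2:
            continue
        _, m, e, _ = _point_estimate(rest)
        jack_r2p.append(m - e)
    r2p = mean_r2 - exp_r2
    if len(jack_r2p) >= 2:
        jack_r2p = np.array(jack_r2p)
        g = len(jack_r2p)
        var = (g - 1) / g * np.sum((jack_r2p - jack_r2p.mean()) ** 2)
        half = 1.959964 * math.sqrt(var)
        lo_r2p, hi_r2p = r2p - half, r2p + half
        ci_jack = (_ne_from_r2prime(hi_r2p, s_harm),
                   _ne_from_r2prime(lo_r2p, s_harm))
    else:
        ci_jack = (0.0, math.inf)

    # parametric: r2 * n / chi2 quantiles with n = number of comparisons
    lo_r2 = mean_r2 * n_comp / chi2.ppf(0.975, n_comp)
    hi_r2 = mean_r2 * n_comp / chi2.ppf(0.025, n_comp)
    ci_par = (_ne_from_r2prime(hi_r2 - exp_r2, s_harm),
              _ne_from_r2prime(lo_r2 - exp_r2, s_harm))
    return NeEstimate(ne_point=ne,
                      ci95_jackknife=(float(ci_jack[0]), float(ci_jack[1])),
                      ci95_parametric=(float(ci_par[0]), float(ci_par[1])),
                      mean_r2=mean_r2, expected_sample_r2=exp_r2,
                      n_comparisons=n_comp, harmonic_mean_s=s_harm)
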