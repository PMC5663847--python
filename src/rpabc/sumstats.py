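"""Diversity and differentiation statistics for microsatellite and mtDNA data.

Microsatellite side: observed/expected heterozygosity, Weir & Cockerham F_IS and
pairwise theta (F_ST) from variance components, rarefied (private) allelic
richness, and the Garza-Williamson M ratio with its coalescent-simulation null
test.  Sequence side: segregating sites, haplotype diversity, pi, Watterson's
theta, Tajima's D with a coalescent null, Hudson's F_ST from mean pairwise
differences, and the Snn nearest-neighbour permutation test.

All statistics treat a missing genotype as absent (never as size 0), and exclude
alignment columns containing non-ACGT symbols listwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .popdata import (MISSING, GenotypeTable, HaplotypeAlignment,
                      PopulationPartition)


class StatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Allele bookkeeping
# ---------------------------------------------------------------------------

def _pop_tables(geno: GenotypeTable, partition: PopulationPartition
                ) -> dict[str, GenotypeTable]:
    out = {}
    for label in partition.labels:
        members = partition.members(label, geno.individual_ids)
        if members:
            out[label] = geno.subset(members)
    return out


def allele_counts(table: GenotypeTable, locus: int) -> dict[int, int]:
    """Counts of each allele (gene copies) among typed individuals at a locus."""
    col = table.alleles[:, locus, :]
    flat = col[col[:, 0] != MISSING].ravel()
    if flat.size == 0:
        return {}
    if flat.max() < 100_000:  # bincount beats unique for small allele sizes
        bc = np.bincount(flat)
        vals = np.nonzero(bc)[0]
        return dict(zip(vals.tolist(), bc[vals].tolist()))
    vals, counts = np.unique(flat, return_counts=True)
    return dict(zip(vals.tolist(), counts.tolist()))


# ---------------------------------------------------------------------------
# Heterozygosity and F_IS
# ---------------------------------------------------------------------------

@dataclass
class MicrosatDiversityRecord:
    population: str
    n_mean: float
    n_sd: float
    n_max: int
    na_frac: float
    he_mean: float
    he_sd: float
    ho_mean: float
    ho_sd: float
    fis: float | None
    fis_p: float | None
    m_gw: float
    ar_mean: float | None = None
    ar_se: float | None = None
    pa_mean: float | None = None
    pa_se: float | None = None
    m_gw_p: float | None = None


def heterozygosity(table: GenotypeTable, unbiased: bool = False
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (He, Ho).

    He = 1 - sum p_i^2 over typed gene copies; with ``unbiased`` the Nei (1978)
    small-sample correction 2n/(2n-1) is applied.  Ho = fraction of typed
    individuals that are heterozygous.
    """
    he = np.zeros(table.n_loci)
    ho = np.zeros(table.n_loci)
    for l in range(table.n_loci):
        counts = allele_counts(table, l)
        n_copies = sum(counts.values())
        if n_copies == 0:
            he[l] = ho[l] = np.nan
            continue
        p = np.array(list(counts.values())) / n_copies
        he[l] = 1.0 - np.sum(p ** 2)
        if unbiased and n_copies > 1:
            he[l] *= n_copies / (n_copies - 1)
        typed = table.alleles[:, l, :]
        typed = typed[typed[:, 0] != MISSING]
        ho[l] = np.mean(typed[:, 0] != typed[:, 1]) if len(typed) else np.nan
    return he, ho


def _wc_single_pop_components(table: GenotypeTable) -> tuple[float, float]:
    """Weir-Cockerham within-population components (sum b, sum c) over loci/alleles.

    For one population:  b = n/(n-1) * [p(1-p) - (2n-1)/(4n) * h],  c = h/2,
    where h is the frequency of heterozygotes carrying the allele.  The
    multilocus inbreeding coefficient is f = 1 - sum(c)/sum(b+c).
    """
    sum_b = sum_c = 0.0
    for l in range(table.n_loci):
        col = table.alleles[:, l, :]
        col = col[col[:, 0] != MISSING]
        n = len(col)
        if n < 2:
            continue
        alleles = np.unique(col)
        if len(alleles) < 2:
            continue
        for a in alleles:
            p = np.mean(col == a)
            h = np.mean((col == a).sum(axis=1) == 1)
            b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            c = h / 2
            sum_b += b
            sum_c += c
    return sum_b, sum_c


def inbreeding_fis(table: GenotypeTable, method: str = "wc") -> float | None:
    """Multilocus F_IS of one population (None if undefined: all loci monomorphic)."""
    if method == "wc":
        b, c = _wc_single_pop_components(table)
        denom = b + c
        return None if denom == 0 else 1.0 - c / denom
    elif method == "nei":
        he, ho = heterozygosity(table)
        ok = ~np.isnan(he) & (he > 0)
        if not ok.any():
            return None
        return 1.0 - ho[ok].sum() / he[ok].sum()
    raise StatError(f"unknown F_IS method {method!r}")


def fis_permutation_test(table: GenotypeTable, n_perm: int = 10_000,
                         seed: int | None = None, method: str = "wc"
                         ) -> tuple[float | None, float | None]:
    """F_IS with a two-tailed permutation p-value.

    The null randomizes gene copies among individuals within the population
    (per locus), which enforces Hardy-Weinberg while preserving allele
    frequencies and the missing-data pattern.
    """
    obs = inbreeding_fis(table, method)
    if obs is None:
        return None, None
    rng = np.random.default_rng(seed)
    hits = 0
    shuffled = GenotypeTable(table.individual_ids, table.locus_names,
                             table.alleles.copy(), table.motif_lengths,
                             table.locality)
    for _ in range(n_perm):
        arr = shuffled.alleles
        for l in range(table.n_loci):
            typed = arr[:, l, 0] != MISSING
            copies = arr[typed, l, :].ravel()
            rng.shuffle(copies)
            arr[typed, l, :] = copies.reshape(-1, 2)
        f = inbreeding_fis(shuffled, method)
        if f is not None and abs(f) >= abs(obs):
            hits += 1
    return obs, (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta (F_ST)
# ---------------------------------------------------------------------------

def _wc_locus_components(tables: Sequence[GenotypeTable], locus: int
                         ) -> tuple[float, float]:
    """(sum_a, sum_abc) over alleles at one locus for r >= 2 populations."""
    r = len(tables)
    ns, cols = [], []
    for t in tables:
        col = t.alleles[:, locus, :]
        col = col[col[:, 0] != MISSING]
        ns.append(len(col))
        cols.append(col)
    ns = np.array(ns, dtype=float)
    if (ns < 1).any() or ns.sum() < 2:
        return 0.0, 0.0
    alleles = np.unique(np.concatenate([c.ravel() for c in cols]))
    if len(alleles) < 2:
        return 0.0, 0.0
    n_bar = ns.mean()
    n_c = (r * n_bar - np.sum(ns ** 2) / (r * n_bar)) / (r - 1)
    # (r, A) allele-frequency and heterozygote-frequency matrices, vectorised
    p_i = np.empty((r, len(alleles)))
    h_i = np.empty((r, len(alleles)))
    for k, c in enumerate(cols):
        eq = c[:, :, None] == alleles[None, None, :]  # (n, 2, A)
        dose = eq.sum(axis=1)  # copies of each allele per individual
        p_i[k] = dose.sum(axis=0) / (2 * len(c))
        h_i[k] = (dose == 1).mean(axis=0)
    w = ns[:, None]
    p_bar = (w * p_i).sum(axis=0) / (r * n_bar)
    s2 = (w * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (w * h_i).sum(axis=0) / (r * n_bar)
    inner = p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4
    a_comp = n_bar / n_c * (s2 - inner / (n_bar - 1))
    b_comp = n_bar / (n_bar - 1) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c_comp = h_bar / 2
    return float(a_comp.sum()), float((a_comp + b_comp + c_comp).sum())


def wc_theta(tables: Sequence[GenotypeTable]) -> float:
    """Multilocus Weir-Cockerham theta: ratio of summed variance components."""
    a_tot = abc_tot = 0.0
    for l in range(tables[0].n_loci):
        a, abc = _wc_locus_components(tables, l)
        a_tot += a
        abc_tot += abc
    if abc_tot == 0:
        return np.nan
    return a_tot / abc_tot


@dataclass
class PairwiseDifferentiation:
    pair: tuple[str, str]
    fst: float
    ci95: tuple[float, float] | None
    p_value: float | None
    marker: str  # "nuclear" | "mitochondrial"


def pairwise_fst_microsat(geno: GenotypeTable, partition: PopulationPartition,
                          n_boot: int = 10_000, n_perm: int = 10_000,
                          seed: int | None = None
                          ) -> list[PairwiseDifferentiation]:
    """Pairwise Weir-Cockerham theta, bootstrap-over-loci 95% CI, permutation p.

    The permutation null reshuffles individuals between the two populations
    (one-tailed: theta_perm >= theta_obs).
    """
    pops = _pop_tables(geno, partition)
    labels = [l for l in partition.labels if l in pops]
    if len(labels) < 2:
        raise StatError("need >= 2 populations with members")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            ta, tb = pops[labels[i]], pops[labels[j]]
            per_locus = np.array([_wc_locus_components([ta, tb], l)
                                  for l in range(geno.n_loci)])
            a_l, abc_l = per_locus[:, 0], per_locus[:, 1]
            theta = a_l.sum() / abc_l.sum() if abc_l.sum() else np.nan
            usable = np.nonzero(abc_l != 0)[0]
            ci = None
            if len(usable) >= 2 and n_boot > 0:
                idx = rng.integers(0, geno.n_loci, size=(n_boot, geno.n_loci))
                num = a_l[idx].sum(axis=1)
                den = abc_l[idx].sum(axis=1)
                ok = den != 0
                reps = num[ok] / den[ok]
                if len(reps):
                    ci = (float(np.percentile(reps, 2.5)),
                          float(np.percentile(reps, 97.5)))
            p = None
            if n_perm > 0 and np.isfinite(theta):
                merged_ids = ta.individual_ids + tb.individual_ids
                merged = geno.subset(merged_ids)
                na = ta.n_individuals
                hits = 0
                order = np.arange(merged.n_individuals)
                for _ in range(n_perm):
                    rng.shuffle(order)
                    pa = merged.subset([merged_ids[k] for k in order[:na]])
                    pb = merged.subset([merged_ids[k] for k in order[na:]])
                    t_perm = wc_theta([pa, pb])
                    if np.isfinite(t_perm) and t_perm >= theta:
                        hits += 1
                p = (hits + 1) / (n_perm + 1)
            out.append(PairwiseDifferentiation((labels[i], labels[j]),
                                               float(theta), ci, p, "nuclear"))
    return out


# ---------------------------------------------------------------------------
# Rarefied allelic richness
# ---------------------------------------------------------------------------

def _absent_prob(n_total: int, n_allele: int, g: int) -> float:
    """P(a size-g gene-copy subsample misses an allele with n_allele copies)."""
    if n_total - n_allele < g:
        return 0.0
    return math.exp(gammaln(n_total - n_allele + 1) - gammaln(n_total - n_allele - g + 1)
                    - gammaln(n_total + 1) + gammaln(n_total - g + 1))


def allelic_richness(geno: GenotypeTable, partition: PopulationPartition,
                     g: int) -> dict[str, tuple[float, float]]:
    """Rarefied allelic richness per population at ``g`` gene copies.

    Per locus: A_r = sum over alleles of [1 - C(N - N_i, g) / C(N, g)];
    returned as (mean over loci, SE over loci).
    """
    pops = _pop_tables(geno, partition)
    out = {}
    for label, table in pops.items():
        per_locus = []
        for l in range(table.n_loci):
            counts = allele_counts(table, l)
            n_total = sum(counts.values())
            if n_total < g:
                raise StatError(
                    f"locus {table.locus_names[l]} in {label}: only {n_total} "
                    f"gene copies < g={g}")
            ar = sum(1.0 - _absent_prob(n_total, c, g) for c in counts.values())
            per_locus.append(ar)
        per_locus = np.array(per_locus)
        out[label] = (float(per_locus.mean()),
                      float(per_locus.std(ddof=1) / np.sqrt(len(per_locus)))
                      if len(per_locus) > 1 else 0.0)
    return out


def private_allelic_richness(geno: GenotypeTable,
                             partition: PopulationPartition,
                             g: int) -> dict[str, tuple[float, float]]:
    """Rarefied private allelic richness at ``g`` gene copies.

    For each allele: P(present in a size-g subsample of the focal population)
    times the product over the other populations of P(absent from their size-g
    subsamples); summed over alleles, averaged over loci.
    """
    pops = _pop_tables(geno, partition)
    labels = list(pops)
    out = {}
    for focal in labels:
        per_locus = []
        for l in range(geno.n_loci):
            counts_by_pop = {lab: allele_counts(pops[lab], l) for lab in labels}
            totals = {lab: sum(c.values()) for lab, c in counts_by_pop.items()}
            for lab, tot in totals.items():
                if tot < g:
                    raise StatError(
                        f"locus {geno.locus_names[l]} in {lab}: only {tot} "
                        f"gene copies < g={g}")
            all_alleles = set()
            for c in counts_by_pop.values():
                all_alleles |= set(c)
            pa = 0.0
            for a in all_alleles:
                present = 1.0 - _absent_prob(totals[focal],
                                             counts_by_pop[focal].get(a, 0), g)
                absent_others = 1.0
                for lab in labels:
                    if lab == focal:
                        continue
                    absent_others *= _absent_prob(
                        totals[lab], counts_by_pop[lab].get(a, 0), g)
                pa += present * absent_others
            per_locus.append(pa)
        per_locus = np.array(per_locus)
        out[focal] = (float(per_locus.mean()),
                      float(per_locus.std(ddof=1) / np.sqrt(len(per_locus)))
                      if len(per_locus) > 1 else 0.0)
    return out


# ---------------------------------------------------------------------------
# Garza-Williamson M
# ---------------------------------------------------------------------------

def garza_williamson_m(geno: GenotypeTable, partition: PopulationPartition,
                       include_monomorphic: bool = True
                       ) -> dict[str, float]:
    """Mean-over-loci M = k / (r + 1) per population (allele sizes in repeat units).

    k is the number of distinct alleles and r the allele-size range.  A locus
    monomorphic within the population has M = 1; ``include_monomorphic=False``
    drops such loci from the mean instead.
    """
    pops = _pop_tables(geno, partition)
    out = {}
    for label, table in pops.items():
        ms = []
        for l in range(table.n_loci):
            counts = allele_counts(table, l)
            if not counts:
                continue
            sizes = np.array(sorted(counts))
            if len(sizes) == 1 and not include_monomorphic:
                continue
            ms.append(len(sizes) / (sizes.max() - sizes.min() + 1))
        out[label] = float(np.mean(ms)) if ms else np.nan
    return out


def m_gw_null_distribution(n_diploid: int, n_loci: int, n_sims: int,
                           seed: int | None = None, *,
                           ne_bounds: tuple[float, float] = (10.0, 20_000.0),
                           mu_bounds: tuple[float, float] = (1e-4, 1e-3),
                           p_gsm_bounds: tuple[float, float] = (0.0, 0.3),
                           range_bound: int = 40) -> np.ndarray:
    """Null distribution of mean-over-loci M under constant population size.

    Each simulation draws Ne uniformly, the microsatellite mutation rate
    log-uniformly and the GSM parameter uniformly from their priors, simulates
    ``n_loci`` independent genealogies for ``n_diploid`` individuals in a
    constant-size deme, and records the mean M ratio.  The distribution can be
    reused across observed values with the same sampling configuration.
    """
    from . import coalsim  # deferred: avoids import at popdata-only use

    rng = np.random.default_rng(seed)
    values = np.empty(n_sims)
    for s in range(n_sims):
        ne = rng.uniform(*ne_bounds)
        mu = math.exp(rng.uniform(math.log(mu_bounds[0]), math.log(mu_bounds[1])))
        p_gsm = rng.uniform(*p_gsm_bounds)
        sizes = coalsim.simulate_constant_microsats(
            n_diploid=n_diploid, n_loci=n_loci, ne=ne, mu=mu, p_gsm=p_gsm,
            range_bound=range_bound, seed=int(rng.integers(1, 2**31 - 1)))
        ms = []
        for locus in sizes:  # (2*n_diploid,) allele sizes
            uniq = np.unique(locus)
            ms.append(len(uniq) / (uniq.max() - uniq.min() + 1))
        values[s] = np.mean(ms)
    return values


def m_gw_test(observed_m: float, n_diploid: int, n_loci: int,
              n_sims: int = 10_000, seed: int | None = None,
              null_values: np.ndarray | None = None, **null_kwargs) -> float:
    """p-value of an observed mean M ratio against the constant-size null.

    p = fraction of simulated M values below the observed one (a small p
    indicates a bottleneck footprint).  ``null_values`` allows reusing a
    precomputed null distribution.
    """
    if null_values is None:
        if n_sims < 100:
            raise StatError("n_sims < 100 gives an unstable p-value; refuse")
        null_values = m_gw_null_distribution(n_diploid, n_loci, n_sims,
                                             seed, **null_kwargs)
    elif len(null_values) < 100:
        raise StatError("null distribution too small (< 100)")
    return float(np.mean(null_values < observed_m))


# ---------------------------------------------------------------------------
# Sequence statistics
# ---------------------------------------------------------------------------

@dataclass
class SequenceDiversityRecord:
    population: str
    n: int
    length_used: int
    s: int
    singletons: int
    shared_polymorphisms: int
    n_hap: int
    hd: float
    pi_per_site: float
    theta_w_per_site: float
    tajima_d: float
    tajima_degenerate: bool
    tajima_p: float | None = None


def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def _site_spectrum(mat: np.ndarray) -> tuple[int, int, int, float]:
    """(S, singletons, shared, total mean pairwise difference) of a clean matrix."""
    n, L = mat.shape
    if L == 0:
        return 0, 0, 0, 0.0
    npairs = n * (n - 1) / 2
    letters = [b"A", b"C", b"G", b"T"] if mat.dtype.kind == "S" else list("ACGT")
    counts = np.stack([(mat == b).sum(axis=0) for b in letters])  # (4, L)
    poly = (counts > 0).sum(axis=0) > 1
    s = int(poly.sum())
    singles = int(((n - counts.max(axis=0) == 1) & poly).sum())
    same_pairs = (counts * (counts - 1) // 2).sum(axis=0)
    pi_total = float(((npairs - same_pairs)[poly] / npairs).sum())
    return s, singles, s - singles, pi_total


def tajima_d_value(pi_total: float, s: int, n: int) -> float:
    """Tajima's D from total mean pairwise differences, S and sample size."""
    if s == 0 or n < 4:
        return 0.0
    a1 = _harmonic(n)
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return 0.0
    return (pi_total - s / a1) / math.sqrt(var)


def sequence_diversity(mt: HaplotypeAlignment,
                       partition: PopulationPartition | None = None,
                       include_total: bool = True
                       ) -> list[SequenceDiversityRecord]:
    """Per-population (and total) sequence diversity summary.

    pi and theta_W are per site over the columns free of gaps/ambiguities;
    theta_W = S / (a_{n-1} * L).  Populations with n < 2 are flagged undefined.
    """
    groups: list[tuple[str, HaplotypeAlignment]] = []
    if include_total:
        groups.append(("Total", mt))
    if partition is not None:
        for label in partition.labels:
            members = partition.members(label, mt.individual_ids)
            if members:
                groups.append((label, mt.subset(members)))
    out = []
    for label, aln in groups:
        mat = aln.as_matrix()
        n = len(aln.sequences)
        L = mat.shape[1] if mat.size else aln.length
        if n < 2:
            out.append(SequenceDiversityRecord(label, n, L, 0, 0, 0,
                                               min(n, 1), 0.0, 0.0, 0.0,
                                               0.0, True))
            continue
        s, singles, shared, pi_total = _site_spectrum(mat)
        _, hap_counts = np.unique(mat, axis=0, return_counts=True)
        p_h = hap_counts / n
        hd = n / (n - 1) * (1 - np.sum(p_h ** 2)) if n > 1 else 0.0
        theta_w = s / (_harmonic(n) * L) if L else 0.0
        d = tajima_d_value(pi_total, s, n)
        out.append(SequenceDiversityRecord(
            label, n, L, s, singles, shared, len(hap_counts), float(hd),
            float(pi_total / L) if L else 0.0, float(theta_w), d,
            s == 0 or n < 4))
    return out


def simulate_tajima_null(n: int, theta: float, n_sims: int,
                         seed: int | None = None) -> np.ndarray:
    """Constant-size coalescent null distribution of Tajima's D.

    Conditions on the per-locus theta estimate (theta = 4*N*mu*L in coalescent
    units): genealogies are standard n-coalescents, mutations Poisson with rate
    theta/2 per unit branch length (infinite sites).  Vectorised across
    replicates; returns the n_sims simulated D values.
    """
    rng = np.random.default_rng(seed)
    sizes = np.ones((n_sims, n), dtype=np.int64)
    s_rep = np.zeros(n_sims, dtype=np.int64)
    pi_rep = np.zeros(n_sims)
    npairs = n * (n - 1) / 2
    for k in range(n, 1, -1):
        rate = k * (k - 1) / 2
        t = rng.exponential(1.0 / rate, size=n_sims)
        m = rng.poisson(theta / 2 * k * t)
        nz = np.nonzero(m)[0]
        for rep in nz:
            d = sizes[rep, rng.integers(0, k, size=m[rep])]
            s_rep[rep] += m[rep]
            pi_rep[rep] += np.sum(d * (n - d)) / npairs
        # merge a random pair of lineages in every replicate
        i_idx = rng.integers(0, k, size=n_sims)
        j_idx = rng.integers(0, k - 1, size=n_sims)
        j_idx = np.where(j_idx >= i_idx, j_idx + 1, j_idx)
        rows = np.arange(n_sims)
        sizes[rows, i_idx] += sizes[rows, j_idx]
        sizes[rows, j_idx] = sizes[rows, k - 1]
    return np.array([tajima_d_value(pi_rep[r], int(s_rep[r]), n)
                     for r in range(n_sims)])


def tajima_d_test(mt: HaplotypeAlignment, n_sims: int = 10_000,
                  seed: int | None = None) -> tuple[float, float | None, bool]:
    """(D, two-tailed simulation p-value, degenerate flag) for one alignment.

    Simulations are conditioned on the Watterson estimate of theta from the
    data (per locus, not per site).  Degenerate data (S = 0 or n < 4) reports
    D = 0 with no p-value.
    """
    mat = mt.as_matrix()
    n = mt.n_sequences
    if n < 2 or not mat.size:
        return 0.0, None, True
    s, _, _, pi_total = _site_spectrum(mat)
    d = tajima_d_value(pi_total, s, n)
    if s == 0 or n < 4:
        return 0.0, None, True
    theta = s / _harmonic(n)
    null = simulate_tajima_null(n, theta, n_sims, seed)
    p_low = np.mean(null <= d)
    p_high = np.mean(null >= d)
    return d, float(min(1.0, 2 * min(p_low, p_high))), False


# ---------------------------------------------------------------------------
# Hudson F_ST and Snn
# ---------------------------------------------------------------------------

def hamming_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distance (site counts) between rows of a clean matrix."""
    n = mat.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        dist[i] = (mat != mat[i]).sum(axis=1)
    return dist


def hudson_fst(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    """F_ST = 1 - Hw/Hb from mean pairwise differences (Hudson-Slatkin-Maddison).

    Hw is the simple average of the two within-population mean pairwise
    differences; Hb the mean between-population pairwise difference.  Identical
    pooled samples give 0; reciprocally monomorphic, distinct samples give 1.
    """
    def within(m: np.ndarray) -> float:
        n = m.shape[0]
        if n < 2:
            return np.nan
        d = hamming_matrix(m)
        return d[np.triu_indices(n, 1)].mean()

    hw = np.nanmean([within(mat_a), within(mat_b)])
    hb = np.array([(mat_b != row).sum(axis=1).mean() for row in mat_a]).mean()
    if hb == 0:
        return 0.0
    return float(1.0 - hw / hb)


@dataclass
class SnnResult:
    snn: float
    p_value: float
    n_permutations: int


def _snn_value(nearest: list[np.ndarray], labels: np.ndarray) -> float:
    vals = [np.mean(labels[nn] == labels[i]) for i, nn in enumerate(nearest)]
    return float(np.mean(vals))


def snn_test(mt: HaplotypeAlignment, partition: PopulationPartition,
             pair: tuple[str, str], n_perm: int = 1000,
             seed: int | None = None) -> SnnResult:
    """Hudson's nearest-neighbour statistic with a label-permutation p-value.

    For each sequence the nearest neighbours (minimum Hamming distance, ties
    sharing weight equally) are found once; permuting labels then only
    re-scores membership.  p = P(Snn_perm >= Snn_obs).
    """
    ids_a = partition.members(pair[0], mt.individual_ids)
    ids_b = partition.members(pair[1], mt.individual_ids)
    sub = mt.subset(ids_a + ids_b)
    mat = sub.as_matrix()
    labels = np.array([0] * len(ids_a) + [1] * len(ids_b))
    dist = hamming_matrix(mat)
    np.fill_diagonal(dist, np.inf)
    nearest = [np.nonzero(dist[i] == dist[i].min())[0]
               for i in range(len(labels))]
    obs = _snn_value(nearest, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _snn_value(nearest, perm) >= obs:
            hits += 1
    return SnnResult(obs, (hits + 1) / (n_perm + 1), n_perm)


def pairwise_fst_mtdna(mt: HaplotypeAlignment, partition: PopulationPartition,
                       n_perm: int = 1000, seed: int | None = None
                       ) -> list[PairwiseDifferentiation]:
    """Hudson F_ST for every population pair, significance from the Snn test.

    Populations with fewer than 2 sequences are excluded (warning in record
    omission).
    """
    labels = [l for l in partition.labels
              if len(partition.members(l, mt.individual_ids)) >= 2]
    rng = np.random.default_rng(seed)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = mt.subset(partition.members(labels[i], mt.individual_ids))
            b = mt.subset(partition.members(labels[j], mt.individual_ids))
            # align the two sub-alignments on the *shared* clean columns
            pooled = HaplotypeAlignment(a.individual_ids + b.individual_ids,
                                        a.sequences + b.sequences)
            mat = pooled.as_matrix()
            mat_a, mat_b = mat[:a.n_sequences], mat[a.n_sequences:]
            fst = hudson_fst(mat_a, mat_b)
            snn = snn_test(mt, partition, (labels[i], labels[j]), n_perm,
                           int(rng.integers(1, 2**31 - 1)))
            out.append(PairwiseDifferentiation(
                (labels[i], labels[j]), fst, None, snn.p_value,
                "mitochondrial"))
    return out


# ---------------------------------------------------------------------------
# Per-population microsatellite summary (Table-1 style)
# ---------------------------------------------------------------------------

def microsat_diversity(geno: GenotypeTable, partition: PopulationPartition,
                       n_perm: int = 10_000, seed: int | None = None,
                       unbiased_he: bool = False
                       ) -> dict[str, MicrosatDiversityRecord]:
    """He/Ho (mean +- SD over loci), F_IS with permutation p, M_GW, sample sizes."""
    pops = _pop_tables(geno, partition)
    rng = np.random.default_rng(seed)
    mgw = garza_williamson_m(geno, partition)
    out = {}
    for label, table in pops.items():
        if table.n_individuals < 2:
            raise StatError(f"population {label} has < 2 individuals")
        typed = table.typed_mask().sum(axis=0)
        he, ho = heterozygosity(table, unbiased=unbiased_he)
        ok = ~np.isnan(he)
        fis, fis_p = fis_permutation_test(table, n_perm,
                                          int(rng.integers(1, 2**31 - 1)))
        out[label] = MicrosatDiversityRecord(
            population=label,
            n_mean=float(typed.mean()), n_sd=float(typed.std(ddof=1)),
            n_max=int(typed.max()),
            na_frac=float(table.missing_fraction().mean()),
            he_mean=float(he[ok].mean()), he_sd=float(he[ok].std(ddof=1)),
            ho_mean=float(ho[ok].mean()), ho_sd=float(ho[ok].std(ddof=1)),
            fis=fis, fis_p=fis_p, m_gw=mgw[label])
    return out
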