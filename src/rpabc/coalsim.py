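"""Multi-population coalescent simulation of microsatellite + mtDNA datasets.

Genealogies come from msprime (continuous-time coalescent, piecewise-constant
deme sizes, backward-time population splits).  Microsatellite mutations are
dropped on the resulting trees by a generalized stepwise model (GSM) written
here: Poisson mutations along branches, step magnitudes geometric with
parameter ``p_gsm`` (``p_gsm = 0`` is the strict stepwise model), reflecting
truncation inside a contiguous allele range whose root allele sits at the
range midpoint.  mtDNA sequences evolve under a finite-sites HKY model via
``msprime.sim_mutations``.

Scaling conventions
-------------------
Deme sizes are diploid individuals.  Nuclear lineages coalesce pairwise at
rate 1/(2N) per generation; the mtDNA locus is haploid and maternally
inherited, so its effective copy number is N/2 and the simulator runs it as a
haploid deme of size N/2 (pairwise rate 2/N, i.e. mean TMRCA one quarter of
the nuclear one).  All event times are in generations backward from sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import msprime
import numpy as np
import tskit

from .popdata import GenotypeTable, HaplotypeAlignment, PopulationPartition

BASES = np.array(list("ACGT"))


class DemographyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------

@dataclass
class SplitEvent:
    """Backward-time merge of the derived demes into the ancestral deme."""
    time: float  # generations
    derived: list[str]
    ancestral: str


@dataclass
class ResizeEvent:
    """Deme size change at ``time`` generations backward (new size applies older)."""
    time: float
    population: str
    size: float


@dataclass
class RealizedDemography:
    """Tree of demes with piecewise-constant diploid sizes and split events."""

    populations: dict[str, float]  # name -> size at sampling time
    events: list[SplitEvent | ResizeEvent] = field(default_factory=list)
    generation_time_years: float = 10.0

    def validate(self) -> None:
        derived_seen: dict[str, float] = {}
        for ev in self.events:
            if ev.time <= 0:
                raise DemographyError(f"event time {ev.time} must be > 0")
            if isinstance(ev, SplitEvent):
                if ev.ancestral not in self.populations:
                    raise DemographyError(f"unknown ancestral {ev.ancestral}")
                for d in ev.derived:
                    if d not in self.populations:
                        raise DemographyError(f"unknown derived {d}")
                    if d in derived_seen:
                        raise DemographyError(f"{d} derived twice")
                    derived_seen[d] = ev.time
            elif ev.population not in self.populations:
                raise DemographyError(f"unknown population {ev.population}")
        roots = [p for p in self.populations if p not in derived_seen]
        if len(roots) != 1:
            raise DemographyError(
                f"demography must reach a single root deme, found {roots}")
        # each deme must merge no later than the deme it merges into
        split_time = dict(derived_seen)
        parent = {}
        for ev in self.events:
            if isinstance(ev, SplitEvent):
                for d in ev.derived:
                    parent[d] = ev.ancestral
        for d, t in split_time.items():
            anc = parent[d]
            if anc in split_time and split_time[anc] < t:
                raise DemographyError(
                    f"{d} merges into {anc} at {t} but {anc} itself merges "
                    f"earlier at {split_time[anc]}")

    def to_msprime(self, marker: str = "nuclear") -> msprime.Demography:
        if marker not in {"nuclear", "mtDNA"}:
            raise DemographyError(f"unknown marker {marker!r}")
        self.validate()
        scale = 1.0 if marker == "nuclear" else 0.5  # haploid deme of N/2 copies
        dem = msprime.Demography()
        for name, size in self.populations.items():
            dem.add_population(name=name, initial_size=max(size * scale, 1e-9))
        for ev in sorted(self.events, key=lambda e: e.time):
            if isinstance(ev, SplitEvent):
                dem.add_population_split(time=ev.time, derived=list(ev.derived),
                                         ancestral=ev.ancestral)
            else:
                dem.add_population_parameters_change(
                    time=ev.time, population=ev.population,
                    initial_size=max(ev.size * scale, 1e-9))
        return dem


@dataclass
class SamplingDesign:
    """Numbers of nuclear diploids and mtDNA sequences sampled per population."""

    n_diploid: dict[str, int]
    n_mt: dict[str, int]
    n_loci: int = 11
    mt_length: int = 597
    motif_lengths: list[int] | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 0 or self.mt_length < 0:
            raise ValueError("counts must be >= 0")
        if all(v == 0 for v in self.n_diploid.values()) and \
           all(v == 0 for v in self.n_mt.values()):
            raise ValueError("at least one marker must be sampled")

    @property
    def populations(self) -> list[str]:
        return list(self.n_diploid)

    def individual_ids(self, pop: str) -> list[str]:
        return [f"{pop}_{k + 1:03d}" for k in range(self.n_diploid.get(pop, 0))]

    def partition(self) -> PopulationPartition:
        assignment = {}
        for pop in self.populations:
            for ind in self.individual_ids(pop):
                assignment[ind] = pop
            for ind in self.mt_ids(pop):
                assignment.setdefault(ind, pop)
        return PopulationPartition(assignment, self.populations)

    def mt_ids(self, pop: str) -> list[str]:
        n_dip = self.n_diploid.get(pop, 0)
        n_mt = self.n_mt.get(pop, 0)
        ids = self.individual_ids(pop)[:n_mt]
        # mtDNA-only individuals (more sequences than diploids) get own labels
        ids += [f"{pop}_mt{k + 1:03d}" for k in range(max(0, n_mt - n_dip))]
        return ids


@dataclass
class MutationModel:
    """Microsatellite GSM + mtDNA HKY parameters (rates per generation)."""

    mu_mic: float = 5e-4
    p_gsm: float = 0.22
    range_bound: int | None = 40  # contiguous allele states; None = unbounded
    mu_mt: float = 1e-7  # per site
    kappa: float = 10.0

    def __post_init__(self) -> None:
        if not (0 <= self.p_gsm < 1):
            raise ValueError("p_gsm must be in [0, 1)")
        if self.mu_mic < 0 or self.mu_mt < 0:
            raise ValueError("rates must be >= 0")
        if self.range_bound is not None and self.range_bound < 2:
            raise ValueError("allele range bound must be >= 2")


@dataclass
class ScenarioDraw:
    """One realized prior draw: parameter values + demography + mutation model."""

    params: dict[str, float]
    demography: RealizedDemography
    mutation: MutationModel
    scenario: str = ""


# ---------------------------------------------------------------------------
# Genealogies
# ---------------------------------------------------------------------------

def sample_genealogy(demography: RealizedDemography,
                     samples: dict[str, int], marker: str, seed: int,
                     num_replicates: int | None = None,
                     sequence_length: float = 1.0):
    """Coalescent genealogies (tskit tree sequences) for one marker.

    ``samples`` counts individuals: diploid for nuclear, haploid sequences for
    mtDNA.  With ``num_replicates`` an iterator of independent genealogies is
    returned (same demography, e.g. unlinked microsatellite loci).
    """
    dem = demography.to_msprime(marker)
    ploidy = 2 if marker == "nuclear" else 1
    sample_spec = {p: n for p, n in samples.items() if n > 0}
    return msprime.sim_ancestry(
        samples=sample_spec, demography=dem, ploidy=ploidy,
        sequence_length=sequence_length, random_seed=seed,
        num_replicates=num_replicates)


def gsm_step(p_gsm: float, rng: np.random.Generator) -> int:
    """One signed mutation step: magnitude geometric(1 - p_gsm) on {1, 2, ...}."""
    mag = 1 if p_gsm == 0 else int(rng.geometric(1 - p_gsm))
    return mag if rng.random() < 0.5 else -mag


def _reflect(x: int, lo: int, hi: int) -> int:
    while x < lo or x > hi:
        if x > hi:
            x = 2 * hi - x
        if x < lo:
            x = 2 * lo - x
    return x


def mutate_microsat(ts: tskit.TreeSequence, model: MutationModel,
                    rng: np.random.Generator) -> np.ndarray:
    """Allele sizes (repeat units) at the sampled tips of a one-locus genealogy."""
    tree = ts.first()
    allele = np.zeros(ts.num_nodes, dtype=int)
    if model.range_bound is not None:
        lo, hi = 1, model.range_bound
        root_allele = (lo + hi) // 2
    else:
        lo = hi = None
        root_allele = 10_000  # translation-invariant statistics; far from zero
    times = ts.nodes_time
    for u in tree.nodes(order="preorder"):
        parent = tree.parent(u)
        if parent == tskit.NULL:
            allele[u] = root_allele
            continue
        n_mut = rng.poisson(model.mu_mic * (times[parent] - times[u]))
        x = int(allele[parent])
        for _ in range(n_mut):
            x += gsm_step(model.p_gsm, rng)
            if lo is not None:
                x = _reflect(x, lo, hi)
        allele[u] = x
    return allele[ts.samples()]


def mutate_sequence(ts: tskit.TreeSequence, model: MutationModel,
                    rng: np.random.Generator) -> list[str]:
    """Finite-sites HKY haplotypes at the tips of an mtDNA genealogy."""
    L = int(ts.sequence_length)
    n = len(ts.samples())
    mat = np.tile(rng.choice(BASES, size=L), (n, 1))
    if model.mu_mt > 0:
        mts = msprime.sim_mutations(
            ts, rate=model.mu_mt, model=msprime.HKY(kappa=model.kappa),
            random_seed=int(rng.integers(1, 2**31 - 1)), discrete_genome=True)
        for var in mts.variants():
            pos = int(var.site.position)
            mat[:, pos] = np.array(var.alleles)[var.genotypes]
    return ["".join(row) for row in mat]


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------

def _sample_nodes_by_population(ts: tskit.TreeSequence) -> dict[str, np.ndarray]:
    import json

    names = {}
    for pop in ts.populations():
        meta = pop.metadata
        if isinstance(meta, bytes):
            meta = json.loads(meta.decode() or "{}")
        names[pop.id] = meta.get("name", str(pop.id))
    samples = ts.samples()
    pops = ts.nodes_population[samples]
    return {names[p]: samples[pops == p] for p in np.unique(pops)}


def simulate_dataset(draw: ScenarioDraw, design: SamplingDesign, seed: int
                     ) -> tuple[GenotypeTable | None, HaplotypeAlignment | None]:
    """Simulate one full dataset (all microsatellite loci + the mtDNA locus).

    Deterministic under a fixed seed: per-locus genealogies, mutations and the
    mtDNA locus all derive their streams from ``seed``.
    """
    rng = np.random.default_rng(seed)
    geno = None
    if design.n_loci > 0 and any(design.n_diploid.values()):
        anc_seed = int(rng.integers(1, 2**31 - 1))
        reps = sample_genealogy(draw.demography, design.n_diploid, "nuclear",
                                anc_seed, num_replicates=design.n_loci)
        ids: list[str] = []
        locality: list[str] = []
        per_locus_cols = []
        for locus_index, ts in enumerate(reps):
            by_pop = _sample_nodes_by_population(ts)
            col = []
            if locus_index == 0:
                for pop in design.populations:
                    if design.n_diploid.get(pop, 0):
                        ids.extend(design.individual_ids(pop))
                        locality.extend([pop] * design.n_diploid[pop])
            sizes = mutate_microsat(ts, draw.mutation, rng)
            size_of = dict(zip(ts.samples().tolist(), sizes.tolist()))
            for pop in design.populations:
                nodes = by_pop.get(pop, np.empty(0, dtype=int))
                pairs = np.array([size_of[n] for n in nodes]).reshape(-1, 2)
                col.append(pairs)
            per_locus_cols.append(np.concatenate(col, axis=0))
        alleles = np.stack(per_locus_cols, axis=1)  # (n, L, 2)
        geno = GenotypeTable(ids, [f"L{k + 1:02d}" for k in range(design.n_loci)],
                             alleles, locality=locality)
    mt = None
    if design.mt_length > 0 and any(design.n_mt.values()):
        mt_seed = int(rng.integers(1, 2**31 - 1))
        ts = sample_genealogy(draw.demography, design.n_mt, "mtDNA", mt_seed,
                              sequence_length=design.mt_length)
        by_pop = _sample_nodes_by_population(ts)
        seqs = mutate_sequence(ts, draw.mutation, rng)
        seq_of = dict(zip(ts.samples().tolist(), seqs))
        mt_ids, mt_seqs = [], []
        for pop in design.populations:
            nodes = by_pop.get(pop, np.empty(0, dtype=int))
            labels = design.mt_ids(pop)
            for lab, node in zip(labels, nodes):
                mt_ids.append(lab)
                mt_seqs.append(seq_of[node])
        mt = HaplotypeAlignment(mt_ids, mt_seqs)
    return geno, mt


def simulate_constant_microsats(n_diploid: int, n_loci: int, ne: float,
                                mu: float, p_gsm: float,
                                range_bound: int | None, seed: int
                                ) -> list[np.ndarray]:
    """Per-locus tip allele sizes under a single constant-size deme (null model)."""
    rng = np.random.default_rng(seed)
    dem = RealizedDemography(populations={"pop": ne})
    # a single deme is its own root; bypass multi-deme validation
    model = MutationModel(mu_mic=mu, p_gsm=p_gsm, range_bound=range_bound)
    reps = msprime.sim_ancestry(
        samples={"pop": n_diploid},
        demography=dem.to_msprime("nuclear"), ploidy=2, sequence_length=1,
        random_seed=int(rng.integers(1, 2**31 - 1)), num_replicates=n_loci)
    return [mutate_microsat(ts, model, rng) for ts in reps]
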