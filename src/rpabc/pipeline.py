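"""Config-driven orchestration: statistics report and the three-step ABC analysis.

``run_stats`` produces a per-population diversity table (microsatellite +
mtDNA), pairwise differentiation matrices with Bonferroni-corrected
significance, and an LD-Ne row — the machine-readable analogue of the study's
summary tables.  ``run_abc`` runs the nested scenario analysis: branching
order, then ancestral size change, then recent collapse, each step
conditioning on the previous winner, with model choice by both ABC-LDA and
ABC-RF, error calibration, and — for the final winner — parameter posteriors
and a posterior predictive check.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abc_engine, ldne, sumstats
from .popdata import (GenotypeTable, HaplotypeAlignment, PopulationPartition,
                      filter_individuals, read_genotypes, read_haplotypes,
                      read_partition)
from .scenarios import (MutationPriors, ScenarioSet, build_step1_topologies,
                        build_step2_sizechange, build_step3_collapse)
from .coalsim import SamplingDesign


@dataclass
class AnalysisConfig:
    """Tunable knobs of the full analysis (defaults follow the study's choices)."""

    ar_gene_copies: int | None = None  # None: largest feasible, capped at 52
    pa_gene_copies: int = 6
    n_perm: int = 10_000
    n_boot: int = 10_000
    snn_perm: int = 1000
    mgw_sims: int = 10_000
    tajima_sims: int = 10_000
    p_crit: float = 0.02
    bonferroni: bool = True
    generation_time_years: float = 10.0
    abc_populations: tuple[str, ...] = ("XCSS", "PY", "TL")
    n_per_scenario: int = 10_000
    tolerance: float = 0.01
    n_trees: int = 500
    n_error_pods: int = 100
    ppc_sims: int = 500
    seed: int = 1
    cache_dir: str | None = None

    def fingerprint(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stars(p: float | None, alpha_levels=(0.05, 0.01, 0.001)) -> str:
    if p is None:
        return ""
    if p <= alpha_levels[2]:
        return "***"
    if p <= alpha_levels[1]:
        return "**"
    if p <= alpha_levels[0]:
        return "*"
    return "ns"


def _max_feasible_g(geno: GenotypeTable, partition: PopulationPartition) -> int:
    g = None
    for label in partition.labels:
        members = partition.members(label, geno.individual_ids)
        if not members:
            continue
        sub = geno.subset(members)
        copies = 2 * sub.typed_mask().sum(axis=0).min()
        g = copies if g is None else min(g, copies)
    return int(g or 2)


def run_stats(geno: GenotypeTable, mt: HaplotypeAlignment | None,
              partition: PopulationPartition,
              config: AnalysisConfig | None = None) -> dict:
    """Diversity + differentiation + LD-Ne report (JSON-serialisable dict)."""
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.seed)
    partition.validate_against(geno, mt)
    report: dict = {"config_fingerprint": config.fingerprint(),
                    "seed": config.seed}

    g_max = _max_feasible_g(geno, partition)
    g_ar = config.ar_gene_copies or min(g_max, 52)
    g_pa = min(config.pa_gene_copies, g_max)
    micro = sumstats.microsat_diversity(geno, partition, config.n_perm,
                                        int(rng.integers(1, 2**31 - 1)))
    ar = sumstats.allelic_richness(geno, partition, g_ar)
    pa = sumstats.private_allelic_richness(geno, partition, g_pa)
    mgw_p: dict[str, float] = {}
    if config.mgw_sims >= 100:
        for label, rec in micro.items():
            members = partition.members(label, geno.individual_ids)
            mgw_p[label] = sumstats.m_gw_test(
                rec.m_gw, n_diploid=len(members), n_loci=geno.n_loci,
                n_sims=config.mgw_sims, seed=int(rng.integers(1, 2**31 - 1)))
    table1_mic = {}
    for label, rec in micro.items():
        rec.ar_mean, rec.ar_se = ar[label]
        rec.pa_mean, rec.pa_se = pa[label]
        rec.m_gw_p = mgw_p.get(label)
        d = dataclasses.asdict(rec)
        d["fis_stars"] = _stars(rec.fis_p)
        d["m_gw_stars"] = _stars(rec.m_gw_p)
        table1_mic[label] = d
    report["microsat_diversity"] = table1_mic
    report["rarefaction_gene_copies"] = {"ar": g_ar, "pa": g_pa}

    if mt is not None:
        seq_records = sumstats.sequence_diversity(mt, partition)
        table1_mt = {}
        for rec in seq_records:
            sub_ids = (mt.individual_ids if rec.population == "Total"
                       else partition.members(rec.population, mt.individual_ids))
            d_val, d_p, degen = sumstats.tajima_d_test(
                mt.subset(sub_ids), config.tajima_sims,
                int(rng.integers(1, 2**31 - 1)))
            entry = dataclasses.asdict(rec)
            entry["tajima_p"] = d_p
            entry["tajima_stars"] = _stars(d_p) if not degen else ""
            table1_mt[rec.population] = entry
        report["mtdna_diversity"] = table1_mt

    fst_mic = sumstats.pairwise_fst_microsat(
        geno, partition, config.n_boot, config.n_perm,
        int(rng.integers(1, 2**31 - 1)))
    n_tests = len(fst_mic)
    table2 = {"microsatellite": [], "mtdna": []}
    for rec in fst_mic:
        p_adj = (min(1.0, rec.p_value * n_tests)
                 if (config.bonferroni and rec.p_value is not None)
                 else rec.p_value)
        table2["microsatellite"].append(
            {"pair": list(rec.pair), "fst": rec.fst, "ci95": rec.ci95,
             "p_value": rec.p_value, "p_bonferroni": p_adj,
             "stars": _stars(p_adj)})
    if mt is not None:
        fst_mt = sumstats.pairwise_fst_mtdna(
            mt, partition, config.snn_perm, int(rng.integers(1, 2**31 - 1)))
        n_tests_mt = max(len(fst_mt), 1)
        for rec in fst_mt:
            p_adj = (min(1.0, rec.p_value * n_tests_mt)
                     if (config.bonferroni and rec.p_value is not None)
                     else rec.p_value)
            table2["mtdna"].append(
                {"pair": list(rec.pair), "fst": rec.fst,
                 "p_value": rec.p_value, "p_bonferroni": p_adj,
                 "stars": _stars(p_adj)})
    report["pairwise_fst"] = table2

    table3 = {}
    cfg = ldne.LdNeConfig(p_crit=config.p_crit)
    for label in list(partition.labels) + ["Total"]:
        members = (geno.individual_ids if label == "Total"
                   else partition.members(label, geno.individual_ids))
        if len(members) < 4:
            continue
        try:
            est = ldne.ldne_estimate(geno.subset(members), cfg)
        except ldne.LdNeError as exc:
            table3[label] = {"error": str(exc)}
            continue
        table3[label] = {
            "ne": est.ne_point, "ci95_jackknife": list(est.ci95_jackknife),
            "ci95_parametric": list(est.ci95_parametric),
            "mean_r2": est.mean_r2, "n_comparisons": est.n_comparisons,
            "harmonic_mean_s": est.harmonic_mean_s}
    report["ld_ne"] = table3
    return report


def load_inputs(genotypes: str, haplotypes: str | None, partition: str,
                format: str = "genepop", apply_filter: bool = True
                ) -> tuple[GenotypeTable, HaplotypeAlignment | None,
                           PopulationPartition, dict]:
    geno = read_genotypes(genotypes, format=format)
    mt = read_haplotypes(haplotypes) if haplotypes else None
    part = read_partition(partition)
    info = {"n_input": geno.n_individuals}
    if apply_filter:
        geno, rep = filter_individuals(geno, mt)
        info["n_retained"] = geno.n_individuals
        info["removed"] = rep.removed
    return geno, mt, part, info


# ---------------------------------------------------------------------------
# ABC orchestration
# ---------------------------------------------------------------------------

def _abc_design(geno: GenotypeTable, mt: HaplotypeAlignment | None,
                partition: PopulationPartition, pops: tuple[str, ...],
                mt_length: int) -> SamplingDesign:
    n_dip = {p: len(partition.members(p, geno.individual_ids)) for p in pops}
    n_mt = {p: (len(partition.members(p, mt.individual_ids)) if mt else 0)
            for p in pops}
    return SamplingDesign(n_diploid=n_dip, n_mt=n_mt, n_loci=geno.n_loci,
                          mt_length=mt_length)


def _get_table(scenario_set: ScenarioSet, config: AnalysisConfig,
               seed: int) -> abc_engine.ReferenceTable:
    if config.cache_dir:
        key = (f"{scenario_set.name}_{abc_engine.design_fingerprint(scenario_set)}"
               f"_{config.n_per_scenario}_{seed}.csv")
        path = Path(config.cache_dir) / key
        if path.exists():
            return abc_engine.ReferenceTable.from_csv(path)
        table = abc_engine.build_reference_table(scenario_set,
                                                 config.n_per_scenario, seed)
        path.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(path)
        return table
    return abc_engine.build_reference_table(scenario_set,
                                            config.n_per_scenario, seed)


def _run_step(scenario_set: ScenarioSet, observed_ss: dict[str, float],
              config: AnalysisConfig, seed: int) -> dict:
    table = _get_table(scenario_set, config, seed)
    obs = abc_engine.observed_vector(observed_ss, table.ss_cols)
    selected, dist = abc_engine.rejection_select(obs, table, config.tolerance)
    logistic = abc_engine.model_choice_logistic(selected, obs, table)
    rf = abc_engine.model_choice_rf(table, obs, config.n_trees, seed)
    step = {"scenarios": scenario_set.scenario_names(),
            "logistic": {"probabilities": logistic.probabilities,
                         "ci95": logistic.ci95, "best": logistic.best},
            "rf": {"probabilities": rf.probabilities, "votes": rf.votes,
                   "best": rf.best, "posterior": rf.rf_posterior,
                   "posterior_sd": rf.posterior_sd,
                   "prior_error_rate": rf.prior_error_rate}}
    if config.n_error_pods > 0:
        cal = abc_engine.calibrate_errors(
            scenario_set, table, config.n_error_pods, config.tolerance,
            seed + 17, method="rf", n_trees=config.n_trees)
        step["calibration"] = {
            "confusion": cal.confusion.tolist(), "type_i": cal.type_i,
            "type_ii": cal.type_ii, "prior_error_rate": cal.prior_error_rate}
    # the step winner: the scenario both classifiers agree on, else the RF one
    step["winner"] = (logistic.best if logistic.best == rf.best else rf.best)
    step["_table"] = table
    step["_selected"] = selected
    step["_distances"] = dist
    return step


def run_abc(geno: GenotypeTable, mt: HaplotypeAlignment | None,
            partition: PopulationPartition,
            config: AnalysisConfig | None = None,
            mutation_priors: MutationPriors | None = None) -> dict:
    """Three-step nested ABC analysis of the observed dataset.

    Step 1 chooses among 10 branching orders; step 2 among 6 size-change
    scenarios on the chosen topology; step 3 between constancy and a recent
    collapse.  Each step conditions on the previous winner (winners are not
    revisited).  The final winner gets parameter posteriors and a posterior
    predictive check.
    """
    config = config or AnalysisConfig()
    pops = config.abc_populations
    sub_part = PopulationPartition(
        {i: p for i, p in partition.assignment.items() if p in pops},
        [p for p in pops])
    keep_geno = [i for i in geno.individual_ids if i in sub_part.assignment]
    geno_abc = geno.subset(keep_geno)
    mt_abc = None
    if mt is not None:
        keep_mt = [i for i in mt.individual_ids if i in sub_part.assignment]
        mt_abc = mt.subset(keep_mt)
    observed_ss = abc_engine.summary_statistics(geno_abc, mt_abc, sub_part)
    design = _abc_design(geno_abc, mt_abc, sub_part, pops,
                         mt_abc.length if mt_abc is not None else 0)
    mp = mutation_priors or MutationPriors()
    report: dict = {"config_fingerprint": config.fingerprint(),
                    "seed": config.seed, "observed_ss": observed_ss}
    if all(v == 0.0 for v in observed_ss.values()):
        raise abc_engine.AbcError("all observed summary statistics degenerate")

    steps = [("step1", build_step1_topologies(design, mp)),
             ("step2", build_step2_sizechange(design, mp)),
             ("step3", build_step3_collapse(design, mp))]
    prev_winner = None
    final_step = None
    final_set = None
    for i, (name, sset) in enumerate(steps):
        step = _run_step(sset, observed_ss, config, config.seed + 101 * (i + 1))
        step["conditioned_on"] = prev_winner
        prev_winner = f"{name}:{step['winner']}"
        final_step, final_set = step, sset
        report[name] = {k: v for k, v in step.items()
                        if not k.startswith("_")}

    winner = final_step["winner"]
    table = final_step["_table"]
    # estimate on the winner's rows only, accepting enough rows to keep the
    # local-linear regression well-posed (accepted >> statistic dimension)
    win_rows = table.data[table.data["scenario"] == winner].reset_index(drop=True)
    win_table = abc_engine.ReferenceTable(
        win_rows, table.param_cols, table.ss_cols, [winner], table.seed,
        table.design_fingerprint)
    n_target = max(100, 2 * len(table.ss_cols))
    est_tol = min(1.0, max(config.tolerance, n_target / max(len(win_rows), 1)))
    obs_vec = abc_engine.observed_vector(observed_ss, table.ss_cols)
    selected_win, dist_win = abc_engine.rejection_select(obs_vec, win_table,
                                                         est_tol)
    bounds = final_set.prior_bounds(winner)
    posterior = None
    try:
        posterior = abc_engine.estimate_parameters(
            selected_win, dist_win, observed_ss, bounds, table)
        report["posterior"] = {
            "scenario": winner,
            "summaries": posterior.summaries.reset_index().to_dict("records")}
    except abc_engine.AbcError as exc:
        report["posterior"] = {"scenario": winner, "error": str(exc)}
    if posterior is not None and config.ppc_sims > 0:
        ppc = abc_engine.posterior_predictive_check(
            posterior, final_set, winner, observed_ss, config.ppc_sims,
            config.seed + 999)
        report["ppc"] = ppc.reset_index().to_dict("records")
    report["final_winner"] = winner
    return report


def write_report(report: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict("records")
        return str(o)

    Path(path).write_text(json.dumps(report, indent=2, default=default))
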