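"""Approximate Bayesian Computation: reference tables, rejection, model choice,
error calibration, parameter estimation and posterior predictive checks.

The workflow follows the five classical steps: (1) simulate pseudo-observed
datasets (PODs) under every competing scenario and summarise each with a fixed
vector of statistics; (2) choose the scenario, both by multinomial logistic
regression on linear-discriminant axes of the closest PODs (ABC-LDA) and by a
random-forest classifier with an out-of-bag posterior-probability estimate
(ABC-RF); (3) calibrate type-I/type-II error rates and the prior error rate on
held-out PODs; (4) estimate parameter posteriors by local-linear regression
adjustment of the accepted draws (logit-transformed within prior bounds,
Epanechnikov weights); (5) check goodness-of-fit by simulating from the fitted
posterior and locating each observed statistic in the simulated distribution.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression

from . import sumstats
from .coalsim import simulate_dataset
from .popdata import GenotypeTable, HaplotypeAlignment, PopulationPartition
from .scenarios import ScenarioSet


class AbcError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def summary_statistics(geno: GenotypeTable | None,
                       mt: HaplotypeAlignment | None,
                       partition: PopulationPartition) -> dict[str, float]:
    """Fixed-order summary-statistic vector for one dataset.

    Per population: mean allele count, mean expected heterozygosity, mean
    allele-size variance, Garza-Williamson M (microsatellites); segregating
    sites, haplotype diversity, per-site pi and Tajima's D (mtDNA).  Per pair:
    Weir-Cockerham F_ST, shared-allele distance, Goldstein's (delta mu)^2 and
    Hudson's mtDNA F_ST.  Non-finite values (e.g. Tajima's D of a monomorphic
    sample) are imputed as 0 with a companion 0/1 degeneracy indicator, so
    monomorphism itself stays informative.
    """
    labels = partition.labels
    out: dict[str, float] = {}
    if geno is not None:
        tables = {lab: geno.subset(partition.members(lab, geno.individual_ids))
                  for lab in labels}
        # allele counts computed once per (population, locus) and reused
        counts_by_pop = {
            lab: [sumstats.allele_counts(tables[lab], l)
                  for l in range(geno.n_loci)] for lab in labels}
        for lab in labels:
            nall, szvar, he_terms, mgw_terms = [], [], [], []
            for counts in counts_by_pop[lab]:
                if not counts:
                    continue
                n_copies = sum(counts.values())
                sizes = np.array(list(counts))
                freqs = np.array(list(counts.values())) / n_copies
                nall.append(len(counts))
                he_terms.append(1.0 - np.sum(freqs ** 2))
                mean_sz = float(np.sum(sizes * freqs))
                szvar.append(float(np.sum(freqs * (sizes - mean_sz) ** 2)))
                mgw_terms.append(len(sizes) / (sizes.max() - sizes.min() + 1))
            out[f"mic_nall_{lab}"] = float(np.mean(nall)) if nall else 0.0
            out[f"mic_he_{lab}"] = float(np.mean(he_terms)) if he_terms else 0.0
            out[f"mic_szvar_{lab}"] = float(np.mean(szvar)) if szvar else 0.0
            out[f"mic_mgw_{lab}"] = float(np.mean(mgw_terms)) if mgw_terms else 1.0
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = labels[i], labels[j]
                theta = sumstats.wc_theta([tables[a], tables[b]])
                out[f"mic_fst_{a}_{b}"] = 0.0 if not np.isfinite(theta) else theta
                das, dmu2 = _pairwise_microsat_distances(
                    counts_by_pop[a], counts_by_pop[b])
                out[f"mic_das_{a}_{b}"] = das
                out[f"mic_dmu2_{a}_{b}"] = dmu2
    if mt is not None:
        recs = {r.population: r
                for r in sumstats.sequence_diversity(mt, partition,
                                                     include_total=False)}
        for lab in labels:
            r = recs.get(lab)
            if r is None:
                out[f"mt_s_{lab}"] = 0.0
                out[f"mt_hd_{lab}"] = 0.0
                out[f"mt_pi_{lab}"] = 0.0
                out[f"mt_tajd_{lab}"] = 0.0
                out[f"mt_tajd_def_{lab}"] = 1.0
                continue
            out[f"mt_s_{lab}"] = float(r.s)
            out[f"mt_hd_{lab}"] = r.hd
            out[f"mt_pi_{lab}"] = r.pi_per_site
            out[f"mt_tajd_{lab}"] = 0.0 if r.tajima_degenerate else r.tajima_d
            out[f"mt_tajd_def_{lab}"] = float(r.tajima_degenerate)
        mat_by_pop = {}
        for lab in labels:
            members = partition.members(lab, mt.individual_ids)
            if len(members) >= 2:
                mat_by_pop[lab] = mt.subset(members)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = labels[i], labels[j]
                if a in mat_by_pop and b in mat_by_pop:
                    pooled = HaplotypeAlignment(
                        mat_by_pop[a].individual_ids + mat_by_pop[b].individual_ids,
                        mat_by_pop[a].sequences + mat_by_pop[b].sequences)
                    m = pooled.as_matrix()
                    na = mat_by_pop[a].n_sequences
                    fst = sumstats.hudson_fst(m[:na], m[na:])
                else:
                    fst = 0.0
                out[f"mt_fst_{a}_{b}"] = fst if np.isfinite(fst) else 0.0
    return out


def _pairwise_microsat_distances(counts_a: list[dict[int, int]],
                                 counts_b: list[dict[int, int]]
                                 ) -> tuple[float, float]:
    """(shared-allele distance, (delta mu)^2) averaged over loci."""
    das_terms, dmu_terms = [], []
    for ca, cb in zip(counts_a, counts_b):
        na, nb = sum(ca.values()), sum(cb.values())
        if na == 0 or nb == 0:
            continue
        shared = sum(min(ca.get(a, 0) / na, cb.get(a, 0) / nb)
                     for a in set(ca) | set(cb))
        das_terms.append(1.0 - shared)
        mean_a = sum(a * c for a, c in ca.items()) / na
        mean_b = sum(a * c for a, c in cb.items()) / nb
        dmu_terms.append((mean_a - mean_b) ** 2)
    return (float(np.mean(das_terms)) if das_terms else 0.0,
            float(np.mean(dmu_terms)) if dmu_terms else 0.0)


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """(scenario, parameters, summary statistics) across all simulations."""

    data: pd.DataFrame
    param_cols: list[str]
    ss_cols: list[str]
    scenario_names: list[str]
    seed: int
    design_fingerprint: str = ""

    def to_csv(self, path) -> None:
        meta = {"param_cols": self.param_cols, "ss_cols": self.ss_cols,
                "scenario_names": self.scenario_names, "seed": self.seed,
                "design_fingerprint": self.design_fingerprint}
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(meta) + "\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        with open(path) as fh:
            meta = json.loads(fh.readline().lstrip("#"))
            data = pd.read_csv(fh)
        return cls(data=data, **meta)


def design_fingerprint(scenario_set: ScenarioSet) -> str:
    return hashlib.sha256(scenario_set.to_yaml().encode()).hexdigest()[:16]


def simulate_pod(scenario_set: ScenarioSet, scenario: str, seed: int,
                 fixed: dict[str, float] | None = None
                 ) -> tuple[dict[str, float], dict[str, float]]:
    """Simulate one POD: returns (parameter draw, summary-statistic vector)."""
    draw = scenario_set.sample_prior(scenario, seed, fixed)
    geno, mt = simulate_dataset(draw, scenario_set.design, seed)
    part = scenario_set.design.partition()
    return draw.params, summary_statistics(geno, mt, part)


def build_reference_table(scenario_set: ScenarioSet, n_per_scenario: int,
                          seed: int, progress: bool = False) -> ReferenceTable:
    """Balanced reference table; each row deterministic from (seed, scenario, index)."""
    rows = []
    ss_cols: list[str] | None = None
    all_params: list[str] = []
    for s in scenario_set.scenarios:
        for p in s.param_names():
            if p not in all_params:
                all_params.append(p)
    for p in ("mu_mic", "p_gsm", "mu_mt"):
        if p not in all_params:
            all_params.append(p)
    for s_idx, scen in enumerate(scenario_set.scenarios):
        for i in range(n_per_scenario):
            row_seed = int(np.random.SeedSequence(
                [seed, s_idx, i]).generate_state(1)[0] % (2**31 - 1)) + 1
            params, ss = simulate_pod(scenario_set, scen.name, row_seed)
            if ss_cols is None:
                ss_cols = list(ss)
            elif list(ss) != ss_cols:
                raise AbcError("summary-statistic dimension mismatch between PODs")
            row = {"scenario": scen.name}
            row.update({f"param_{k}": params.get(k, np.nan) for k in all_params})
            row.update({f"ss_{k}": ss[k] for k in ss_cols})
            rows.append(row)
        if progress:
            print(f"  simulated {scen.name}: {n_per_scenario} PODs")
    data = pd.DataFrame(rows)
    return ReferenceTable(data=data,
                          param_cols=[f"param_{k}" for k in all_params],
                          ss_cols=[f"ss_{k}" for k in (ss_cols or [])],
                          scenario_names=scenario_set.scenario_names(),
                          seed=seed,
                          design_fingerprint=design_fingerprint(scenario_set))


def observed_vector(observed_ss: dict[str, float], ss_cols: Sequence[str]
                    ) -> np.ndarray:
    missing = [c for c in ss_cols if c.removeprefix("ss_") not in observed_ss]
    if missing:
        raise AbcError(f"observed summary statistics missing: {missing}")
    return np.array([observed_ss[c.removeprefix("ss_")] for c in ss_cols])


# ---------------------------------------------------------------------------
# Rejection
# ---------------------------------------------------------------------------

def _robust_scale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column scale: median absolute deviation, falling back to the
    standard deviation for columns whose MAD is zero (e.g. statistics that are
    zero in most but not all PODs); columns constant everywhere are flagged."""
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    sd = X.std(axis=0)
    scale = np.where(mad > 0, mad, sd)
    keep = scale > 0
    scale = np.where(keep, scale, 1.0)
    return scale, keep

def rejection_select(observed_ss: dict[str, float] | np.ndarray,
                     table: ReferenceTable, tolerance: float
                     ) -> tuple[pd.DataFrame, np.ndarray]:
    """The ceil(tolerance * rows) PODs closest to the observed statistics.

    Distance is Euclidean on statistics standardised by the reference-table
    median absolute deviation; zero-MAD statistics are dropped (with a
    warning).  Ties break by row index for determinism.  Returns the selected
    rows (a copy, in increasing distance order) and their distances.
    """
    if not (0 < tolerance <= 1):
        raise AbcError("tolerance must be in (0, 1]")
    obs = (observed_ss if isinstance(observed_ss, np.ndarray)
           else observed_vector(observed_ss, table.ss_cols))
    X = table.data[table.ss_cols].to_numpy(float)
    scale, keep = _robust_scale(X)
    if not keep.all():
        dropped = [c for c, k in zip(table.ss_cols, keep) if not k]
        warnings.warn(f"zero-variance statistics dropped from distance: {dropped}")
    if not keep.any():
        raise AbcError("all summary statistics degenerate")
    d = np.sqrt((((X[:, keep] - obs[keep]) / scale[keep]) ** 2).sum(axis=1))
    n_keep = int(np.ceil(tolerance * len(X)))
    order = np.lexsort((np.arange(len(d)), d))[:n_keep]
    return table.data.iloc[order].copy(), d[order]


# ---------------------------------------------------------------------------
# Model choice
# ---------------------------------------------------------------------------

@dataclass
class ModelChoiceResult:
    method: str  # "logistic" | "rf"
    scenario_names: list[str]
    probabilities: dict[str, float]
    ci95: dict[str, tuple[float, float]] | None = None
    best: str = ""
    votes: dict[str, int] | None = None
    rf_posterior: float | None = None
    posterior_sd: float | None = None
    prior_error_rate: float | None = None

    def __post_init__(self) -> None:
        if not self.best:
            self.best = max(self.probabilities, key=self.probabilities.get)


def _lda_axes(X: np.ndarray, y: np.ndarray) -> LinearDiscriminantAnalysis:
    lda = LinearDiscriminantAnalysis()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lda.fit(X, y)
    return lda


def model_choice_logistic(selected: pd.DataFrame,
                          observed_ss: dict[str, float] | np.ndarray,
                          table: ReferenceTable) -> ModelChoiceResult:
    """ABC-LDA: multinomial logistic regression on LDA axes of the accepted PODs.

    Scenario posterior probabilities evaluated at the observed point; 95% CIs
    by the delta method from the regression's asymptotic covariance (omitted
    when the fit is degenerate, e.g. perfectly separated classes).
    """
    obs = (observed_ss if isinstance(observed_ss, np.ndarray)
           else observed_vector(observed_ss, table.ss_cols))
    y_labels = selected["scenario"].to_numpy()
    present = [s for s in table.scenario_names if (y_labels == s).any()]
    if not present:
        raise AbcError("no accepted rows")
    if len(present) == 1:
        warnings.warn("all accepted PODs come from one scenario; absent "
                      "scenarios get probability 0")
        probs = {s: float(s == present[0]) for s in table.scenario_names}
        return ModelChoiceResult("logistic", list(table.scenario_names), probs)
    X = selected[table.ss_cols].to_numpy(float)
    y = np.array([present.index(s) for s in y_labels])
    lda = _lda_axes(X, y)
    Z = lda.transform(X)
    z_obs = lda.transform(obs.reshape(1, -1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(penalty=None, max_iter=2000)
        clf.fit(Z, y)
        p_obs = clf.predict_proba(z_obs)[0]
    probs = {s: 0.0 for s in table.scenario_names}
    for k, s in enumerate(present):
        probs[s] = float(p_obs[k])
    missing = set(table.scenario_names) - set(present)
    if missing:
        warnings.warn(f"scenarios absent from accepted rows get probability 0: "
                      f"{sorted(missing)}")
    ci = _logistic_prob_ci(Z, y, z_obs[0], len(present))
    ci_dict = None
    if ci is not None:
        ci_dict = {s: (0.0, 0.0) for s in table.scenario_names}
        for k, s in enumerate(present):
            ci_dict[s] = ci[k]
    return ModelChoiceResult("logistic", list(table.scenario_names), probs,
                             ci95=ci_dict)


def _logistic_prob_ci(Z: np.ndarray, y: np.ndarray, z_obs: np.ndarray,
                      n_classes: int) -> list[tuple[float, float]] | None:
    """Delta-method 95% CIs of multinomial-logistic class probabilities.

    Refits a baseline-category multinomial by Newton iterations to obtain the
    observed-information covariance; returns None when the information matrix
    is numerically singular (separation).
    """
    n, p = Z.shape
    K = n_classes
    X1 = np.hstack([np.ones((n, 1)), Z])
    q = X1.shape[1]
    beta = np.zeros((K - 1, q))
    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0
    try:
        for _ in range(100):
            eta = X1 @ beta.T  # (n, K-1)
            expo = np.exp(np.clip(eta, -500, 500))
            denom = 1.0 + expo.sum(axis=1, keepdims=True)
            P = np.hstack([1.0 / denom, expo / denom])  # (n, K)
            grad = ((Y[:, 1:] - P[:, 1:]).T @ X1).ravel()
            H = np.zeros(((K - 1) * q, (K - 1) * q))
            for a in range(K - 1):
                for b in range(K - 1):
                    w = P[:, a + 1] * ((a == b) - P[:, b + 1])
                    H[a * q:(a + 1) * q, b * q:(b + 1) * q] = (X1 * w[:, None]).T @ X1
            step = np.linalg.solve(H, grad)
            if not np.all(np.isfinite(step)):
                return None
            beta += step.reshape(K - 1, q)
            if np.abs(step).max() < 1e-8:
                break
        if np.abs(beta).max() > 50:  # separation: probabilities pinned at 0/1
            return None
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    x1 = np.concatenate([[1.0], z_obs])
    eta = beta @ x1
    expo = np.exp(np.clip(eta, -500, 500))
    denom = 1.0 + expo.sum()
    probs = np.concatenate([[1.0 / denom], expo / denom])
    # d p_k / d beta_{a,:} (baseline class 0 has no parameters)
    out = []
    for k in range(K):
        grad = np.zeros((K - 1) * q)
        for a in range(K - 1):
            dk = probs[k] * (((a + 1) == k) - probs[a + 1])
            grad[a * q:(a + 1) * q] = dk * x1
        var = float(grad @ cov @ grad)
        half = 1.959964 * np.sqrt(max(var, 0.0))
        out.append((max(0.0, probs[k] - half), min(1.0, probs[k] + half)))
    return out


def model_choice_rf(table: ReferenceTable,
                    observed_ss: dict[str, float] | np.ndarray,
                    n_trees: int = 500, seed: int | None = None
                    ) -> ModelChoiceResult:
    """ABC-RF: classification forest on raw statistics plus LDA axes.

    The chosen scenario is the majority tree vote at the observed point; its
    posterior probability is estimated by a regression forest trained on the
    out-of-bag correctness of the classifier (1 - local error rate), with an
    SD across trees.  The prior error rate is the overall out-of-bag
    misclassification rate.
    """
    if n_trees < 50:
        raise AbcError("n_trees < 50 is refused: vote noise too high")
    obs = (observed_ss if isinstance(observed_ss, np.ndarray)
           else observed_vector(observed_ss, table.ss_cols))
    X = table.data[table.ss_cols].to_numpy(float)
    y_labels = table.data["scenario"].to_numpy()
    names = table.scenario_names
    y = np.array([names.index(s) for s in y_labels])
    lda = _lda_axes(X, y)
    feats = np.hstack([X, lda.transform(X)])
    f_obs = np.hstack([obs, lda.transform(obs.reshape(1, -1))[0]])
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                 oob_score=True, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(feats, y)
    tree_votes = np.array([int(t.predict(f_obs.reshape(1, -1))[0])
                           for t in clf.estimators_])
    votes = {names[k]: int(np.sum(clf.classes_[tree_votes] == k))
             for k in range(len(names))}
    best = max(votes, key=votes.get)
    oob = clf.oob_decision_function_
    valid = ~np.isnan(oob).any(axis=1)
    oob_pred = np.full(len(y), -1)
    oob_pred[valid] = clf.classes_[np.argmax(oob[valid], axis=1)]
    prior_error = float(np.mean(oob_pred[valid] != y[valid]))
    correct = (oob_pred == y).astype(float)
    reg = RandomForestRegressor(n_estimators=n_trees,
                                random_state=None if seed is None else seed + 1,
                                n_jobs=1)
    reg.fit(feats[valid], correct[valid])
    tree_posts = np.array([t.predict(f_obs.reshape(1, -1))[0]
                           for t in reg.estimators_])
    posterior = float(np.mean(tree_posts))
    post_sd = float(np.std(tree_posts) / np.sqrt(n_trees))
    probs = {s: votes[s] / n_trees for s in names}
    return ModelChoiceResult("rf", list(names), probs, best=best, votes=votes,
                             rf_posterior=posterior, posterior_sd=post_sd,
                             prior_error_rate=prior_error)


# ---------------------------------------------------------------------------
# Error calibration
# ---------------------------------------------------------------------------

@dataclass
class ErrorCalibration:
    scenario_names: list[str]
    confusion: np.ndarray  # rows: true scenario, normalized
    type_i: dict[str, float]
    type_ii: dict[str, float]
    prior_error_rate: float


def calibrate_errors(scenario_set: ScenarioSet, table: ReferenceTable,
                     n_pods_per_scenario: int, tolerance: float, seed: int,
                     method: str = "logistic", n_trees: int = 500
                     ) -> ErrorCalibration:
    """Classify fresh held-out PODs to estimate scenario-choice error rates.

    type-I of scenario s = fraction of s-PODs not assigned to s; type-II of s
    = fraction of other-scenario PODs assigned to s; prior error rate = overall
    misclassification under equal scenario priors.
    """
    names = scenario_set.scenario_names()
    K = len(names)
    rng = np.random.default_rng(seed)
    clf = None
    lda_full = None
    if method == "rf":
        X = table.data[table.ss_cols].to_numpy(float)
        y = np.array([names.index(s) for s in table.data["scenario"]])
        lda_full = _lda_axes(X, y)
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                     n_jobs=1)
        clf.fit(np.hstack([X, lda_full.transform(X)]), y)
    counts = np.zeros((K, K))
    for s_idx, scen in enumerate(scenario_set.scenarios):
        for i in range(n_pods_per_scenario):
            pod_seed = int(rng.integers(1, 2**31 - 1))
            _, ss = simulate_pod(scenario_set, scen.name, pod_seed)
            obs = observed_vector(ss, table.ss_cols)
            if method == "logistic":
                selected, _ = rejection_select(obs, table, tolerance)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = model_choice_logistic(selected, obs, table)
                    win = res.best
                except AbcError:
                    win = selected["scenario"].mode()[0]
            elif method == "rf":
                f = np.hstack([obs, lda_full.transform(obs.reshape(1, -1))[0]])
                win = names[int(clf.predict(f.reshape(1, -1))[0])]
            else:
                raise AbcError(f"unknown calibration method {method!r}")
            counts[s_idx, names.index(win)] += 1
    confusion = counts / counts.sum(axis=1, keepdims=True)
    type_i = {s: float(1.0 - confusion[k, k]) for k, s in enumerate(names)}
    type_ii = {}
    for k, s in enumerate(names):
        others = [j for j in range(K) if j != k]
        type_ii[s] = float(counts[others, k].sum()
                           / max(counts[others, :].sum(), 1))
    prior_error = float(1.0 - np.trace(counts) / counts.sum())
    return ErrorCalibration(names, confusion, type_i, type_ii, prior_error)


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSample:
    params: pd.DataFrame  # regression-adjusted draws, one column per parameter
    weights: np.ndarray
    summaries: pd.DataFrame  # index: parameter; columns mode/mean/q2.5/q50/q97.5

    def point(self, param: str, kind: str = "median") -> float:
        col = {"mode": "mode", "mean": "mean", "median": "q50"}[kind]
        return float(self.summaries.loc[param, col])

    def interval(self, param: str) -> tuple[float, float]:
        return (float(self.summaries.loc[param, "q2.5"]),
                float(self.summaries.loc[param, "q97.5"]))


def _weighted_quantile(x: np.ndarray, w: np.ndarray, qs: Sequence[float]
                       ) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(qs, cum, x)


def estimate_parameters(selected: pd.DataFrame, distances: np.ndarray,
                        observed_ss: dict[str, float] | np.ndarray,
                        prior_bounds: dict[str, tuple[float, float]],
                        table: ReferenceTable) -> PosteriorSample:
    """Local-linear regression adjustment of the accepted parameter draws.

    Each bounded parameter is regressed on the (MAD-standardised) deviation of
    the statistics from the observed point, on the logit scale of its prior
    range, with Epanechnikov weights in distance; the fitted trend is removed
    and the intercept (the value predicted at the observed point) retained.
    """
    if len(selected) < 50:
        raise AbcError("fewer than 50 accepted rows: widen the tolerance or "
                       "enlarge the reference table")
    obs = (observed_ss if isinstance(observed_ss, np.ndarray)
           else observed_vector(observed_ss, table.ss_cols))
    X = selected[table.ss_cols].to_numpy(float)
    scale, keep = _robust_scale(table.data[table.ss_cols].to_numpy(float))
    D = (X[:, keep] - obs[keep]) / scale[keep]
    d_max = distances.max() * (1 + 1e-12) if distances.max() > 0 else 1.0
    w = 1.0 - (distances / d_max) ** 2
    w = np.clip(w, 1e-12, None)
    eps = 1e-8
    adjusted: dict[str, np.ndarray] = {}
    rows = []
    for pname, (lo, hi) in prior_bounds.items():
        col = f"param_{pname}"
        if col not in selected.columns:
            continue
        v = selected[col].to_numpy(float)
        if np.isnan(v).all():
            continue
        u = np.clip((v - lo) / (hi - lo), eps, 1 - eps)
        ylog = np.log(u / (1 - u))
        if np.ptp(ylog) < 1e-12:
            adj = v.copy()
        else:
            A = np.hstack([np.ones((len(D), 1)), D])
            W = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(A * W[:, None], ylog * W, rcond=None)
            resid = ylog - A @ beta
            y_adj = beta[0] + resid
            u_adj = 1.0 / (1.0 + np.exp(-np.clip(y_adj, -500, 500)))
            adj = lo + u_adj * (hi - lo)
        adjusted[pname] = adj
        q = _weighted_quantile(adj, w, [0.025, 0.05, 0.5, 0.95, 0.975])
        mean = float(np.average(adj, weights=w))
        if np.ptp(adj) < 1e-12:
            mode = float(adj[0])
        else:
            try:
                kde = gaussian_kde(adj, weights=w)
                grid = np.linspace(adj.min(), adj.max(), 512)
                mode = float(grid[np.argmax(kde(grid))])
            except np.linalg.LinAlgError:
                mode = float(q[2])
        rows.append({"parameter": pname, "mode": mode, "mean": mean,
                     "q2.5": q[0], "q5": q[1], "q50": q[2], "q95": q[3],
                     "q97.5": q[4]})
    summaries = pd.DataFrame(rows).set_index("parameter")
    return PosteriorSample(pd.DataFrame(adjusted), w, summaries)


# ---------------------------------------------------------------------------
# Posterior predictive checks
# ---------------------------------------------------------------------------

def posterior_predictive_check(posterior: PosteriorSample,
                               scenario_set: ScenarioSet, scenario: str,
                               observed_ss: dict[str, float], n_sims: int,
                               seed: int) -> pd.DataFrame:
    """Goodness-of-fit: simulate from the posterior, locate each observed statistic.

    Per statistic, p is the two-tailed empirical tail probability of the
    observed value in the posterior-predictive distribution (with the +1
    continuity correction); statistics with p < 0.05 are flagged as misfits.
    """
    rng = np.random.default_rng(seed)
    n_rows = len(posterior.params)
    p_w = posterior.weights / posterior.weights.sum()
    scen = scenario_set.get(scenario)
    sims: list[dict[str, float]] = []
    for _ in range(n_sims):
        row = int(rng.choice(n_rows, p=p_w))
        fixed = {k: float(posterior.params[k].iloc[row])
                 for k in posterior.params.columns}
        pod_seed = int(rng.integers(1, 2**31 - 1))
        try:
            _, ss = simulate_pod(scenario_set, scenario, pod_seed, fixed)
        except Exception:
            continue  # a posterior draw violating scenario conditions is skipped
        sims.append(ss)
    if not sims:
        raise AbcError("no posterior-predictive simulation succeeded")
    sim_df = pd.DataFrame(sims)
    rows = []
    for stat, obs_val in observed_ss.items():
        if stat not in sim_df.columns:
            continue
        vals = sim_df[stat].to_numpy(float)
        n = len(vals)
        p_low = (np.sum(vals <= obs_val) + 1) / (n + 1)
        p_high = (np.sum(vals >= obs_val) + 1) / (n + 1)
        p = min(1.0, 2 * min(p_low, p_high))
        rows.append({"statistic": stat, "observed": obs_val,
                     "sim_mean": float(vals.mean()), "sim_sd": float(vals.std()),
                     "p_value": p, "flagged": p < 0.05})
    return pd.DataFrame(rows).set_index("statistic")
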