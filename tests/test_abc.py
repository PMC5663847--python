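"""ABC engine: rejection oracle, model choice, posteriors, predictive checks."""

import numpy as np
import pandas as pd
import pytest

from rpabc import abc_engine
from rpabc.abc_engine import (AbcError, ReferenceTable, estimate_parameters,
                              model_choice_logistic, model_choice_rf,
                              posterior_predictive_check, rejection_select)
from rpabc.coalsim import SamplingDesign
from rpabc.scenarios import build_step3_collapse


def numeric_table(rng, n_per=300, k=2, d=5, shift=0.0):
    """Synthetic numeric reference table: Gaussian statistics per scenario,
    scenario j shifted by j*shift along every axis."""
    rows = []
    for j in range(k):
        X = rng.normal(j * shift, 1.0, size=(n_per, d))
        for i in range(n_per):
            row = {"scenario": f"S{j + 1}", "param_theta": rng.uniform(0, 1)}
            row.update({f"ss_x{m}": X[i, m] for m in range(d)})
            rows.append(row)
    return ReferenceTable(pd.DataFrame(rows), ["param_theta"],
                          [f"ss_x{m}" for m in range(d)],
                          [f"S{j + 1}" for j in range(k)], seed=0)


class TestRejection:
    def test_matches_brute_force_sort(self, rng):
        table = numeric_table(rng, n_per=500, k=2)
        obs = rng.normal(0, 1, size=5)
        sel, dist = rejection_select(obs, table, 0.07)
        # oracle: full standardized-distance sort
        X = table.data[table.ss_cols].to_numpy()
        med = np.median(X, axis=0)
        mad = np.median(np.abs(X - med), axis=0)
        d_all = np.sqrt((((X - obs) / mad) ** 2).sum(axis=1))
        expected = np.argsort(d_all, kind="stable")[:int(np.ceil(0.07 * 1000))]
        assert list(sel.index) == list(expected)
        assert np.allclose(dist, d_all[expected])

    def test_tolerance_one_returns_everything(self, rng):
        table = numeric_table(rng, n_per=50)
        obs = np.zeros(5)
        sel, _ = rejection_select(obs, table, 1.0)
        assert len(sel) == len(table.data)

    def test_observed_equal_to_row_ranks_first(self, rng):
        table = numeric_table(rng, n_per=100)
        obs = table.data.iloc[37][table.ss_cols].to_numpy(float)
        sel, dist = rejection_select(obs, table, 0.05)
        assert sel.index[0] == 37
        assert dist[0] == 0.0

    def test_bad_tolerance_rejected(self, rng):
        table = numeric_table(rng, n_per=10)
        with pytest.raises(AbcError):
            rejection_select(np.zeros(5), table, 0.0)


class TestModelChoice:
    def test_indistinguishable_scenarios_near_half(self, rng):
        # identical generating processes: over replicate analyses the mean
        # posterior must sit near 1/2 and the CIs must overlap 1/2 often
        probs, ci_hits = [], 0
        for _ in range(20):
            table = numeric_table(rng, n_per=250, k=2, shift=0.0)
            obs = rng.normal(0, 1, size=5)
            sel, _ = rejection_select(obs, table, 0.5)
            res = model_choice_logistic(sel, obs, table)
            probs.append(res.probabilities["S1"])
            if res.ci95 is not None:
                lo, hi = res.ci95["S1"]
                ci_hits += lo <= 0.5 <= hi
        assert abs(np.mean(probs) - 0.5) < 0.1
        assert ci_hits >= 10

    def test_separable_scenarios_confident_winner(self, rng):
        table = numeric_table(rng, n_per=400, k=2, shift=12.0)
        obs = np.full(5, 12.0)  # squarely inside scenario S2's support
        sel, _ = rejection_select(obs, table, 0.5)
        res = model_choice_logistic(sel, obs, table)
        assert res.best == "S2"
        assert res.probabilities["S2"] > 0.99
        rf = model_choice_rf(table, obs, n_trees=100, seed=3)
        assert rf.best == "S2"
        assert rf.prior_error_rate < 0.02
        assert rf.votes["S2"] >= 99

    def test_identical_scenarios_rf_coin_flip(self, rng):
        table = numeric_table(rng, n_per=400, k=2, shift=0.0)
        rf = model_choice_rf(table, np.zeros(5), n_trees=100, seed=5)
        assert abs(rf.prior_error_rate - 0.5) < 0.08
        assert sum(rf.votes.values()) == 100

    def test_small_forest_refused(self, rng):
        table = numeric_table(rng, n_per=50)
        with pytest.raises(AbcError, match="n_trees"):
            model_choice_rf(table, np.zeros(5), n_trees=10)

    def test_probabilities_sum_to_one(self, rng):
        table = numeric_table(rng, n_per=200, k=3, shift=1.0)
        obs = rng.normal(1, 1, size=5)
        sel, _ = rejection_select(obs, table, 0.4)
        res = model_choice_logistic(sel, obs, table)
        assert sum(res.probabilities.values()) == pytest.approx(1.0, abs=1e-9)


class TestEstimateParameters:
    def test_degenerate_posterior_at_shared_value(self, rng):
        table = numeric_table(rng, n_per=200)
        table.data["param_theta"] = 0.42
        obs = np.zeros(5)
        sel, dist = rejection_select(obs, table, 0.5)
        post = estimate_parameters(sel, dist, obs, {"theta": (0.0, 1.0)}, table)
        assert post.point("theta") == pytest.approx(0.42, abs=1e-9)
        lo, hi = post.interval("theta")
        assert hi - lo < 1e-9

    def test_adjustment_respects_prior_bounds(self, rng):
        table = numeric_table(rng, n_per=400)
        # parameter correlated with the first statistic
        table.data["param_theta"] = (
            0.5 + 0.2 * table.data["ss_x0"]).clip(0.01, 0.99)
        obs = np.full(5, 0.5)
        sel, dist = rejection_select(obs, table, 0.25)
        post = estimate_parameters(sel, dist, obs, {"theta": (0.0, 1.0)}, table)
        vals = post.params["theta"].to_numpy()
        assert np.all((vals >= 0.0) & (vals <= 1.0))
        # regression shrinks the spread relative to the raw accepted draws
        raw = sel["param_theta"].to_numpy()
        assert vals.std() < raw.std()

    def test_too_few_rows_fail_with_guidance(self, rng):
        table = numeric_table(rng, n_per=30)
        obs = np.zeros(5)
        sel, dist = rejection_select(obs, table, 0.2)
        with pytest.raises(AbcError, match="tolerance"):
            estimate_parameters(sel, dist, obs, {"theta": (0, 1)}, table)


@pytest.fixture(scope="module")
def small_fit():
    design = SamplingDesign(n_diploid={"PY": 6, "TL": 5, "XCSS": 5},
                            n_mt={"PY": 4, "TL": 3, "XCSS": 3},
                            n_loci=6, mt_length=300)
    sset = build_step3_collapse(design)
    table = abc_engine.build_reference_table(sset, 150, seed=21)
    obs_params, obs_ss = abc_engine.simulate_pod(sset, "SC1", 4242)
    obs = abc_engine.observed_vector(obs_ss, table.ss_cols)
    sub = ReferenceTable(
        table.data[table.data["scenario"] == "SC1"].reset_index(drop=True),
        table.param_cols, table.ss_cols, ["SC1"], table.seed)
    sel, dist = rejection_select(obs, sub, 0.5)
    post = estimate_parameters(sel, dist, obs, sset.prior_bounds("SC1"), sub)
    return sset, post, obs_ss, table


class TestPosteriorPredictive:

    def test_well_specified_model_rarely_flagged(self, small_fit):
        sset, post, obs_ss, table = small_fit
        ppc = posterior_predictive_check(post, sset, "SC1", obs_ss,
                                         n_sims=80, seed=11)
        # data simulated under the fitted model: few statistics flagged
        assert ppc["flagged"].mean() < 0.25

    def test_shifted_statistic_is_flagged(self, small_fit):
        sset, post, obs_ss, table = small_fit
        shifted = dict(obs_ss)
        sd = table.data["ss_mic_he_PY"].std()
        shifted["mic_he_PY"] = obs_ss["mic_he_PY"] + 10 * sd
        ppc = posterior_predictive_check(post, sset, "SC1", shifted,
                                         n_sims=80, seed=12)
        assert bool(ppc.loc["mic_he_PY", "flagged"])
        assert ppc.loc["mic_he_PY", "p_value"] < 0.05
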