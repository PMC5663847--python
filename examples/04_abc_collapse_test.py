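"""ABC model choice: did the populations collapse recently?

Plants a known truth (a collapse to a 2% remnant within the last five
generations) in a synthetic dataset, simulates a reference table under the
two competing final-step scenarios, and runs both model-choice procedures
(logistic regression on LDA axes, and random forest) plus parameter
estimation for the remnant fraction.

Desk-scale settings (a few hundred simulations per scenario) keep this under
a couple of minutes; accuracy grows with the table size.
"""

import numpy as np

from rpabc import abc_engine
from rpabc.coalsim import SamplingDesign
from rpabc.scenarios import build_step3_collapse
from rpabc.synthetic import TruthConfig, generate_study_like

kw = dict(n_diploid={"PY": 16, "TL": 10, "XCSS": 10},
          n_mt={"PY": 10, "TL": 8, "XCSS": 8}, missing_rate=0.05)
geno, mt, part, _ = generate_study_like(
    TruthConfig(scenario="collapse", seed=11, **kw))
observed = abc_engine.summary_statistics(geno, mt, part)

design = SamplingDesign(n_diploid=kw["n_diploid"], n_mt=kw["n_mt"],
                        n_loci=11, mt_length=597)
sset = build_step3_collapse(design)
print("simulating the reference table (2 scenarios x 400 PODs)...")
table = abc_engine.build_reference_table(sset, 400, seed=3)

obs = abc_engine.observed_vector(observed, table.ss_cols)
selected, dist = abc_engine.rejection_select(obs, table, 0.1)
logi = abc_engine.model_choice_logistic(selected, obs, table)
rf = abc_engine.model_choice_rf(table, obs, n_trees=300, seed=5)

print(f"\nABC-LDA posterior P(collapse) = {logi.probabilities['SC2']:.1%}")
print(f"ABC-RF  votes for collapse    = {rf.probabilities['SC2']:.1%} "
      f"(posterior {rf.rf_posterior:.1%} +- {rf.posterior_sd:.1%})")
print(f"RF prior error rate           = {rf.prior_error_rate:.1%}")

win = table.data[table.data["scenario"] == "SC2"].reset_index(drop=True)
win_table = abc_engine.ReferenceTable(win, table.param_cols, table.ss_cols,
                                      ["SC2"], table.seed)
sel_w, dist_w = abc_engine.rejection_select(obs, win_table, 0.3)
post = abc_engine.estimate_parameters(sel_w, dist_w, obs,
                                      sset.prior_bounds("SC2"), win_table)
meds = [post.point(f"f_{p}") for p in ("PY", "TL", "XCSS")]
print(f"\nremnant-fraction posterior medians: "
      + ", ".join(f"{m:.3f}" for m in meds)
      + f"  -> median {np.median(meds):.3f}  (truth: 0.020)")
print("\nBoth procedures should favour the collapse scenario. Individual "
      "per-population remnants are noisy at this desk scale (few hundred "
      "PODs, 10-16 diploids per group); the median across populations "
      "should still sit below 0.1, pointing at a severe collapse.")
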