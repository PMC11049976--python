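"""Measure per-site prediction accuracy under the CV1, CV2 and CV3 designs.

CV1 hides whole lines (new-line prediction), CV2 hides lines at a subset of
sites (sparse multi-site testing), CV3 keeps only a small training set at
one focal site.  Accuracy is the Pearson correlation between predicted and
observed (site-centered line-mean) breeding values of the test set,
averaged over folds.
"""

from famet import SimConfig, simulate_dataset
from famet.cv import run_cv

cfg = SimConfig(n_genotypes=60, n_markers=400, n_sites=3, seed=3)
markers, truth, pheno = simulate_dataset(cfg)

for scheme, opts in [("CV1", None),
                     ("CV2", None),
                     ("CV3", {"n_train_focal": 15, "focal_site": "S1"})]:
    table, summary = run_cv(pheno, markers, scheme, ["FA+G"], n_folds=5,
                            seed=1, scheme_opts=opts, truth=truth.to_frame())
    mean_obs = table[table.model == "FA+G"]["pearson_r"].mean()
    mean_tru = table[table.model == "FA+G:truth"]["pearson_r"].mean()
    print(f"{scheme}: mean accuracy {mean_obs:.2f} vs observed values, "
          f"{mean_tru:.2f} vs the simulator's true genetic values")

print("\nCV2 and CV3 exceed CV1 because test lines keep phenotypes at other "
      "sites,\nso prediction can borrow their own records through the "
      "genetic site covariance,\nwhereas CV1 lines are predicted from "
      "marker relatedness alone.")
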