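"""Simulate a multi-environment wheat trial with known genetic architecture.

Generates an inbred-line SNP panel, marker-driven genetic values with a
factor-analytic site covariance, and replicated plot yields, then prints
the generating parameters next to simple empirical summaries.
"""

import numpy as np

from famet import SimConfig, simulate_dataset

cfg = SimConfig(n_genotypes=120, n_markers=800, n_sites=4, n_reps=2,
                missing_rate=0.03, seed=42)
markers, truth, pheno = simulate_dataset(cfg)

print(f"panel: {markers.n_genotypes} lines x {markers.n_markers} SNPs "
      f"({100 * np.isnan(markers.values).mean():.1f}% missing calls)")
print(f"trial: {pheno.n_records} yield records over {cfg.n_sites} sites, "
      f"{cfg.n_reps} replicates\n")

print("generating site covariance (Lambda Lambda' + Psi):")
print(np.round(cfg.site_covariance(), 3))
print("\nempirical covariance of the true genetic values across sites:")
print(np.round(np.cov(truth.true_genetic_values.T), 3))
# the two matrices agree because factor scores are standardised exactly;
# residual differences come from the site-specific deviations (psi draws)

h2 = np.diag(cfg.site_covariance()) / (
    np.diag(cfg.site_covariance()) + cfg.res_var / cfg.n_reps)
print(f"\nline-mean heritability per site: {np.round(h2, 2)}")
print("(the fraction of variance among line means at a site that is genetic)")
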