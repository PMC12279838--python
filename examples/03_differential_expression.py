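"""Moderated t-test differential expression on true miRNA data.

Runs the empirical-Bayes moderated two-group comparison and shows that the
simulated differentially expressed miRNAs surface at the top of the ranking.
Raw p-values only — no multiplicity adjustment is applied anywhere.
"""

import numpy as np

from crossmir import SimConfig, expected_mirna_logfc, moderated_t_test, simulate_paired_dataset

sim = SimConfig(n_mirna=200, n_mrna=100, seed=3)
_, Y, groups, truth = simulate_paired_dataset(sim)

res = moderated_t_test(Y, groups)
print(f"prior df d0 = {res.d0:.2f}, prior variance s0^2 = {res.s0_sq:.4f} "
      f"(residual df per feature: {res.residual_df:.0f})")

order = np.argsort(res.p_raw)
top10 = [res.feature_ids[i] for i in order[:10]]
hits = sum(g in truth.de_mirna_ids for g in top10)
print(f"top 10 by p-value: {hits}/10 are truly differentially expressed")

oracle = expected_mirna_logfc(truth, sim)
r = np.corrcoef(res.logfc, oracle)[0, 1]
print(f"empirical logFC vs. noise-free truth: r = {r:.3f}")
print("""
The moderation borrows strength across miRNAs: each feature's variance is
shrunk toward the prior with d0 extra degrees of freedom, stabilizing the
t-statistics at n = 5 + 5.
""")
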