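"""Consensus clustering on a separable planted four-cluster cohort:
run the resampling loop, inspect the stability diagnostics, select k."""

from sklearn.metrics import adjusted_rand_score

import hrsclust as hc

cohort = hc.simulate_cohort(hc.high_separation_config(n_admissions=240, seed=2))
features = hc.zscore_continuous(hc.encode_features(cohort))

config = hc.ConsensusConfig(k_min=2, k_max=6, iterations=50, seed=0)
matrices = hc.run_consensus(features, config)

diag = hc.compute_diagnostics(matrices)
selected, rationale = hc.select_optimal_k(diag)
print(diag.to_frame()[["cdf_area", "delta_area", "pac",
                       "mean_cluster_consensus"]].round(4))
print(f"\nselected k = {selected}  ({rationale['rule']})")

ari = adjusted_rand_score(cohort.true_labels, matrices[selected].labels)
print(f"adjusted Rand index vs planted labels: {ari:.3f}")

# PAC (lower = fewer ambiguous pairs) bottoms out and the within-cluster
# consensus peaks at the planted k = 4; ARI 1.0 means the partition
# recovered the planted clusters exactly.
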