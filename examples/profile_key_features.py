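"""Identify each cluster's key features by standardized mean difference."""

import hrsclust as hc

cohort = hc.simulate_cohort(hc.table1_config(n_admissions=5564, seed=1))
records = hc.key_features(cohort, cohort.true_labels, cutoff=0.3)

for cluster in (1, 2, 3, 4):
    top = [r for r in records if r.cluster == cluster and r.flagged][:5]
    print(f"cluster {cluster}: " + ", ".join(
        f"{r.variable} ({r.smd:+.2f})" for r in top))

# Each line lists the five variables whose prevalence (or mean, for age)
# most separates that cluster from the pooled rest; |SMD| > 0.3 counts as
# a key feature, and the sign says whether the cluster is enriched (+) or
# depleted (-).
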