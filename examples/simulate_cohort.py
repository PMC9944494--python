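"""Simulate an admission cohort from the published per-cluster parameters
and check that the generator reproduces them."""

import hrsclust as hc

config = hc.table1_config(n_admissions=5564, seed=1)
cohort = hc.simulate_cohort(config)
print(f"simulated {cohort.n_admissions} admissions, "
      f"{len(cohort.variables)} variables, "
      f"{int(cohort.outcome.sum())} in-hospital deaths")

observed = {p.label: p for p in
            hc.empirical_frequencies(cohort, cohort.true_labels)}
print("\ncluster  prevalence (target)   alcoholic cirrhosis (target)   age mean (target)")
for target in config.profiles:
    obs = observed[target.label]
    print(f"   {target.label}     {obs.prevalence:.3f} ({target.prevalence:.3f})        "
          f"{obs.binary_probs['Alcoholic cirrhosis']:.3f} ({target.binary_probs['Alcoholic cirrhosis']:.3f})"
          f"                {obs.age_mean:.1f} ({target.age_mean})")

# Each observed value should sit within sampling noise (a few binomial
# standard errors) of the generator parameter it was drawn from.
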