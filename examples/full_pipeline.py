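"""The whole analysis in one call, at reduced size for a quick demo:
simulate, encode, consensus-cluster, select k, profile, compare mortality."""

import hrsclust as hc

result = hc.run_pipeline(
    generator=hc.high_separation_config(n_admissions=300, seed=5),
    consensus=hc.ConsensusConfig(k_min=2, k_max=6, iterations=50, seed=5),
)

print(f"selected k = {result.selected_k}")
print("\nmortality by assigned cluster:")
print(result.mortality[["n", "deaths", "percent"]])
print("\nodds ratios vs lowest-mortality cluster:")
print(result.odds_ratios.round(2))

# result.write("output/")  # would persist every table and figure

# The planted four-cluster structure is recovered; the mortality gradient
# built into the generator (10%..40% across clusters) shows up as odds
# ratios increasing away from the reference cluster.
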