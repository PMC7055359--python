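"""Generate a synthetic cohort and inspect its ground truth.

Eight animals (four controls, four cases) each get a latent disease severity
that drives both their behavioral battery and the expression of a planted
18-gene signature in an overdispersed RNA-seq count matrix.
"""

from npsle import SyntheticConfig, generate_cohort, planted_signature

config = SyntheticConfig(seed=1)
battery, counts, severity = generate_cohort(config)

print("latent severity (ground truth):")
print(severity.round(2).to_string())
print("\nbehavioral battery (selected subtests):")
print(battery[["group", "mwm_latency_d5", "fc_context", "ppi_12khz", "rotarod_d5"]].round(1))
print(f"\ncount matrix: {counts.counts.shape[0]} genes x {counts.counts.shape[1]} samples")
print(f"planted signature genes: {', '.join(planted_signature(config)[:5])}, ...")
print("\nCases (higher severity) show longer water-maze latency, less context")
print("freezing, higher %PPI at 12 kHz and shorter rotarod times than controls.")
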