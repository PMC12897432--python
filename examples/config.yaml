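# Minimal configuration: every unspecified parameter takes the study default
# (100 cows, 24 years, June 15 x 90-day breeding, 2.25 Mcal ME/kg diet,
# 3x3 genotype grid x 4 intake levels, 5 replicates).
rng_seed: 1

# Example overrides for a faster exploratory run:
herd_size: 60
horizon_years: 14
n_replicates: 2
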