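# Strong-migration regime: produces clustered mesoscale architecture.
# Keys mirror ModelParams; omitted keys keep their defaults.
n_neurons: 100
domain_side: 447.2136        # density-preserving scale-down of 500 / 1 mm^2
rho_migration: 150           # µm/day
duration_days: 14.0
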