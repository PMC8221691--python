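# Run configuration for the benchmark analysis.
perspective: societal        # societal | healthcare (excludes informal care)
n_imputations: 10
n_bootstrap: 5000
alpha: 0.05
collinearity_cutoff: 0.4     # |Spearman rho| above this flags a covariate pair
quarter_days: 91
interpolation_weights: [0.5, 1.5]
rng_seed: 1
price_table: reference
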