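# A reduced synthetic-cohort scenario (the full study-scale defaults apply
# to any field omitted here).  Effects are additive shifts in expected
# 6-month societal cost per client.
n_orgs_per_model: {CM1: 3, CM2: 3, CM3: 3}
n_clients_per_org: 120
true_model_effects: {CM1: 0.0, CM2: 2230.0, CM3: -321.0}
missingness: {mechanism: mcar, rate: 0.037}
seed: 42
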