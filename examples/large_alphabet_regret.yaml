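# Worst-case regret study on a heavy-tailed alphabet:
# n draws from Zipf(s=1.5) over 1000 symbols, per-draw regret vs the
# natural oracle, replicated k times.
generator:
  family: zipf
  params: {m: 1000, s: 1.5}
n_grid: [20, 40, 80]
k: 2000
estimators: [good_turing, loo_uniform, loo_nml]
metric: regret_vs_oracle
alpha: 0.05
master_seed: 1
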