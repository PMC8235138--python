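# Gaussian unknown-mean study: KL of each estimate from N(0,1),
# comparing the plug-in MLE with the capacity mixture and the NML.
generator:
  family: gaussian
  params: {d: 1}
n_grid: [5, 10, 20]
k: 2000
estimators: [mle, mixture, nml]
metric: kl
alpha: 0.05
master_seed: 1
options: {mix_interior: 9, ba_tol: 1.0e-6, quad_nodes: 120}
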