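# End-to-end demo: generate a bulk titration and a synthetic-cell
# population, fit the full model, profile two parameters, and summarize the
# population. Completes in a few minutes on one CPU.
seed: 11
out_dir: scratch/demo_run
stages: [generate, fit, profile, summarize]

generate:
  bulk:
    dna_levels_nM: [0.94, 1.875, 3.75]
    replicates: 3
    noise_cv: 0.02
  population:
    dna_levels_nM: [1.75, 3.5, 7.0]
    n_cells: 40

fit:
  variant: V1
  n_starts: 4
  free: [k_r, K_r, delta_r, k_p, K_p, delta_TsR, delta_TlR, a, b]
  fixed: {k_mat: 2.15, K_l: 1.21e-06, tau_d: 0.433, tau_l: 0.0}

profile:
  parameters: [k_r, delta_r]
  n_grid: 11

summarize: {}
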