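# Scenario grid for `sparseclr experiment`: fold-change sweep in four steps
# from 1 to 2 at three library-size-variability levels, plus a
# coupled-treatment block with and without stringent extra filtering.
# Replication is reduced; raise n_sims/n_perm for publication-grade rates.
defaults:
  I: 50
  J: 500
  sigma_t: 2
  n_da: 100
  min_prevalence: 5
  n_sims: 100
  n_perm: 199
  method: lr_rda

scenarios:
  # power vs fold change (no treatment-library-size coupling)
  - {fold_change: 1.0,  sigma_a: 0.0}
  - {fold_change: 1.33, sigma_a: 0.0}
  - {fold_change: 1.67, sigma_a: 0.0}
  - {fold_change: 2.0,  sigma_a: 0.0}
  - {fold_change: 1.0,  sigma_a: 0.5}
  - {fold_change: 1.33, sigma_a: 0.5}
  - {fold_change: 1.67, sigma_a: 0.5}
  - {fold_change: 2.0,  sigma_a: 0.5}
  - {fold_change: 1.0,  sigma_a: 1.0}
  - {fold_change: 1.33, sigma_a: 1.0}
  - {fold_change: 1.67, sigma_a: 1.0}
  - {fold_change: 2.0,  sigma_a: 1.0}
  # type-I error with treatment coupled to library size
  - {fold_change: 1.0, sigma_a: 1.0, gamma: 2.0, name: coupled}
  - {fold_change: 1.0, sigma_a: 1.0, gamma: 2.0, name: coupled-filtered,
     extra_min_prevalence: 25, extra_min_mean_abundance: 2.0}
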