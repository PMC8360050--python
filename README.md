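# sparseclr

Log-ratio analysis of sparse count tables — and the diagnostics that tell
you when it silently depends on library size.

## The problem

Amplicon-sequencing count tables (microbiome 16S/18S data and the like) are
compositional: the total count per sample, the *library size*, is a
technical artefact of the sequencing platform. The standard compositional
remedy is the centred log-ratio (clr) transform followed by PCA — a
*log-ratio PCA* — or its constrained cousin, log-ratio redundancy analysis
(RDA), tested by permutation. For strictly positive data this removes the
per-sample total exactly.

Real amplicon tables, however, combine two awkward features: a large
fraction of zeros and large library-size variation. Zeros force a
pseudo-count, and the pseudo-count destroys the proportionality on which
the clr relies. Writing `L = log(Y + 1)`, `r` for its row means and `c` for
its column means, log-ratio PCA decomposes the double-centred matrix

```
s_ij = l_ij − r_i − c_j + l..          S = U Σ Vᵀ
```

For a zero cell, `s_ij = −r_i − c_j + l..`: rare taxa end up carrying `−r`
— the library-size signal — rather than biology. The consequences are
concrete: power to detect a real treatment effect collapses as library-size
variability grows, and if the treatment happens to correlate with library
size, the permutation test's type-I error inflates toward 1.

`sparseclr` packages the machinery to study, detect and mitigate this:

* a negative-binomial simulator with a log-linear mean
  `log μ_ij = a_i + t_j + b_j x_i`, controllable library-size variability
  (`σ_a`), treatment effects (fold change on a subset of taxa) and optional
  treatment–library-size coupling via
  `x_i ~ Bernoulli(g·σ(γ a_i))` with `g` tuned for balanced groups;
* the transforms: pseudo-count log, clr, double centring, plus the
  alternatives (geometric Bayesian-multiplicative zero imputation, log
  proportions, square roots);
* ordination: log-ratio PCA, RDA, CCA, and the Monte-Carlo permutation
  test on the constrained-inertia fraction;
* the two per-taxon diagnostics — `ρ_Sr` (correlation of each S column
  with `r`) and per-axis contributions (`V²`), both against log mean
  abundance — with an automated flag;
* a scenario harness for type-I-error / power studies over parameter grids.

## Worked example

`examples/02_diagnose_library_size_dependence.py` simulates the same
community twice — without (`σ_a = 0`) and with (`σ_a = 1`) library-size
variability — and runs the diagnostics:

```
sigma_a = 0.0
  axis-1 / axis-2 explained inertia: 7.3% / 3.8%
  median rho_Sr of rarest decile:   -0.14
  rho_Sr trend with abundance:       spearman +0.34
  variance of S explained by r:      3.6%
  library-size dependence flagged:   False

sigma_a = 1.0
  axis-1 / axis-2 explained inertia: 9.4% / 5.2%
  median rho_Sr of rarest decile:   -0.75
  rho_Sr trend with abundance:       spearman +0.91
  variance of S explained by r:      8.5%
  library-size dependence flagged:   True
```

Same biology, same treatment — but once library sizes vary, the rarest
taxa correlate at −0.75 with `r` and the flag fires: part of what the PCA
displays is the sequencing depth, not the community.

The companion scripts show the downstream consequences.
`examples/03_rda_permutation_test.py` contrasts a genuine effect with a
spurious one (no effect, treatment coupled to library size) — both give
small p-values. `examples/04_power_study.py` runs a miniature grid:

```
          scenario  rejection_rate  mc_se  mean_corr_xr
fc=1.0 sigma_a=0.5           0.030  0.017         0.013
fc=1.0 sigma_a=1.0           0.020  0.014         0.009
fc=1.5 sigma_a=0.5           0.650  0.048         0.031
fc=1.5 sigma_a=1.0           0.170  0.038         0.015
```

Type-I error stays nominal, but power at fold change 1.5 drops from 0.65
to 0.17 as `σ_a` goes from 0.5 to 1.

There is also a thin CLI over the same functions:

```sh
sparseclr simulate --sigma-a 1 --seed 7 --out-dir out/
sparseclr diagnose out/counts.tsv --out-dir out/
sparseclr rda-test out/counts.tsv --metadata out/truth.tsv --n-perm 999
sparseclr experiment --config examples/power_grid.yaml --out-dir out/
```

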