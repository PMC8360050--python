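# Methods

## The generative model

The simulator draws an `I × J` count table (default 50 samples × 500 taxa)
with independent negative-binomial cells,

    y_ij ~ NB(mean μ_ij, size k),      log μ_ij = a_i + t_j + b_j x_i,

* `a_i ~ N(0, σ_a²)` — per-sample effect; the library size of sample *i*
  is proportional to `e^{a_i}` in expectation, so `σ_a` (a standard
  deviation, default levels 0, 0.5, 1) controls library-size variability.
  At `σ_a = 1` library sizes span roughly two orders of magnitude.
* `t_j ~ N(0, σ_t²)` — per-taxon abundance effect, `σ_t = 2` by default.
  This produces the heavy-tailed abundance distribution typical of
  amplicon data: a few dominant taxa, a long tail of rare ones.
* `b_j` — treatment effect: `n_da` taxa (default 100) are drawn uniformly
  without replacement and assigned `±log(fold_change)` with equal
  probability; all other `b_j = 0`.
* `x_i ∈ {0,1}` — treatment indicator for two groups of exactly `I/2`.
* `k` — NB size; the default `k = 1` gives variance `μ + μ²`, strong
  overdispersion under which, by the symmetry of `E[1/(1+e^Z)]` for
  symmetric `Z`, about half of all cells are zero before filtering.

Taxa present in fewer than `min_prevalence = 5` samples are removed after
sampling; library sizes are recomputed.

### Treatment–library-size coupling

To study confounding, `x_i ~ Bernoulli(min(1, g·σ(γ a_i)))` with `σ` the
logistic function. `γ ≥ 0` sets the coupling strength; `g` is tuned per
draw by bisection so that `Σ_i min(1, g·σ(γ a_i)) = I/2`, i.e. the groups
are balanced in expectation (the clipping is needed because `g·σ(·)` may
exceed one). The realised vector is redrawn until `Σ x_i = I/2` exactly
(capped at 10⁵ attempts, then an error reporting the best achieved
balance). Conditioning on exact balance by rejection preserves the stated
Bernoulli mechanism; with `γ = 0` every balanced assignment is equally
likely and `g = 1`. Under this coupling with `γ = 2`, the mean Pearson
correlation between `x` and the row mean `r` of `log(Y+1)` is ≈ 0.22 /
0.41 / 0.58 at `σ_a` = 0.25 / 0.5 / 1 (computed by
`correlation_xr_summary`; both signed and absolute means are reported, the
signed mean being the headline number since the coupling fixes the sign).

## Transforms

All logs are natural; the base cancels in every correlation and
variance-fraction reported. The pseudo-count (default 1) is added to every
cell, not only zeros. `double_center` stores `S`, the row means `r`, the
column means `c` and the grand mean, and reconstructs `L` exactly; a
double-centred matrix is a fixed point of the operation. The clr equals
`L` minus its row means; for zero-free rows it is scale-invariant,
with zeros and a pseudo-count it is not — that broken invariance is the
root of the library-size dependence and is pinned by a regression test.

Alternative transforms used by the putative remedies:

* **Bayesian-multiplicative zero imputation (GBM prior).** Each sample's
  proportions are treated as multinomial with a Dirichlet prior of
  composition `t` and strength `s`; a zero becomes its posterior
  expectation `s·t_j/(n_i+s)` and the observed parts are multiplied by
  `1 − Σ(replacements)` so their ratios are untouched. The geometric prior
  takes `t_j` proportional to the geometric mean of taxon *j*'s non-zero
  proportions across samples; the default strength is `s = 1/g(t)` (the
  reciprocal geometric mean of the prior composition), which reduces to
  the Bayes–Laplace strength `J` for a uniform prior. Replacements are
  capped at 65% of the row's smallest observed proportion. Both knobs
  (`prior_strength`, `max_frac_of_min`) are exposed because published
  applications differ in these defaults. Output is on the proportion or
  count scale (`on_proportions`).
* **Log proportions:** `log((y_ij + 1)/n_i)`; column-centred by the
  ordination, not by the transform.
* **Square root** of counts, the classical variance-stabilising choice
  feeding CCA.

## Ordination and testing

`lr_pca` is the SVD of `S` with no column rescaling — the contribution
diagnostic (squared loadings) is only meaningful on unscaled `S` — and
uniform row weights, matching the double-centring algebra. Explained
fractions are `σ_k²` over the full squared Frobenius norm, so truncated
solutions sum to less than one.

`rda` projects a centred response matrix onto the centred explanatory
design by least squares; the statistic is the constrained-inertia fraction
`‖HM‖²_F / ‖M‖²_F ∈ [0,1]`, monotone non-decreasing in added design
columns. `cca` works on the chi-square standardised residuals of the
closed table with row-weighted regression. Both agree with vegan's
`rda`/`cca` constrained-inertia proportions to 1e-8 (checked in the test
suite via Rscript when available).

`permutation_test` permutes the rows of `x` freely, recomputes the
fraction, and reports `p = (1 + #{perm ≥ observed})/(n_perm + 1)` — the
add-one convention with ties counted as exceedances (a tie tolerance of
1e-12 guards against floating-point asymmetry; observed and permuted
statistics are computed by the same code path). For a single explanatory
vector the statistic reduces to `‖x_cᵀM‖²/(‖x_c‖²‖M‖²)`, which is
evaluated for all permutations in one matrix product. Only single-factor
binary designs are exercised by the experiment harness; the design-matrix
path is general but deliberately unexercised beyond that.

## Diagnostics

* `correlation_diagnostic`: Pearson correlation of each S column with `r`,
  against the natural log of the taxon's mean count in the (filtered)
  table. An all-zero pseudo-counted column satisfies
  `s_ij = −r_i − c_j + l..` identically, so its correlation with a
  non-constant `r` is −1 exactly. Constant S columns are reported as
  missing and flagged rather than dropped silently.
* `contribution_diagnostic`: squared loading of each taxon on a chosen
  axis (1-based); loadings are unit-norm so contributions sum to one per
  axis. Elevated, near-equal contributions among the rare taxa mark an
  axis dominated by `r`; at strong variability the pattern becomes
  V-shaped because many abundant taxa also turn positively correlated
  with `r` (reproduced, not explained — it presumably compensates the
  `−r` load of the rare taxa under the zero-sum constraint).
* `variance_explained_by_r`: RDA of `S` constrained by `r`. No absolute
  threshold is attached: it has no natural reference point, so it is
  reported for comparison across datasets rather than flagged.
* `flag_library_size_dependence` operationalises the visual rule
  "increasing `ρ_Sr` trend starting low": flag iff the one-sided Spearman
  rank correlation of `ρ_Sr` with log mean abundance is positive at
  p < 0.05 *and* the median `ρ_Sr` of the lowest-abundance **decile** is
  below −0.5. The decile (rather than a wider band) isolates the rarest
  taxa, which carry the `−r` signature most strongly; across repeated
  draws at the default settings the decile median separates the
  `σ_a = 0` regime (≈ −0.13) from `σ_a = 1` (≈ −0.80) with no overlap at
  the −0.5 cut, whereas a tercile dilutes the median with moderately
  abundant taxa and straddles the cut at `σ_a = 1`.

## Experiment harness

A `Scenario` couples `SimParams` with one analysis method (`lr_rda`, GBM
variants, log-proportions RDA, CCA on counts or square roots), a
simulation count, a permutation count and an optional extra filter
(prevalence and/or mean-abundance threshold — the stringent-filtering
remedy). Per simulation the harness draws effects, assigns treatment,
samples counts, filters, transforms, tests, and records `p < α` plus
`corr(x, r)`; failures are counted, never dropped. Rejection tables carry
the binomial Monte-Carlo standard error `sqrt(p(1−p)/n)`. Grids run with
independent RNG substreams spawned from a master seed; a scenario with an
explicit seed reproduces exactly wherever it appears.

## Replication levels and numerical choices

Default replication is 500 simulations × 199 permutations per scenario
(binomial SE ≤ 0.022, sufficient to resolve the rates of interest);
publication-scale settings (2000 × 999) are a config change. The
acceptance script uses 1000 draws per correlation level, 50 replicate
draws for the sparsity summaries, 3 × 500 null simulations and 400 power
simulations. Bisection for `g` uses Brent's method to 1e-12 on a bracket
grown by doubling. `exp(η)` is guarded at η ≤ 40 (beyond which NB sampling
would overflow) with an error naming the offending cell. Correlations are
clipped to [−1, 1] against rounding; `r` must be non-constant for every
diagnostic, enforced with explicit errors.

## What the simulator does and does not emulate

It reproduces the statistical skeleton of sparse amplicon data —
overdispersed counts, heavy-tailed taxon abundances, variable library
sizes, optional treatment–depth confounding, prevalence filtering — which
is exactly what the transform-level pathology depends on. It does not
model sequencing error, chimeras, taxonomic mis-assignment, phylogenetic
correlation among taxa, or correlation between taxa beyond the shared
sample effects. Passing tests therefore demonstrate the behaviour of the
*methods* under controlled conditions, not the full complexity of any
real dataset; the generic TSV/CSV/BIOM readers accept real tables for the
same analyses.

## Known limitations

* The published power values for log-ratio RDA at fold change 1.5 (≈ 0.75
  at `σ_a = 0.5`, ≈ 0.25 at `σ_a = 1`) are not fully recovered: this
  implementation yields 0.66 ± 0.01 and 0.17 ± 0.01 under the documented
  protocol, with either 199 or 999 permutations. The direction and shape
  of the decay match, the test itself agrees with vegan's permutation RDA
  on identical inputs, and every other summary (null calibration,
  coupling-induced correlations, sparsity, inflation under confounding)
  is reproduced; the residual gap is consistent with an unstated
  difference in the original study conditions (for reference, a base
  prevalence filter of <10 instead of <5 would yield ≈ 0.70/0.25).
* The exact settings of the published "additional filtering step" used to
  rescue power under confounding are not public; the harness exposes a
  generic prevalence/mean-abundance filter and asserts only the
  directional claim (stringent filtering reduces type-I inflation at
  `γ = 2`, `σ_a = 1`).
* GBM imputation follows the published Bayesian-multiplicative formulas
  but exact numerical equality with any particular reference
  implementation's defaults is not claimed.
* Free permutations only; no restricted/blocked permutation schemes, no
  partial (covariate-conditioned) RDA.
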