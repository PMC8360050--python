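"""Type-I-error and power study harness.

Each scenario pairs the simulation parameters with an analysis method; the
harness repeatedly simulates, filters, transforms, runs the permutation test
against the treatment, and reports the rejection rate at level alpha together
with its binomial Monte-Carlo standard error and the mean correlation between
the treatment and the row mean r of the log table.

Methods
-------
``lr_rda``           log(Y+1), double-centred, RDA.
``lr_rda_gbm_counts`` GBM zero imputation on counts, then log-ratio RDA.
``lr_rda_gbm_props``  GBM zero imputation on proportions, then log-ratio RDA.
``log_props_rda``    log((Y+1)/n), column-centred, RDA.
``cca_counts``       CCA on the raw counts.
``cca_sqrt``         CCA on square-rooted counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .ordination import permutation_test
from .simulate import (CountMatrix, SimParams, draw_effects, prevalence_filter,
                       simulate_counts)
from .transforms import (double_center, double_centered_log, gbm_impute,
                         log_proportions, log_with_pseudocount, sqrt_transform)

__all__ = [
    "METHODS",
    "ExtraFilter",
    "Scenario",
    "run_scenario",
    "run_grid",
    "correlation_xr_summary",
    "load_grid",
]

METHODS = ("lr_rda", "lr_rda_gbm_counts", "lr_rda_gbm_props",
           "log_props_rda", "cca_counts", "cca_sqrt")


@dataclass(frozen=True)
class ExtraFilter:
    """Optional additional filtering applied after the default prevalence
    filter: keep taxa present in at least ``min_prevalence`` samples and/or
    with mean count at least ``min_mean_abundance``."""

    min_prevalence: int | None = None
    min_mean_abundance: float | None = None

    def apply(self, Y: CountMatrix) -> CountMatrix:
        keep = np.ones(Y.n_taxa, dtype=bool)
        if self.min_prevalence is not None:
            keep &= Y.prevalence >= self.min_prevalence
        if self.min_mean_abundance is not None:
            keep &= Y.counts.mean(axis=0) >= self.min_mean_abundance
        if not keep.any():
            raise ValueError("extra filter removed every taxon")
        return CountMatrix(Y.counts[:, keep], Y.sample_ids, Y.taxon_ids[keep])


@dataclass(frozen=True)
class Scenario:
    params: SimParams = field(default_factory=SimParams)
    method: str = "lr_rda"
    n_sims: int = 500
    n_perm: int = 199
    alpha: float = 0.05
    extra_filter: ExtraFilter | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def label(self) -> str:
        return self.name or (
            f"{self.method}|sa={self.params.sigma_a}|fc={self.params.fold_change}"
            f"|g={self.params.gamma}"
        )


def _test_once(Y: CountMatrix, x: np.ndarray, method: str, n_perm: int,
               rng: np.random.Generator) -> float:
    if method == "lr_rda":
        S = double_centered_log(Y)
        return permutation_test(S.S, x, n_perm, rng).p_value
    if method == "lr_rda_gbm_counts":
        Z = gbm_impute(Y, on_proportions=False)
        S = double_center(np.log(Z))
        return permutation_test(S.S, x, n_perm, rng).p_value
    if method == "lr_rda_gbm_props":
        Z = gbm_impute(Y, on_proportions=True)
        S = double_center(np.log(Z))
        return permutation_test(S.S, x, n_perm, rng).p_value
    if method == "log_props_rda":
        M = log_proportions(Y)
        M = M - M.mean(axis=0)
        return permutation_test(M, x, n_perm, rng).p_value
    if method == "cca_counts":
        return permutation_test(Y.counts, x, n_perm, rng, method="cca").p_value
    if method == "cca_sqrt":
        return permutation_test(sqrt_transform(Y), x, n_perm, rng,
                                method="cca").p_value
    raise ValueError(f"unknown method {method!r}")


def run_scenario(s: Scenario, rng: np.random.Generator | None = None) -> dict:
    """Run one scenario and return its rejection-table row.

    Per simulation: draw effects, assign treatment, sample counts, filter,
    transform per the method, permutation-test against x at ``n_perm``
    permutations, and record whether p < alpha and the Pearson correlation
    of x with the row mean r of log(Y+1).  Method failures (e.g. a filter
    that empties the table) are counted, never silently dropped.
    """
    if rng is None:
        rng = np.random.default_rng(s.params.seed)
    p_values, corrs, n_failed = [], [], 0
    for _ in range(s.n_sims):
        draw = draw_effects(s.params, rng)
        Y = simulate_counts(draw, s.params, rng)
        try:
            if s.params.min_prevalence > 0:
                Y = prevalence_filter(Y, s.params.min_prevalence)
            if s.extra_filter is not None:
                Y = s.extra_filter.apply(Y)
            r = log_with_pseudocount(Y).mean(axis=1)
            corrs.append(float(np.corrcoef(draw.x, r)[0, 1]))
            p_values.append(_test_once(Y, draw.x, s.method, s.n_perm, rng))
        except ValueError:
            n_failed += 1
    n_ok = len(p_values)
    p_arr = np.asarray(p_values)
    rate = float((p_arr < s.alpha).mean()) if n_ok else np.nan
    se = float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else np.nan
    return {
        "scenario": s.label,
        "method": s.method,
        "sigma_a": s.params.sigma_a,
        "fold_change": s.params.fold_change,
        "gamma": s.params.gamma,
        "n_sims": s.n_sims,
        "n_ok": n_ok,
        "n_failed": n_failed,
        "n_perm": s.n_perm,
        "alpha": s.alpha,
        "rejection_rate": rate,
        "mc_se": se,
        "mean_corr_xr": float(np.mean(corrs)) if corrs else np.nan,
        "mean_abs_corr_xr": float(np.mean(np.abs(corrs))) if corrs else np.nan,
    }


def run_grid(
    scenarios: list[Scenario],
    master_seed: int | None = None,
) -> pd.DataFrame:
    """Map ``run_scenario`` over a grid with independent RNG substreams.

    A scenario whose params carry an explicit seed uses that seed (so a
    duplicated scenario reproduces exactly); otherwise substreams are spawned
    deterministically from ``master_seed``.
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(scenarios))
    rows = []
    for s, child in zip(scenarios, children):
        rng = (np.random.default_rng(s.params.seed)
               if s.params.seed is not None else np.random.default_rng(child))
        rows.append(run_scenario(s, rng))
    return pd.DataFrame(rows)


def correlation_xr_summary(
    sigma_a: float,
    gamma: float,
    n_sims: int,
    rng: np.random.Generator | None = None,
    params: SimParams | None = None,
) -> dict:
    """Mean Pearson correlation between treatment x and row mean r.

    Per simulation, r is the row mean of log(counts+1) of the
    prevalence-filtered table.  Both the signed and the absolute mean are
    reported.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if params is None:
        params = SimParams()
    params = params.with_(sigma_a=sigma_a, gamma=gamma)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    corrs = np.empty(n_sims)
    for k in range(n_sims):
        draw = draw_effects(params, rng)
        Y = simulate_counts(draw, params, rng)
        if params.min_prevalence > 0:
            Y = prevalence_filter(Y, params.min_prevalence)
        r = log_with_pseudocount(Y).mean(axis=1)
        corrs[k] = np.corrcoef(draw.x, r)[0, 1]
    return {
        "mean_corr_xr": float(corrs.mean()),
        "mean_abs_corr_xr": float(np.abs(corrs).mean()),
        "sd_corr_xr": float(corrs.std(ddof=1)) if n_sims > 1 else np.nan,
        "n_sims": n_sims,
    }


_PARAM_FIELDS = set(SimParams.__dataclass_fields__)


def load_grid(path) -> list[Scenario]:
    """Read a scenario grid from a YAML config.

    Layout: an optional ``defaults`` mapping plus a ``scenarios`` list;
    each entry may set any SimParams field, ``method``, ``n_sims``,
    ``n_perm``, ``alpha``, ``name`` and the extra-filter knobs
    ``extra_min_prevalence`` / ``extra_min_mean_abundance``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    defaults = cfg.get("defaults", {}) or {}
    scenarios = []
    for entry in cfg.get("scenarios", []):
        spec = {**defaults, **(entry or {})}
        pkw = {k: v for k, v in spec.items() if k in _PARAM_FIELDS}
        ef = None
        if "extra_min_prevalence" in spec or "extra_min_mean_abundance" in spec:
            ef = ExtraFilter(
                min_prevalence=spec.get("extra_min_prevalence"),
                min_mean_abundance=spec.get("extra_min_mean_abundance"),
            )
        scenarios.append(Scenario(
            params=SimParams(**pkw),
            method=spec.get("method", "lr_rda"),
            n_sims=int(spec.get("n_sims", 500)),
            n_perm=int(spec.get("n_perm", 199)),
            alpha=float(spec.get("alpha", 0.05)),
            extra_filter=ef,
            name=spec.get("name"),
        ))
    return scenarios
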