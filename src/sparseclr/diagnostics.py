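"""Diagnostics for library-size dependence of clr / double-centred log data.

Sparse count tables transformed with a pseudo-count clr carry an imprint of
the row mean ``r`` of the log table: a zero cell becomes ``s_ij = -r_i +
const_j`` after double centring, so rare taxa end up strongly negatively
correlated with ``r`` while abundant, zero-free taxa are unaffected (and in
extreme settings positively correlated, producing a V-shaped contribution
plot).  Two per-taxon diagnostics expose this:

* ``rho_Sr`` — Pearson correlation of each column of S with r, plotted
  against log mean abundance; an increasing trend that starts well below
  zero (around -0.5) for the rarest taxa flags the problem.
* the per-axis contribution (squared taxon loading) against log mean
  abundance; near-equal, elevated contributions among the rare taxa flag an
  axis that mostly carries ``r``.

A third check fits an RDA of S constrained by ``r`` and reports the variance
fraction attributable to ``r``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ordination import OrdinationResult, rda
from .simulate import CountMatrix
from .transforms import CenteredLogMatrix

__all__ = [
    "correlation_diagnostic",
    "contribution_diagnostic",
    "variance_explained_by_r",
    "flag_library_size_dependence",
]


def _log_mean_abundance(Y: CountMatrix) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(Y.counts.mean(axis=0))


def correlation_diagnostic(S: CenteredLogMatrix, Y: CountMatrix) -> pd.DataFrame:
    """Per-taxon Pearson correlation of the S columns with r.

    Returns a table with columns ``rho_Sr``, ``log_mean_abundance``,
    ``prevalence`` and a ``constant`` flag; a constant S column has no
    defined correlation and is reported as NaN with the flag set.
    """
    if S.S.shape != Y.counts.shape:
        raise ValueError("S and Y have different shapes")
    r = S.r
    rc = r - r.mean()
    r_norm = np.sqrt((rc ** 2).sum())
    if r_norm < 1e-12:
        raise ValueError("r is constant; the correlation diagnostic is undefined")
    Sc = S.S - S.S.mean(axis=0)
    col_norms = np.sqrt((Sc ** 2).sum(axis=0))
    constant = col_norms < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ Sc) / (r_norm * col_norms)
    rho[constant] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    return pd.DataFrame({
        "taxon_id": Y.taxon_ids,
        "rho_Sr": rho,
        "log_mean_abundance": _log_mean_abundance(Y),
        "prevalence": Y.prevalence,
        "constant": constant,
    })


def contribution_diagnostic(
    ord_res: OrdinationResult, Y: CountMatrix, axis: int = 1
) -> pd.DataFrame:
    """Squared taxon loading on a principal axis (1-based) vs log abundance.

    Loadings are unit-norm, so the contributions on an axis sum to one over
    taxa.
    """
    if not 1 <= axis <= ord_res.K:
        raise ValueError(f"axis must lie in [1, {ord_res.K}], got {axis}")
    contrib = ord_res.taxon_loadings[:, axis - 1] ** 2
    return pd.DataFrame({
        "taxon_id": Y.taxon_ids,
        "contribution": contrib,
        "log_mean_abundance": _log_mean_abundance(Y),
        "prevalence": Y.prevalence,
    })


def variance_explained_by_r(S: CenteredLogMatrix) -> float:
    """Fraction of the variance of S captured by an RDA constrained by r."""
    if np.ptp(S.r) < 1e-12:
        raise ValueError("r is constant")
    return rda(S.S, S.r).constrained_fraction


def flag_library_size_dependence(
    diag: pd.DataFrame, rho_threshold: float = -0.5
) -> tuple[bool, dict]:
    """Decide whether the rho_Sr pattern indicates library-size dependence.

    Flags when (i) rho_Sr increases with log mean abundance (one-sided
    Spearman rank correlation, p < 0.05) and (ii) the median rho_Sr of the
    lowest-abundance decile is below ``rho_threshold``.  The visual rule is
    "an increasing trend starting from a low value"; this operationalises it.
    The decile isolates the rarest taxa, which carry the -r signature most
    strongly; wider bands dilute the median with moderately abundant taxa.
    """
    d = diag.dropna(subset=["rho_Sr", "log_mean_abundance"])
    if len(d) < 10:
        raise ValueError("need at least 10 taxa with defined rho_Sr")
    res = stats.spearmanr(d["log_mean_abundance"], d["rho_Sr"],
                          alternative="greater")
    order = d.sort_values("log_mean_abundance")
    decile = order.iloc[: max(len(order) // 10, 5)]
    low_median = float(decile["rho_Sr"].median())
    increasing = bool(res.statistic > 0 and res.pvalue < 0.05)
    low_start = bool(low_median < rho_threshold)
    summary = {
        "spearman_rho": float(res.statistic),
        "spearman_p": float(res.pvalue),
        "increasing_trend": increasing,
        "low_decile_median_rho": low_median,
        "low_start": low_start,
        "n_taxa": int(len(d)),
    }
    return increasing and low_start, summary
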