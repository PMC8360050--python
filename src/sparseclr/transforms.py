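"""Matrix transforms: pseudo-count log, clr, double centring, and the
alternative transforms (Bayesian-multiplicative zero imputation, log
proportions, square root).

The central object is the double-centred log matrix

    s_ij = l_ij - r_i - c_j + l..

with ``L = log(Y + pseudo)``, row means ``r``, column means ``c`` and grand
mean ``l..``.  Its SVD is the log-ratio PCA.  For strictly positive data the
row centring makes the result independent of the per-sample total; for sparse
data with a pseudo-count it does not — a zero cell contributes
``s_ij = -r_i - c_j + l..``, which is how the row mean ``r`` (and with it the
library size) leaks back into the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CountMatrix

__all__ = [
    "CenteredLogMatrix",
    "log_with_pseudocount",
    "double_center",
    "double_centered_log",
    "clr",
    "gbm_impute",
    "log_proportions",
    "sqrt_transform",
]


def _counts_of(Y) -> np.ndarray:
    return Y.counts if isinstance(Y, CountMatrix) else np.asarray(Y, dtype=float)


@dataclass
class CenteredLogMatrix:
    """Double-centred log matrix together with the removed margins.

    ``S + r (+) c - grand_mean`` reconstructs the log matrix exactly, where
    ``(+)`` is the outer sum of the row means ``r`` and column means ``c``.
    """

    S: np.ndarray
    r: np.ndarray
    c: np.ndarray
    grand_mean: float
    pseudo_count: float = 1.0
    sample_ids: np.ndarray | None = None
    taxon_ids: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.S.shape

    def reconstruct(self) -> np.ndarray:
        """The log matrix L that was double-centred."""
        return self.S + self.r[:, None] + self.c[None, :] - self.grand_mean


def log_with_pseudocount(Y, pseudo: float = 1.0) -> np.ndarray:
    """Natural log of (counts + pseudo), elementwise."""
    if pseudo <= 0:
        raise ValueError(f"pseudo-count must be > 0, got {pseudo}")
    return np.log(_counts_of(Y) + pseudo)


def double_center(
    L: np.ndarray,
    pseudo_count: float = 1.0,
    sample_ids: np.ndarray | None = None,
    taxon_ids: np.ndarray | None = None,
) -> CenteredLogMatrix:
    """Subtract row means, column means, and add back the grand mean."""
    L = np.asarray(L, dtype=float)
    if L.size == 0:
        raise ValueError("cannot double-centre an empty matrix")
    r = L.mean(axis=1)
    c = L.mean(axis=0)
    gm = float(L.mean())
    S = L - r[:, None] - c[None, :] + gm
    return CenteredLogMatrix(S=S, r=r, c=c, grand_mean=gm,
                             pseudo_count=pseudo_count,
                             sample_ids=sample_ids, taxon_ids=taxon_ids)


def double_centered_log(Y: CountMatrix, pseudo: float = 1.0) -> CenteredLogMatrix:
    """``double_center(log(Y + pseudo))`` keeping the table's identifiers."""
    L = log_with_pseudocount(Y, pseudo)
    return double_center(L, pseudo_count=pseudo,
                         sample_ids=getattr(Y, "sample_ids", None),
                         taxon_ids=getattr(Y, "taxon_ids", None))


def clr(Y, pseudo: float = 1.0) -> np.ndarray:
    """Centred log-ratio: log counts (plus pseudo) minus their row means.

    Equals ``log(y_i / g(y_i))`` per sample for strictly positive rows, where
    ``g`` is the geometric mean.  ``pseudo=0`` is allowed only for zero-free
    tables.
    """
    counts = _counts_of(Y)
    if pseudo < 0:
        raise ValueError("pseudo-count must be >= 0")
    if pseudo == 0 and (counts <= 0).any():
        raise ValueError("pseudo=0 requires a strictly positive table")
    L = np.log(counts + pseudo)
    return L - L.mean(axis=1, keepdims=True)


def gbm_impute(
    Y,
    on_proportions: bool = False,
    prior_strength: float | None = None,
    max_frac_of_min: float = 0.65,
) -> np.ndarray:
    """Replace zeros by geometric Bayesian-multiplicative (GBM) estimates.

    Bayesian-multiplicative replacement treats each sample's proportions as
    multinomial with a Dirichlet prior of expectation ``t`` (a composition)
    and strength ``s``; a zero is replaced by its posterior expectation
    ``s * t_j / (n_i + s)`` and the observed parts are shrunk by the common
    factor ``1 - sum(replacements)`` so their ratios are untouched.  The GBM
    prior takes ``t`` from the data itself: ``t_j`` is proportional to the
    geometric mean of the non-zero proportions of taxon j across samples.

    Parameters
    ----------
    on_proportions
        If True, rows are closed to sum 1 and the output rows sum to 1;
        otherwise the imputed proportions are re-scaled to the count scale
        by the library size.
    prior_strength
        Dirichlet strength ``s``.  Default ``1 / g(t)`` (the geometric mean
        of the prior composition), which reduces to the Bayes-Laplace
        strength ``J`` for a uniform prior.
    max_frac_of_min
        Cap each replaced proportion at this fraction of the row's smallest
        observed proportion, so an imputed value never rivals an observed one.

    Returns a strictly positive matrix of the same shape.
    """
    counts = _counts_of(Y).astype(float)
    I, J = counts.shape
    n = counts.sum(axis=1)
    if (n == 0).any():
        raise ValueError("gbm_impute requires every row to have a nonzero count")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("gbm_impute requires every taxon to be observed at "
                         "least once (apply a prevalence filter first)")
    P = counts / n[:, None]
    logP = np.zeros_like(P)
    np.log(P, where=P > 0, out=logP)
    npos = (P > 0).sum(axis=0)
    t = np.exp(logP.sum(axis=0) / npos)
    t = t / t.sum()
    if prior_strength is None:
        s = float(1.0 / np.exp(np.mean(np.log(t))))
    else:
        s = float(prior_strength)
        if s <= 0:
            raise ValueError("prior_strength must be > 0")

    repl = (s * t)[None, :] / (n + s)[:, None]        # candidate replacements
    zero = counts == 0
    out = P.copy()
    for i in range(I):
        zi = zero[i]
        if not zi.any():
            continue
        cap = max_frac_of_min * P[i][~zi].min()
        ri = np.minimum(repl[i], cap)
        out[i, zi] = ri[zi]
        out[i, ~zi] = P[i, ~zi] * (1.0 - ri[zi].sum())
    if not on_proportions:
        out = out * n[:, None]
    return out


def log_proportions(Y, pseudo: float = 1.0) -> np.ndarray:
    """``log((y_ij + pseudo) / n_i)`` with ``n_i`` the library size."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be > 0")
    counts = _counts_of(Y)
    n = counts.sum(axis=1)
    if (n == 0).any():
        raise ValueError("log_proportions requires positive library sizes")
    return np.log((counts + pseudo) / n[:, None])


def sqrt_transform(Y) -> np.ndarray:
    """Elementwise square root of the counts."""
    return np.sqrt(_counts_of(Y))
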