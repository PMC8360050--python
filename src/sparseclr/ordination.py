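"""Ordination: log-ratio PCA (SVD of the double-centred log matrix),
redundancy analysis (RDA), canonical correspondence analysis (CCA), and the
Monte-Carlo permutation test on the constrained-inertia fraction.

RDA constrains a (centred) response matrix to the span of explanatory
variables by least squares; the test statistic is the fraction of total
variance captured by the fitted matrix, ``||HM||_F^2 / ||M||_F^2``, and its
null distribution is obtained by freely permuting the rows of the
explanatory data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transforms import CenteredLogMatrix

__all__ = [
    "OrdinationResult",
    "RdaResult",
    "RdaTestResult",
    "lr_pca",
    "rda",
    "cca",
    "permutation_test",
]


@dataclass
class OrdinationResult:
    """Truncated SVD of a (centred) matrix.

    ``explained_fraction`` is per-axis ``sigma_k^2 / total_inertia`` where
    ``total_inertia`` is the full squared Frobenius norm, so the fractions of
    a truncated solution sum to less than one.
    """

    sample_scores: np.ndarray     # (I, K), orthonormal columns
    taxon_loadings: np.ndarray    # (J, K), orthonormal columns
    singular_values: np.ndarray   # (K,), non-increasing
    explained_fraction: np.ndarray
    total_inertia: float
    K: int


@dataclass
class RdaResult:
    constrained_fraction: float
    ordination: OrdinationResult   # SVD of the fitted (constrained) matrix


@dataclass
class RdaTestResult:
    """Permutation test of the constrained-inertia fraction.

    ``p_value = (1 + #{perm_stats >= observed}) / (n_perm + 1)``.
    """

    constrained_fraction: float
    n_perm: int
    perm_stats: np.ndarray
    p_value: float


def _as_matrix(M) -> np.ndarray:
    if isinstance(M, CenteredLogMatrix):
        return M.S
    return np.asarray(M, dtype=float)


def _svd_result(M: np.ndarray, K: int | None, total_inertia: float | None = None
                ) -> OrdinationResult:
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    total = float((s ** 2).sum()) if total_inertia is None else total_inertia
    if K is None:
        K = len(s)
    U, s, Vt = U[:, :K], s[:K], Vt[:K]
    frac = s ** 2 / total if total > 0 else np.zeros_like(s)
    return OrdinationResult(sample_scores=U, taxon_loadings=Vt.T,
                            singular_values=s, explained_fraction=frac,
                            total_inertia=total, K=K)


def lr_pca(S, K: int | None = None) -> OrdinationResult:
    """Log-ratio PCA: SVD of the double-centred log matrix, no rescaling.

    ``K`` defaults to the maximal informative rank ``min(I-1, J-1)`` of a
    double-centred matrix.
    """
    M = _as_matrix(S)
    I, J = M.shape
    kmax = max(min(I - 1, J - 1), 1)
    if K is None:
        K = kmax
    if K > kmax:
        raise ValueError(f"K={K} exceeds the informative rank {kmax}")
    return _svd_result(M, K)


def _design_matrix(x, n_rows: int) -> np.ndarray:
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n_rows:
        raise ValueError("explanatory data and matrix have different row counts")
    Xc = X - X.mean(axis=0)
    if not np.any(np.abs(Xc) > 1e-12):
        raise ValueError("explanatory variable is constant")
    return Xc


def _fitted(M: np.ndarray, Xc: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Xc, M, rcond=None)
    return Xc @ coef


def rda(M, x, K: int | None = None) -> RdaResult:
    """Redundancy analysis of a centred matrix on explanatory variables.

    ``M`` must already be column-centred (and row-centred when it is the
    double-centred log matrix); ``x`` is a vector or design matrix, centred
    internally.  Returns the constrained-inertia fraction and the SVD of the
    fitted matrix.
    """
    M = _as_matrix(M)
    total = float((M ** 2).sum())
    if total == 0:
        raise ValueError("response matrix has zero variance")
    Xc = _design_matrix(x, M.shape[0])
    fitted = _fitted(M, Xc)
    frac = float((fitted ** 2).sum() / total)
    ord_res = _svd_result(fitted, K, total_inertia=total)
    return RdaResult(constrained_fraction=min(frac, 1.0), ordination=ord_res)


def cca(Y, x, K: int | None = None) -> RdaResult:
    """Canonical correspondence analysis of a non-negative table on ``x``.

    Works on the chi-square standardised residuals
    ``q_ij = (p_ij - w_i w_j) / sqrt(w_i w_j)`` of the closed table and
    projects them onto the explanatory variables with row weights ``w_i``
    (weighted least squares).  The statistic is constrained inertia over
    total inertia.
    """
    P = np.asarray(Y.counts if hasattr(Y, "counts") else Y, dtype=float)
    if (P < 0).any():
        raise ValueError("cca requires a non-negative table")
    grand = P.sum()
    if grand == 0:
        raise ValueError("cca requires a non-empty table")
    P = P / grand
    wr = P.sum(axis=1)
    wc = P.sum(axis=0)
    if (wr == 0).any() or (wc == 0).any():
        raise ValueError("cca requires positive row and column sums")
    E = np.outer(wr, wc)
    Q = (P - E) / np.sqrt(E)
    total = float((Q ** 2).sum())
    if total == 0:
        raise ValueError("table carries no inertia")
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != P.shape[0]:
        raise ValueError("explanatory data and table have different row counts")
    Xc = X - wr @ X                      # weighted column centring
    Z = np.sqrt(wr)[:, None] * Xc
    if not np.any(np.abs(Z) > 1e-12):
        raise ValueError("explanatory variable is constant")
    fitted = _fitted(Q, Z)
    frac = float((fitted ** 2).sum() / total)
    ord_res = _svd_result(fitted, K, total_inertia=total)
    return RdaResult(constrained_fraction=min(frac, 1.0), ordination=ord_res)


def _rda_stat_vectorised(M: np.ndarray, X_rows: np.ndarray) -> np.ndarray:
    """Constrained fraction for many single-vector designs at once.

    ``X_rows`` holds one candidate explanatory vector per row.  For a single
    centred vector xc the fitted matrix is ``xc (xc'M)/||xc||^2`` so the
    statistic reduces to ``||xc'M||^2 / (||xc||^2 ||M||^2)``.
    """
    Xc = X_rows - X_rows.mean(axis=1, keepdims=True)
    norms = (Xc ** 2).sum(axis=1)
    G = Xc @ M
    total = (M ** 2).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        stats = (G ** 2).sum(axis=1) / (norms * total)
    return np.where(norms > 1e-24, stats, 0.0)


def permutation_test(
    M,
    x,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    method: str = "rda",
) -> RdaTestResult:
    """Monte-Carlo permutation test of the constrained-inertia fraction.

    Rows of ``x`` are permuted uniformly at random (free permutation); the
    p-value uses the add-one convention with ties counted as exceedances.
    ``method`` selects the constrained ordination: ``"rda"`` (M must be
    centred) or ``"cca"`` (M must be a non-negative table).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    if method == "rda" and x.ndim == 1:
        Mm = _as_matrix(M)
        _design_matrix(x, Mm.shape[0])   # validation (constant x, shape)
        perms = np.stack([rng.permutation(x.size) for _ in range(n_perm)])
        all_rows = np.vstack([x[None, :], x[perms]])
        stats = _rda_stat_vectorised(Mm, all_rows)
        obs, perm_stats = float(stats[0]), stats[1:]
    else:
        fit = rda if method == "rda" else cca
        if method not in ("rda", "cca"):
            raise ValueError(f"unknown method {method!r}")
        obs = fit(M, x).constrained_fraction
        perm_stats = np.empty(n_perm)
        for k in range(n_perm):
            perm_stats[k] = fit(M, x[rng.permutation(x.shape[0])]).constrained_fraction
    n_ge = int((perm_stats >= obs - 1e-12).sum())
    p = (1 + n_ge) / (n_perm + 1)
    return RdaTestResult(constrained_fraction=obs, n_perm=n_perm,
                         perm_stats=np.asarray(perm_stats), p_value=p)
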