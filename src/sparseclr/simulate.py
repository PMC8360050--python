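"""Negative-binomial simulator for sparse amplicon-like count tables.

The generative model draws an ``I x J`` count matrix with

    log(mu_ij) = a_i + t_j + b_j * x_i,      y_ij ~ NB(mu_ij, size k)

where ``a_i ~ N(0, sigma_a^2)`` controls between-sample library-size
variability, ``t_j ~ N(0, sigma_t^2)`` the overall abundance of taxon j,
``x_i`` is a binary treatment indicator for two groups of equal size, and
``b_j`` is ``+log(fold_change)`` or ``-log(fold_change)`` for a random subset
of differentially abundant taxa (zero elsewhere).  With the default size
parameter ``k = 1`` the NB variance is ``mu + mu^2``, i.e. strongly
overdispersed, which is what makes roughly half of all cells zero under the
default effect scales.

Treatment can be coupled to library size: ``x_i ~ Bernoulli(g * sigmoid(gamma
* a_i))`` with ``g`` tuned per draw so the expected group sizes are equal, and
the draw rejected until the realised groups are exactly balanced.  ``gamma =
0`` recovers independent balanced assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "SimParams",
    "SimDraw",
    "CountMatrix",
    "draw_effects",
    "assign_treatment",
    "simulate_counts",
    "prevalence_filter",
    "zero_fraction",
    "simulate_dataset",
]

# beyond this exp(eta) overflows the int64 range NB sampling needs
_MAX_LOG_MEAN = 40.0


@dataclass(frozen=True)
class SimParams:
    """Parameters of the count-simulation model.

    Attributes
    ----------
    I : number of samples (must be even so the two groups can be balanced).
    J : number of taxa.
    sigma_a : SD of the per-sample effect ``a_i`` (library-size variability).
    sigma_t : SD of the per-taxon effect ``t_j``.
    fold_change : multiplicative treatment effect; ``b = log(fold_change)``.
    n_da : number of differentially abundant taxa (split ~50/50 into up/down).
    gamma : strength of the treatment-library-size coupling (>= 0).
    dispersion_size : NB size parameter ``k``; variance is ``mu + mu^2/k``.
    min_prevalence : taxa present in fewer samples are removed after sampling.
    seed : optional RNG seed used by convenience wrappers.
    """

    I: int = 50
    J: int = 500
    sigma_a: float = 1.0
    sigma_t: float = 2.0
    fold_change: float = 1.0
    n_da: int = 100
    gamma: float = 0.0
    dispersion_size: float = 1.0
    min_prevalence: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.I <= 0 or self.I % 2 != 0:
            raise ValueError(f"I must be a positive even integer, got {self.I}")
        if self.J <= 0:
            raise ValueError(f"J must be positive, got {self.J}")
        if not 0 <= self.n_da <= self.J:
            raise ValueError(f"n_da must lie in [0, J={self.J}], got {self.n_da}")
        for name in ("sigma_a", "sigma_t", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fold_change < 1:
            raise ValueError(f"fold_change must be >= 1, got {self.fold_change}")
        if self.dispersion_size <= 0:
            raise ValueError("dispersion_size must be > 0")
        if self.min_prevalence < 0:
            raise ValueError("min_prevalence must be >= 0")

    @property
    def b(self) -> float:
        return float(np.log(self.fold_change))

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SimDraw:
    """One realisation of the latent effects of the simulation model."""

    a: np.ndarray          # (I,) sample effects
    t: np.ndarray          # (J,) taxon effects
    b_vec: np.ndarray      # (J,) signed treatment effects, 0 for non-DA taxa
    x: np.ndarray          # (I,) binary treatment indicator, sum = I/2
    g: float               # balancing scalar of the assignment mechanism
    da_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))


@dataclass
class CountMatrix:
    """Non-negative integer sample x taxon table with identifiers.

    ``library_sizes`` is always the exact row sum of ``counts``.
    """

    counts: np.ndarray
    sample_ids: np.ndarray
    taxon_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integer-valued")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.taxon_ids = np.asarray(self.taxon_ids, dtype=object)
        if len(self.sample_ids) != self.counts.shape[0]:
            raise ValueError("sample_ids length does not match counts")
        if len(self.taxon_ids) != self.counts.shape[1]:
            raise ValueError("taxon_ids length does not match counts")
        for ids, what in ((self.sample_ids, "sample"), (self.taxon_ids, "taxon")):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {what} ids")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def prevalence(self) -> np.ndarray:
        """Number of samples in which each taxon is present (count > 0)."""
        return (self.counts > 0).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.taxon_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), df.index.to_numpy(), df.columns.to_numpy())


def draw_effects(params: SimParams, rng: np.random.Generator) -> SimDraw:
    """Draw one realisation of (a, t, b_vec, x, g) from the model priors.

    ``n_da`` taxa are chosen uniformly without replacement; each gets
    ``+log(fold_change)`` or ``-log(fold_change)`` with probability 1/2.
    """
    a = rng.normal(0.0, params.sigma_a, size=params.I)
    t = rng.normal(0.0, params.sigma_t, size=params.J)
    b_vec = np.zeros(params.J)
    da = rng.choice(params.J, size=params.n_da, replace=False)
    signs = rng.choice([1.0, -1.0], size=params.n_da)
    b_vec[da] = signs * params.b
    x, g = assign_treatment(a, params.gamma, rng)
    return SimDraw(a=a, t=t, b_vec=b_vec, x=x, g=g, da_indices=np.sort(da))


def _balance_equation(g: float, sig: np.ndarray) -> float:
    return float(np.minimum(1.0, g * sig).sum())


def assign_treatment(
    a: np.ndarray,
    gamma: float,
    rng: np.random.Generator,
    max_redraws: int = 100_000,
) -> tuple[np.ndarray, float]:
    """Assign samples to two balanced groups, optionally coupled to ``a``.

    Each sample gets probability ``p_i = min(1, g * sigmoid(gamma * a_i))`` of
    treatment, with ``g`` solving ``sum_i p_i = I/2`` by bisection so the
    groups are balanced in expectation.  The Bernoulli vector is redrawn until
    it is exactly balanced (``sum(x) = I/2``).

    Returns ``(x, g)``.
    """
    a = np.asarray(a, dtype=float)
    I = a.size
    if I == 0 or I % 2 != 0:
        raise ValueError("length of a must be positive and even")
    half = I // 2
    if gamma == 0:
        g = 1.0
        p = np.full(I, 0.5)
    else:
        sig = expit(gamma * a)
        hi = 1.0
        while _balance_equation(hi, sig) < half:
            hi *= 2.0
            if hi > 1e12:  # pragma: no cover - sigmoid is never exactly 0
                raise RuntimeError("failed to bracket the balancing scalar g")
        g = float(brentq(lambda v: _balance_equation(v, sig) - half, 0.0, hi,
                         xtol=1e-12))
        p = np.minimum(1.0, g * sig)
    best = -1
    for _ in range(max_redraws):
        x = (rng.random(I) < p).astype(np.int8)
        s = int(x.sum())
        if s == half:
            return x, g
        best = s if best < 0 or abs(s - half) < abs(best - half) else best
    raise RuntimeError(
        f"could not draw a balanced treatment vector in {max_redraws} attempts; "
        f"closest achieved group size {best} (target {half})"
    )


def simulate_counts(
    draw: SimDraw, params: SimParams, rng: np.random.Generator
) -> CountMatrix:
    """Sample the NB count matrix for one realisation of the latent effects.

    Cell means are ``mu_ij = exp(a_i + t_j + b_j x_i)`` and each count is an
    independent NB draw with size ``dispersion_size`` (variance
    ``mu + mu^2/size``).
    """
    eta = draw.a[:, None] + draw.t[None, :] + draw.b_vec[None, :] * draw.x[:, None]
    if eta.max() > _MAX_LOG_MEAN:
        i, j = np.unravel_index(int(np.argmax(eta)), eta.shape)
        raise ValueError(
            f"log-mean {eta[i, j]:.1f} at cell ({i}, {j}) exceeds the safe "
            f"range (|log mu| <= {_MAX_LOG_MEAN}); reduce effect scales"
        )
    mu = np.exp(eta)
    k = params.dispersion_size
    counts = rng.negative_binomial(k, k / (k + mu))
    sample_ids = np.array([f"s{i:03d}" for i in range(params.I)], dtype=object)
    taxon_ids = np.array([f"taxon{j:04d}" for j in range(params.J)], dtype=object)
    return CountMatrix(counts, sample_ids, taxon_ids)


def prevalence_filter(Y: CountMatrix, min_prevalence: int) -> CountMatrix:
    """Remove taxa present (count > 0) in fewer than ``min_prevalence`` samples."""
    if min_prevalence < 0:
        raise ValueError("min_prevalence must be >= 0")
    keep = Y.prevalence >= min_prevalence
    if not keep.any():
        raise ValueError("prevalence filter removed every taxon")
    return CountMatrix(Y.counts[:, keep], Y.sample_ids, Y.taxon_ids[keep])


def zero_fraction(Y: CountMatrix) -> float:
    """Fraction of zero cells in the table."""
    if Y.counts.size == 0:
        raise ValueError("empty count table")
    return float((Y.counts == 0).mean())


def simulate_dataset(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, SimDraw]:
    """Draw effects, sample counts, and apply the prevalence filter.

    Convenience wrapper used by the experiment harness and the CLI; returns
    the filtered count table together with the latent draw.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    draw = draw_effects(params, rng)
    Y = simulate_counts(draw, params, rng)
    if params.min_prevalence > 0:
        Y = prevalence_filter(Y, params.min_prevalence)
    return Y, draw
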