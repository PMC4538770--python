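"""DCOL: distance based on conditional ordered list.

Given a sample ordering (a conditioning order), the DCOL of a gene is the
mean absolute difference between consecutive values of the gene taken along
that order.  If the gene depends on whatever produced the order, consecutive
values are close and the DCOL is small; under independence the order is just
a random shuffle of the gene, which gives the permutation null used for the
significance test.

The null distribution of the DCOL does not depend on the conditioning
variable, only on the gene's own values, so one batch of B column
permutations of the whole matrix yields null parameters (mu_i, sigma_i)
for every gene at once.  Observed DCOL values are converted to left-tail
p-values under a Normal(mu_i, sigma_i) approximation of that null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix

__all__ = [
    "GeneNullParams",
    "dcol",
    "dcol_matrix",
    "estimate_null_params",
    "dcol_pvalue",
]


@dataclass(frozen=True)
class GeneNullParams:
    """Per-gene permutation-null mean and sd of the DCOL.

    ``mu[i]`` and ``sigma[i]`` are the sample mean and sample sd of gene i's
    DCOL over ``n_permutations`` random column orders.
    """

    mu: np.ndarray
    sigma: np.ndarray
    n_permutations: int

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.shape != sigma.shape:
            raise ValueError("mu and sigma must have the same length")
        if (sigma < 0).any():
            raise ValueError("sigma must be nonnegative")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)


def _check_order(order: Sequence[int], n: int) -> np.ndarray:
    order = np.asarray(order, dtype=int)
    if order.shape != (n,) or not np.array_equal(np.sort(order), np.arange(n)):
        raise ValueError(f"order must be a permutation of 0..{n - 1}")
    return order


def dcol(y: Sequence[float], order: Sequence[int]) -> float:
    """Mean absolute difference of ``y`` between consecutive positions of ``order``.

    Returns ``(1/(n-1)) * sum_i |y[order[i]] - y[order[i-1]]|``; invariant
    under reversal of the order.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    order = _check_order(order, n)
    return float(np.abs(np.diff(y[order])).mean())


def dcol_matrix(values: np.ndarray, order: Sequence[int]) -> np.ndarray:
    """DCOL of every row of ``values`` against one sample order (vectorized)."""
    values = np.asarray(values, dtype=float)
    order = _check_order(order, values.shape[1])
    return np.abs(np.diff(values[:, order], axis=1)).mean(axis=1)


def estimate_null_params(
    matrix: ExpressionMatrix, B: int = 500, seed: int | np.random.SeedSequence = 0
) -> GeneNullParams:
    """Estimate each gene's null DCOL mean and sd from B column permutations.

    One shared stream of B uniformly random column permutations is applied
    to all genes jointly; for gene i, ``mu[i]`` / ``sigma[i]`` are the sample
    mean / sample sd (ddof=1) of its B permuted DCOL values.  Deterministic
    given ``seed``.
    """
    if B < 2:
        raise ValueError("B must be >= 2 (sample sd undefined otherwise)")
    rng = np.random.default_rng(seed)
    values = matrix.values
    p, n = values.shape
    total = np.zeros(p)
    total_sq = np.zeros(p)
    for _ in range(B):
        perm = rng.permutation(n)
        d = np.abs(np.diff(values[:, perm], axis=1)).mean(axis=1)
        total += d
        total_sq += d * d
    mu = total / B
    # sample variance, clipped: roundoff can drive it slightly negative for
    # constant rows
    var = np.maximum((total_sq - B * mu**2) / (B - 1), 0.0)
    return GeneNullParams(mu=mu, sigma=np.sqrt(var), n_permutations=B)


def dcol_pvalue(
    d: float | np.ndarray, mu: float | np.ndarray, sigma: float | np.ndarray
) -> float | np.ndarray:
    """Left-tail p-value of an observed DCOL under Normal(mu, sigma).

    Small DCOL is evidence of dependence, hence the left tail.  Genes with
    sigma = 0 (constant rows: every permutation gives the same DCOL) get
    p = 1 so they can never reach significance.
    """
    d = np.asarray(d, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if (sigma < 0).any():
        raise ValueError("sigma must be nonnegative")
    safe = np.where(sigma > 0, sigma, 1.0)
    p = stats.norm.cdf(d, loc=mu, scale=safe)
    p = np.where(sigma > 0, p, 1.0)
    if p.ndim == 0:
        return float(p)
    return p
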