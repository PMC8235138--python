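"""Data-driven restricted model classes from confidence regions.

Two region geometries are supported:

* :class:`EllipsoidRegion` -- the exact ``100(1-alpha)%`` confidence
  ellipsoid for a multivariate normal mean with known covariance,
  ``{mu : (xbar - mu)' Sigma^{-1} (xbar - mu) <= chi2_d(1-alpha)/n}``,
  plus the whitening map that reduces it to a ball around the origin.

* :class:`BoxSimplexRegion` -- the Sison-Glaz simultaneous rectangular
  region for multinomial proportions, intersected with the probability
  simplex.  The intersection is a polytope whose vertices (each with at
  most one coordinate strictly between its bounds) carry the minimax
  solution, so :func:`enumerate_vertices` turns it into a finite class.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, List, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .divergence import DiscreteDistribution, GaussianModel

__all__ = [
    "EllipsoidRegion",
    "BoxSimplexRegion",
    "FiniteModelClass",
    "WhiteningTransform",
    "gaussian_mean_region",
    "whiten",
    "sison_glaz_intervals",
    "enumerate_vertices",
]


@dataclass(frozen=True)
class EllipsoidRegion:
    """Confidence ellipsoid ``(center - mu)' shape^{-1} (center - mu) <= radius_sq``."""

    center: np.ndarray
    shape: np.ndarray
    radius_sq: float
    alpha: float
    n: int

    def __post_init__(self) -> None:
        c = np.atleast_1d(np.asarray(self.center, dtype=float))
        S = np.atleast_2d(np.asarray(self.shape, dtype=float))
        if self.radius_sq <= 0:
            raise ValueError("radius_sq must be positive")
        if not np.allclose(S, S.T, atol=1e-10) or np.any(np.linalg.eigvalsh(S) <= 0):
            raise ValueError("shape matrix must be SPD")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "shape", S)

    @property
    def dim(self) -> int:
        return self.center.size

    def contains(self, mu: np.ndarray, tol: float = 1e-9) -> bool:
        d = np.atleast_1d(np.asarray(mu, dtype=float)) - self.center
        q = float(d @ np.linalg.solve(self.shape, d))
        return q <= self.radius_sq + tol


@dataclass(frozen=True)
class BoxSimplexRegion:
    """Per-category bounds ``l <= p <= u`` intersected with the simplex."""

    lower: np.ndarray
    upper: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        l = np.asarray(self.lower, dtype=float).ravel()
        u = np.asarray(self.upper, dtype=float).ravel()
        if l.size != u.size:
            raise ValueError("bound vectors must have equal length")
        if np.any(l < -1e-12) or np.any(u > 1 + 1e-12) or np.any(l > u + 1e-12):
            raise ValueError("bounds must satisfy 0 <= l <= u <= 1")
        if l.sum() > 1 + 1e-9 or u.sum() < 1 - 1e-9:
            raise ValueError("box does not intersect the simplex")
        object.__setattr__(self, "lower", np.clip(l, 0.0, 1.0))
        object.__setattr__(self, "upper", np.clip(u, 0.0, 1.0))

    @property
    def m(self) -> int:
        return self.lower.size

    def contains(self, p: np.ndarray, tol: float = 1e-9) -> bool:
        p = np.asarray(p, dtype=float).ravel()
        return (
            abs(p.sum() - 1.0) <= tol
            and np.all(p >= self.lower - tol)
            and np.all(p <= self.upper + tol)
        )


@dataclass
class FiniteModelClass:
    """Indexed finite set of candidate models sharing one alphabet/dimension."""

    models: List[Union[DiscreteDistribution, GaussianModel]]
    labels: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model class must be nonempty")
        if not self.labels:
            self.labels = [str(i) for i in range(len(self.models))]
        first = self.models[0]
        if isinstance(first, DiscreteDistribution):
            m = first.alphabet_size
            if any(mod.alphabet_size != m for mod in self.models):
                raise ValueError("all models must share one alphabet size")
        else:
            d = first.dim
            if any(mod.dim != d for mod in self.models):
                raise ValueError("all models must share one dimension")

    def __len__(self) -> int:
        return len(self.models)

    def as_matrix(self) -> np.ndarray:
        """(K, m) matrix of probability vectors; discrete classes only."""
        if not isinstance(self.models[0], DiscreteDistribution):
            raise TypeError("as_matrix requires a discrete model class")
        return np.stack([m.probs for m in self.models], axis=0)


def gaussian_mean_region(
    xbar: np.ndarray, Sigma: np.ndarray, n: int, alpha: float
) -> EllipsoidRegion:
    """Exact confidence ellipsoid for a normal mean with known covariance.

    The squared radius is ``chi2_d(1 - alpha) / n``, so the region shrinks
    at the usual ``1/sqrt(n)`` rate in every principal direction.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    xbar = np.atleast_1d(np.asarray(xbar, dtype=float))
    d = xbar.size
    radius_sq = float(stats.chi2.ppf(1.0 - alpha, df=d)) / n
    return EllipsoidRegion(xbar, Sigma, radius_sq, alpha, n)


@dataclass(frozen=True)
class WhiteningTransform:
    """Affine map ``T(mu) = Sigma^{-1/2} (mu - center)`` and its inverse.

    Equal-covariance Gaussian KL divergences are invariant under ``T``, so
    capacity problems over the ellipsoid can be solved in the whitened
    (identity-covariance, origin-centered) frame.
    """

    center: np.ndarray
    sqrt: np.ndarray       # Sigma^{1/2} (symmetric)
    inv_sqrt: np.ndarray   # Sigma^{-1/2} (symmetric)

    def forward(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return (mu - self.center) @ self.inv_sqrt

    def inverse(self, mu_prime: np.ndarray) -> np.ndarray:
        mu_prime = np.asarray(mu_prime, dtype=float)
        return mu_prime @ self.sqrt + self.center


def _sym_sqrt(S: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    w, V = np.linalg.eigh(S)
    root = (V * np.sqrt(w)) @ V.T
    inv_root = (V / np.sqrt(w)) @ V.T
    return root, inv_root


def whiten(region: EllipsoidRegion) -> Tuple[WhiteningTransform, EllipsoidRegion]:
    """Map the ellipsoid to the ball ``{mu' : mu''mu' <= radius_sq}``."""
    root, inv_root = _sym_sqrt(region.shape)
    transform = WhiteningTransform(region.center, root, inv_root)
    image = EllipsoidRegion(
        np.zeros(region.dim),
        np.eye(region.dim),
        region.radius_sq,
        region.alpha,
        region.n,
    )
    return transform, image


# ---------------------------------------------------------------------------
# Sison-Glaz simultaneous intervals
# ---------------------------------------------------------------------------

def _poisson_interval(lo: np.ndarray, hi: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """P(lo <= Z <= hi) elementwise for Z ~ Poisson(lam)."""
    return stats.poisson.cdf(hi, lam) - stats.poisson.cdf(lo - 1, lam)


def _sg_coverage(counts: np.ndarray, n: int, c: int) -> float:
    """Approximate P(all counts within +-c) for the multinomial.

    Uses the truncated-Poisson representation: independent Poisson(n_i)
    variables truncated to [n_i - c, min(n_i + c, n)], conditioned on
    summing to ``n`` via an Edgeworth expansion (third and fourth
    cumulants) of the sum's distribution.  Vectorized over cells via the
    factorial moments of the truncated Poisson law.
    """
    lam = counts.astype(float)
    b = np.maximum(counts - c, 0)
    a = np.minimum(counts + c, n)
    mass = _poisson_interval(b, a, lam)
    if np.any(mass <= 0):
        return 0.0
    # r-th factorial moments of the truncated Poisson variables
    fm = []
    for r in range(1, 5):
        adj = (_poisson_interval(a - r + 1, a, lam)
               - _poisson_interval(b - r, b - 1, lam)) / mass
        fm.append(lam**r * (1.0 - adj))
    m1, m2f, m3f, m4f = fm
    mu = m1
    s2 = m2f + mu - mu**2
    m3 = m3f + m2f * (3 - 3 * mu) + mu - 3 * mu**2 + 2 * mu**3
    m4 = (m4f + m3f * (6 - 4 * mu) + m2f * (7 - 12 * mu + 6 * mu**2)
          + mu - 4 * mu**2 + 6 * mu**3 - 3 * mu**4)
    s2_sum = float(np.sum(s2))
    mass_prod = float(np.prod(mass))
    if s2_sum <= 0:
        return mass_prod
    sd = math.sqrt(s2_sum)
    x = (n - float(np.sum(mu))) / sd
    g1 = float(np.sum(m3)) / sd**3
    g2 = float(np.sum(m4 - 3.0 * s2**2)) / sd**4
    he3 = x**3 - 3 * x
    he4 = x**4 - 6 * x**2 + 3
    he6 = x**6 - 15 * x**4 + 45 * x**2 - 15
    poly = 1.0 + g1 / 6.0 * he3 + g2 / 24.0 * he4 + g1**2 / 72.0 * he6
    f_edge = float(stats.norm.pdf(x)) * poly / sd
    denom = float(stats.poisson.pmf(n, n))
    if denom <= 0:
        return 0.0
    return mass_prod * f_edge / denom


def sison_glaz_intervals(
    counts: Sequence[int], alpha: float
) -> BoxSimplexRegion:
    """Simultaneous Sison-Glaz confidence intervals for multinomial cells.

    Searches for the smallest integer half-width ``c`` whose approximate
    simultaneous coverage reaches ``1 - alpha``, then interpolates the
    fractional part ``2*delta/n`` onto the upper bounds, following the
    truncated-Poisson/Edgeworth construction.
    """
    counts = np.asarray(counts, dtype=int).ravel()
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    n = int(counts.sum())
    if n == 0:
        raise ValueError("region undefined for n = 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    target = 1.0 - alpha
    # find the first crossing nu(c*-1) < 1-alpha <= nu(c*); the base
    # half-width is c*-1 and the fractional remainder 2*delta/n goes on
    # the upper bounds.  The approximate nu need not be monotone for very
    # skewed counts, so the search walks c upward to the first crossing.
    cov_prev = _sg_coverage(counts, n, 0)
    c_star = None
    for c in range(1, n + 1):
        cov = _sg_coverage(counts, n, c)
        if cov_prev < target <= cov:
            c_star = c
            break
        cov_prev = cov
    if c_star is None:  # saturate: whole simplex
        c_star, cov = n, 1.0
    if cov > cov_prev:
        delta = (target - cov_prev) / (cov - cov_prev)
    else:
        delta = 0.0
    delta = min(max(delta, 0.0), 1.0)
    c_use = c_star - 1
    phat = counts / n
    lower = np.clip(phat - c_use / n, 0.0, 1.0)
    upper = np.clip(phat + c_use / n + 2.0 * delta / n, 0.0, 1.0)
    lower, upper = _relax_to_feasible(lower, upper)
    return BoxSimplexRegion(lower, upper, alpha)


def _relax_to_feasible(lower: np.ndarray, upper: np.ndarray):
    """Minimal widening so the box meets the simplex (tiny-n pathologies)."""
    lower = lower.copy()
    upper = upper.copy()
    for _ in range(100):
        deficit = 1.0 - upper.sum()
        if deficit <= 1e-12:
            break
        room = 1.0 - upper
        grow = np.where(room > 0, room, 0.0)
        if grow.sum() <= 0:
            break
        upper = np.clip(upper + deficit * grow / grow.sum(), 0.0, 1.0)
    for _ in range(100):
        excess = lower.sum() - 1.0
        if excess <= 1e-12:
            break
        shrink = np.where(lower > 0, lower, 0.0)
        if shrink.sum() <= 0:
            break
        lower = np.clip(lower - excess * shrink / shrink.sum(), 0.0, 1.0)
    return lower, upper


def enumerate_vertices(
    region: BoxSimplexRegion, tol: float = 1e-10
) -> FiniteModelClass:
    """All vertices of ``{p : l <= p <= u, sum p = 1}``.

    A vertex of the box-simplex intersection has at most one coordinate
    strictly between its bounds, so enumeration assigns each coordinate to
    its lower or upper bound and, when the bound assignment misses the
    simplex, solves for a single free coordinate and checks feasibility.
    Exhaustive over ``2^m`` assignments; intended for small ``m``.
    """
    m = region.m
    if m > 16:
        raise ValueError("vertex enumeration supported only for m <= 16")
    l, u = region.lower, region.upper
    seen = {}
    for bits in itertools.product((0, 1), repeat=m):
        v = np.where(np.asarray(bits, dtype=bool), u, l)
        s = v.sum()
        if abs(s - 1.0) <= tol:
            key = tuple(np.round(v / s, 10))
            seen.setdefault(key, v / s)
            continue
        for j in range(m):
            free = 1.0 - (s - v[j])
            if l[j] - tol <= free <= u[j] + tol:
                vj = v.copy()
                vj[j] = min(max(free, l[j]), u[j])
                vj = vj / vj.sum()
                key = tuple(np.round(vj, 10))
                seen.setdefault(key, vj)
    if not seen:
        raise ValueError("empty polytope: no vertex satisfies the bounds")
    models = [DiscreteDistribution(v) for v in seen.values()]
    return FiniteModelClass(models)
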