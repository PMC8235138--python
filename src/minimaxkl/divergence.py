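"""Kullback-Leibler divergence and logarithmic-loss primitives.

Everything downstream (capacity solvers, NML estimators, the simulation
harness) measures estimation error as a KL divergence ``D(p || q)`` between
a true model ``p`` and a density estimate ``q``, or as the per-sample
log-loss regret ``-log q(x) + log p(x)`` whose expectation under ``p`` is
exactly that divergence.

All internal arithmetic is in nats.  The ``base`` argument selects the
reporting unit (``2`` for bits -- the default used in reports -- or ``"e"``
for nats).  An unbounded divergence (some ``p(i) > 0`` where ``q(i) = 0``)
is returned as ``math.inf`` rather than raised, so that simulation reports
can tally unbounded replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np

__all__ = [
    "DiscreteDistribution",
    "GaussianModel",
    "DensityEstimate",
    "QuadratureSpec",
    "kl_discrete",
    "kl_gaussian_vs_density",
    "logloss_regret",
]

_LN2 = math.log(2.0)


def _log_base(base: Union[int, float, str]) -> float:
    """Natural log of the requested base (divisor for nat -> unit)."""
    if base in (2, "2", "bits"):
        return _LN2
    if base in ("e", "nats", math.e):
        return 1.0
    raise ValueError(f"unsupported log base: {base!r}")


@dataclass(frozen=True)
class DiscreteDistribution:
    """Probability vector over a finite alphabet of size ``m``.

    The constructor validates nonnegativity and normalization (sum within
    1e-9 of one) and then renormalizes exactly, so stored entries sum to
    one to machine precision.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float).ravel()
        if p.size < 1:
            raise ValueError("alphabet size must be >= 1")
        if np.any(p < -1e-12):
            raise ValueError("probabilities must be nonnegative")
        s = p.sum()
        if not math.isfinite(s) or abs(s - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {s})")
        p = np.clip(p, 0.0, None)
        object.__setattr__(self, "probs", p / p.sum())

    @property
    def alphabet_size(self) -> int:
        return self.probs.size

    m = alphabet_size

    def log_probs(self) -> np.ndarray:
        """Elementwise natural log; zeros map to ``-inf`` silently."""
        with np.errstate(divide="ignore"):
            return np.log(self.probs)


@dataclass(frozen=True)
class GaussianModel:
    """Multivariate normal ``N(mean, cov)`` with known SPD covariance."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mean, dtype=float))
        S = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if S.shape != (mu.size, mu.size):
            raise ValueError("cov shape must match mean dimension")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("cov must be symmetric")
        w = np.linalg.eigvalsh(S)
        if np.any(w <= 0):
            raise ValueError("cov must be positive definite")
        object.__setattr__(self, "mean", mu)
        object.__setattr__(self, "cov", S)

    @property
    def dim(self) -> int:
        return self.mean.size

    def _chol(self) -> np.ndarray:
        return np.linalg.cholesky(self.cov)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        """Natural-log density at points ``x`` of shape (..., d)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        L = self._chol()
        z = np.linalg.solve(L, (x - self.mean).T).T
        quad = np.sum(z * z, axis=-1)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        return -0.5 * (self.dim * math.log(2.0 * math.pi) + logdet + quad)


@dataclass
class DensityEstimate:
    """An evaluable density estimate ``q``: a map to natural-log density.

    ``log_density`` accepts either an array of points of shape (k, d)
    (continuous kinds) or an integer array of symbol indices (``discrete``
    kind), and returns natural-log probabilities/densities.
    """

    log_density: Callable[[np.ndarray], np.ndarray]
    kind: str  # gaussian | gaussian_mixture | nml_piecewise | discrete
    meta: dict = field(default_factory=dict)

    @staticmethod
    def from_gaussian(model: GaussianModel) -> "DensityEstimate":
        return DensityEstimate(model.logpdf, "gaussian", {"model": model})

    @staticmethod
    def from_discrete(dist: DiscreteDistribution) -> "DensityEstimate":
        logp = dist.log_probs()

        def ld(idx: np.ndarray) -> np.ndarray:
            return logp[np.asarray(idx, dtype=int)]

        return DensityEstimate(ld, "discrete", {"dist": dist})

    @staticmethod
    def from_gaussian_mixture(
        means: np.ndarray, cov: np.ndarray, weights: np.ndarray
    ) -> "DensityEstimate":
        """Finite mixture of equal-covariance Gaussians."""
        means = np.atleast_2d(np.asarray(means, dtype=float))
        w = np.asarray(weights, dtype=float).ravel()
        if w.size != means.shape[0]:
            raise ValueError("one weight per component required")
        keep = w > 0
        means, w = means[keep], w[keep]
        logw = np.log(w / w.sum())
        components = [GaussianModel(m, cov) for m in means]

        def ld(x: np.ndarray) -> np.ndarray:
            x = np.atleast_2d(np.asarray(x, dtype=float))
            lp = np.stack([c.logpdf(x) for c in components], axis=0)
            return _logsumexp(lp + logw[:, None], axis=0)

        return DensityEstimate(
            ld, "gaussian_mixture", {"means": means, "cov": cov, "weights": w}
        )


def _logsumexp(a: np.ndarray, axis: int = 0) -> np.ndarray:
    amax = np.max(a, axis=axis, keepdims=True)
    amax = np.where(np.isfinite(amax), amax, 0.0)
    out = np.log(np.sum(np.exp(a - amax), axis=axis)) + np.squeeze(amax, axis=axis)
    return out


@dataclass(frozen=True)
class QuadratureSpec:
    """Numerical-integration scheme for continuous KL integrals.

    ``d <= 2`` uses tensor Gauss-Hermite with ``nodes_per_axis`` nodes;
    higher dimensions fall back to seeded Monte Carlo with ``mc_samples``
    draws from the reference Gaussian.
    """

    nodes_per_axis: int = 200
    mc_samples: int = 200_000
    seed: int = 0


def kl_discrete(
    p: DiscreteDistribution, q: DiscreteDistribution, base: Union[int, str] = 2
) -> float:
    """``sum_i p(i) log(p(i)/q(i))`` in the requested base.

    Terms with ``p(i) = 0`` contribute zero; returns ``inf`` when ``q``
    places zero mass on a symbol ``p`` supports.
    """
    if p.alphabet_size != q.alphabet_size:
        raise ValueError(
            f"alphabet sizes differ: {p.alphabet_size} vs {q.alphabet_size}"
        )
    return kl_from_probs(p.probs, q.probs) / _log_base(base)


def kl_from_probs(p: np.ndarray, q: np.ndarray) -> float:
    """KL divergence in nats between two raw probability vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    support = p > 0
    if np.any(q[support] <= 0):
        return math.inf
    ps, qs = p[support], q[support]
    return float(np.sum(ps * (np.log(ps) - np.log(qs))))


def _gauss_hermite_nodes(p: GaussianModel, n_nodes: int):
    """Affinely transformed tensor Gauss-Hermite rule for E_p[f(X)]."""
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    d = p.dim
    if d == 1:
        Z = z[:, None]
        W = w
    elif d == 2:
        Z = np.stack(
            [np.repeat(z, n_nodes), np.tile(z, n_nodes)], axis=1
        )
        W = np.repeat(w, n_nodes) * np.tile(w, n_nodes)
    else:  # pragma: no cover - guarded by caller
        raise ValueError("tensor Gauss-Hermite only for d <= 2")
    L = p._chol()
    X = p.mean + math.sqrt(2.0) * Z @ L.T
    W = W / math.pi ** (d / 2.0)
    return X, W


def kl_gaussian_vs_density(
    p: GaussianModel,
    q: DensityEstimate,
    scheme: QuadratureSpec = QuadratureSpec(),
    base: Union[int, str] = 2,
) -> float:
    """Numerical ``\\int p log(p/q)`` for Gaussian ``p``, any evaluable ``q``.

    Tiny negative round-off (|value| < 1e-9 nats) is clamped to zero.
    Returns ``inf`` when ``q`` vanishes at a node of non-negligible weight.
    """
    if p.dim <= 2:
        X, W = _gauss_hermite_nodes(p, scheme.nodes_per_axis)
        logq = np.asarray(q.log_density(X), dtype=float)
        logp = p.logpdf(X)
        bad = ~np.isfinite(logq)
        if np.any(bad & (W > 1e-300)):
            return math.inf
        val = float(np.sum(W * (logp - logq)))
    else:
        rng = np.random.default_rng(scheme.seed)
        L = p._chol()
        Z = rng.standard_normal((scheme.mc_samples, p.dim))
        X = p.mean + Z @ L.T
        logq = np.asarray(q.log_density(X), dtype=float)
        if np.any(~np.isfinite(logq)):
            return math.inf
        val = float(np.mean(p.logpdf(X) - logq))
    if abs(val) < 1e-9:
        val = 0.0
    if val < 0 and val > -1e-6:
        val = 0.0
    return val / _log_base(base)


def logloss_regret(
    x: Union[np.ndarray, int, Sequence[float]],
    q: DensityEstimate,
    p: DensityEstimate,
    base: Union[int, str] = 2,
) -> float:
    """Excess log loss ``-log q(x) + log p(x)`` of ``q`` relative to ``p``."""
    if q.kind == "discrete":
        xq = np.asarray([x]) if np.isscalar(x) else np.asarray(x)
    else:
        xq = np.atleast_2d(np.asarray(x, dtype=float))
    lq = float(np.asarray(q.log_density(xq)).ravel()[0])
    lp = float(np.asarray(p.log_density(xq)).ravel()[0])
    return (lp - lq) / _log_base(base)
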