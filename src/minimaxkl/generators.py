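"""Seeded synthetic-data generators for the simulation studies.

Families mirror the benchmark settings of the experiments: Zipf's law
``p(i) ~ i^{-s}`` (natural count data), a geometric law ``p(i) ~
(1-s)^{i-1} s`` truncated to the alphabet, the uniform law, and
multivariate Gaussians with known covariance.  Discrete samples are
0-based symbol indices; Gaussian samples are (n, d) arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .divergence import DiscreteDistribution

__all__ = ["GeneratorSpec", "zipf_pmf", "geometric_pmf", "uniform_pmf", "sample"]


def zipf_pmf(m: int, s: float) -> DiscreteDistribution:
    """``p(i) ~ i^{-s}`` over symbols ``1..m`` (stored 0-based); s=0 is uniform."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if s < 0:
        raise ValueError("s must be nonnegative")
    w = np.arange(1, m + 1, dtype=float) ** (-s)
    return DiscreteDistribution(w / w.sum())


def geometric_pmf(m: int, s: float) -> DiscreteDistribution:
    """``p(i) ~ (1-s)^{i-1} s`` truncated at ``m`` and renormalized."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < s < 1:
        raise ValueError("s must lie in (0, 1)")
    i = np.arange(1, m + 1, dtype=float)
    logw = (i - 1.0) * np.log1p(-s) + np.log(s)
    w = np.exp(logw - logw.max())
    return DiscreteDistribution(w / w.sum())


def uniform_pmf(m: int) -> DiscreteDistribution:
    return DiscreteDistribution(np.full(m, 1.0 / m))


@dataclass(frozen=True)
class GeneratorSpec:
    """Distribution family, parameters and seed for one data source."""

    family: str  # zipf | geometric | uniform | gaussian
    params: dict = field(default_factory=dict)
    seed: int = 0

    def pmf(self) -> DiscreteDistribution:
        if self.family == "zipf":
            return zipf_pmf(int(self.params["m"]), float(self.params["s"]))
        if self.family == "geometric":
            return geometric_pmf(int(self.params["m"]), float(self.params["s"]))
        if self.family == "uniform":
            return uniform_pmf(int(self.params["m"]))
        raise ValueError(f"no pmf for family {self.family!r}")

    def gaussian_params(self):
        d = int(self.params.get("d", 1))
        mean = np.asarray(self.params.get("mean", np.zeros(d)), dtype=float)
        cov = np.asarray(self.params.get("cov", np.eye(mean.size)), dtype=float)
        return mean, np.atleast_2d(cov)


def sample(
    spec: GeneratorSpec, n: int, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """``n`` i.i.d. draws; identical seed gives identical output."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.family == "gaussian":
        mean, cov = spec.gaussian_params()
        L = np.linalg.cholesky(cov)
        z = rng.standard_normal((n, mean.size))
        return mean + z @ L.T
    p = spec.pmf().probs
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(p.size, size=n, p=p).astype(np.int64)
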