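"""Normalized maximum likelihood (Shtarkov) estimators over restricted classes.

The NML estimator ``q_nml(x) = max_{p in class} p(x) / Z`` with
``Z = sum_x max_p p(x)`` attains the minimax pointwise regret over *all*
true distributions relative to the best member of the class, with constant
regret ``Gamma = log Z``.  Two cases are implemented exactly: any finite
class over a finite alphabet, and the Gaussian mean-interval class, whose
normalizer has the closed form ``Z = 1 + a * sqrt(2/pi)`` for a
standardized symmetric interval ``[-a, a]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .divergence import DensityEstimate, DiscreteDistribution
from .regions import FiniteModelClass

__all__ = ["NMLResult", "nml_finite", "nml_gaussian_interval"]

_LN2 = math.log(2.0)


@dataclass
class NMLResult:
    estimate: DensityEstimate
    gamma_bits: float
    z: float
    probs: Optional[DiscreteDistribution] = None  # finite-alphabet case

    def to_dict(self) -> dict:
        return {"gamma_bits": self.gamma_bits, "z": self.z}


def nml_finite(model_class: FiniteModelClass) -> NMLResult:
    """Exact NML over a finite class on a finite alphabet."""
    W = model_class.as_matrix()
    best = W.max(axis=0)
    z = float(best.sum())
    probs = DiscreteDistribution(best / z)
    return NMLResult(
        estimate=DensityEstimate.from_discrete(probs),
        gamma_bits=math.log(z) / _LN2,
        z=z,
        probs=probs,
    )


def nml_probs(W: np.ndarray):
    """Vectorized finite NML from a (K, m) matrix; returns (probs, z)."""
    best = W.max(axis=0)
    z = float(best.sum())
    return best / z, z


def nml_gaussian_interval(center: float, a: float, sigma: float = 1.0) -> NMLResult:
    """Closed-form NML for the unit-family mean interval ``[center - a*sigma, center + a*sigma]``.

    In standardized coordinates ``t = (x - center)/sigma`` the maximized
    likelihood is ``phi(t - clip(t, -a, a))``: the standard normal bump
    shifted to the nearest interval endpoint outside ``[-a, a]`` and flat
    at ``phi(0)`` inside.  Its integral is ``Z = 1 + a sqrt(2/pi)``, so
    the regret guarantee is ``Gamma = log2 Z`` bits.

    ``a`` is the interval half-width in units of ``sigma``.
    """
    if a < 0:
        raise ValueError("halfwidth must be nonnegative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = 1.0 + a * math.sqrt(2.0 / math.pi)
    log_norm = -0.5 * math.log(2.0 * math.pi) - math.log(z) - math.log(sigma)

    def ld(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = (x - center) / sigma
        shifted = t - np.clip(t, -a, a)
        out = log_norm - 0.5 * shifted**2
        return out.reshape(np.shape(x)[:1] if np.ndim(x) > 1 else np.shape(x))

    est = DensityEstimate(
        lambda pts: ld(np.atleast_2d(np.asarray(pts, dtype=float))[:, 0]),
        "nml_piecewise",
        {"center": center, "a": a, "sigma": sigma},
    )
    return NMLResult(estimate=est, gamma_bits=math.log(z) / _LN2, z=z)
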