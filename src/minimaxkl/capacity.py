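"""Redundancy-capacity solvers: the minimax estimator as a channel problem.

The minimax density-estimation problem ``min_q max_{theta in Theta_r}
D(p_theta || q)`` equals the capacity ``C(Theta_r)`` of the channel whose
transition law is the model class, and the minimax estimator is the
capacity-achieving mixture ``q_pi``.  Over finite classes the capacity is
computed by Blahut-Arimoto.  A constrained variant solves the robust
objective ``F(Theta, Theta_r)`` -- the worst-case regret relative to the
best member of a restricted class when the truth may lie outside it -- by
the same alternating scheme with each model's divergence offset by its KL
projection distance onto the restricted class.

For Gaussian-mean confidence ellipsoids with small enough radius the
capacity-achieving prior is uniform on the ellipsoid boundary, giving the
closed-form sphere mixture (:func:`sphere_mixture_gaussian`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple, Union

import numpy as np
from scipy import special, stats

from .divergence import (
    DensityEstimate,
    DiscreteDistribution,
    GaussianModel,
)
from .regions import (
    BoxSimplexRegion,
    EllipsoidRegion,
    FiniteModelClass,
    enumerate_vertices,
    whiten,
)

__all__ = [
    "CapacityResult",
    "ConstrainedCapacityResult",
    "DiscretizationSpec",
    "R_D_TABLE",
    "blahut_arimoto",
    "mixture_minimax",
    "sphere_mixture_gaussian",
    "constrained_capacity",
    "kl_project_gaussian",
    "kl_project_discrete",
]

_LN2 = math.log(2.0)

#: Largest ball radius for which the capacity-achieving input of the
#: amplitude-constrained vector Gaussian channel is uniform on the single
#: outer sphere.  Only the d=2 value is shipped; other dimensions must be
#: supplied by the caller with provenance.
R_D_TABLE = {2: 2.454}


@dataclass
class CapacityResult:
    capacity_bits: float
    prior: np.ndarray
    mixture: DensityEstimate
    per_model_divergence_bits: np.ndarray
    iterations: int
    converged: bool
    support: Optional[np.ndarray] = None  # model parameters backing the prior

    def to_dict(self) -> dict:
        return {
            "capacity_bits": self.capacity_bits,
            "prior": self.prior.tolist(),
            "per_model_divergence_bits": self.per_model_divergence_bits.tolist(),
            "iterations": self.iterations,
            "converged": self.converged,
        }


@dataclass
class ConstrainedCapacityResult:
    f_bits: float
    phi: np.ndarray
    mixture: DensityEstimate
    psi: np.ndarray  # (K, J) conditional weights, columns sum to 1
    iterations: int
    converged: bool
    per_model_advantage_bits: np.ndarray = field(default=None)

    def to_dict(self) -> dict:
        return {
            "f_bits": self.f_bits,
            "phi": self.phi.tolist(),
            "iterations": self.iterations,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class DiscretizationSpec:
    """How continuous regions are reduced to finite supports.

    ``n_boundary`` boundary angles for d=2 ellipsoids; ``n_interior``
    evenly spaced interior support points added between the endpoints for
    d=1 intervals (the solver prunes them if the endpoints suffice);
    ``grid_halfwidth``/``grid_step`` control the trapezoid evaluation grid
    in the whitened sample space.
    """

    n_boundary: int = 360
    n_interior: int = 0
    grid_halfwidth: float = 7.0
    grid_step: float = 0.02
    grid_step_2d: float = 0.15


def _ba_core(
    W: np.ndarray,
    u: np.ndarray,
    tol_bits: float,
    max_iter: int,
    offsets_nats: Optional[np.ndarray] = None,
    history: Optional[list] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    """Blahut-Arimoto ascent on ``sum_k pi_k (D(p_k || q_pi) - offset_k)``.

    ``W[k, j]`` is the density/pmf of model ``k`` at support point ``j``
    and ``u[j]`` the quadrature weight (ones for a discrete alphabet).
    With zero offsets this is the plain capacity iteration; with offsets
    ``D(p_k || p*_k)`` it is the constrained (projected) iteration, which
    reduces to the same multiplicative update.  Convergence is declared
    when the standard capacity gap ``max_k E_k - sum_k pi_k E_k`` drops
    below ``tol_bits``.
    """
    K, J = W.shape
    if offsets_nats is None:
        offsets_nats = np.zeros(K)
    with np.errstate(divide="ignore"):
        logW = np.where(W > 0, np.log(np.where(W > 0, W, 1.0)), -np.inf)
    pi = np.full(K, 1.0 / K)
    Wu = W * u  # fold weights into the transition matrix rows
    value = -math.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q = pi @ W
        with np.errstate(divide="ignore"):
            logq = np.where(q > 0, np.log(np.where(q > 0, q, 1.0)), -np.inf)
        diff = logW - logq[None, :]
        diff = np.where(W > 0, diff, 0.0)
        D = np.einsum("kj,kj->k", Wu, diff)  # nats
        E = D - offsets_nats
        lower = float(pi @ E)
        upper = float(np.max(E))
        if history is not None:
            history.append(lower)
        value = max(value, lower)
        if upper - lower < tol_bits * _LN2:
            converged = True
            value = lower
            break
        pi = pi * np.exp(E - np.max(E))
        pi = pi / pi.sum()
    q = pi @ W
    with np.errstate(divide="ignore"):
        logq = np.where(q > 0, np.log(np.where(q > 0, q, 1.0)), -np.inf)
    diff = np.where(W > 0, logW - logq[None, :], 0.0)
    D = np.einsum("kj,kj->k", Wu, diff)
    return pi, q, D - offsets_nats, float(pi @ (D - offsets_nats)), it, converged


def _discrete_class_matrix(model_class: FiniteModelClass) -> np.ndarray:
    return model_class.as_matrix()


def blahut_arimoto(
    model_class: FiniteModelClass,
    alphabet_or_grid: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> CapacityResult:
    """Capacity of the channel defined by a finite model class.

    For discrete classes the support is the alphabet itself; for Gaussian
    classes ``alphabet_or_grid = (points, weights)`` supplies a quadrature
    grid over the sample space.  ``tol`` is the capacity-gap tolerance in
    bits.  The returned mixture is the minimax density estimate.
    """
    first = model_class.models[0]
    if isinstance(first, DiscreteDistribution):
        W = _discrete_class_matrix(model_class)
        u = np.ones(W.shape[1])
        pi, q, D, value, it, conv = _ba_core(W, u, tol, max_iter)
        mix = DensityEstimate.from_discrete(DiscreteDistribution(q / q.sum()))
        support = W
    else:
        if alphabet_or_grid is None:
            raise ValueError("Gaussian classes require an evaluation grid")
        points, u = alphabet_or_grid
        W = np.exp(
            np.stack([m.logpdf(points) for m in model_class.models], axis=0)
        )
        pi, q, D, value, it, conv = _ba_core(W, u, tol, max_iter)
        means = np.stack([m.mean for m in model_class.models], axis=0)
        mix = DensityEstimate.from_gaussian_mixture(
            means, first.cov, pi
        )
        support = means
    return CapacityResult(
        capacity_bits=value / _LN2,
        prior=pi,
        mixture=mix,
        per_model_divergence_bits=D / _LN2,
        iterations=it,
        converged=conv,
        support=support,
    )


def _interval_support(a: float, n_interior: int) -> np.ndarray:
    if n_interior > 0:
        return np.linspace(-a, a, n_interior + 2)
    return np.array([-a, a])


def _trapezoid_grid_1d(a: float, spec: DiscretizationSpec):
    hw = a + spec.grid_halfwidth
    x = np.arange(-hw, hw + spec.grid_step, spec.grid_step)
    pts = x[:, None]
    w = np.full(x.size, spec.grid_step)
    return pts, w


def _trapezoid_grid_2d(a: float, spec: DiscretizationSpec):
    hw = a + spec.grid_halfwidth
    step = spec.grid_step_2d
    x = np.arange(-hw, hw + step, step)
    X1, X2 = np.meshgrid(x, x, indexing="ij")
    pts = np.stack([X1.ravel(), X2.ravel()], axis=1)
    w = np.full(pts.shape[0], step * step)
    return pts, w


def mixture_minimax(
    region: Union[EllipsoidRegion, BoxSimplexRegion],
    resolution: DiscretizationSpec = DiscretizationSpec(),
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> CapacityResult:
    """Data-dependent minimax mixture over a confidence region.

    Multinomial boxes are reduced to their vertex set (the capacity over
    the polytope is attained there); Gaussian ellipsoids are whitened and
    discretized -- interval endpoints (optionally plus an interior grid)
    for d=1, equally spaced boundary angles for d=2 -- and solved by
    Blahut-Arimoto on a trapezoid quadrature grid.
    """
    if isinstance(region, BoxSimplexRegion):
        vertices = enumerate_vertices(region)
        return blahut_arimoto(vertices, tol=tol, max_iter=max_iter)
    transform, ball = whiten(region)
    a = math.sqrt(ball.radius_sq)
    d = region.dim
    if d == 1:
        support_w = _interval_support(a, resolution.n_interior)[:, None]
        grid = _trapezoid_grid_1d(a, resolution)
    elif d == 2:
        ang = np.linspace(0.0, 2.0 * math.pi, resolution.n_boundary, endpoint=False)
        support_w = a * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        grid = _trapezoid_grid_2d(a, resolution)
    else:
        raise ValueError("ellipsoid discretization implemented for d <= 2")
    models = [GaussianModel(mu, np.eye(d)) for mu in support_w]
    res = blahut_arimoto(
        FiniteModelClass(models), alphabet_or_grid=grid, tol=tol, max_iter=max_iter
    )
    # map the whitened mixture back to the original coordinates
    means_orig = transform.inverse(support_w)
    res.mixture = DensityEstimate.from_gaussian_mixture(
        means_orig, region.shape, res.prior
    )
    res.support = means_orig
    return res


def sphere_mixture_gaussian(
    region: EllipsoidRegion,
    r_d: Optional[float] = None,
) -> Tuple[DensityEstimate, Optional[bool]]:
    """Closed-form uniform boundary mixture ``q ~ int_{boundary} N(mu, Sigma) dmu``.

    Valid as the exact minimax estimator whenever the whitened region
    radius does not exceed the single-sphere threshold ``r_d``
    (``condition_ok``); the density is returned regardless, with
    ``condition_ok = None`` when no threshold is known for ``d``.

    d=1: equal two-point Gaussian mixture at the interval endpoints.
    d=2: radial density ``(2 pi)^{-1} exp(-(r^2 + a^2)/2) I_0(a r)`` in the
    whitened frame.
    """
    transform, ball = whiten(region)
    a = math.sqrt(ball.radius_sq)
    d = region.dim
    r_known = r_d if r_d is not None else R_D_TABLE.get(d)
    condition_ok = None if r_known is None else bool(a <= r_known)

    if a < 1e-12:
        return DensityEstimate.from_gaussian(
            GaussianModel(region.center, region.shape)
        ), condition_ok

    if d == 1:
        sd = math.sqrt(float(region.shape[0, 0]))
        means = np.array([[region.center[0] - a * sd], [region.center[0] + a * sd]])
        est = DensityEstimate.from_gaussian_mixture(
            means, region.shape, np.array([0.5, 0.5])
        )
        est.kind = "gaussian_mixture"
        return est, condition_ok
    if d == 2:
        inv_sqrt = transform.inv_sqrt
        logdet_sqrt = float(np.linalg.slogdet(transform.sqrt)[1])

        def ld(x: np.ndarray) -> np.ndarray:
            x = np.atleast_2d(np.asarray(x, dtype=float))
            z = (x - region.center) @ inv_sqrt
            r = np.linalg.norm(z, axis=-1)
            # log I0(a r) = log ive(0, a r) + a r  (scaled Bessel, stable)
            log_i0 = np.log(special.ive(0, a * r)) + a * r
            return (
                -math.log(2.0 * math.pi)
                - 0.5 * (r**2 + a**2)
                + log_i0
                - logdet_sqrt
            )

        return DensityEstimate(ld, "gaussian_mixture", {"a": a}), condition_ok
    raise ValueError("closed-form sphere mixture implemented for d <= 2")


def constrained_capacity(
    full_class: FiniteModelClass,
    project: Callable,
    alphabet_or_grid: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> ConstrainedCapacityResult:
    """Robust minimax value ``F(Theta, Theta_r)`` and its projected mixture.

    ``project`` maps each model of the full class to its KL-closest member
    of the restricted class.  The alternating update -- conditional weights
    ``psi(theta, x) = phi(theta) p_theta(x) / q(x)`` followed by the
    exponential-family reweighting of ``phi`` -- collapses to a
    Blahut-Arimoto iteration on divergences offset by each model's
    projection distance ``D(p_theta || p_theta*)``.
    """
    first = full_class.models[0]
    if isinstance(first, DiscreteDistribution):
        W = full_class.as_matrix()
        u = np.ones(W.shape[1])
        Wstar = np.stack(
            [np.asarray(project(m).probs, dtype=float) for m in full_class.models],
            axis=0,
        )
    else:
        if alphabet_or_grid is None:
            raise ValueError("Gaussian classes require an evaluation grid")
        points, u = alphabet_or_grid
        W = np.exp(np.stack([m.logpdf(points) for m in full_class.models], axis=0))
        Wstar = np.exp(
            np.stack([project(m).logpdf(points) for m in full_class.models], axis=0)
        )
    with np.errstate(divide="ignore"):
        ratio = np.where(W > 0, np.log(np.where(W > 0, W, 1.0)), -np.inf) - np.where(
            Wstar > 0, np.log(np.where(Wstar > 0, Wstar, 1.0)), -np.inf
        )
    ratio = np.where(W > 0, ratio, 0.0)
    offsets = np.einsum("kj,kj,j->k", W, ratio, u)  # D(p_k || p*_k), nats
    phi, q, E, value, it, conv = _ba_core(W, u, tol, max_iter, offsets_nats=offsets)
    psi = phi[:, None] * W
    colsum = psi.sum(axis=0)
    psi = np.divide(psi, colsum[None, :], out=np.zeros_like(psi), where=colsum > 0)
    if isinstance(first, DiscreteDistribution):
        mix = DensityEstimate.from_discrete(DiscreteDistribution(q / q.sum()))
    else:
        means = np.stack([m.mean for m in full_class.models], axis=0)
        mix = DensityEstimate.from_gaussian_mixture(means, first.cov, phi)
    return ConstrainedCapacityResult(
        f_bits=value / _LN2,
        phi=phi,
        mixture=mix,
        psi=psi,
        iterations=it,
        converged=conv,
        per_model_advantage_bits=E / _LN2,
    )


def kl_project_gaussian(mu: np.ndarray, region: EllipsoidRegion) -> np.ndarray:
    """KL projection of ``N(mu, Sigma)`` onto the ellipsoid of means.

    Equal-covariance Gaussian KL is the squared Mahalanobis distance of
    the means, so the projection whitens, clips radially to the ball
    boundary, and maps back.
    """
    transform, ball = whiten(region)
    z = transform.forward(np.atleast_1d(np.asarray(mu, dtype=float)))
    r = float(np.linalg.norm(z))
    a = math.sqrt(ball.radius_sq)
    if r <= a or r == 0.0:
        return np.atleast_1d(np.asarray(mu, dtype=float))
    return transform.inverse(z * (a / r))


def kl_project_discrete(
    p: DiscreteDistribution, region: BoxSimplexRegion, tol: float = 1e-12
) -> DiscreteDistribution:
    """``argmin_{q in box cap simplex} D(p || q)`` by KKT water-filling.

    Stationarity gives ``q_i = clip(p_i / lam, l_i, u_i)`` with the
    multiplier ``lam`` chosen so the clipped vector sums to one; the sum
    is monotone in ``lam`` so bisection solves it.
    """
    if p.alphabet_size != region.m:
        raise ValueError("alphabet size mismatch")
    pv = p.probs
    l, u = region.lower, region.upper

    def total(lam: float) -> float:
        return float(np.sum(np.clip(pv / lam, l, u)))

    lo, hi = 1e-12, 1e12
    if total(hi) > 1.0:  # all at lower bounds still above 1: infeasible guard
        lam = hi
    elif total(lo) < 1.0:
        lam = lo
    else:
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if total(mid) > 1.0:
                lo = mid
            else:
                hi = mid
            if hi / lo < 1 + 1e-15:
                break
        lam = math.sqrt(lo * hi)
    q = np.clip(pv / lam, l, u)
    s = q.sum()
    if abs(s - 1.0) > 1e-9:
        # distribute the residual over coordinates strictly inside their bounds
        interior = (q > l + tol) & (q < u - tol)
        if np.any(interior):
            q[interior] += (1.0 - s) / interior.sum()
    q = np.clip(q, l, u)
    q = q / q.sum()
    if not region.contains(q, tol=1e-9):
        raise RuntimeError("projection failed to produce a feasible point")
    return DiscreteDistribution(q)
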