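"""Capacity solvers vs grid-search oracles; projections vs optimizers."""

import math

import numpy as np
import pytest
from scipy import optimize

from minimaxkl import (
    BoxSimplexRegion,
    DiscretizationSpec,
    DiscreteDistribution,
    EllipsoidRegion,
    FiniteModelClass,
    GaussianModel,
    QuadratureSpec,
    blahut_arimoto,
    constrained_capacity,
    gaussian_mean_region,
    kl_discrete,
    kl_gaussian_vs_density,
    kl_project_discrete,
    kl_project_gaussian,
    mixture_minimax,
    sphere_mixture_gaussian,
)
from minimaxkl.capacity import _ba_core

LN2 = math.log(2.0)


def mutual_information_bits(pi, W):
    """Direct I(T;X) for a prior pi over rows of W (independent oracle)."""
    q = pi @ W
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(W > 0, np.log(W / q), 0.0)
    return float(np.einsum("k,kj,kj->", pi, W, ratio)) / LN2


def simplex_grid(step):
    """All priors on the 2-simplex with the given step, as an (N, 3) array."""
    g = np.arange(0.0, 1.0 + step / 2, step)
    p1, p2 = np.meshgrid(g, g, indexing="ij")
    keep = p1 + p2 <= 1.0 + 1e-12
    p1, p2 = p1[keep], p2[keep]
    return np.stack([p1, p2, 1.0 - p1 - p2], axis=1)


def grid_search_capacity_bits(W, offsets_bits=None, step=1e-3):
    """Exhaustive prior search for sup_pi [I(T;X) - pi @ offsets] (vectorized)."""
    P = simplex_grid(step)
    Q = P @ W  # (N, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        logW = np.where(W > 0, np.log(np.where(W > 0, W, 1.0)), 0.0)
        logQ = np.where(Q > 0, np.log(np.where(Q > 0, Q, 1.0)), 0.0)
    # I(pi) = sum_k pi_k sum_j W_kj (log W_kj - log q_j)
    H_terms = np.einsum("kj,kj->k", W, logW)  # constant per model
    cross = np.einsum("nk,kj,nj->n", P, W, logQ)
    mi = (P @ H_terms - cross) / LN2
    if offsets_bits is not None:
        mi = mi - P @ offsets_bits
    return float(mi.max())


class TestBlahutArimoto:
    def test_single_model_zero_capacity(self):
        fc = FiniteModelClass([DiscreteDistribution([0.2, 0.8])])
        res = blahut_arimoto(fc)
        assert res.capacity_bits == pytest.approx(0.0, abs=1e-12)
        assert res.prior[0] == 1.0

    def test_noiseless_binary_channel(self):
        fc = FiniteModelClass(
            [DiscreteDistribution([1.0, 0.0]), DiscreteDistribution([0.0, 1.0])]
        )
        res = blahut_arimoto(fc)
        assert res.capacity_bits == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(res.prior, 0.5)

    def test_three_models_match_simplex_grid_search(self, rng):
        W = rng.dirichlet(np.ones(4), size=3)
        fc = FiniteModelClass([DiscreteDistribution(w) for w in W])
        res = blahut_arimoto(fc, tol=1e-10)
        best = grid_search_capacity_bits(W, step=1e-3)
        assert res.capacity_bits == pytest.approx(best, abs=1e-4)

    def test_equalization_at_convergence(self, rng):
        for _ in range(5):
            W = rng.dirichlet(np.ones(5), size=4)
            res = blahut_arimoto(
                FiniteModelClass([DiscreteDistribution(w) for w in W]), tol=1e-10
            )
            D = res.per_model_divergence_bits
            supported = res.prior > 1e-6
            assert np.all(np.abs(D[supported] - res.capacity_bits) < 1e-8)
            assert np.all(D <= res.capacity_bits + 1e-8)

    def test_lower_bound_monotone_per_iteration(self, rng):
        W = rng.dirichlet(np.ones(6), size=4)
        hist = []
        _ba_core(W, np.ones(6), tol_bits=1e-12, max_iter=300, history=hist)
        assert all(b - a > -1e-12 for a, b in zip(hist, hist[1:]))


class TestMixtureMinimax:
    def test_single_vertex_region(self):
        p = [0.2, 0.3, 0.5]
        box = BoxSimplexRegion(p, p, 0.05)
        res = mixture_minimax(box)
        assert res.capacity_bits == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.mixture.meta["dist"].probs, p)

    def test_interval_prior_concentrates_on_endpoints(self):
        region = EllipsoidRegion([0.0], [[1.0]], 1.0**2, 0.05, 1)
        res = mixture_minimax(region, DiscretizationSpec(n_interior=39), tol=1e-9)
        pr = res.prior
        assert pr[0] == pytest.approx(0.5, abs=1e-4)
        assert pr[-1] == pytest.approx(0.5, abs=1e-4)
        assert pr[1:-1].max() < 1e-4
        # brute-force symmetric two-point prior search on a 41-point support
        support = np.linspace(-1.0, 1.0, 41)
        models = [GaussianModel([s], [[1.0]]) for s in support]
        best = 0.0
        x = np.arange(-8, 8.0001, 0.02)[:, None]
        W = np.exp(np.stack([m.logpdf(x) for m in models]) ) * 0.02
        for w_end in np.linspace(0, 0.5, 101):
            pi = np.zeros(41)
            pi[0] = pi[-1] = w_end
            pi[20] = 1 - 2 * w_end
            q = pi @ W
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(W > 0, np.log(W / q), 0.0)
            best = max(best, float(np.einsum("k,kj,kj->", pi, W, ratio)) / LN2)
        assert res.capacity_bits == pytest.approx(best, abs=1e-3)

    def test_worst_case_bounded_by_capacity(self, rng):
        region = gaussian_mean_region([0.4], [[1.0]], 6, 0.05)
        res = mixture_minimax(region, DiscretizationSpec(n_interior=19), tol=1e-8)
        a = math.sqrt(region.radius_sq)
        worst = 0.0
        for mu in np.linspace(region.center[0] - a, region.center[0] + a, 41):
            kl = kl_gaussian_vs_density(
                GaussianModel([mu], [[1.0]]), res.mixture, base=2
            )
            worst = max(worst, kl)
        assert worst <= res.capacity_bits + 1e-3


class TestSphereMixture:
    def test_degenerate_radius_recovers_plugin_gaussian(self):
        region = EllipsoidRegion([1.0], [[2.0]], 1e-26, 0.05, 10)
        est, _ = sphere_mixture_gaussian(region)
        g = GaussianModel([1.0], [[2.0]])
        x = np.linspace(-4, 6, 31)[:, None]
        assert np.allclose(est.log_density(x), g.logpdf(x), atol=1e-10)

    def test_d1_equals_two_point_mixture(self):
        region = EllipsoidRegion([0.3], [[1.0]], 1.0, 0.05, 1)
        est, _ = sphere_mixture_gaussian(region)
        direct = 0.5 * np.exp(-0.5 * (np.linspace(-4, 4, 41) - (0.3 - 1)) ** 2) + \
            0.5 * np.exp(-0.5 * (np.linspace(-4, 4, 41) - (0.3 + 1)) ** 2)
        direct = np.log(direct / math.sqrt(2 * math.pi))
        x = np.linspace(-4, 4, 41)[:, None]
        assert np.allclose(est.log_density(x), direct, atol=1e-12)

    def test_d2_closed_form_vs_monte_carlo_circle(self):
        region = gaussian_mean_region([0.0, 0.0], np.eye(2), 1, 0.05)
        est, ok = sphere_mixture_gaussian(region)
        assert ok is True  # a = 2.448 <= r_2 = 2.454
        a = math.sqrt(region.radius_sq)
        rng = np.random.default_rng(11)
        thetas = rng.uniform(0, 2 * math.pi, 200_000)
        mus = a * np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
        pts = rng.standard_normal((20, 2)) * 1.5
        for x in pts:
            vals = np.exp(-0.5 * np.sum((x - mus) ** 2, axis=1)) / (2 * math.pi)
            mc, se = float(np.mean(vals)), float(np.std(vals) / math.sqrt(len(vals)))
            assert abs(math.exp(est.log_density(x[None, :])[0]) - mc) < 3 * se + 1e-12

    def test_unknown_dimension_threshold_reported(self):
        region = EllipsoidRegion([0.0], [[1.0]], 4.0, 0.05, 1)
        est, ok = sphere_mixture_gaussian(region)
        assert ok is None and est is not None


class TestConstrainedCapacity:
    def test_identity_projection_reduces_to_blahut_arimoto(self, rng):
        W = rng.dirichlet(np.ones(4), size=3)
        fc = FiniteModelClass([DiscreteDistribution(w) for w in W])
        ba = blahut_arimoto(fc, tol=1e-10)
        cc = constrained_capacity(fc, lambda m: m, tol=1e-10)
        assert cc.f_bits == pytest.approx(ba.capacity_bits, abs=1e-8)
        assert np.allclose(cc.phi, ba.prior, atol=1e-4)
        assert np.allclose(cc.psi.sum(axis=0), 1.0)

    def test_single_model_class_zero(self):
        fc = FiniteModelClass([DiscreteDistribution([0.4, 0.6])])
        cc = constrained_capacity(fc, lambda m: m)
        assert cc.f_bits == pytest.approx(0.0, abs=1e-12)

    def test_matches_grid_search_with_projection(self, rng):
        # 3-model full class over 4 symbols, 2-model restricted class
        W = rng.dirichlet(np.ones(4), size=3)
        restricted = [DiscreteDistribution(W[0]), DiscreteDistribution(W[1])]
        fc = FiniteModelClass([DiscreteDistribution(w) for w in W])

        def project(model):
            kls = [kl_discrete(model, r, base="e") for r in restricted]
            return restricted[int(np.argmin(kls))]

        cc = constrained_capacity(fc, project, tol=1e-11)
        offsets = np.array(
            [min(kl_discrete(DiscreteDistribution(w), r, base=2) for r in restricted)
             for w in W]
        )
        best = grid_search_capacity_bits(W, offsets_bits=offsets, step=1e-3)
        assert cc.f_bits == pytest.approx(best, abs=1e-4)


class TestKLProjections:
    def test_gaussian_interior_point_unchanged(self):
        region = EllipsoidRegion([0.0, 0.0], np.eye(2), 2.0, 0.05, 1)
        mu = np.array([0.3, -0.4])
        assert np.allclose(kl_project_gaussian(mu, region), mu)

    def test_gaussian_d1_clips_to_endpoint(self):
        region = EllipsoidRegion([0.0], [[1.0]], 1.0**2, 0.05, 1)
        assert kl_project_gaussian([3.0], region)[0] == pytest.approx(1.0)

    def test_gaussian_d2_matches_constrained_optimizer(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        region = EllipsoidRegion([0.1, -0.2], S, 0.8, 0.05, 3)
        mu = np.array([2.5, 1.7])
        mine = kl_project_gaussian(mu, region)
        Sinv = np.linalg.inv(S)

        def obj(v):
            return 0.5 * (v - mu) @ Sinv @ (v - mu)  # KL between equal-cov Gaussians

        cons = {
            "type": "ineq",
            "fun": lambda v: region.radius_sq - (v - region.center) @ Sinv @ (v - region.center),
        }
        res = optimize.minimize(obj, region.center, constraints=[cons], tol=1e-14)
        assert np.allclose(mine, res.x, atol=1e-5)

    def test_discrete_interior_point_unchanged(self):
        region = BoxSimplexRegion([0.1, 0.1, 0.1], [0.8, 0.8, 0.8], 0.05)
        p = DiscreteDistribution([0.3, 0.3, 0.4])
        assert np.allclose(kl_project_discrete(p, region).probs, p.probs, atol=1e-10)

    def test_discrete_m2_binding_bound_matches_line_search(self):
        region = BoxSimplexRegion([0.0, 0.3], [0.7, 1.0], 0.05)
        p = DiscreteDistribution([0.9, 0.1])
        proj = kl_project_discrete(p, region)
        # 1-parameter oracle: q = (t, 1-t), t in [0, 0.7] with 1-t >= 0.3
        ts = np.linspace(1e-6, 0.7, 200_001)
        kl = 0.9 * np.log(0.9 / ts) + 0.1 * np.log(0.1 / (1 - ts))
        t_best = ts[np.argmin(kl)]
        assert proj.probs[0] == pytest.approx(t_best, abs=1e-5)
        assert proj.probs[0] == pytest.approx(0.7, abs=1e-9)  # clipped at the bound

    def test_discrete_m3_matches_grid_search(self, rng):
        region = BoxSimplexRegion([0.05, 0.1, 0.2], [0.4, 0.5, 0.9], 0.05)
        p = DiscreteDistribution([0.7, 0.2, 0.1])
        proj = kl_project_discrete(p, region)
        step = 1e-3
        best = np.inf
        for q1 in np.arange(0.05, 0.4 + step / 2, step):
            for q2 in np.arange(0.1, 0.5 + step / 2, step):
                q3 = 1 - q1 - q2
                if 0.2 - 1e-12 <= q3 <= 0.9 + 1e-12:
                    best = min(best, float(np.sum(p.probs * np.log(p.probs / np.array([q1, q2, q3])))))
        mine = float(np.sum(p.probs * np.log(p.probs / proj.probs)))
        assert mine <= best + 1e-5
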