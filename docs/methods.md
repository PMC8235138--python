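# Methods

## The estimation problem

Given `n` i.i.d. samples from an unknown distribution `p`, the package does
not return the single best-fitting model. Instead it builds a *data-driven
restricted model class* — a set of models that describe the sample with
high confidence — and returns the density estimate `q` minimizing the
worst-case Kullback–Leibler divergence over that class:

    min_q  max_{p_theta in class}  D(p_theta || q).

By the redundancy–capacity theorem this minimax problem is a channel-capacity
problem: view the class as the transition law of a channel; then the minimax
value is the capacity `C` and the optimal `q` is the mixture of class members
under the capacity-achieving (least favorable) prior. Since `D(p_theta || q)`
is also the expected log-loss regret of `q` on a future sample, the same
estimator carries a prediction guarantee: with confidence `1 - alpha` the
expected regret is at most `C` bits.

Three estimators are provided, ordered by how much they assume:

1. **Capacity mixture** `q_pi` (assumes the truth lies in the class):
   worst-case divergence `C(Theta_r)`.
2. **Projected mixture** `q_Theta` (truth anywhere in a wider class
   `Theta`): worst-case regret `F(Theta, Theta_r)` relative to the best
   member of the restricted class, solved by an alternating
   Blahut–Arimoto-type iteration in which each model's divergence is offset
   by its KL-projection distance onto the restricted class.
3. **Normalized maximum likelihood** `q_nml(x) = max_class p(x) / Z`
   (no assumption at all): constant pointwise regret
   `Gamma = log2 Z >= F >= C`.

## Model classes

**Gaussian mean, known covariance.** The restricted class is the exact
confidence ellipsoid `(xbar - mu)' Sigma^{-1} (xbar - mu) <= chi2_d(1-alpha)/n`.
Whitening (`mu -> Sigma^{-1/2}(mu - xbar)`) reduces it to a ball of radius
`a = sqrt(chi2_d(1-alpha)/n)` around the origin; equal-covariance Gaussian
KL divergences are invariant under this map, so all capacity computations
happen in the whitened frame. When `a` does not exceed the single-sphere
threshold `r_d` of the amplitude-constrained Gaussian channel (shipped:
`r_2 = 2.454`; other dimensions must be supplied by the caller), the
capacity-achieving prior is uniform on the boundary sphere and the mixture
has a closed form — for `d = 1` an equal two-point mixture at the interval
endpoints, for `d = 2` the radial density
`(2 pi)^{-1} exp(-(r^2 + a^2)/2) I_0(a r)`. For the one-dimensional interval
the NML density is piecewise (flat at `phi(0)` inside, Gaussian tails
re-centered at the endpoints outside) with the exact normalizer
`Z = 1 + a sqrt(2/pi)`.

**Multinomial.** The restricted class is the Sison–Glaz simultaneous
rectangular region intersected with the simplex. The box is computed from
the truncated-Poisson representation: for integer half-width `c`, the joint
coverage is the product of truncated `Poisson(n_i)` masses on
`[n_i - c, min(n_i + c, n)]` times an Edgeworth density (third and fourth
cumulants) of their sum at `n`, normalized by `Poisson(n).pmf(n)`; the
smallest `c` reaching `1 - alpha` is interpolated fractionally onto the
upper bounds. The capacity over the box–simplex polytope is attained on its
vertex set (each vertex has at most one coordinate strictly between its
bounds), so vertices are enumerated exhaustively over low/high bound
assignments (practical for `m <= 16`) and Blahut–Arimoto runs on the finite
class. If clipping leaves the box disjoint from the simplex (tiny-`n`
pathology), bounds are minimally relaxed toward feasibility.

**Large alphabets (m >> n).** No usable confidence region exists, so the
class is the *leave-one-out* (LOO) class: the estimates obtained by deleting
one observation each. Deleting an occurrence of symbol `s` changes only
`count(s)`, so the class holds one distinct model per distinct observed
symbol, with multiplicities summing to `n`. For any *proper* base estimator
(finite expected KL; improvement `Delta_p(n)` eventually nonnegative and
non-increasing — checked empirically by `proper_diagnostic`), the best LOO
member is in expectation at least as good as the full-sample estimate up to
`O(1/n)`, which justifies aggregating the class by NML (constant regret
`Gamma`) or by uniform averaging. Performance is reported as regret against
the *natural oracle*: the KL-optimal estimator that knows `p` but must give
equal probability to symbols with equal observed counts (the group-average
of the true probabilities, count-zero group included).

## Simple Good–Turing

The Good–Turing base estimator follows Gale's recipe exactly (verified
against the canonical `edgeR::goodTuring` implementation to ~1e-10):
averaged frequency-of-frequency transform `Z_r = N_r / (0.5 (t - q))` with
`q, t` the neighboring observed frequencies; least-squares fit of
`log Z` on `log r`; smoothed counts `r* = r (1 + 1/r)^{b+1}`; the Turing
estimate `(r+1) N_{r+1} / N_r` is used for small `r` until it is within
`1.65` standard deviations of the smoothed value (or `N_{r+1} = 0`), after
which the smoothed value is used permanently. Total unseen mass is
`P0 = N_1 / n`, split uniformly over the `m - (observed distinct)` unseen
symbols (the alphabet size `m` is assumed known); seen probabilities are
scaled to `1 - P0`. Documented fallbacks: a single observed frequency makes
the regression impossible (raw counts are used); if every symbol was seen
but `N_1 > 0`, the unseen mass is redistributed proportionally (flagged).

## Numerical choices

- All internal arithmetic is in nats; reported quantities default to bits.
- Continuous KL integrals: tensor Gauss–Hermite with 200 nodes per axis for
  `d <= 2` (doubling the node count moves results by < 1e-6 nats on the
  fixture densities), seeded Monte Carlo with 200,000 draws for `d > 2`.
  Tiny negative round-off (|value| < 1e-9 nats) is clamped to zero;
  divergence against an estimate that vanishes on the support is reported
  as `inf`, not raised, so simulation reports can tally unbounded
  replicates.
- Blahut–Arimoto: deterministic uniform-prior initialization (tie-break
  free), multiplicative update, convergence when the capacity gap
  (max minus average divergence) drops below 1e-9 bits, at most 10,000
  iterations; unconverged runs are flagged, never silently accepted. The
  lower bound is monotone per iteration and is checked in tests.
- Region discretization (the solver needs finite supports): `d = 1` uses
  the two interval endpoints plus an optional uniform interior grid (the
  prior prunes interior points when the endpoints suffice); `d = 2` uses
  360 equally spaced boundary angles. The evaluation grid is a trapezoid
  rule in the whitened sample space, step 0.02 (`d=1`) / 0.15 (`d=2`),
  extending 7 standard deviations beyond the region — rapidly decaying
  smooth integrands make the trapezoid rule effectively spectrally
  accurate here.
- The projected-mixture full class for the Gaussian interval is a symmetric
  mean grid extending 4 interval-widths beyond the interval, spacing 0.01
  widths by default (configurable); the KL projection onto the ellipsoid is
  a radial clip in the whitened frame, and onto the box–simplex polytope a
  KKT water-filling `q_i = clip(p_i / lambda, l_i, u_i)` solved by
  bisection on the multiplier.

## Simulation harness

The protocol mirrors the benchmark studies: for each sample size `n`, draw
`k` replicates, fit every estimator on each, and report the mean, variance
and maximum (with the attaining replicate index, for audit) of the KL
divergence from the truth — or of the per-draw regret against the natural
oracle. Replicates are paired across estimators (all see the same draws),
and the replicate stream is keyed by `(master_seed, n, replicate)` so every
cell is bit-reproducible. Replicates with unbounded divergence are excluded
from mean/variance and counted separately. For Gaussian experiments the
sample mean is drawn directly from `N(mu, Sigma/n)` — it is sufficient for
every estimator involved — rather than materializing `n` raw draws.

Two readings of "worst-case regret" are possible: the maximum over
replicates of the per-draw difference, or the difference of the two maxima.
The per-draw reading is used: it is the quantity the LOO construction
controls, and the difference-of-maxima reading produces values an order of
magnitude smaller than the documented behavior of these estimators.

The uniform LOO average weights each left-out sample index equally
(multiplicity weighting), matching the class's per-index definition;
distinct-uniform weighting is available as an option.

## Synthetic generators and what passing tests show

The generators produce exactly the benchmark families: Zipf `p(i) ~ i^{-s}`
(the heavy-tailed regime where unseen-mass estimation is hard), geometric
`p(i) ~ (1-s)^{i-1} s` truncated at `m` and renormalized (truncation
handling is this package's choice; the tail beyond `m` is negligible for
the default `s = 0.05, m = 1000`), uniform, and Gaussian with known
covariance. They emulate i.i.d. sampling only: no dependence, drift,
contamination, or misspecified covariance. Tests passing on these fixtures
therefore certify the estimators' minimax/regret properties under correct
i.i.d. sampling, not robustness to violations of it (the projected mixture
and NML are precisely the tools whose *guarantees* survive
misspecification, but the simulations here do not exercise misspecified
generators).

A caution on worst-case cells: the maximum over 10,000 replicates of a
heavy-tailed regret distribution is a high-quantile estimate with
substantial seed-to-seed variability. Orderings between estimators are
stable across seeds; second-digit levels are not.

## Known limitations

- Closed-form sphere mixtures and region discretization cover `d <= 2`;
  higher-dimensional ellipsoids would need sphere quadrature and the
  user-supplied `r_d` threshold.
- Vertex enumeration is exponential in `m` (guarded at `m <= 16`); large-`m`
  multinomial regions should use the LOO route instead.
- The Sison–Glaz Edgeworth approximation degrades for very small `n` or
  very few categories; degenerate boxes are relaxed to feasibility rather
  than refused.
- NML for general continuous classes is approximated by the finite-class
  formula on a discretization grid; only the mean-interval class has an
  exact continuous normalizer.
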