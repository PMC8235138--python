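"""Large-alphabet probability estimation and leave-one-out model classes.

When the alphabet size ``m`` is large relative to the sample size ``n``,
plug-in estimates fail (zero mass on unseen symbols gives unbounded KL
loss) and no usable confidence region exists.  The restricted model class
is instead built from the data itself: the *leave-one-out* (LOO) class
collects the ``n`` estimates obtained by deleting one observation each.
For any *proper* base estimator the best LOO member is, in expectation, at
least as good as the full-sample estimate up to an ``O(1/n)`` term, which
justifies aggregating the class by NML or by uniform averaging.

Base estimators: maximum likelihood, add-constant (Krichevsky-Trofimov at
``const = 1/2``, Laplace at ``1``), and Simple Good-Turing following
Gale's recipe (log-log smoothing of the frequency-of-frequencies with the
standard-deviation switch rule).

The *natural oracle* knows the true distribution but must assign equal
probability to symbols with equal observed counts; it is the KL-optimal
count-measurable estimate and serves as the lower-bound baseline for
regret reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np

from .divergence import DiscreteDistribution, kl_from_probs
from .nml import NMLResult, nml_finite
from .regions import FiniteModelClass

__all__ = [
    "CountVector",
    "LooClass",
    "mle_counts",
    "add_constant",
    "simple_good_turing",
    "loo_class",
    "loo_class_from_counts",
    "loo_nml",
    "uniform_mixture",
    "natural_oracle",
    "natural_oracle_probs",
    "proper_diagnostic",
    "base_estimator",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class CountVector:
    """Symbol counts ``n_i`` over an alphabet of known size ``m``."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.size < 1:
            raise ValueError("alphabet size must be >= 1")
        if np.any(c < 0) or not np.all(np.equal(np.mod(c, 1), 0)):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def m(self) -> int:
        return self.counts.size


def mle_counts(c: CountVector) -> DiscreteDistribution:
    """Empirical frequencies ``n_i / n``; zero mass on unseen symbols."""
    if c.n == 0:
        raise ValueError("MLE undefined for n = 0")
    return DiscreteDistribution(c.counts / c.n)


def add_constant(c: CountVector, const: float = 0.5) -> DiscreteDistribution:
    """``(n_i + const) / (n + m*const)``; ``const = 1/2`` is Krichevsky-Trofimov."""
    if const <= 0:
        raise ValueError("const must be positive")
    return DiscreteDistribution((c.counts + const) / (c.n + c.m * const))


# ---------------------------------------------------------------------------
# Simple Good-Turing (Gale's recipe)
# ---------------------------------------------------------------------------

def _sgt_smoothed_counts(r: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Adjusted counts r* for each observed frequency, Gale's switch rule.

    ``r`` are the distinct observed frequencies (ascending) and ``N`` the
    number of symbols at each.  The log-log regression uses averaged
    frequency-of-frequency values Z_r = N_r / (0.5 (t - q)) with q, t the
    neighboring observed frequencies.  The Turing estimate is used for a
    frequency while it differs from the smoothed value by more than 1.65
    standard deviations; once they agree (or N_{r+1} is unavailable) the
    smoothed estimate is used for all larger frequencies.
    """
    k = r.size
    if k == 1:
        # regression impossible; fall back to the Turing estimate when the
        # next frequency count exists (it never does here), else raw r
        return r.astype(float)
    q = np.concatenate(([0.0], r[:-1].astype(float)))
    t = np.concatenate((r[1:].astype(float), [2.0 * r[-1] - r[-2]]))
    Z = N / (0.5 * (t - q))
    logr = np.log(r.astype(float))
    logZ = np.log(Z)
    # least-squares slope/intercept of log Z on log r
    b, a = np.polyfit(logr, logZ, 1)
    r_smooth = r * (1.0 + 1.0 / r) ** (b + 1.0)

    nr_of: Dict[int, float] = {int(rv): float(nv) for rv, nv in zip(r, N)}
    rstar = np.empty(k)
    switched = False
    for j in range(k):
        rj = int(r[j])
        if not switched:
            n_next = nr_of.get(rj + 1, 0.0)
            if n_next <= 0:
                switched = True
            else:
                turing = (rj + 1.0) * n_next / nr_of[rj]
                sd = math.sqrt(
                    (rj + 1.0) ** 2 * (n_next / nr_of[rj] ** 2) * (1.0 + n_next / nr_of[rj])
                )
                if abs(turing - r_smooth[j]) <= 1.65 * sd:
                    switched = True
                else:
                    rstar[j] = turing
                    continue
        rstar[j] = r_smooth[j]
    return rstar


def sgt_probs_from_counts(counts: np.ndarray, flagged: Optional[list] = None) -> np.ndarray:
    """Raw-array Simple Good-Turing probabilities over the full alphabet."""
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if n < 1:
        raise ValueError("Good-Turing undefined for n = 0")
    m = counts.size
    observed = counts > 0
    m0 = int(m - observed.sum())
    r, N = np.unique(counts[observed], return_counts=True)
    rstar = _sgt_smoothed_counts(r, N.astype(float))
    n1 = float(N[r == 1][0]) if np.any(r == 1) else 0.0
    p0 = n1 / n
    total = float(np.sum(N * rstar))
    if total <= 0:  # degenerate smoothing; fall back to raw counts
        rstar = r.astype(float)
        total = float(np.sum(N * rstar))
    weight_of = dict(zip(r.tolist(), (rstar / total).tolist()))
    probs = np.zeros(m)
    seen_scale = 1.0 - p0
    for rv, wv in weight_of.items():
        probs[counts == rv] = seen_scale * wv
    if m0 > 0:
        probs[~observed] = p0 / m0
    elif p0 > 0:
        # no unseen symbols to carry the Good-Turing missing mass:
        # redistribute it proportionally over the seen estimates
        if flagged is not None:
            flagged.append("unseen-mass-redistributed")
        probs = probs / probs.sum()
    s = probs.sum()
    if s <= 0:
        raise RuntimeError("Good-Turing produced an empty estimate")
    return probs / s


def simple_good_turing(c: CountVector) -> DiscreteDistribution:
    """Simple Good-Turing estimate with unseen mass ``N_1/n`` spread uniformly."""
    return DiscreteDistribution(sgt_probs_from_counts(c.counts))


# ---------------------------------------------------------------------------
# Base-estimator registry and the leave-one-out class
# ---------------------------------------------------------------------------

def base_estimator(name: str, const: float = 0.5) -> Callable[[np.ndarray], np.ndarray]:
    """Resolve an estimator identifier to a raw counts -> probs function."""
    if name in ("mle",):
        def f(counts):
            n = counts.sum()
            if n == 0:
                raise ValueError("MLE undefined for n = 0")
            return counts / n
        return f
    if name in ("kt", "add_half"):
        return lambda counts: (counts + 0.5) / (counts.sum() + 0.5 * counts.size)
    if name in ("laplace",):
        return lambda counts: (counts + 1.0) / (counts.sum() + counts.size)
    if name in ("add_constant",):
        return lambda counts: (counts + const) / (counts.sum() + const * counts.size)
    if name in ("good_turing", "sgt"):
        return sgt_probs_from_counts
    raise ValueError(f"unknown base estimator: {name!r}")


@dataclass
class LooClass:
    """Distinct leave-one-out estimates with their multiplicities.

    Deleting one occurrence of symbol ``s`` changes the counts only at
    ``s``, so the class has at most one distinct model per distinct
    observed symbol; ``multiplicities`` records how many left-out sample
    indices map to each model and sums to ``n``.
    """

    base_name: str
    models: FiniteModelClass
    multiplicities: np.ndarray

    def __post_init__(self) -> None:
        if len(self.models) != self.multiplicities.size:
            raise ValueError("one multiplicity per model required")

    def matrix(self) -> np.ndarray:
        return self.models.as_matrix()


def loo_class_from_counts(
    c: CountVector, base: str = "good_turing", const: float = 0.5
) -> LooClass:
    """Leave-one-out class from sufficient statistics (the counts)."""
    if c.n < 2:
        raise ValueError("leave-one-out requires n >= 2")
    fn = base_estimator(base, const)
    rows: List[np.ndarray] = []
    mult: List[int] = []
    work = c.counts.astype(np.int64).copy()
    seen: Dict[tuple, int] = {}
    for s in np.flatnonzero(work):
        work[s] -= 1
        probs = fn(work)
        work[s] += 1
        key = tuple(np.round(probs, 12))
        if key in seen:
            mult[seen[key]] += int(c.counts[s])
        else:
            seen[key] = len(rows)
            rows.append(probs)
            mult.append(int(c.counts[s]))
    models = FiniteModelClass([DiscreteDistribution(p) for p in rows])
    return LooClass(base, models, np.asarray(mult, dtype=np.int64))


def loo_class(
    sample: Sequence[int], base: str = "good_turing", m: Optional[int] = None,
    const: float = 0.5,
) -> LooClass:
    """Leave-one-out class from a raw symbol sequence (0-based indices)."""
    sample = np.asarray(sample, dtype=np.int64)
    if sample.size < 2:
        raise ValueError("leave-one-out requires n >= 2")
    if m is None:
        m = int(sample.max()) + 1
    counts = np.bincount(sample, minlength=m)
    return loo_class_from_counts(CountVector(counts), base=base, const=const)


def loo_nml(cls: LooClass) -> NMLResult:
    """NML aggregation of the leave-one-out class (constant-regret estimator)."""
    return nml_finite(cls.models)


def uniform_mixture(
    cls: LooClass, weighting: str = "multiplicity"
) -> DiscreteDistribution:
    """Average of the LOO class members.

    ``multiplicity`` (default) weights each left-out sample index equally,
    matching the class's per-index definition; ``distinct-uniform``
    weights each distinct model equally.
    """
    W = cls.matrix()
    if weighting == "multiplicity":
        w = cls.multiplicities / cls.multiplicities.sum()
    elif weighting in ("distinct-uniform", "uniform"):
        w = np.full(len(cls.models), 1.0 / len(cls.models))
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")
    return DiscreteDistribution(w @ W)


# ---------------------------------------------------------------------------
# Natural oracle and the proper-estimator diagnostic
# ---------------------------------------------------------------------------

def natural_oracle_probs(p_true: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Group-averaged truth: KL-optimal among count-measurable estimates.

    Symbols are grouped by their observed count (count 0 included); every
    symbol in a group receives the group's average true probability,
    which minimizes ``D(p_true || q)`` over assignments constant within
    groups.
    """
    counts = np.asarray(counts)
    probs = np.empty_like(np.asarray(p_true, dtype=float))
    for v in np.unique(counts):
        idx = counts == v
        probs[idx] = p_true[idx].sum() / idx.sum()
    return probs


def natural_oracle(p_true: DiscreteDistribution, c: CountVector) -> DiscreteDistribution:
    if p_true.alphabet_size != c.m:
        raise ValueError("alphabet size mismatch")
    return DiscreteDistribution(natural_oracle_probs(p_true.probs, c.counts))


def proper_diagnostic(
    base: str,
    p_true: DiscreteDistribution,
    n_grid: Sequence[int],
    reps: int = 1000,
    seed: int = 0,
    const: float = 0.5,
) -> dict:
    """Monte-Carlo check of the proper-estimator conditions.

    Estimates the improvement rate ``Delta_p(n) = E[KL(p||q_n)] -
    E[KL(p||q_{n+1})]`` with coupled samples (the size-``n`` sample is the
    size-``n+1`` sample minus one uniformly chosen draw) and reports, per
    ``n``: the estimate, its standard error, and the fraction of finite
    replicates.  The three conditions -- finite expected loss,
    ``Delta_p(n) >= 0``, and ``Delta_p(n)`` non-increasing -- are assessed
    within two standard errors.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    fn = base_estimator(base, const)
    rng = np.random.default_rng(seed)
    p = p_true.probs
    rows = {}
    deltas = []
    for n in n_grid:
        vals = np.empty(reps)
        finite = 0
        for r in range(reps):
            counts_np1 = rng.multinomial(n + 1, p)
            # remove one uniformly chosen observation
            drop = rng.choice(p.size, p=counts_np1 / (n + 1))
            counts_n = counts_np1.copy()
            counts_n[drop] -= 1
            kl_n = kl_from_probs(p, fn(counts_n)) / _LN2
            kl_np1 = kl_from_probs(p, fn(counts_np1)) / _LN2
            if math.isfinite(kl_n) and math.isfinite(kl_np1):
                vals[r] = kl_n - kl_np1
                finite += 1
            else:
                vals[r] = math.nan
        ok = vals[np.isfinite(vals)]
        delta = float(np.mean(ok)) if ok.size else math.inf
        se = float(np.std(ok, ddof=1) / math.sqrt(ok.size)) if ok.size > 1 else math.inf
        rows[int(n)] = {
            "delta_bits": delta,
            "se_bits": se,
            "finite_fraction": finite / reps,
        }
        deltas.append((delta, se))
    finite_ok = all(v["finite_fraction"] == 1.0 for v in rows.values())
    nonneg_ok = all(d >= -2.0 * s for d, s in deltas)
    monotone_ok = all(
        deltas[i + 1][0] <= deltas[i][0] + 2.0 * math.hypot(deltas[i][1], deltas[i + 1][1])
        for i in range(len(deltas) - 1)
    )
    return {
        "base": base,
        "per_n": rows,
        "finite_expected_loss": finite_ok,
        "improvement_nonnegative": nonneg_ok,
        "improvement_nonincreasing": monotone_ok,
    }
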