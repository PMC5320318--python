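"""Bayesian Monte-Carlo odds-ratio inference for a 2x2 table.

The model places independent uniform priors on the exposure proportions of the
two groups; observing ``n`` exposed and ``n'`` unexposed chromosomes gives a
Beta(n+1, n'+1) posterior per group. The posterior of the odds ratio

    OR = [p1/(1-p1)] / [p2/(1-p2)]

has no convenient closed form, so it is summarized by simulation: draw the two
proportions, form OR draws, and read point estimate, credible bounds and tail
probabilities off the empirical distribution. The tail mass below/above 1 is
the posterior evidence for a protective/risk effect; the reported p-value is
the smaller of the two masses.

With a zero margin on one side the posterior mass piles up toward 0 or
infinity; following the usual display convention the point estimate and the
outer credible bound are then reported as 0 / inf while the inner bound and the
tail probabilities remain well defined (the uniform prior regularizes them).

``bayes_or_exact`` computes the same functionals by deterministic quadrature
over the two Beta densities and serves as the independent oracle for the
Monte-Carlo path in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .tables_io import ContingencyTable2x2

Sided = Literal["one", "two"]


@dataclass(frozen=True)
class BetaPosterior:
    """Beta(alpha, beta) posterior of a proportion under the uniform prior."""

    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def dist(self):
        return stats.beta(self.alpha, self.beta)


@dataclass(frozen=True)
class BayesORResult:
    or_point: float
    ci_low: float
    ci_high: float
    p_less: float
    p_greater: float
    p_reported: float
    n_draws: int
    seed: int | None
    sided: Sided

    def as_dict(self) -> dict[str, object]:
        return {
            "or_point": self.or_point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_less": self.p_less,
            "p_greater": self.p_greater,
            "p_reported": self.p_reported,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "sided": self.sided,
        }


def beta_posterior(n_success: int, n_failure: int) -> BetaPosterior:
    """Posterior of a proportion after ``n_success``/``n_failure`` observations.

    With no data this is Beta(1, 1), the uniform prior itself.
    """
    if n_success < 0 or n_failure < 0:
        raise ValueError("counts must be non-negative")
    return BetaPosterior(n_success + 1, n_failure + 1)


def _finalize(
    or_point: float,
    ci_low: float,
    ci_high: float,
    p_less: float,
    p_greater: float,
    t: ContingencyTable2x2,
    n_draws: int,
    seed: int | None,
    sided: Sided,
) -> BayesORResult:
    # mirror the classical display convention for degenerate tables: point and
    # outer bound shown as inf (resp. 0) exactly when the sample OR is; tables
    # degenerate on both diagonals keep their posterior summaries as computed
    inf_like = (t.b == 0 or t.c == 0) and t.a > 0 and t.d > 0
    zero_like = (t.a == 0 or t.d == 0) and t.b > 0 and t.c > 0
    if inf_like:
        or_point = math.inf
        ci_high = math.inf
    elif zero_like:
        or_point = 0.0
        ci_low = 0.0
    if sided == "one":
        if or_point > 1 or math.isinf(or_point):
            ci_high = math.inf
        else:
            ci_low = 0.0
    return BayesORResult(
        or_point=or_point,
        ci_low=ci_low,
        ci_high=ci_high,
        p_less=p_less,
        p_greater=p_greater,
        p_reported=min(p_less, p_greater),
        n_draws=n_draws,
        seed=seed,
        sided=sided,
    )


def bayes_or_test(
    t: ContingencyTable2x2,
    n_draws: int = 1_000_000,
    seed: int = 0,
    sided: Sided = "one",
) -> BayesORResult:
    """Monte-Carlo posterior summary of the odds ratio of a 2x2 table.

    Parameters
    ----------
    t
        Counts (a, b) for group 1 and (c, d) for group 2, exposed/unexposed.
    n_draws
        Number of simulated (p1, p2) pairs; at least 10,000.
    seed
        Seeds a PCG64 generator; identical (table, seed, n_draws) give a
        bit-identical result.
    sided
        ``"one"`` reports the 95% bound in the direction of the effect
        ([5th pct, inf) when the point estimate exceeds 1, (0, 95th pct]
        otherwise); ``"two"`` reports the equal-tailed 2.5/97.5 interval.
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be at least 10,000")
    rng = np.random.default_rng(seed)
    p1 = rng.beta(t.a + 1, t.b + 1, size=n_draws)
    p2 = rng.beta(t.c + 1, t.d + 1, size=n_draws)
    log_or = (np.log(p1) - np.log1p(-p1)) - (np.log(p2) - np.log1p(-p2))
    p_less = float(np.mean(log_or < 0))
    p_eq = float(np.mean(log_or == 0))  # measure zero in theory; split if it occurs
    p_less += p_eq / 2
    p_greater = 1.0 - p_less
    med = float(np.exp(np.median(log_or)))
    if sided == "one":
        lo, hi = np.percentile(log_or, [5.0, 95.0])
        if med > 1:
            ci = (float(np.exp(lo)), math.inf)
        else:
            ci = (0.0, float(np.exp(hi)))
    else:
        lo, hi = np.percentile(log_or, [2.5, 97.5])
        ci = (float(np.exp(lo)), float(np.exp(hi)))
    return _finalize(med, ci[0], ci[1], p_less, p_greater, t, n_draws, seed, sided)


# ---------------------------------------------------------------------------
# deterministic quadrature oracle
# ---------------------------------------------------------------------------


def _cdf_log_or(t: ContingencyTable2x2, log_m: float, nodes: np.ndarray, weights: np.ndarray) -> float:
    """P(log OR < log_m) by Gauss-Legendre quadrature over the group-2 density."""
    b1 = stats.beta(t.a + 1, t.b + 1)
    b2 = stats.beta(t.c + 1, t.d + 1)
    m = math.exp(log_m)
    q2 = nodes / (1.0 - nodes)
    thr = m * q2 / (1.0 + m * q2)
    vals = b2.pdf(nodes) * b1.cdf(thr)
    return float(np.sum(weights * vals))


def bayes_or_exact(
    t: ContingencyTable2x2, grid_size: int = 4096, sided: Sided = "one"
) -> BayesORResult:
    """Quadrature counterpart of :func:`bayes_or_test` (no randomness).

    Integrates the posterior CDF of the odds ratio on a ``grid_size``-node
    Gauss-Legendre rule; the median and percentile bounds are found by root
    finding on that CDF.
    """
    if grid_size < 512:
        raise ValueError("grid_size must be at least 512")
    x, w = np.polynomial.legendre.leggauss(grid_size)
    nodes = 0.5 * (x + 1.0)
    weights = 0.5 * w

    def cdf(log_m: float) -> float:
        return _cdf_log_or(t, log_m, nodes, weights)

    p_less = cdf(0.0)
    p_greater = 1.0 - p_less

    def quantile(q: float) -> float:
        f = lambda lm: cdf(lm) - q
        lo, hi = -1.0, 1.0
        while f(lo) > 0 and lo > -60:
            lo *= 2
        while f(hi) < 0 and hi < 60:
            hi *= 2
        return math.exp(optimize.brentq(f, lo, hi, xtol=1e-12))

    med = quantile(0.5)
    if sided == "one":
        ci = (quantile(0.05), math.inf) if med > 1 else (0.0, quantile(0.95))
    else:
        ci = (quantile(0.025), quantile(0.975))
    return _finalize(med, ci[0], ci[1], p_less, p_greater, t, 0, None, sided)
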