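"""Independent oracles used to derive expected values.

Everything here is deliberately implemented through a different route than
the package: the normal CDF by numerical quadrature of the density, its
inverse by bisection, prevalences by explicit-genotype Monte Carlo, joint
genotype probabilities by full 3^m enumeration, and expectations by direct
series summation. None of it calls polyedit.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq


def quad_normal_cdf(x: float) -> float:
    """Φ(x) by adaptive quadrature of the standard normal density."""
    density = lambda u: math.exp(-0.5 * u * u) / math.sqrt(2.0 * math.pi)
    if x >= 0:
        tail, _ = quad(density, x, np.inf)
        return 1.0 - tail
    lower, _ = quad(density, -np.inf, x)
    return lower


def quad_normal_ppf(q: float) -> float:
    """Φ⁻¹(q) by bisection over the quadrature CDF."""
    return brentq(lambda x: quad_normal_cdf(x) - q, -10.0, 10.0, xtol=1e-12)


def quad_normal_pdf(x: float) -> float:
    return math.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)


def mc_edited_prevalence(
    K: float,
    ps: list[float],
    betas: list[float],
    n_draws: int,
    seed: int,
    edited: bool,
) -> tuple[float, float]:
    """Explicit-genotype Monte Carlo prevalence and its standard error.

    Genotypes x_i ~ Binomial(2, p_i) (HWE), genetic value
    g = Σ (x_i − 2p_i)β_i, residual e ~ N(0, 1 − var(g)), disease when
    g + e > t = Φ⁻¹(1−K). ``edited=True`` forces x_i = 0 at every locus.
    """
    rng = np.random.default_rng(seed)
    ps_arr = np.asarray(ps)
    betas_arr = np.asarray(betas)
    var_g = float(np.sum(2 * ps_arr * (1 - ps_arr) * betas_arr**2))
    t = quad_normal_ppf(1.0 - K)
    if edited:
        g = np.full(n_draws, -float(np.sum(2 * ps_arr * betas_arr)))
    else:
        x = rng.binomial(2, ps_arr, size=(n_draws, len(ps)))
        g = (x - 2 * ps_arr) @ betas_arr
    e = rng.normal(0.0, math.sqrt(1.0 - var_g), size=n_draws)
    hits = (g + e) > t
    phat = float(hits.mean())
    se = math.sqrt(max(phat * (1 - phat), 1e-30) / n_draws)
    return phat, se


def mc_shifted_prevalence(K: float, delta: float, n_draws: int, seed: int) -> tuple[float, float]:
    """Prevalence after a pure liability shift, by drawing standard-normal
    liabilities and counting exceedances of t + delta."""
    rng = np.random.default_rng(seed)
    t = quad_normal_ppf(1.0 - K)
    hits = rng.standard_normal(n_draws) > (t + delta)
    phat = float(hits.mean())
    return phat, math.sqrt(phat * (1 - phat) / n_draws)


def enumerate_joint_genotypes(ps: list[float]):
    """All 3^m multi-locus genotypes with their HWE × LE probabilities."""
    per_locus = [
        [(0, (1 - p) ** 2), (1, 2 * p * (1 - p)), (2, p * p)] for p in ps
    ]
    for combo in itertools.product(*per_locus):
        counts = tuple(c for c, _ in combo)
        prob = math.prod(pr for _, pr in combo)
        yield counts, prob


def poisson_expectation_series(lam: float, s: float, kmax: int = 50) -> float:
    """E[(1−s)^X] for X ~ Poisson(lam) by direct series summation."""
    total = 0.0
    for k in range(kmax + 1):
        total += math.exp(-lam) * lam**k / math.factorial(k) * (1 - s) ** k
    return total


def gini_pairwise(values) -> float:
    """Gini index by the O(n²) mean-absolute-pairwise-difference definition."""
    x = np.asarray(values, dtype=float)
    n = x.size
    mad = np.abs(x[:, None] - x[None, :]).sum() / (n * n)
    return mad / (2.0 * x.mean())
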