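"""Closed-form liability-threshold primitives.

Disease occurs when a latent liability ℓ = g + e exceeds a threshold t.
In the unedited population ℓ is standard normal (E[ℓ]=0, var[ℓ]=1), so the
threshold for lifetime prevalence K is t = Φ⁻¹(1−K). Genotype counts x_i at
locus i follow Hardy–Weinberg equilibrium (E[x_i]=2p_i,
var[x_i]=2p_i(1−p_i)); loci are in linkage equilibrium so multi-locus
genotype probabilities multiply. Editing shifts the mean liability of
carriers while the threshold and the residual variance convention
(var[e] = 1 − var[g], fixed at unedited values) stay unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "LiabilityThreshold",
    "threshold_from_prevalence",
    "prevalence_from_shift",
    "genotype_probability",
    "joint_genotype_probability",
    "PREVALENCE_FLOOR",
]

#: Prevalences below this are numerically indistinguishable from 0 and are
#: reported as 0.0 (with a warning).
PREVALENCE_FLOOR = 1e-12


@dataclass(frozen=True)
class LiabilityThreshold:
    """Consistent (K, t, z) triple: t = Φ⁻¹(1−K), z = φ(t), K = 1 − Φ(t)."""

    K: float
    t: float
    z: float


def threshold_from_prevalence(K: float) -> LiabilityThreshold:
    """Liability threshold and normal density for lifetime prevalence K."""
    if not (0.0 < K < 1.0):
        raise ValueError(f"prevalence K must be in (0,1), got {K}")
    t = float(norm.ppf(1.0 - K))
    return LiabilityThreshold(K=K, t=t, z=float(norm.pdf(t)))


def prevalence_from_shift(K: float, delta: float) -> float:
    """Prevalence among genomes whose mean liability is reduced by ``delta``.

    K_g = 1 − Φ(t + delta): editing m loci homozygous protective lowers the
    mean liability by delta = Σ 2p_iβ_i, so the edited subpopulation sits
    ``delta`` further below the (unchanged) threshold. Strictly decreasing
    in delta; equals K at delta = 0. Uses the normal survival function,
    accurate in both tails; values below :data:`PREVALENCE_FLOOR` are
    reported as exactly 0.
    """
    if not (0.0 < K < 1.0):
        raise ValueError(f"prevalence K must be in (0,1), got {K}")
    if not np.isfinite(delta):
        raise ValueError(f"delta must be finite, got {delta}")
    t = norm.ppf(1.0 - K)
    kg = float(norm.sf(t + delta))
    if kg < PREVALENCE_FLOOR:
        warnings.warn(
            f"edited prevalence {kg:.3e} below {PREVALENCE_FLOOR:g}; reporting 0",
            stacklevel=2,
        )
        return 0.0
    return kg


def genotype_probability(p: float, count: int) -> float:
    """Hardy–Weinberg probability of carrying ``count`` copies of an allele
    with frequency ``p``: (1−p)², 2p(1−p), p² for count 0, 1, 2."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"allele frequency must be in (0,1), got {p}")
    if count == 0:
        return (1.0 - p) ** 2
    if count == 1:
        return 2.0 * p * (1.0 - p)
    if count == 2:
        return p**2
    raise ValueError(f"genotype count must be 0, 1 or 2, got {count}")


def joint_genotype_probability(ps: Sequence[float], counts: Sequence[int]) -> float:
    """Multi-locus genotype probability under linkage equilibrium
    (product of per-locus HWE probabilities)."""
    if len(ps) != len(counts):
        raise ValueError("ps and counts must have equal length")
    prob = 1.0
    for p, c in zip(ps, counts):
        prob *= genotype_probability(p, c)
    return prob
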