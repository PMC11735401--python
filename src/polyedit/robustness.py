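"""Sensitivity and fitness-cost analyses for editing plans.

Covers four ways the headline predictions degrade in practice:
misidentified causal variants (edited loci with no true effect),
effect-size overestimation (winner's curse, stratification — a uniform
shrinkage of all effects), off-target mutational load (a fitness cost per
unintended edit), and stabilizing selection (fitness cost of moving a
phenotype far from its optimum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .editing_model import EditPlan, PredictionCurve, predict_curve
from .gwas_io import OrientedLocus

__all__ = [
    "MisidentificationSpec",
    "OffTargetParams",
    "StabilizingParams",
    "apply_misidentification",
    "shrink_effects",
    "offtarget_fitness",
    "stabilizing_fitness",
]


@dataclass(frozen=True)
class MisidentificationSpec:
    """1-based rank positions (within the ranked edit list) whose putative
    effect is actually zero."""

    null_indices: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "null_indices", frozenset(self.null_indices))
        if any(i < 1 for i in self.null_indices):
            raise ValueError("null_indices are 1-based rank positions (>= 1)")


@dataclass(frozen=True)
class OffTargetParams:
    """Off-target mutational load: each intended edit independently produces
    off-target mutations; each mutation multiplies fitness by (1−s).

    q: probability of an off-target effect per intended edit.
    s: selection coefficient per off-target mutation.
    lambda_mode: 'poisson' — counts X ~ Poisson(edits·q); 'binomial' —
    at most one off-target per edit, X ~ Binomial(edits, q).
    """

    q: float
    s: float
    edits: int
    lambda_mode: str = "poisson"

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"q must be in [0,1], got {self.q}")
        if not (0.0 <= self.s <= 1.0):
            raise ValueError(f"s must be in [0,1], got {self.s}")
        if self.edits < 0:
            raise ValueError(f"edits must be >= 0, got {self.edits}")
        if self.lambda_mode not in ("poisson", "binomial"):
            raise ValueError(f"unknown lambda_mode {self.lambda_mode!r}")


@dataclass(frozen=True)
class StabilizingParams:
    """Gaussian stabilizing-selection profile: fitness
    exp(−(z − optimum)²/(2·Vs)). Vs is the profile width in squared
    phenotypic s.d.; the conventional default 20 corresponds to weak
    selection on a one-s.d. displacement (fitness ≈ 0.975)."""

    Vs: float = 20.0
    optimum: float = 0.0

    def __post_init__(self) -> None:
        if self.Vs <= 0:
            raise ValueError(f"Vs must be > 0, got {self.Vs}")


def apply_misidentification(
    plan: EditPlan, spec: MisidentificationSpec
) -> PredictionCurve:
    """Prediction curve when some edited loci have no true effect.

    The effects at the specified rank positions are zeroed but the loci keep
    their slot in the ranking: the edit list was chosen believing them
    causal, so re-ranking would be information the editor does not have.
    With equal per-locus contributions the quantitative outcome falls
    exactly proportionally to the fraction misidentified; for diseases,
    nulling top-ranked loci costs disproportionately more because of the
    nonlinear liability→prevalence map.
    """
    n = min(plan.max_m, len(plan.loci))
    out_of_range = [i for i in spec.null_indices if i > n]
    if out_of_range:
        raise ValueError(
            f"null_indices {sorted(out_of_range)} exceed the {n} loci in the plan"
        )
    new_loci = [
        OrientedLocus(l.locus_id, l.p_undesirable, 0.0)
        if (rank + 1) in spec.null_indices
        else l
        for rank, l in enumerate(plan.loci)
    ]
    nulled = EditPlan(trait=plan.trait, loci=tuple(new_loci), max_m=plan.max_m, rg=plan.rg)
    return predict_curve(nulled)


def shrink_effects(plan: EditPlan, factor: float) -> PredictionCurve:
    """Prediction curve with every effect multiplied by ``factor`` ∈ (0,1].

    Models uniform effect-size overestimation: if estimates are 10% too
    large the true outcome is the factor-0.9 curve, and quantitative deltas
    scale exactly by the factor.
    """
    if not (0.0 < factor <= 1.0):
        raise ValueError(f"shrinkage factor must be in (0,1], got {factor}")
    shrunk = [
        OrientedLocus(l.locus_id, l.p_undesirable, l.beta * factor) for l in plan.loci
    ]
    return predict_curve(
        EditPlan(trait=plan.trait, loci=tuple(shrunk), max_m=plan.max_m, rg=plan.rg)
    )


def offtarget_fitness(params: OffTargetParams) -> float:
    """Expected relative fitness under cumulative off-target load,
    E[(1−s)^X].

    poisson mode: X ~ Poisson(λ = edits·q), whose generating function gives
    E[(1−s)^X] = exp(−λ·s) exactly. binomial mode: X ~ Binomial(edits, q),
    E[(1−s)^X] = (1 − q·s)^edits. Equals 1 when q, s or edits is 0 and is
    strictly decreasing in each argument when the others are positive.
    """
    lam = params.edits * params.q
    if params.lambda_mode == "poisson":
        return math.exp(-lam * params.s)
    return (1.0 - params.q * params.s) ** params.edits


def stabilizing_fitness(delta_z: float, params: StabilizingParams) -> float:
    """Relative fitness of a phenotype displaced ``delta_z`` phenotypic s.d.
    from the current mean under a Gaussian stabilizing-selection profile:
    exp(−(delta_z − optimum)²/(2·Vs)). Symmetric about the optimum, 1 at it."""
    d = delta_z - params.optimum
    return math.exp(-(d * d) / (2.0 * params.Vs))
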