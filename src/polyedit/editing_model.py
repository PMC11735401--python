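"""Prediction curves for edited genomes: prevalence / phenotype vs loci edited.

Editing the top-m ranked loci homozygous protective lowers the mean
liability (or phenotype) of edited genomes by delta_m = Σ_{i≤m} 2p_iβ_i.
For a disease with prevalence K and threshold t, the edited-genome
prevalence is K_g = 1 − Φ(t + r_g·delta_m), where r_g ∈ [0,1] is the
genetic correlation between the effects estimated in the current
environment and those realized in the future one (G×E attenuation; r_g = 1
means the environment is unchanged, r_g = 0 means the edits do nothing).
Uncertainty bands reflect between-genome variation in the realized gain:
its s.d. is the square root of the variance explained by the edited loci in
the unedited population, sqrt(Σ 2p_i(1−p_i)β_i²), and is applied to the
liability shift before the probit map to the prevalence scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gwas_io import OrientedLocus, TraitConfig
from .liability_core import prevalence_from_shift, threshold_from_prevalence

__all__ = [
    "EditPlan",
    "PredictionPoint",
    "PredictionCurve",
    "trait_shift",
    "sd_of_gain",
    "disease_curve",
    "quantitative_curve",
    "predict_curve",
    "population_mean_shift",
    "protective_genotype_probability",
]


@dataclass(frozen=True)
class EditPlan:
    """An editing strategy: which loci, how many, under what G×E attenuation.

    ``loci`` must already be ranked (see :func:`polyedit.gwas_io.rank_loci`);
    the plan edits the first 1…max_m of them in order.
    """

    trait: TraitConfig
    loci: tuple[OrientedLocus, ...]
    max_m: int = 10
    rg: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        if self.max_m < 1:
            raise ValueError(f"max_m must be >= 1, got {self.max_m}")
        if not (0.0 <= self.rg <= 1.0):
            raise ValueError(f"rg must be in [0,1], got {self.rg}")


@dataclass(frozen=True)
class PredictionPoint:
    """Prediction after editing the top ``m_edited`` loci.

    ``delta`` is the cumulative mean shift among edited genomes (liability
    s.d. for diseases — positive = risk reduction; phenotypic s.d. for
    quantitative traits — negative = trait reduction). ``band_low`` and
    ``band_high`` bracket the prediction one between-genome s.d. of the
    gain either side, on the prevalence scale for diseases and the
    phenotype scale otherwise.
    """

    m_edited: int
    delta: float
    sd_gain: float
    band_low: float
    band_high: float
    K_g: float | None = None
    fold_change: float | None = None


@dataclass(frozen=True)
class PredictionCurve:
    trait_name: str
    kind: str
    rg: float
    points: tuple[PredictionPoint, ...]

    def to_frame(self) -> pd.DataFrame:
        """Tidy DataFrame, one row per number of edited loci."""
        return pd.DataFrame(
            [
                {
                    "trait": self.trait_name,
                    "rg": self.rg,
                    "m": p.m_edited,
                    "delta": p.delta,
                    "sd_gain": p.sd_gain,
                    "K_g": p.K_g,
                    "fold_change": p.fold_change,
                    "band_low": p.band_low,
                    "band_high": p.band_high,
                }
                for p in self.points
            ]
        )


def trait_shift(
    loci: Sequence[OrientedLocus], m: int, direction: str = "decrease"
) -> float:
    """Mean phenotype change from editing the first m loci homozygous.

    decrease: all undesirable alleles removed (x_i = 0), shift −Σ 2p_iβ_i.
    increase: all undesirable alleles fixed (x_i = 2), shift +Σ 2(1−p_i)β_i.
    """
    if m > len(loci):
        raise ValueError(f"requested m={m} loci but only {len(loci)} available")
    if direction == "decrease":
        return -sum(2.0 * l.p_undesirable * l.beta for l in loci[:m])
    if direction == "increase":
        return sum(2.0 * (1.0 - l.p_undesirable) * l.beta for l in loci[:m])
    raise ValueError(f"direction must be 'decrease' or 'increase', got {direction!r}")


def sd_of_gain(loci: Sequence[OrientedLocus], m: int) -> float:
    """Between-genome s.d. of the editing gain: sqrt(Σ_{i≤m} 2p_i(1−p_i)β_i²),
    the square root of the variance the edited loci explain in the
    unedited population."""
    if m > len(loci):
        raise ValueError(f"requested m={m} loci but only {len(loci)} available")
    return math.sqrt(
        sum(2.0 * l.p_undesirable * (1.0 - l.p_undesirable) * l.beta**2 for l in loci[:m])
    )


def disease_curve(plan: EditPlan) -> PredictionCurve:
    """Edited-genome prevalence curve for a binary trait.

    For each m = 1…max_m: delta = Σ 2p_iβ_i, K_g = 1 − Φ(t + r_g·delta),
    fold change K/K_g, and one-s.d. bands 1 − Φ(t + r_g·delta ∓ sd_gain)
    (shift bands applied before the probit conversion).
    """
    trait = plan.trait
    if trait.kind != "binary":
        raise ValueError(f"disease_curve requires a binary trait, got {trait.kind!r}")
    assert trait.prevalence_K is not None
    K = trait.prevalence_K
    t = threshold_from_prevalence(K).t
    n_points = min(plan.max_m, len(plan.loci))
    points = []
    for m in range(1, n_points + 1):
        delta = -trait_shift(plan.loci, m, "decrease")  # Σ 2pβ ≥ 0
        sd = sd_of_gain(plan.loci, m)
        kg = prevalence_from_shift(K, plan.rg * delta)
        band_high = float(norm.sf(t + plan.rg * delta - sd))  # less gain → more risk
        band_low = float(norm.sf(t + plan.rg * delta + sd))
        points.append(
            PredictionPoint(
                m_edited=m,
                delta=delta,
                sd_gain=sd,
                K_g=kg,
                fold_change=(K / kg) if kg > 0 else math.inf,
                band_low=band_low,
                band_high=band_high,
            )
        )
    return PredictionCurve(trait.name, "binary", plan.rg, tuple(points))


def quantitative_curve(
    plan: EditPlan, in_units: bool = False, direction: str = "decrease"
) -> PredictionCurve:
    """Edited-genome mean-shift curve for a quantitative trait.

    delta_m = −r_g·Σ 2p_iβ_i (phenotypic s.d.) for the default
    trait-decreasing direction, +r_g·Σ 2(1−p_i)β_i for ``direction=
    "increase"``; bands are delta ± sd_gain. With ``in_units=True``
    everything is multiplied by the trait's phenotypic s.d. to give
    physical units.
    """
    trait = plan.trait
    if trait.kind != "quantitative":
        raise ValueError(
            f"quantitative_curve requires a quantitative trait, got {trait.kind!r}"
        )
    scale = 1.0
    if in_units:
        if trait.phenotypic_sd is None:
            raise ValueError(f"trait {trait.name!r} has no phenotypic_sd for unit conversion")
        scale = trait.phenotypic_sd
    n_points = min(plan.max_m, len(plan.loci))
    points = []
    for m in range(1, n_points + 1):
        delta = plan.rg * trait_shift(plan.loci, m, direction) * scale
        sd = sd_of_gain(plan.loci, m) * scale
        points.append(
            PredictionPoint(
                m_edited=m,
                delta=delta,
                sd_gain=sd,
                band_low=delta - sd,
                band_high=delta + sd,
            )
        )
    return PredictionCurve(trait.name, "quantitative", plan.rg, tuple(points))


def predict_curve(plan: EditPlan) -> PredictionCurve:
    """Dispatch to :func:`disease_curve` or :func:`quantitative_curve`."""
    if plan.trait.kind == "binary":
        return disease_curve(plan)
    return quantitative_curve(plan)


def population_mean_shift(delta_edited: float, fraction_edited: float) -> float:
    """Population-level mean change when only a fraction of genomes is edited:
    fraction × delta. A 5 s.d. reduction in 1% of genomes moves the
    population mean by just 0.05 s.d."""
    if not (0.0 <= fraction_edited <= 1.0):
        raise ValueError(f"fraction_edited must be in [0,1], got {fraction_edited}")
    return fraction_edited * delta_edited


def protective_genotype_probability(
    loci: Sequence[OrientedLocus], mode: str = "hom_protective"
) -> float:
    """Chance a random unedited genome already carries the protective
    genotype class at every locus (HWE within loci, independence across).

    hom_protective: homozygous protective everywhere, Π (1−p_i)².
    at_least_one_copy: at least one protective allele per locus, Π (1−p_i²).
    """
    if not loci:
        raise ValueError("protective_genotype_probability needs at least one locus")
    prob = 1.0
    for l in loci:
        if mode == "hom_protective":
            prob *= (1.0 - l.p_undesirable) ** 2
        elif mode == "at_least_one_copy":
            prob *= 1.0 - l.p_undesirable**2
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return prob
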