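"""Reading, validation and standardization of GWAS summary-statistic locus tables.

Input tables are tab-separated lists of genome-wide-significant (GWS) loci,
one file per trait, as published in GWAS papers: effect allele, other allele,
effect-allele frequency, per-allele effect (log odds ratio for diseases,
trait units for quantitative traits), standard error, sample size, p-value.
This module validates each row, re-expresses every locus in terms of the
*undesirable* allele (the allele that increases disease liability or moves a
biomarker in the harmful direction) on the model scale (liability standard
deviations for diseases, phenotypic standard deviations for quantitative
traits), and ranks loci for editing by the per-locus liability gain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "LocusRecord",
    "OrientedLocus",
    "TraitConfig",
    "SchemaError",
    "LocusValidationError",
    "read_locus_table",
    "orient_to_undesirable",
    "oriented_loci",
    "logor_to_liability",
    "liability_to_logor",
    "estimate_phenotypic_sd",
    "rank_loci",
    "write_oriented_table",
    "load_trait_configs",
]

VALID_ALLELE_CHARS = set("ACGTDI-")  # D/I/- cover indel codes


class SchemaError(ValueError):
    """A required column is missing or the table layout is unusable."""


class LocusValidationError(ValueError):
    """One or more rows violate locus-level invariants."""


@dataclass(frozen=True)
class TraitConfig:
    """Trait-level configuration.

    Binary traits carry a lifetime prevalence ``prevalence_K``; quantitative
    traits carry a phenotypic standard deviation ``phenotypic_sd`` with a
    ``units`` string (e.g. mmol/l, mmHg) used only for unit conversion of
    model-scale predictions.
    """

    name: str
    kind: str  # "binary" | "quantitative"
    prevalence_K: float | None = None
    phenotypic_sd: float | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "quantitative"):
            raise ValueError(f"kind must be 'binary' or 'quantitative', got {self.kind!r}")
        if self.kind == "binary":
            if self.prevalence_K is None or not (0.0 < self.prevalence_K < 1.0):
                raise ValueError(
                    f"binary trait {self.name!r} requires prevalence_K in (0,1), "
                    f"got {self.prevalence_K!r}"
                )
            if self.phenotypic_sd is not None:
                raise ValueError("binary trait must not set phenotypic_sd")
        else:
            if self.prevalence_K is not None:
                raise ValueError("quantitative trait must not set prevalence_K")
            if self.phenotypic_sd is not None and self.phenotypic_sd <= 0:
                raise ValueError("phenotypic_sd must be positive")


@dataclass(frozen=True)
class LocusRecord:
    """One GWAS summary-statistic row, as published (raw scale)."""

    locus_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta_raw: float
    se: float | None = None
    n_samples: int | None = None
    p_value: float | None = None
    trait_name: str = ""
    chrom: str | None = None
    pos: int | None = None
    is_gws: bool | None = None

    def validate(self) -> list[str]:
        """Return a list of human-readable invariant violations (empty if valid)."""
        problems: list[str] = []
        if not (0.0 < self.eaf < 1.0):
            problems.append(f"eaf must be in (0,1), got {self.eaf}")
        if not self.effect_allele or not self.other_allele:
            problems.append("alleles must be non-empty")
        elif self.effect_allele == self.other_allele:
            problems.append("effect_allele equals other_allele")
        else:
            for a in (self.effect_allele, self.other_allele):
                if not set(a.upper()) <= VALID_ALLELE_CHARS:
                    problems.append(f"allele {a!r} contains invalid characters")
        if self.se is not None and not self.se > 0:
            problems.append(f"se must be > 0, got {self.se}")
        if self.n_samples is not None and not self.n_samples > 0:
            problems.append(f"n_samples must be > 0, got {self.n_samples}")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            problems.append(f"p_value must be in [0,1], got {self.p_value}")
        if self.pos is not None and self.pos < 1:
            problems.append(f"pos must be >= 1, got {self.pos}")
        if not math.isfinite(self.beta_raw):
            problems.append(f"beta_raw must be finite, got {self.beta_raw}")
        return problems


@dataclass(frozen=True)
class OrientedLocus:
    """A locus re-expressed as the frequency and non-negative model-scale
    effect of the undesirable (risk- or trait-increasing) allele.

    ``beta`` is in liability s.d. for diseases and phenotypic s.d. for
    quantitative traits. ``rank_score = p_undesirable * beta`` is half the
    per-locus expected liability/phenotype gain 2pβ from editing the locus
    homozygous protective.
    """

    locus_id: str
    p_undesirable: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_undesirable < 1.0):
            raise ValueError(
                f"{self.locus_id}: p_undesirable must be in (0,1), got {self.p_undesirable}"
            )
        if self.beta < 0:
            raise ValueError(f"{self.locus_id}: beta must be >= 0, got {self.beta}")

    @property
    def rank_score(self) -> float:
        return self.p_undesirable * self.beta


# ---------------------------------------------------------------------------
# Scale conversion
# ---------------------------------------------------------------------------

def logor_to_liability(beta_logor: float, K: float) -> float:
    """Convert a log odds ratio to a liability-scale effect.

    Uses the standard probit approximation β = β_logOR · K(1−K)/z, where
    z = φ(t) is the standard-normal density at the liability threshold
    t = Φ⁻¹(1−K) for lifetime prevalence K. Linear and sign-preserving in
    ``beta_logor``.
    """
    if not (0.0 < K < 1.0):
        raise ValueError(f"prevalence K must be in (0,1), got {K}")
    t = norm.ppf(1.0 - K)
    z = norm.pdf(t)
    return beta_logor * K * (1.0 - K) / z


def liability_to_logor(beta_liability: float, K: float) -> float:
    """Inverse of :func:`logor_to_liability` (same multiplier, divided out)."""
    if not (0.0 < K < 1.0):
        raise ValueError(f"prevalence K must be in (0,1), got {K}")
    t = norm.ppf(1.0 - K)
    z = norm.pdf(t)
    return beta_liability * z / (K * (1.0 - K))


def estimate_phenotypic_sd(records: Sequence[LocusRecord]) -> float:
    """Estimate the phenotypic standard deviation of a quantitative trait.

    For a standardized trait the sampling variance of a per-allele estimate
    is se² ≈ 1/[2p(1−p)N]; on the raw scale it is multiplied by the
    phenotypic variance. The estimator is therefore
    sqrt(mean over loci of 2·p_i(1−p_i)·N_i·se_i²); it returns 1 when the
    source GWAS analysed a standardized trait.
    """
    if not records:
        raise ValueError("cannot estimate phenotypic s.d. from an empty table")
    missing = [r.locus_id for r in records if r.se is None or r.n_samples is None]
    if missing:
        raise ValueError(
            "phenotypic s.d. estimation needs se and n_samples for every locus; "
            f"missing for: {', '.join(missing)}"
        )
    terms = [
        2.0 * r.eaf * (1.0 - r.eaf) * r.n_samples * r.se**2  # type: ignore[operator]
        for r in records
    ]
    return float(np.sqrt(np.mean(terms)))


# ---------------------------------------------------------------------------
# Table reading
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS: Mapping[str, str] = {
    "locus_id": "locus_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta_raw": "beta",
    "se": "se",
    "n_samples": "n",
    "p_value": "p_value",
}

_REQUIRED_BINARY = ("effect_allele", "other_allele", "eaf", "beta_raw")
_REQUIRED_QUANTITATIVE = _REQUIRED_BINARY + ("se", "n_samples")


def read_locus_table(
    path: str | Path,
    trait: TraitConfig,
    column_map: Mapping[str, str] | None = None,
) -> list[LocusRecord]:
    """Read a tab-separated GWS locus table into validated records.

    ``column_map`` maps internal field names to the file's header names
    (source GWAS papers use heterogeneous headers); unmapped fields use
    :data:`DEFAULT_COLUMNS`. Lines starting with ``#`` are comments.
    Disease tables may omit se/N (effects go through the log-OR
    conversion); quantitative tables require them for the phenotypic-s.d.
    estimator. Raises :class:`SchemaError` for missing columns and
    :class:`LocusValidationError` listing offending rows otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = _REQUIRED_QUANTITATIVE if trait.kind == "quantitative" else _REQUIRED_BINARY
    missing = [cols[f] for f in required if cols[f] not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {', '.join(missing)} "
            f"for {trait.kind} trait {trait.name!r}"
        )

    records: list[LocusRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based, after the header line

        def get(fieldname: str, cast=float):
            col = cols[fieldname]
            if col not in df.columns:
                return None
            val = row[col]
            if pd.isna(val) or val == "":
                return None
            return cast(val)

        try:
            rec = LocusRecord(
                locus_id=str(get("locus_id", str) or f"{path.stem}_row{rownum}"),
                chrom=get("chrom", str),
                pos=get("pos", lambda v: int(float(v))),
                effect_allele=str(get("effect_allele", str) or ""),
                other_allele=str(get("other_allele", str) or ""),
                eaf=float(row[cols["eaf"]]),
                beta_raw=float(row[cols["beta_raw"]]),
                se=get("se"),
                n_samples=get("n_samples", lambda v: int(float(v))),
                p_value=get("p_value"),
                trait_name=trait.name,
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"row {rownum}: unparseable ({exc})")
            continue
        problems = rec.validate()
        if trait.kind == "quantitative" and (rec.se is None or rec.n_samples is None):
            problems.append("quantitative trait requires se and n")
        if problems:
            errors.append(f"row {rownum} ({rec.locus_id}): " + "; ".join(problems))
        else:
            records.append(rec)
    if errors:
        raise LocusValidationError(f"{path.name}: " + " | ".join(errors))
    return records


# ---------------------------------------------------------------------------
# Orientation and ranking
# ---------------------------------------------------------------------------

def orient_to_undesirable(
    record: LocusRecord,
    trait: TraitConfig,
    phenotypic_sd: float | None = None,
) -> OrientedLocus:
    """Re-express a locus as (frequency, effect ≥ 0) of the undesirable allele.

    If ``beta_raw`` is stated for the protective allele (negative), the
    orientation flips to the other allele: frequency 1−eaf, effect −beta_raw.
    Disease effects (log odds ratios) are converted to the liability scale;
    quantitative effects are divided by ``phenotypic_sd`` when given
    (pass the :func:`estimate_phenotypic_sd` output for raw-unit tables;
    omit it when effects are already in phenotypic s.d.).
    """
    if record.beta_raw == 0:
        warnings.warn(
            f"{record.locus_id}: zero effect size; locus retained with beta=0",
            stacklevel=2,
        )
    if record.beta_raw < 0:
        p, b = 1.0 - record.eaf, -record.beta_raw
    else:
        p, b = record.eaf, record.beta_raw
    if trait.kind == "binary":
        assert trait.prevalence_K is not None
        b = logor_to_liability(b, trait.prevalence_K)
    elif phenotypic_sd is not None:
        b = b / phenotypic_sd
    return OrientedLocus(locus_id=record.locus_id, p_undesirable=p, beta=b)


def oriented_loci(
    records: Sequence[LocusRecord],
    trait: TraitConfig,
    standardize: bool = True,
) -> list[OrientedLocus]:
    """Orient a whole table to the undesirable allele on the model scale.

    For quantitative traits with ``standardize=True`` the phenotypic s.d. is
    estimated from the table itself (se/N identity) and divided out, so the
    returned effects are in phenotypic standard deviations.
    """
    sd = None
    if trait.kind == "quantitative" and standardize:
        sd = estimate_phenotypic_sd(records)
    return [orient_to_undesirable(r, trait, phenotypic_sd=sd) for r in records]


def rank_loci(loci: Sequence[OrientedLocus], max_m: int) -> list[OrientedLocus]:
    """Order loci for editing by decreasing p_undesirable × beta.

    The product is half the expected per-locus liability (or phenotype) gain
    2pβ from fixing the locus homozygous protective, so this ordering edits
    the most valuable loci first. Ties break lexicographically on locus_id
    for determinism. Returns at most ``max_m`` loci.
    """
    if max_m < 1:
        raise ValueError(f"max_m must be >= 1, got {max_m}")
    if not loci:
        warnings.warn("rank_loci called with an empty locus list", stacklevel=2)
        return []
    ordered = sorted(loci, key=lambda l: (-l.rank_score, l.locus_id))
    return ordered[:max_m]


def write_oriented_table(loci: Iterable[OrientedLocus], path: str | Path) -> None:
    """Write oriented loci as a normalized TSV (locus_id, p, beta, rank_score)."""
    df = pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "p_undesirable": l.p_undesirable,
                "beta_model_scale": l.beta,
                "rank_score": l.rank_score,
            }
            for l in loci
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def load_trait_configs(
    path: str | Path,
) -> tuple[dict[str, TraitConfig], dict[str, str]]:
    """Load trait configurations and an optional column mapping from YAML.

    Layout::

        traits:
          AD:  {kind: binary, prevalence: 0.05}
          LDL: {kind: quantitative, sd: 0.4, units: mmol/l}
        columns:
          eaf: EAF

    Returns ``(traits, column_map)``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    traits: dict[str, TraitConfig] = {}
    for name, cfg in (raw.get("traits") or {}).items():
        kind = cfg["kind"]
        traits[name] = TraitConfig(
            name=name,
            kind=kind,
            prevalence_K=cfg.get("prevalence") if kind == "binary" else None,
            phenotypic_sd=cfg.get("sd") if kind == "quantitative" else None,
            units=cfg.get("units"),
        )
    column_map = {str(k): str(v) for k, v in (raw.get("columns") or {}).items()}
    return traits, column_map
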