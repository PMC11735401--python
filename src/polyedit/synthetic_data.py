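"""Synthetic GWS-locus tables with the statistical structure the model assumes.

Generates true locus effects (frequency–effect coupling emulating negative
selection, under which large-effect variants segregate at lower
frequencies), noisy GWAS estimates with standard errors consistent with a
given sample size, two-sided p-values and a genome-wide-significance
filter — so every pipeline stage, including winner's-curse behaviour of
significance-selected estimates, is testable without any download. All
emitted tables are clearly labelled SYNTHETIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gwas_io import (
    LocusRecord,
    OrientedLocus,
    TraitConfig,
    liability_to_logor,
)

__all__ = [
    "SyntheticConfig",
    "TRAIT_PRESETS",
    "simulate_true_loci",
    "simulate_gwas_estimates",
    "filter_gws",
    "records_to_frame",
    "write_locus_table",
    "make_disease_fixture",
    "winners_curse_experiment",
]

#: The ten modelled traits: five common diseases with their lifetime
#: prevalences and five quantitative biomarkers with plausible phenotypic
#: s.d. values used only for unit conversion of s.d.-scale predictions.
TRAIT_PRESETS: dict[str, TraitConfig] = {
    "AD": TraitConfig("AD", "binary", prevalence_K=0.05),
    "SCZ": TraitConfig("SCZ", "binary", prevalence_K=0.01),
    "T2D": TraitConfig("T2D", "binary", prevalence_K=0.10),
    "CAD": TraitConfig("CAD", "binary", prevalence_K=0.06),
    "MDD": TraitConfig("MDD", "binary", prevalence_K=0.15),
    "FG": TraitConfig("FG", "quantitative", phenotypic_sd=0.8, units="mmol/l"),
    "LDL": TraitConfig("LDL", "quantitative", phenotypic_sd=0.4, units="mmol/l"),
    "TG": TraitConfig("TG", "quantitative", phenotypic_sd=1.0, units="mmol/l"),
    "SBP": TraitConfig("SBP", "quantitative", phenotypic_sd=18.0, units="mmHg"),
    "DBP": TraitConfig("DBP", "quantitative", phenotypic_sd=10.0, units="mmHg"),
}

_ALLELES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    freq_dist: ("uniform", lo, hi) or ("beta", a, b) for undesirable-allele
    frequencies. effect_sd is the s.d. of true effects on the model scale at
    2p(1−p) = 1; coupling_alpha couples effect variance to heterozygosity,
    var(β) ∝ [2p(1−p)]^alpha — 0 decouples them, negative values make rarer
    alleles larger-effect (alpha = −1 equalizes expected per-locus variance
    contributions 2p(1−p)β²). Defaults describe a modern well-powered GWAS:
    40 candidate loci, frequencies uniform on (0.01, 0.99), effect_sd 0.05
    liability/phenotypic s.d., alpha −0.5, 100,000 samples, GWS threshold
    5e-8.
    """

    m_loci: int = 40
    freq_dist: tuple = ("uniform", 0.01, 0.99)
    effect_sd: float = 0.05
    coupling_alpha: float = -0.5
    n_gwas: int = 100_000
    gws_threshold: float = 5e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_loci < 1:
            raise ValueError(f"m_loci must be >= 1, got {self.m_loci}")
        if self.effect_sd <= 0:
            raise ValueError(f"effect_sd must be > 0, got {self.effect_sd}")
        if not (0.0 < self.gws_threshold < 1.0):
            raise ValueError(f"gws_threshold must be in (0,1), got {self.gws_threshold}")
        if self.n_gwas < 1:
            raise ValueError(f"n_gwas must be >= 1, got {self.n_gwas}")
        kind = self.freq_dist[0]
        if kind == "uniform":
            _, lo, hi = self.freq_dist
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"degenerate uniform bounds {self.freq_dist}")
        elif kind == "beta":
            _, a, b = self.freq_dist
            if a <= 0 or b <= 0:
                raise ValueError(f"beta parameters must be positive, got {self.freq_dist}")
        else:
            raise ValueError(f"freq_dist must be 'uniform' or 'beta', got {kind!r}")


def _draw_frequencies(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    kind = config.freq_dist[0]
    if kind == "uniform":
        _, lo, hi = config.freq_dist
        return rng.uniform(lo, hi, size=config.m_loci)
    _, a, b = config.freq_dist
    p = rng.beta(a, b, size=config.m_loci)
    return np.clip(p, 1e-6, 1.0 - 1e-6)


def simulate_true_loci(config: SyntheticConfig, trait: TraitConfig) -> list[OrientedLocus]:
    """Draw true oriented loci: frequencies from freq_dist and effects
    |N(0, effect_sd²·[2p(1−p)]^alpha)|, already oriented to the undesirable
    allele (beta ≥ 0). Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    p = _draw_frequencies(config, rng)
    het = 2.0 * p * (1.0 - p)
    sd = config.effect_sd * het ** (config.coupling_alpha / 2.0)
    beta = np.abs(rng.normal(0.0, sd))
    width = len(str(config.m_loci))
    return [
        OrientedLocus(f"{trait.name}_L{i + 1:0{width}d}", float(p[i]), float(beta[i]))
        for i in range(config.m_loci)
    ]


def simulate_gwas_estimates(
    true_loci: Sequence[OrientedLocus],
    config: SyntheticConfig,
    trait: TraitConfig | None = None,
) -> list[LocusRecord]:
    """Add GWAS sampling noise to true effects and build raw-scale records.

    On the standardized model scale the per-allele sampling s.d. is
    se = 1/sqrt(2p(1−p)·n_gwas); β̂ = β + noise, with a two-sided normal
    p-value from β̂/se and an ``is_gws`` flag at the configured threshold.
    For binary traits both β̂ and se are re-expressed as log odds ratios
    (the raw scale published for diseases) so the table round-trips through
    the reader and the liability conversion. A fresh stream seeded from
    ``config.seed`` drives the noise.
    """
    rng = np.random.default_rng([config.seed, 1])
    records: list[LocusRecord] = []
    for locus in true_loci:
        p = locus.p_undesirable
        se_model = 1.0 / np.sqrt(2.0 * p * (1.0 - p) * config.n_gwas)
        beta_hat = locus.beta + rng.normal(0.0, se_model)
        pval = float(2.0 * norm.sf(abs(beta_hat) / se_model))
        if trait is not None and trait.kind == "binary":
            assert trait.prevalence_K is not None
            beta_raw = liability_to_logor(beta_hat, trait.prevalence_K)
            se_raw = liability_to_logor(se_model, trait.prevalence_K)
        else:
            beta_raw = beta_hat
            se_raw = se_model
        ref, alt = _alleles_for(locus.locus_id)
        records.append(
            LocusRecord(
                locus_id=locus.locus_id,
                effect_allele=alt,
                other_allele=ref,
                eaf=p,
                beta_raw=float(beta_raw),
                se=float(se_raw),
                n_samples=config.n_gwas,
                p_value=pval,
                trait_name=trait.name if trait is not None else "",
                is_gws=pval < config.gws_threshold,
            )
        )
    return records


def _alleles_for(locus_id: str) -> tuple[str, str]:
    # deterministic, id-derived allele pair (content is irrelevant to the model;
    # built-in hash() is process-randomized, so use a stable digest)
    import zlib

    h = zlib.crc32(locus_id.encode())
    a = str(_ALLELES[h % 4])
    b = str(_ALLELES[(h // 4) % 4])
    if b == a:
        b = str(_ALLELES[(h % 4 + 1) % 4])
    return a, b


def filter_gws(records: Sequence[LocusRecord], threshold: float = 5e-8) -> list[LocusRecord]:
    """Keep loci passing genome-wide significance (p < threshold)."""
    return [r for r in records if r.p_value is not None and r.p_value < threshold]


def records_to_frame(records: Sequence[LocusRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the default table dialect."""
    return pd.DataFrame(
        [
            {
                "locus_id": r.locus_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta_raw,
                "se": r.se,
                "n": r.n_samples,
                "p_value": r.p_value,
            }
            for r in records
        ]
    )


def write_locus_table(
    records: Sequence[LocusRecord], path: str | Path, synthetic: bool = True
) -> Path:
    """Write records as a TSV in the default dialect; synthetic tables get a
    prominent header comment so they are never mistaken for published data."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if synthetic:
            fh.write("# SYNTHETIC locus table generated by polyedit — placeholder\n")
            fh.write("# values for pipeline testing only, NOT published GWAS results\n")
        records_to_frame(records).to_csv(fh, sep="\t", index=False)
    return path


def winners_curse_experiment(
    config: SyntheticConfig,
    n_replicates: int = 10_000,
    seed: int = 0,
) -> dict:
    """Quantify winner's-curse bias of significance-selected edit plans.

    Each replicate draws ``m_loci`` signed true effects z ~ N(0, σ_i²)
    (σ_i = effect_sd·[2p(1−p)]^(alpha/2)) and noisy estimates
    β̂ = z + N(0, se²), keeps genome-wide-significant loci, orients each to
    the allele the *estimate* calls undesirable, and compares three
    per-replicate liability gains from editing the selected loci:

    - predicted: Σ 2p̃ |β̂| — what the editor expects;
    - true: Σ 2p̃ z̃ — what editing actually delivers (z̃ is the true effect
      of the estimate-oriented allele; negative when the sign was wrong);
    - shrunk: Σ 2p̃ f_i |β̂| with the Bayes factor f_i = σ_i²/(σ_i²+se_i²).

    Because selection and orientation are functions of β̂ alone and
    E[z | β̂] = f·β̂ under the normal prior, the shrunk prediction is
    unbiased for the true gain in expectation, while the raw prediction
    overstates it whenever power is incomplete. Returns means, the
    mean bias, and the paired standard error of (shrunk − true).
    """
    rng = np.random.default_rng([seed, 2])
    shape = (n_replicates, config.m_loci)
    # frequencies per replicate
    kind = config.freq_dist[0]
    if kind == "uniform":
        _, lo, hi = config.freq_dist
        p = rng.uniform(lo, hi, size=shape)
    else:
        _, a, b = config.freq_dist
        p = np.clip(rng.beta(a, b, size=shape), 1e-6, 1.0 - 1e-6)
    het = 2.0 * p * (1.0 - p)
    sigma = config.effect_sd * het ** (config.coupling_alpha / 2.0)
    z = rng.normal(0.0, sigma)
    se = 1.0 / np.sqrt(het * config.n_gwas)
    beta_hat = z + rng.normal(0.0, se)
    pvals = 2.0 * norm.sf(np.abs(beta_hat) / se)
    selected = pvals < config.gws_threshold
    # orient to the allele the estimate flags as undesirable
    p_oriented = np.where(beta_hat >= 0, p, 1.0 - p)
    z_oriented = np.where(beta_hat >= 0, z, -z)
    f = sigma**2 / (sigma**2 + se**2)
    w = 2.0 * p_oriented * selected
    predicted = (w * np.abs(beta_hat)).sum(axis=1)
    true = (w * z_oriented).sum(axis=1)
    shrunk = (w * f * np.abs(beta_hat)).sum(axis=1)
    diff = shrunk - true
    return {
        "n_replicates": n_replicates,
        "mean_selected": float(selected.sum(axis=1).mean()),
        "mean_predicted": float(predicted.mean()),
        "mean_true": float(true.mean()),
        "mean_shrunk": float(shrunk.mean()),
        "bias": float((predicted - true).mean()),
        "bias_se": float((predicted - true).std(ddof=1) / np.sqrt(n_replicates)),
        "shrunk_minus_true": float(diff.mean()),
        "shrunk_minus_true_se": float(diff.std(ddof=1) / np.sqrt(n_replicates)),
    }


def make_disease_fixture(
    name: str,
    directory: str | Path = ".",
    config: SyntheticConfig | None = None,
    source_dir: str | Path | None = None,
) -> tuple[TraitConfig, Path]:
    """Produce a schema-complete locus table plus the matching TraitConfig.

    ``name`` must be one of the ten modelled traits. If ``source_dir``
    contains a published table ``<name>.tsv`` it is used as-is; otherwise a
    clearly-labelled synthetic table is generated (seed derived from the
    trait name for per-trait variety under one base seed).
    """
    if name not in TRAIT_PRESETS:
        raise ValueError(
            f"unknown trait {name!r}; valid names: {', '.join(sorted(TRAIT_PRESETS))}"
        )
    trait = TRAIT_PRESETS[name]
    directory = Path(directory)
    if source_dir is not None:
        src = Path(source_dir) / f"{name}.tsv"
        if src.exists():
            return trait, src
    if config is None:
        config = SyntheticConfig()
    trait_seed = int(np.random.SeedSequence(
        [config.seed, sum(ord(c) for c in name)]
    ).generate_state(1)[0] % (2**31))
    cfg = SyntheticConfig(
        m_loci=config.m_loci,
        freq_dist=config.freq_dist,
        effect_sd=config.effect_sd,
        coupling_alpha=config.coupling_alpha,
        n_gwas=config.n_gwas,
        gws_threshold=config.gws_threshold,
        seed=trait_seed,
    )
    true = simulate_true_loci(cfg, trait)
    records = simulate_gwas_estimates(true, cfg, trait)
    path = write_locus_table(records, directory / f"{name}.tsv", synthetic=True)
    return trait, path
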