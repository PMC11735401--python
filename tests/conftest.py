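from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from polyedit import OrientedLocus, TraitConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def ad_trait() -> TraitConfig:
    return TraitConfig("AD", "binary", prevalence_K=0.05)


@pytest.fixture
def ldl_trait() -> TraitConfig:
    return TraitConfig("LDL", "quantitative", phenotypic_sd=0.4, units="mmol/l")


@pytest.fixture
def toy_loci() -> list[OrientedLocus]:
    """Two-locus toy set: shift −0.14 s.d., sd of gain ≈ 0.1105."""
    return [
        OrientedLocus("L1", 0.5, 0.1),
        OrientedLocus("L2", 0.1, 0.2),
    ]


@pytest.fixture
def tsv_writer(tmp_path: Path):
    """Write rows (list of dicts) as a locus TSV in the default dialect."""

    def _write(rows: list[dict], name: str = "loci.tsv") -> Path:
        cols = ["locus_id", "effect_allele", "other_allele", "eaf", "beta", "se", "n", "p_value"]
        path = tmp_path / name
        lines = ["\t".join(cols)]
        for row in rows:
            lines.append("\t".join(str(row.get(c, "")) for c in cols))
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
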