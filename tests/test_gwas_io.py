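"""Locus-table reading, orientation, scale conversion and ranking."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyedit import (
    LocusRecord,
    OrientedLocus,
    TraitConfig,
    estimate_phenotypic_sd,
    liability_to_logor,
    load_trait_configs,
    logor_to_liability,
    orient_to_undesirable,
    prevalence_from_shift,
    rank_loci,
    read_locus_table,
    write_oriented_table,
)
from polyedit.gwas_io import LocusValidationError, SchemaError

from oracles import quad_normal_pdf, quad_normal_ppf


def _row(locus_id="rs1", eaf=0.3, beta=0.1, se=0.01, n=100000, p_value=1e-9):
    return {
        "locus_id": locus_id,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "n": n,
        "p_value": p_value,
    }


class TestReadLocusTable:
    def test_well_formed_table_preserves_rows(self, tsv_writer, ad_trait):
        path = tsv_writer([_row("rs1"), _row("rs2", eaf=0.5), _row("rs3", beta=-0.2)])
        records = read_locus_table(path, ad_trait)
        assert len(records) == 3
        assert [r.locus_id for r in records] == ["rs1", "rs2", "rs3"]

    def test_boundary_frequency_rejected_with_locus_id(self, tsv_writer, ad_trait):
        path = tsv_writer([_row("rs1"), _row("rs_bad", eaf=1.0)])
        with pytest.raises(LocusValidationError, match="rs_bad"):
            read_locus_table(path, ad_trait)

    def test_missing_column_names_the_column(self, tmp_path, ad_trait):
        path = tmp_path / "broken.tsv"
        path.write_text("locus_id\teaf\tbeta\nrs1\t0.3\t0.1\n")
        with pytest.raises(SchemaError, match="effect_allele"):
            read_locus_table(path, ad_trait)

    def test_quantitative_requires_se_and_n(self, tsv_writer, ldl_trait):
        path = tsv_writer([_row(se="", n="")])
        with pytest.raises(LocusValidationError, match="requires se and n"):
            read_locus_table(path, ldl_trait)

    def test_column_mapping_handles_foreign_headers(self, tmp_path, ad_trait):
        path = tmp_path / "gwas.tsv"
        path.write_text("SNP\tA1\tA2\tFreq1\tLogOR\nrs9\tA\tG\t0.25\t0.12\n")
        records = read_locus_table(
            path,
            ad_trait,
            column_map={
                "locus_id": "SNP",
                "effect_allele": "A1",
                "other_allele": "A2",
                "eaf": "Freq1",
                "beta_raw": "LogOR",
            },
        )
        assert records[0].eaf == 0.25
        assert records[0].beta_raw == 0.12


class TestOrientation:
    def test_positive_effect_kept_as_is(self, ldl_trait):
        rec = LocusRecord("rs1", "A", "G", eaf=0.3, beta_raw=0.2)
        loc = orient_to_undesirable(rec, ldl_trait)
        assert loc.p_undesirable == pytest.approx(0.3)
        assert loc.beta == pytest.approx(0.2)

    def test_negative_effect_flips_allele(self, ldl_trait):
        rec = LocusRecord("rs1", "A", "G", eaf=0.3, beta_raw=-0.2)
        loc = orient_to_undesirable(rec, ldl_trait)
        assert loc.p_undesirable == pytest.approx(0.7)
        assert loc.beta == pytest.approx(0.2)

    def test_zero_effect_warns_and_keeps_locus(self, ldl_trait):
        rec = LocusRecord("rs1", "A", "G", eaf=0.3, beta_raw=0.0)
        with pytest.warns(UserWarning, match="zero effect"):
            loc = orient_to_undesirable(rec, ldl_trait)
        assert loc.beta == 0.0

    @given(
        p=st.floats(0.01, 0.99),
        logor=st.floats(0.01, 0.5),
        K=st.sampled_from([0.01, 0.05, 0.15]),
    )
    def test_flip_invariance_of_downstream_prevalence(self, p, logor, K):
        """Encoding a locus by its risk or its protective allele must give
        the same edited-genome prevalence."""
        trait = TraitConfig("D", "binary", prevalence_K=K)
        risk = LocusRecord("rs1", "A", "G", eaf=p, beta_raw=logor)
        protective = LocusRecord("rs1", "G", "A", eaf=1 - p, beta_raw=-logor)
        kg = []
        for rec in (risk, protective):
            loc = orient_to_undesirable(rec, trait)
            kg.append(prevalence_from_shift(K, 2 * loc.p_undesirable * loc.beta))
        assert kg[0] == pytest.approx(kg[1], rel=1e-12)


class TestLiabilityConversion:
    def test_zero_maps_to_zero(self):
        assert logor_to_liability(0.0, 0.37) == 0.0

    def test_multiplier_against_quadrature_oracle(self):
        # K = 0.05: K(1−K)/φ(Φ⁻¹(0.95)) evaluated by independent quadrature
        t = quad_normal_ppf(0.95)
        expected = 0.05 * 0.95 / quad_normal_pdf(t)
        assert expected == pytest.approx(0.4606, abs=5e-4)
        assert logor_to_liability(1.0, 0.05) == pytest.approx(expected, rel=1e-8)

    @given(
        b=st.floats(-2, 2, allow_subnormal=False),
        K=st.sampled_from([0.01, 0.06, 0.3]),
    )
    def test_linear_and_sign_preserving(self, b, K):
        assert logor_to_liability(2 * b, K) == pytest.approx(
            2 * logor_to_liability(b, K), rel=1e-12, abs=1e-15
        )
        assert np.sign(logor_to_liability(b, K)) == np.sign(b)

    def test_round_trip_with_inverse(self):
        assert liability_to_logor(logor_to_liability(0.8, 0.1), 0.1) == pytest.approx(0.8)

    @pytest.mark.parametrize("K", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_range_prevalence_rejected(self, K):
        with pytest.raises(ValueError):
            logor_to_liability(0.1, K)


class TestPhenotypicSd:
    def test_standardized_trait_identity(self):
        # se = 1/sqrt(2p(1−p)N) for every locus → estimate is exactly 1
        recs = []
        for i, p in enumerate([0.1, 0.25, 0.5, 0.8]):
            n = 50_000
            se = 1.0 / np.sqrt(2 * p * (1 - p) * n)
            recs.append(LocusRecord(f"rs{i}", "A", "G", eaf=p, beta_raw=0.1, se=se, n_samples=n))
        assert estimate_phenotypic_sd(recs) == pytest.approx(1.0, abs=1e-12)

    def test_single_locus_arithmetic(self):
        # 2·0.25·0.75·100000·se² = 4  ⇒  sd = 2
        se = np.sqrt(4.0 / (2 * 0.25 * 0.75 * 100_000))
        rec = LocusRecord("rs1", "A", "G", eaf=0.25, beta_raw=0.1, se=se, n_samples=100_000)
        assert estimate_phenotypic_sd([rec]) == pytest.approx(2.0)

    @given(c=st.floats(0.1, 10))
    def test_homogeneous_in_standard_errors(self, c):
        base = [
            LocusRecord("rs1", "A", "G", eaf=0.3, beta_raw=0.1, se=0.01, n_samples=10_000),
            LocusRecord("rs2", "A", "G", eaf=0.6, beta_raw=0.1, se=0.02, n_samples=10_000),
        ]
        scaled = [
            LocusRecord(r.locus_id, "A", "G", eaf=r.eaf, beta_raw=r.beta_raw,
                        se=r.se * c, n_samples=r.n_samples)
            for r in base
        ]
        assert estimate_phenotypic_sd(scaled) == pytest.approx(
            c * estimate_phenotypic_sd(base), rel=1e-12
        )

    def test_missing_se_errors_list_loci(self):
        recs = [
            LocusRecord("rs1", "A", "G", eaf=0.3, beta_raw=0.1, se=0.01, n_samples=1000),
            LocusRecord("rs_missing", "A", "G", eaf=0.3, beta_raw=0.1),
        ]
        with pytest.raises(ValueError, match="rs_missing"):
            estimate_phenotypic_sd(recs)


class TestRankLoci:
    def test_orders_by_frequency_effect_product(self):
        loci = [
            OrientedLocus("a", 0.5, 0.1),  # score 0.05
            OrientedLocus("b", 0.1, 0.3),  # score 0.03
            OrientedLocus("c", 0.4, 0.2),  # score 0.08
        ]
        assert [l.locus_id for l in rank_loci(loci, 10)] == ["c", "a", "b"]

    def test_truncates_to_max_m(self):
        loci = [OrientedLocus(f"L{i:02d}", 0.5, 0.01 * (i + 1)) for i in range(44)]
        assert len(rank_loci(loci, 10)) == 10

    def test_single_locus_is_itself(self):
        only = OrientedLocus("x", 0.2, 0.1)
        assert rank_loci([only], 5) == [only]

    def test_ties_break_lexicographically(self):
        loci = [OrientedLocus("z", 0.2, 0.1), OrientedLocus("a", 0.4, 0.05)]
        assert [l.locus_id for l in rank_loci(loci, 2)] == ["a", "z"]

    def test_empty_list_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert rank_loci([], 3) == []

    @given(scale=st.floats(0.1, 5))
    def test_order_stable_under_monotone_effect_rescaling(self, scale):
        loci = [
            OrientedLocus("a", 0.5, 0.1),
            OrientedLocus("b", 0.1, 0.3),
            OrientedLocus("c", 0.4, 0.2),
        ]
        rescaled = [OrientedLocus(l.locus_id, l.p_undesirable, l.beta * scale) for l in loci]
        assert [l.locus_id for l in rank_loci(loci, 3)] == [
            l.locus_id for l in rank_loci(rescaled, 3)
        ]


def test_trait_config_invariants():
    with pytest.raises(ValueError):
        TraitConfig("D", "binary")  # no prevalence
    with pytest.raises(ValueError):
        TraitConfig("Q", "quantitative", prevalence_K=0.1)
    with pytest.raises(ValueError):
        TraitConfig("D", "binary", prevalence_K=1.2)


def test_yaml_config_and_oriented_table_round_trip(tmp_path):
    cfg = tmp_path / "traits.yaml"
    cfg.write_text(
        "traits:\n"
        "  AD: {kind: binary, prevalence: 0.05}\n"
        "  LDL: {kind: quantitative, sd: 0.4, units: mmol/l}\n"
        "columns: {eaf: EAF}\n"
    )
    traits, column_map = load_trait_configs(cfg)
    assert traits["AD"].prevalence_K == 0.05
    assert traits["LDL"].units == "mmol/l"
    assert column_map == {"eaf": "EAF"}

    out = tmp_path / "oriented.tsv"
    write_oriented_table([OrientedLocus("a", 0.3, 0.2)], out)
    text = out.read_text()
    assert "rank_score" in text and "0.06" in text
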