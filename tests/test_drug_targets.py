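"""Drug-class proxy instruments: region selection, eQTL validation, orientation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mrbp import (
    ConfigError,
    EstimationError,
    EqtlRecord,
    GeneRegion,
    estimate_drug_class_effect,
    generate_eqtl_fixture,
    generate_region_fixture,
    select_eqtl_instruments,
    select_gene_region_instruments,
)
from mrbp.drug_targets import (
    DrugClassInstrumentSet,
    best_eqtl_per_gene,
    read_eqtl_catalog,
    read_region_catalog,
)
from mrbp.summary_data import retained

from .conftest import make_record


def region(**kw) -> GeneRegion:
    base = dict(
        gene_symbol="CACNA1D",
        drug_class="CCB",
        chromosome="3",
        start=1_000,
        end=11_000,
        element_type="gene_body",
    )
    base.update(kw)
    return GeneRegion(**base)


def outcome_like(recs, beta=0.001):
    return [
        make_record(
            variant_id=r.variant_id,
            chromosome=r.chromosome,
            position=r.position,
            eaf=r.eaf,
            beta=beta,
            se=0.006,
            pvalue=0.5,
            n=588_190,
            trait="AF",
        )
        for r in recs
    ]


class TestGeneRegionSelection:
    def toy(self):
        sbp = [
            make_record(variant_id="rs1", chromosome="3", position=2_000, pvalue=1e-9),
            make_record(variant_id="rs2", chromosome="3", position=5_000, pvalue=1e-9),
            make_record(variant_id="rs3", chromosome="3", position=8_000, pvalue=0.01),
        ]
        return sbp, [region()]

    def test_threshold_and_clump_select_significant_in_region(self):
        sbp, regions = self.toy()
        sets = select_gene_region_instruments(sbp, regions, outcome_like(sbp))
        assert sets["CCB"].n_snp == 2  # rs3 fails the p threshold

    def test_boundary_positions_included_both_ends(self):
        for pos in (1_000, 11_000):
            sbp = [make_record(variant_id="rs1", chromosome="3", position=pos, pvalue=1e-9)]
            sets = select_gene_region_instruments(sbp, [region()], outcome_like(sbp))
            assert sets["CCB"].n_snp == 1
        outside = [make_record(variant_id="rs1", chromosome="3", position=11_001, pvalue=1e-9)]
        with pytest.warns(UserWarning, match="no qualifying"):
            sets = select_gene_region_instruments(outside, [region()], outcome_like(outside))
        assert sets["CCB"].n_snp == 0

    def test_no_significant_snp_yields_empty_set_with_warning(self):
        sbp = [make_record(variant_id="rs1", chromosome="3", position=2_000, pvalue=0.5)]
        with pytest.warns(UserWarning, match="no qualifying"):
            sets = select_gene_region_instruments(sbp, [region()], outcome_like(sbp))
        assert sets["CCB"].instruments == []

    def test_variant_shared_between_classes_retained_and_flagged(self):
        sbp = [make_record(variant_id="rs1", chromosome="3", position=2_000, pvalue=1e-9)]
        regions = [region(), region(drug_class="BB", gene_symbol="SHARED")]
        sets = select_gene_region_instruments(sbp, regions, outcome_like(sbp))
        assert sets["CCB"].n_snp == 1 and sets["BB"].n_snp == 1
        assert sets["CCB"].shared_variants == {"rs1": ["BB"]}

    def test_unknown_drug_class_label_is_config_error(self):
        with pytest.raises(ConfigError, match="beta_agonist"):
            region(drug_class="beta_agonist")

    def test_region_fixture_roundtrip(self):
        fx = generate_region_fixture({"CCB": ["CACNA1D"]}, snps_per_gene=3, seed=3)
        sets = select_gene_region_instruments(
            fx.sbp_records(), fx.regions, fx.outcome_records()
        )
        assert sets["CCB"].n_snp == 3  # all planted SNPs significant, unlinked

    def test_zero_enrichment_gives_empty_sets(self):
        fx = generate_region_fixture({"CCB": ["CACNA1D"]}, effect_enrichment=0.0, seed=3)
        with pytest.warns(UserWarning, match="no qualifying"):
            sets = select_gene_region_instruments(
                fx.sbp_records(), fx.regions, fx.outcome_records()
            )
        assert sets["CCB"].n_snp == 0


class TestEqtlSelection:
    def test_best_eqtl_per_gene_smallest_p_tie_by_tissue(self):
        records = [
            EqtlRecord("rs1", "ACE", "Lung", 0.5, 0.05, 1e-6, "ACEi"),
            EqtlRecord("rs2", "ACE", "Aorta", 0.5, 0.05, 1e-8, "ACEi"),
            EqtlRecord("rs3", "ACE", "Artery", 0.5, 0.05, 1e-8, "ACEi"),
        ]
        best = best_eqtl_per_gene(records)
        # smallest nominal p wins; the 1e-8 tie breaks lexically ("Aorta" < "Artery")
        assert len(best) == 1
        assert best[0].variant_id == "rs2" and best[0].tissue == "Aorta"

    def test_failing_validation_excluded(self):
        eqtls = [EqtlRecord("rs1", "ACE", "Lung", 0.5, 0.05, 1e-8, "ACEi")]
        sbp = [make_record(variant_id="rs1", beta=0.001, se=0.01, pvalue=0.9)]  # z = 0.1
        sets = select_eqtl_instruments(eqtls, sbp, outcome_like(sbp))
        assert sets["ACEi"].n_snp == 0
        assert any("failed SBP validation" in n for n in sets["ACEi"].notes)

    def test_planted_fixture_validates_expected_count(self):
        fx = generate_eqtl_fixture(n_genes=4, frac_validating=0.5, seed=5, classes=("CCB",))
        sets = select_eqtl_instruments(fx.eqtls, fx.sbp_records(), fx.outcome_records())
        assert sets["CCB"].n_snp == 2

    def test_zero_validating_fraction_empty(self):
        fx = generate_eqtl_fixture(n_genes=3, frac_validating=0.0, seed=5, classes=("BB",))
        sets = select_eqtl_instruments(fx.eqtls, fx.sbp_records(), fx.outcome_records())
        assert sets["BB"].n_snp == 0

    def test_missing_sbp_variant_dropped_with_reason(self):
        eqtls = [EqtlRecord("rs_absent", "ACE", "Lung", 0.5, 0.05, 1e-8, "ACEi")]
        sbp = [make_record(variant_id="rs1")]
        sets = select_eqtl_instruments(eqtls, sbp, outcome_like(sbp))
        assert sets["ACEi"].n_snp == 0
        assert any("absent from SBP stats" in n for n in sets["ACEi"].notes)

    def test_fixture_determinism(self):
        a = generate_eqtl_fixture(n_genes=4, frac_validating=0.5, seed=9)
        b = generate_eqtl_fixture(n_genes=4, frac_validating=0.5, seed=9)
        assert a.sbp.equals(b.sbp) and a.eqtls == b.eqtls


class TestClassEffect:
    def _set(self, bx, by, sy):
        sbp = [
            make_record(variant_id=f"rs{i}", beta=float(b), se=0.01, pvalue=1e-9)
            for i, b in enumerate(bx)
        ]
        out = [
            make_record(variant_id=f"rs{i}", beta=float(g), se=float(s), pvalue=0.5)
            for i, (g, s) in enumerate(zip(by, sy))
        ]
        from mrbp.summary_data import harmonize

        return DrugClassInstrumentSet(
            drug_class="CCB", route="gene_region", instruments=harmonize(sbp, out)
        )

    def test_reported_or_is_per_decrease(self):
        # per-mmHg increase estimate +0.0416 -> OR per 10-mmHg decrease 0.66
        cset = self._set([1.0, 1.0, 1.0], [0.0416] * 3, [0.01] * 3)
        est = estimate_drug_class_effect(cset)
        assert est.beta == pytest.approx(-0.0416)
        assert est.or_per_10 == pytest.approx(math.exp(-0.416), rel=1e-12)

    def test_decrease_or_is_reciprocal_of_increase_or(self):
        cset = self._set([0.8, 1.2, 1.0], [0.05, 0.03, 0.04], [0.01, 0.02, 0.015])
        from mrbp.estimators import ivw

        inc = ivw(retained(cset.instruments))
        dec = estimate_drug_class_effect(cset)
        assert dec.or_per_10 == pytest.approx(1.0 / inc.or_per_10, rel=1e-12)

    def test_null_instruments_give_or_one(self):
        cset = self._set([1.0, 1.0, 1.0], [0.0, 0.0, 0.0], [0.01] * 3)
        assert estimate_drug_class_effect(cset).or_per_10 == pytest.approx(1.0)

    def test_single_instrument_ivw_only(self):
        cset = self._set([1.0], [0.02], [0.01])
        est = estimate_drug_class_effect(cset)
        assert est.n_snp == 1
        with pytest.raises(EstimationError):
            estimate_drug_class_effect(cset, estimator="weighted_median")

    def test_empty_set_not_assessable(self):
        cset = DrugClassInstrumentSet(drug_class="BB", route="eqtl", instruments=[])
        with pytest.raises(EstimationError, match="not assessable"):
            estimate_drug_class_effect(cset)


class TestCatalogIo:
    def test_region_catalog_roundtrip_and_bed_conversion(self, tmp_path):
        p = tmp_path / "regions.tsv"
        p.write_text(
            "chromosome\tstart\tend\tgene_symbol\tdrug_class\telement_type\n"
            "3\t999\t11000\tCACNA1D\tCCB\tgene_body\n"
        )
        one_based = read_region_catalog(p)
        assert one_based[0].start == 999
        converted = read_region_catalog(p, zero_based_half_open=True)
        assert converted[0].start == 1000 and converted[0].end == 11000

    def test_eqtl_catalog_reader(self, tmp_path):
        p = tmp_path / "eqtl.tsv"
        p.write_text(
            "variant_id\tgene\ttissue\tbeta\tse\tp\tdrug_class\n"
            "rs1\tACE\tLung\t0.5\t0.05\t1e-8\tACEi\n"
        )
        recs = read_eqtl_catalog(p)
        assert recs[0].target_gene == "ACE" and recs[0].drug_class == "ACEi"

    def test_missing_catalog_column_is_config_error(self, tmp_path):
        p = tmp_path / "regions.tsv"
        p.write_text("chromosome\tstart\n3\t1\n")
        with pytest.raises(ConfigError):
            read_region_catalog(p)
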