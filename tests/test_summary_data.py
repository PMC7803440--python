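"""Reading, selection, clumping and harmonization of summary statistics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrbp import (
    ConfigError,
    LdMatrix,
    clump,
    harmonize,
    harmonize_involution_check,
    read_summary_stats,
    retained,
    select_genomewide,
)
from mrbp.summary_data import DataError, records_to_frame

from .conftest import make_record
from .oracles import clump_oracle

TSV = """SNP\tCHR\tBP\tA1\tA2\tEAF\tBETA\tSE\tP\tN
rs1\t1\t100\tA\tG\t0.2\t0.5\t0.05\t1e-9\t1000
rs2\t1\t200\tc\tt\t0.4\t-0.3\t0.04\t1e-5\t1000
rs3\t2\t300\tG\tA\t0.1\t0.1\t0.02\t0.5\t1000
"""


class TestReader:
    def test_well_formed_file_yields_all_records(self, tmp_path):
        p = tmp_path / "stats.tsv"
        p.write_text(TSV)
        res = read_summary_stats(p)
        assert len(res.records) == 3 and res.n_rejected == 0

    def test_lowercase_alleles_uppercased_beta_unchanged(self, tmp_path):
        p = tmp_path / "stats.tsv"
        p.write_text(TSV)
        rec = read_summary_stats(p).records[1]
        assert (rec.effect_allele, rec.other_allele) == ("C", "T")
        assert rec.beta == -0.3

    @pytest.mark.parametrize(
        "bad_row, reason",
        [
            ("rs4\t1\t400\tA\tG\t0.2\t0.5\t0\t1e-9\t1000", "se"),
            ("rs4\t1\t400\tA\tG\t0.2\tnot_a_number\t0.05\t1e-9\t1000", "beta"),
            ("rs4\t1\t400\tA\tA\t0.2\t0.5\t0.05\t1e-9\t1000", "allele"),
            ("rs4\t1\t400\tA\tG\t1.5\t0.5\t0.05\t1e-9\t1000", "eaf"),
        ],
    )
    def test_invalid_rows_rejected_with_line_numbers(self, tmp_path, bad_row, reason):
        p = tmp_path / "stats.tsv"
        p.write_text(TSV + bad_row + "\n")
        res = read_summary_stats(p)
        assert len(res.records) == 3
        assert res.n_rejected == 1
        assert res.rejections[0][0] == 4  # 1-based data line number

    def test_missing_column_is_a_config_error(self, tmp_path):
        p = tmp_path / "stats.tsv"
        p.write_text("SNP\tCHR\nrs1\t1\n")
        with pytest.raises(ConfigError, match="missing"):
            read_summary_stats(p)


class TestSelectGenomewide:
    def test_strict_inequality_at_threshold(self):
        recs = [
            make_record(variant_id=f"rs{i}", pvalue=p)
            for i, p in enumerate([1e-9, 5e-8, 1e-7])
        ]
        kept = select_genomewide(recs, 5e-8)
        assert [r.variant_id for r in kept] == ["rs0"]

    def test_empty_input_and_all_significant(self):
        assert select_genomewide([], 5e-8) == []
        recs = [make_record(variant_id=f"rs{i}", pvalue=1e-10) for i in range(3)]
        assert len(select_genomewide(recs)) == 3

    def test_idempotent(self):
        recs = [make_record(variant_id=f"rs{i}", pvalue=p) for i, p in enumerate([1e-9, 1e-3])]
        once = select_genomewide(recs)
        assert select_genomewide(once) == once


def _ld(ids, mat):
    return LdMatrix(variant_ids=tuple(ids), r2=np.array(mat, dtype=float))


class TestClump:
    def three_snp_setup(self):
        recs = [
            make_record(variant_id="rsA", position=1000, pvalue=1e-10),
            make_record(variant_id="rsB", position=2000, pvalue=1e-9),
            make_record(variant_id="rsC", position=3000, pvalue=1e-8),
        ]
        ld = _ld(
            ["rsA", "rsB", "rsC"],
            [[1, 0.5, 0.0005], [0.5, 1, 0.0005], [0.0005, 0.0005, 1]],
        )
        return recs, ld

    def test_greedy_removal_keeps_index_and_unlinked(self):
        recs, ld = self.three_snp_setup()
        kept = clump(recs, ld, r2_threshold=0.001, window_kb=10_000)
        assert [r.variant_id for r in kept] == ["rsA", "rsC"]

    def test_all_unlinked_all_retained(self):
        recs, _ = self.three_snp_setup()
        ld = _ld(["rsA", "rsB", "rsC"], np.eye(3))
        assert len(clump(recs, ld, 0.001, 10_000)) == 3

    def test_fully_linked_locus_keeps_smallest_p_only(self):
        recs, _ = self.three_snp_setup()
        ld = _ld(["rsA", "rsB", "rsC"], np.ones((3, 3)))
        kept = clump(recs, ld, 0.001, 10_000)
        assert [r.variant_id for r in kept] == ["rsA"]

    def test_outside_window_not_removed_even_if_linked(self):
        recs = [
            make_record(variant_id="rsA", position=1_000, pvalue=1e-10),
            make_record(variant_id="rsB", position=1_000 + 10_000_001, pvalue=1e-9),
        ]
        ld = _ld(["rsA", "rsB"], [[1, 0.9], [0.9, 1]])
        assert len(clump(recs, ld, 0.001, 10_000)) == 2

    def test_variants_missing_from_ld_treated_unlinked_with_warning(self):
        recs, _ = self.three_snp_setup()
        ld = _ld(["rsA"], [[1.0]])
        with pytest.warns(UserWarning, match="unlinked"):
            kept = clump(recs, ld, 0.001, 10_000)
        assert len(kept) == 3

    def test_asymmetric_ld_matrix_rejected(self):
        with pytest.raises(DataError, match="asymmetric"):
            _ld(["a", "b"], [[1, 0.2], [0.5, 1]])

    def test_agrees_with_greedy_oracle_on_random_instances(self, rng):
        """200 random ≤12-SNP instances match the loop-based greedy reference."""
        for _ in range(200):
            j = int(rng.integers(2, 13))
            ids = [f"rs{i}" for i in range(j)]
            raw = rng.uniform(0, 1, (j, j))
            r2 = (raw + raw.T) / 2
            np.fill_diagonal(r2, 1.0)
            positions = rng.integers(1, 5_000_000, j)
            recs = [
                make_record(
                    variant_id=ids[i],
                    position=int(positions[i]),
                    pvalue=float(rng.uniform(1e-12, 1e-6)),
                    se=float(rng.uniform(0.01, 0.05)),
                )
                for i in range(j)
            ]
            ld = _ld(ids, r2)
            thr = float(rng.uniform(0.05, 0.8))
            window = float(rng.choice([100, 1000, 10_000]))
            mine = clump(recs, ld, thr, window)
            ref = clump_oracle(recs, lambda a, b: ld.lookup(a, b) or 0.0, thr, window * 1000)
            assert [r.variant_id for r in mine] == [r.variant_id for r in ref]

    def test_retained_pairs_within_window_below_threshold(self, rng):
        recs, ld = self.three_snp_setup()
        kept = clump(recs, ld, 0.001, 10_000)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                if a.chromosome == b.chromosome and abs(a.position - b.position) <= 1e7:
                    assert (ld.lookup(a.variant_id, b.variant_id) or 0.0) <= 0.001


class TestHarmonize:
    def test_swapped_alleles_flip_beta_and_frequency(self):
        exp = [make_record(effect_allele="A", other_allele="G", beta=0.10)]
        out = [make_record(effect_allele="G", other_allele="A", beta=-0.05, eaf=0.30, se=0.04)]
        h = harmonize(exp, out)[0]
        assert h.action_taken == "allele_flip"
        assert h.beta_outcome == pytest.approx(0.05)
        assert h.eaf_outcome == pytest.approx(0.70)

    def test_identical_alleles_unchanged(self):
        exp = [make_record(beta=0.1)]
        out = [make_record(beta=0.05, se=0.04)]
        h = harmonize(exp, out)[0]
        assert h.action_taken == "unchanged"
        assert h.beta_outcome == pytest.approx(0.05)

    def test_strand_flip_resolved_for_non_palindromic(self):
        exp = [make_record(effect_allele="A", other_allele="G", beta=0.1)]
        out = [make_record(effect_allele="T", other_allele="C", beta=0.05, se=0.04)]
        h = harmonize(exp, out)[0]
        assert h.action_taken == "unchanged"
        assert h.beta_outcome == pytest.approx(0.05)

    def test_irreconcilable_alleles_dropped_with_reason(self):
        exp = [make_record(effect_allele="A", other_allele="G")]
        out = [make_record(effect_allele="A", other_allele="C", se=0.04)]
        h = harmonize(exp, out)[0]
        assert h.action_taken == "dropped" and h.drop_reason == "allele_mismatch"

    def test_missing_outcome_variant_dropped_and_counted(self):
        exp = [make_record(variant_id="rs1"), make_record(variant_id="rs2")]
        out = [make_record(variant_id="rs1", se=0.04)]
        h = harmonize(exp, out)
        dropped = [x for x in h if x.action_taken == "dropped"]
        assert len(dropped) == 1 and dropped[0].drop_reason == "missing_outcome"

    def test_palindromic_ambiguous_frequency_dropped(self):
        exp = [make_record(effect_allele="A", other_allele="T", eaf=0.50)]
        out = [make_record(effect_allele="A", other_allele="T", eaf=0.30, se=0.04)]
        h = harmonize(exp, out, "infer_by_frequency", freq_cutoff=0.42)[0]
        assert h.action_taken == "dropped"
        assert "palindromic" in h.drop_reason

    def test_palindromic_discordant_frequencies_flip(self):
        exp = [make_record(effect_allele="A", other_allele="T", eaf=0.20, beta=0.1)]
        out = [make_record(effect_allele="A", other_allele="T", eaf=0.80, beta=0.05, se=0.04)]
        h = harmonize(exp, out)[0]
        assert h.action_taken == "allele_flip"
        assert h.beta_outcome == pytest.approx(-0.05)
        assert h.eaf_outcome == pytest.approx(0.20)

    def test_palindromic_drop_policy(self):
        exp = [make_record(effect_allele="C", other_allele="G", eaf=0.2)]
        out = [make_record(effect_allele="C", other_allele="G", eaf=0.2, se=0.04)]
        h = harmonize(exp, out, palindrome_policy="drop")[0]
        assert h.action_taken == "dropped" and h.drop_reason == "palindromic"

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        beta=st.floats(-1, 1, allow_nan=False),
        eaf=st.floats(0.01, 0.99),
        swap=st.booleans(),
    )
    def test_magnitude_conserved_under_harmonization(self, beta, eaf, swap):
        """Harmonization may change the sign of beta_outcome, never |beta|."""
        exp = [make_record(effect_allele="A", other_allele="G", beta=0.1)]
        ea, oa = ("G", "A") if swap else ("A", "G")
        out = [make_record(effect_allele=ea, other_allele=oa, beta=beta, eaf=eaf, se=0.04)]
        kept = retained(harmonize(exp, out))
        assert len(kept) == 1
        assert abs(kept[0].beta_outcome) == pytest.approx(abs(beta))

    def test_involution_passes_on_harmonized_set(self, small_study):
        h = harmonize(small_study.exposure_records(), small_study.outcome_records())
        assert harmonize_involution_check(h)

    def test_involution_detects_tampered_record(self):
        exp = [make_record(effect_allele="A", other_allele="T", eaf=0.2, beta=0.1)]
        out = [make_record(effect_allele="A", other_allele="T", eaf=0.2, beta=0.05, se=0.04)]
        h = harmonize(exp, out)
        assert h[0].action_taken == "unchanged"
        # artificially re-flip the outcome frequency: re-harmonization now
        # sees discordant palindromic frequencies and must act
        import dataclasses

        bad = [dataclasses.replace(h[0], eaf_outcome=0.8)]
        assert not harmonize_involution_check(bad)

    def test_involution_on_empty_set(self):
        assert harmonize_involution_check([])


def test_records_roundtrip_to_frame():
    recs = [make_record(variant_id=f"rs{i}") for i in range(3)]
    df = records_to_frame(recs)
    assert list(df["variant_id"]) == ["rs0", "rs1", "rs2"]
    assert df.shape[0] == 3
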