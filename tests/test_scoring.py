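"""Scoring: file parsing, QC, harmonization, PRS arithmetic, standardization."""

import math

import numpy as np
import pandas as pd
import pytest

from prseval.scoring import (
    AmbiguousVariantError,
    QCThresholds,
    ScoreFile,
    ScoreFileError,
    ScoreVariant,
    compute_prs,
    harmonize,
    parse_scorefile,
    qc_filter_variants,
    read_dosage_tsv,
    read_vcf,
    standardize,
    write_dosage_tsv,
    write_vcf,
)

from conftest import make_genotypes


def score_of(variants):
    return ScoreFile(
        pgs_id="PGS_T", trait_label="t", weight_type="log_odds",
        variants=variants,
    )


class TestParseScorefile:
    def test_direct_parse(self, tmp_path, scorefile_writer):
        p = scorefile_writer(
            tmp_path / "s.txt",
            [("rs1", "1", 100, "A", "G", 0.1), ("rs2", "1", 200, "C", "T", -0.2)],
            meta={"pgs_id": "PGS000001", "trait_reported": "demo"},
        )
        sf = parse_scorefile(p)
        assert sf.pgs_id == "PGS000001"
        assert [v.weight for v in sf.variants] == [0.1, -0.2]
        assert sf.variants[0].effect_allele == "A"
        assert sf.variants[0].other_allele == "G"

    def test_odds_ratio_column_log_transformed(self, tmp_path, scorefile_writer):
        p = scorefile_writer(
            tmp_path / "s.txt", [("rs1", "1", 100, "A", "G", 1.0)], weight_col="OR"
        )
        sf = parse_scorefile(p)
        assert sf.variants[0].weight == 0.0
        assert math.isclose(
            parse_scorefile(
                scorefile_writer(tmp_path / "s2.txt",
                                 [("rs1", "1", 100, "A", "G", 1.5)],
                                 weight_col="OR")
            ).variants[0].weight,
            math.log(1.5),
        )

    @pytest.mark.parametrize("wt", [
        "odds ratio over expected risk", "inverse-variance weighting", "unweighted",
    ])
    def test_excluded_weight_types_rejected(self, tmp_path, scorefile_writer, wt):
        p = scorefile_writer(
            tmp_path / "s.txt", [("rs1", "1", 100, "A", "G", 0.1)],
            meta={"weight_type": wt},
        )
        with pytest.raises(ScoreFileError):
            parse_scorefile(p)

    def test_missing_columns_named_in_error(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("rsID\teffect_weight\nrs1\t0.1\n")
        with pytest.raises(ScoreFileError, match="effect_allele"):
            parse_scorefile(p)
        p2 = tmp_path / "bad2.txt"
        p2.write_text("rsID\teffect_allele\nrs1\tA\n")
        with pytest.raises(ScoreFileError, match="effect_weight"):
            parse_scorefile(p2)

    def test_duplicate_rows_dropped(self, tmp_path, scorefile_writer):
        p = scorefile_writer(
            tmp_path / "s.txt",
            [("rs1", "1", 100, "A", "G", 0.1), ("rs1", "1", 100, "A", "G", 0.1),
             ("rs2", "1", 200, "C", "T", 0.2)],
        )
        sf = parse_scorefile(p)
        assert len(sf.variants) == 2

    def test_same_allele_pair_rejected(self):
        with pytest.raises(ScoreFileError):
            ScoreVariant("rs1", "1", 1, "A", "A", 0.1)


class TestQCFilter:
    @pytest.mark.parametrize("field,value,excluded", [
        ("info", 0.79, True), ("info", 0.80, False),
        ("maf", 0.009, True), ("maf", 0.01, False),
        ("hwe_p", 1e-7, True), ("call_rate", 0.94, True),
        ("n_alleles", 3, True),
    ])
    def test_thresholds(self, field, value, excluded):
        g = make_genotypes(np.zeros((4, 1)) + 1.0, maf=[0.3], info=[0.99],
                           hwe_p=[0.5], call_rate=[1.0], n_alleles=[2])
        g.variant_meta.loc[0, field] = value
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            filtered, log = qc_filter_variants(g)
        assert (filtered.n_variants == 0) == excluded
        if excluded:
            assert len(log) == 1 and log.loc[0, "variant_index"] == 0

    def test_empty_result_warns_not_raises(self):
        g = make_genotypes(np.ones((4, 1)), info=[0.1])
        with pytest.warns(UserWarning):
            filtered, _ = qc_filter_variants(g)
        assert filtered.n_variants == 0

    def test_configurable_thresholds(self):
        g = make_genotypes(np.ones((4, 1)), info=[0.79])
        filtered, _ = qc_filter_variants(g, QCThresholds(min_info=0.5))
        assert filtered.n_variants == 1


class TestHarmonize:
    def geno(self):
        # cohort alleles (A, G), counting G
        return make_genotypes(np.array([[0.0], [1.0], [2.0]]),
                              alleles=[("A", "G")], pos=[100])

    def test_direct(self):
        sf = score_of([ScoreVariant("rs1", "1", 100, "G", "A", 0.5)])
        mapping, rep = harmonize(sf, self.geno())
        assert mapping[0].orientation == "direct" and not mapping[0].flip
        assert rep.n_matched_direct == 1

    def test_swapped(self):
        sf = score_of([ScoreVariant("rs1", "1", 100, "A", "G", 0.5)])
        mapping, rep = harmonize(sf, self.geno())
        assert mapping[0].orientation == "swapped" and mapping[0].flip
        assert rep.n_matched_swapped == 1

    def test_complement_orientations(self):
        sf = score_of([ScoreVariant("rs1", "1", 100, "C", "T", 0.5)])
        mapping, rep = harmonize(sf, self.geno())  # comp(C)=G, comp(T)=A
        assert mapping[0].orientation == "complement" and not mapping[0].flip
        sf2 = score_of([ScoreVariant("rs1", "1", 100, "T", "C", 0.5)])
        mapping2, _ = harmonize(sf2, self.geno())
        assert mapping2[0].orientation == "complement_swapped" and mapping2[0].flip

    def test_palindromic_dropped_by_default(self):
        sf = score_of([ScoreVariant("rs1", "1", 100, "A", "T", 0.5)])
        mapping, rep = harmonize(sf, self.geno())
        assert mapping == []
        assert rep.n_palindromic_dropped == 1

    def test_missing_counted(self):
        sf = score_of([ScoreVariant("rs9", "9", 999, "A", "G", 0.5)])
        mapping, rep = harmonize(sf, self.geno())
        assert rep.n_missing == 1 and mapping == []

    def test_counts_partition(self):
        sf = score_of([
            ScoreVariant("rs1", "1", 100, "G", "A", 0.5),
            ScoreVariant("rs2", "1", 100, "A", "T", 0.5),   # palindromic
            ScoreVariant("rs3", "9", 999, "A", "G", 0.5),   # missing
        ])
        _, rep = harmonize(sf, self.geno())
        rep.validate()
        assert (rep.n_matched_direct, rep.n_palindromic_dropped, rep.n_missing) \
            == (1, 1, 1)

    def test_ambiguous_duplicate_position(self):
        g = make_genotypes(np.zeros((2, 2)), alleles=[("A", "G"), ("A", "G")],
                           pos=[100, 100])
        sf = score_of([ScoreVariant("rs1", "1", 100, "G", "A", 0.5)])
        with pytest.raises(AmbiguousVariantError):
            harmonize(sf, g)


class TestComputePRS:
    def test_weighted_sum(self):
        g = make_genotypes(np.ones((1, 3)))
        sf = score_of([
            ScoreVariant(f"rs{i}", "1", 1000 * (i + 1), "G", "A", w)
            for i, w in enumerate((0.1, 0.2, 0.3))
        ])
        mapping, _ = harmonize(sf, g)
        assert compute_prs(sf, g, mapping).raw[0] == pytest.approx(0.6)

    def test_all_zero_dosage(self):
        g = make_genotypes(np.zeros((2, 2)))
        sf = score_of([
            ScoreVariant("rs1", "1", 1000, "G", "A", 0.4),
            ScoreVariant("rs2", "1", 2000, "G", "A", -0.1),
        ])
        mapping, _ = harmonize(sf, g)
        assert np.all(compute_prs(sf, g, mapping).raw == 0.0)

    def test_swapped_orientation_transform(self):
        # stored dosage 2 of the counted allele; effect allele is the other one
        g = make_genotypes(np.array([[2.0]]))
        sf = score_of([ScoreVariant("rs1", "1", 1000, "A", "G", 0.3)])
        mapping, _ = harmonize(sf, g)
        assert mapping[0].flip
        assert compute_prs(sf, g, mapping).raw[0] == 0.0

    def test_zero_matched_is_error(self):
        g = make_genotypes(np.zeros((2, 1)))
        sf = score_of([ScoreVariant("rs9", "9", 9, "G", "A", 0.5)])
        mapping, _ = harmonize(sf, g)
        with pytest.raises(ValueError, match="zero matched"):
            compute_prs(sf, g, mapping)

    def test_missing_imputed_at_twice_allele_frequency(self):
        d = np.array([[0.0], [2.0], [1.0], [np.nan]])
        g = make_genotypes(d)
        sf = score_of([ScoreVariant("rs1", "1", 1000, "G", "A", 1.0)])
        mapping, _ = harmonize(sf, g)
        prs = compute_prs(sf, g, mapping)
        assert prs.raw[3] == pytest.approx(1.0)  # 2 * EAF = 2 * 0.5
        assert prs.n_imputed.tolist() == [0, 0, 0, 1]
        prs0 = compute_prs(sf, g, mapping, missing_policy="zero")
        assert prs0.raw[3] == 0.0

    def test_matches_double_loop_oracle_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(2, 11)
            k = rng.integers(1, 21)
            dosage = rng.integers(0, 3, size=(n, k)).astype(float)
            g = make_genotypes(dosage)
            weights = rng.normal(0, 0.3, size=k)
            flip = rng.random(k) < 0.5
            variants = []
            for j in range(k):
                eff, oth = ("A", "G") if flip[j] else ("G", "A")
                variants.append(ScoreVariant(
                    f"rs{j}", "1", 1000 * (j + 1), eff, oth, weights[j]
                ))
            sf = score_of(variants)
            mapping, _ = harmonize(sf, g)
            raw = compute_prs(sf, g, mapping).raw
            expected = np.zeros(n)
            for i in range(n):
                for j in range(k):
                    x = dosage[i, j]
                    expected[i] += weights[j] * ((2 - x) if flip[j] else x)
            np.testing.assert_array_equal(raw, expected)


class TestStandardize:
    def test_unit_example(self):
        np.testing.assert_allclose(standardize(np.array([1.0, 2.0, 3.0])),
                                   [-1.0, 0.0, 1.0])

    def test_degenerate_error(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            standardize(np.array([2.0, 2.0, 2.0]))
        with pytest.raises(ValueError, match="at least 2"):
            standardize(np.array([1.0]))

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        np.testing.assert_allclose(
            standardize(3.0 * x - 7.0), standardize(x), atol=1e-12
        )

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2, 5, size=40)
        z = standardize(x)
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    def test_stratum_reference(self):
        x = np.array([0.0, 1.0, 2.0, 10.0])
        z = standardize(x, stratum=np.array([0, 1, 2]))
        assert z[:3].mean() == pytest.approx(0.0)
        assert z[:3].std(ddof=1) == pytest.approx(1.0)
        assert z[3] == pytest.approx(9.0)  # scored on the stratum scale


class TestGenotypeIO:
    def test_tsv_round_trip(self, tmp_path):
        d = np.array([[0.0, 1.5], [np.nan, 2.0], [1.0, 0.25]])
        g = make_genotypes(d, alleles=[("A", "C"), ("G", "T")])
        write_dosage_tsv(g, tmp_path / "g.tsv", tmp_path / "g_meta.tsv")
        g2 = read_dosage_tsv(tmp_path / "g.tsv", tmp_path / "g_meta.tsv")
        assert g2.sample_ids == g.sample_ids
        np.testing.assert_array_equal(g2.dosage, g.dosage)
        np.testing.assert_allclose(
            g2.variant_meta["maf"], g.variant_meta["maf"]
        )

    def test_vcf_round_trip(self, tmp_path):
        d = np.array([[0.0, 1.5], [np.nan, 2.0], [1.0, 0.25]])
        g = make_genotypes(d, alleles=[("A", "C"), ("G", "T")])
        write_vcf(g, tmp_path / "g.vcf")
        g2 = read_vcf(tmp_path / "g.vcf")
        assert g2.sample_ids == g.sample_ids
        np.testing.assert_allclose(g2.dosage, g.dosage)
        assert list(g2.variants["allele_b"]) == ["C", "T"]


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=3, max_size=50)
    .filter(lambda xs: len(set(xs)) > 1),
    st.floats(0.1, 100.0),
    st.floats(-1e3, 1e3),
)
def test_standardize_properties(xs, scale, shift):
    """Standardized scores are zero-mean/unit-SD, idempotent, and invariant
    to positive affine transforms of the raw score."""
    raw = np.asarray(xs, dtype=float)
    z = standardize(raw)
    assert abs(z.mean()) < 1e-7
    assert abs(z.std(ddof=1) - 1.0) < 1e-7
    np.testing.assert_allclose(standardize(z), z, atol=1e-9)
    np.testing.assert_allclose(standardize(scale * raw + shift), z, atol=1e-6)
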