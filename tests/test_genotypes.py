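import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sippk.genotypes import (
    CLINT_WT_PER_PMOL,
    FM_WT,
    GENOTYPES,
    WT,
    FmVector,
    GenotypeError,
    build_activity_table,
    canonical_genotype,
    genotype_table_from_csv,
    genotype_table_to_csv,
    interpolate_heterozygote,
    recompute_fm,
    round_half_away,
    scale_clearance,
    scale_clint,
)


class TestInterpolation:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(1.0, 0.089, 0.5445), (1.0, 1.0, 1.0), (0.345, 0.089, 0.217)],
    )
    def test_heterozygote_is_mean_of_homozygotes(self, a, b, expected):
        assert interpolate_heterozygote(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetric(self):
        assert interpolate_heterozygote(0.2, 0.9) == interpolate_heterozygote(0.9, 0.2)

    @pytest.mark.parametrize("bad", [-0.1, 1.2])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(GenotypeError):
            interpolate_heterozygote(bad, 0.5)


class TestClintScaling:
    @pytest.mark.parametrize(
        "pg, expected",
        [(0.345, 16.93), (1.0, 49.07), (0.089, 4.37)],
    )
    def test_examples(self, pg, expected):
        assert scale_clint(pg, 49.07) == pytest.approx(expected, abs=0.01)

    def test_negative_inputs_rejected(self):
        with pytest.raises(GenotypeError):
            scale_clint(-0.1, 49.07)
        with pytest.raises(GenotypeError):
            scale_clint(0.5, -1.0)


class TestActivityTable:
    def test_structure_and_internal_consistency(self):
        table = build_activity_table().set_index("genotype")
        assert list(table.index) == list(GENOTYPES)
        assert table.loc[WT, "pg_ratio"] == 1.0
        # heterozygote = mean of parents; clint proportional to ratio
        for het, (pa, pb) in {
            "*1/*2": ("*1/*1", "*2/*2"),
            "*1/*3": ("*1/*1", "*3/*3"),
            "*2/*3": ("*2/*2", "*3/*3"),
        }.items():
            expected = 0.5 * (table.loc[pa, "pg_ratio"] + table.loc[pb, "pg_ratio"])
            assert table.loc[het, "pg_ratio"] == pytest.approx(expected, abs=1e-15)
            assert not table.loc[het, "is_measured"]
        np.testing.assert_allclose(
            table["clint_per_pmol"], table["pg_ratio"] * CLINT_WT_PER_PMOL, rtol=1e-15
        )
        assert table["pg_ratio"].between(0, 1).all()

    def test_wild_type_ratio_must_be_one(self):
        with pytest.raises(GenotypeError):
            build_activity_table({"*1/*1": 0.99, "*2/*2": 0.3, "*3/*3": 0.1})

    def test_abundance_multiplier_hook(self):
        table = build_activity_table(abundance_multipliers={"*3/*3": 0.5}).set_index("genotype")
        assert table.loc["*3/*3", "abundance_multiplier"] == 0.5
        assert table.loc[WT, "abundance_multiplier"] == 1.0

    def test_csv_round_trip(self, tmp_path):
        table = build_activity_table()
        path = tmp_path / "table.csv"
        genotype_table_to_csv(table, path)
        back = genotype_table_from_csv(path)
        pd.testing.assert_frame_equal(
            back, table[["genotype", "pg_ratio", "clint_per_pmol", "abundance_multiplier"]]
        )


@pytest.mark.parametrize(
    "label, expected",
    [("*1/*2", "*1/*2"), ("*2/*1", "*1/*2"), (" *3/*3 ", "*3/*3")],
)
def test_genotype_canonicalisation(label, expected):
    assert canonical_genotype(label) == expected


def test_bad_genotype_label_rejected():
    with pytest.raises(GenotypeError):
        canonical_genotype("1/2")


class TestRecomputeFm:
    def test_identity_at_wild_type_activity(self):
        fm = recompute_fm(FM_WT, 1.0, 1.0)
        for enzyme, frac in FM_WT.items():
            assert fm[enzyme] == pytest.approx(frac, rel=1e-12)

    def test_poor_metaboliser_example(self):
        fm = recompute_fm({"CYP2C9": 0.8084}, 0.345)
        assert fm["CYP2C9"] == pytest.approx(
            0.8084 * 0.345 / (0.8084 * 0.345 + 0.1916), rel=1e-12
        )
        assert fm["CYP2C9"] == pytest.approx(0.593, abs=5e-4)

    def test_zero_activity_limit(self):
        fm = recompute_fm(FM_WT, 0.0)
        assert fm["CYP2C9"] == 0.0
        # other routes keep their wild-type proportions
        others = {e: f for e, f in FM_WT.items() if e != "CYP2C9"}
        total = sum(others.values())
        for enzyme, frac in others.items():
            assert fm[enzyme] / fm["CYP3A4"] == pytest.approx(
                frac / others["CYP3A4"], rel=1e-12
            )
        assert sum(fm.as_dict().values()) + fm.remainder == pytest.approx(1.0)
        assert total > 0

    def test_degenerate_all_zero_rejected(self):
        with pytest.raises(GenotypeError):
            recompute_fm(FmVector({"CYP2C9": 1.0}), 0.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        fm_2c9=st.floats(0.01, 0.99),
        other=st.floats(0.0, 1.0),
        pg=st.floats(0.0, 1.0),
        mult=st.floats(0.1, 2.0),
    )
    def test_output_sums_to_one(self, fm_2c9, other, pg, mult):
        fm_other = other * (1.0 - fm_2c9) * 0.9
        fm = recompute_fm({"CYP2C9": fm_2c9, "CYP3A4": fm_other}, pg, mult)
        assert sum(fm.as_dict().values()) + fm.remainder == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(pg1=st.floats(0.0, 1.0), pg2=st.floats(0.0, 1.0))
    def test_fm_monotone_in_activity(self, pg1, pg2):
        lo, hi = sorted([pg1, pg2])
        f_lo = recompute_fm(FM_WT, lo)["CYP2C9"]
        f_hi = recompute_fm(FM_WT, hi)["CYP2C9"]
        assert f_lo <= f_hi + 1e-12


class TestScaleClearance:
    def test_identity_at_wild_type(self):
        assert scale_clearance(4.01, 0.8084, 1.0) == pytest.approx(4.01)

    @pytest.mark.parametrize(
        "pg, expected",
        [(0.345, 4.01 * (0.8084 * 0.345 + 0.1916)), (0.089, 4.01 * (0.8084 * 0.089 + 0.1916))],
    )
    def test_linear_mode_hand_arithmetic(self, pg, expected):
        assert scale_clearance(4.01, 0.8084, pg, "linear") == pytest.approx(expected, rel=1e-12)
        # spot values of the hand arithmetic
        assert scale_clearance(4.01, 0.8084, 0.345) == pytest.approx(1.89, abs=0.01)
        assert scale_clearance(4.01, 0.8084, 0.089) == pytest.approx(1.06, abs=0.01)

    def test_unknown_mode_rejected(self):
        with pytest.raises(GenotypeError):
            scale_clearance(4.01, 0.8084, 0.5, mode="nonlinear")

    def test_linear_agrees_with_well_stirred_at_low_extraction(self):
        # the two modes differ by ~E_H*(1-s) to first order, so they agree
        # within the extraction ratio itself, and within 2% once E_H < ~0.02
        for cl_wt in (4.01, 1.8):
            extraction = cl_wt / 97.0
            for pg in (0.089, 0.345, 0.6725):
                lin = scale_clearance(cl_wt, 0.8084, pg, "linear")
                ws = scale_clearance(cl_wt, 0.8084, pg, "well-stirred", fu=0.0002)
                assert abs(ws - lin) / lin <= extraction
        for pg in (0.089, 0.345, 0.6725):
            lin = scale_clearance(1.8, 0.8084, pg, "linear")  # E_H ~ 0.019
            ws = scale_clearance(1.8, 0.8084, pg, "well-stirred", fu=0.0002)
            assert ws == pytest.approx(lin, rel=0.02)

    def test_monotone_in_activity(self):
        values = [scale_clearance(4.01, 0.8084, pg) for pg in np.linspace(0, 1, 11)]
        assert all(a < b for a, b in zip(values, values[1:]))


@pytest.mark.parametrize(
    "x, decimals, expected",
    [(0.6725, 3, 0.673), (33.024, 2, 33.02), (-0.5445, 3, -0.545), (2.5, 0, 3.0)],
)
def test_round_half_away_from_zero(x, decimals, expected):
    assert round_half_away(x, decimals) == expected
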