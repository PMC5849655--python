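import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from sippk.phenotyping import (
    DonorBank,
    DonorBankError,
    correlation_analysis,
    genotype_rate_comparison,
)


def _bank(activities: np.ndarray, rates: np.ndarray, enzymes, endpoints):
    donors = pd.Index([f"D{i}" for i in range(activities.shape[0])], name="donor")
    return DonorBank(
        activities=pd.DataFrame(activities, index=donors, columns=enzymes),
        rates=pd.DataFrame(rates, index=donors, columns=endpoints),
    )


@pytest.fixture
def mixed_bank():
    rng = np.random.default_rng(42)
    act = rng.lognormal(0.0, 0.3, size=(16, 3))
    rate = 0.8 * act[:, 0] + 0.2 * act[:, 1]
    return _bank(act, rate[:, None], ["CYP2C9", "CYP3A4", "CYP1A2"], ["total"])


class TestCorrelationAnalysis:
    def test_perfectly_proportional_rate_gives_r_one(self):
        rng = np.random.default_rng(0)
        act = rng.lognormal(0.0, 0.3, size=(12, 2))
        rate = 3.5 * act[:, 0]
        bank = _bank(act, rate[:, None], ["CYP2C9", "CYP3A4"], ["total"])
        result = correlation_analysis(bank)
        assert result.correlations.loc["total", "CYP2C9"] == pytest.approx(1.0, abs=1e-12)
        assert result.major_enzyme["total"] == "CYP2C9"
        assert result.supported["total"]

    def test_donor_order_permutation_invariance(self, mixed_bank):
        result = correlation_analysis(mixed_bank)
        rng = np.random.default_rng(1)
        perm = rng.permutation(mixed_bank.n_donors)
        shuffled = DonorBank(
            activities=mixed_bank.activities.iloc[perm],
            rates=mixed_bank.rates.iloc[perm],
        )
        result2 = correlation_analysis(shuffled)
        pd.testing.assert_frame_equal(result.correlations, result2.correlations)

    def test_scale_and_location_invariance(self, mixed_bank):
        r0 = correlation_analysis(mixed_bank).correlations
        rescaled = DonorBank(
            activities=mixed_bank.activities * 7.3 + 2.0,
            rates=mixed_bank.rates * 0.11 + 5.0,
        )
        r1 = correlation_analysis(rescaled).correlations
        np.testing.assert_allclose(r0.values.astype(float), r1.values.astype(float), atol=1e-12)

    def test_constant_activity_column_excluded(self):
        rng = np.random.default_rng(3)
        act = rng.lognormal(0.0, 0.3, size=(10, 2))
        act[:, 1] = 1.0  # zero variance marker
        rate = act[:, 0]
        bank = _bank(act, rate[:, None], ["CYP2C9", "CYP2D6"], ["total"])
        with pytest.warns(UserWarning, match="constant"):
            result = correlation_analysis(bank)
        assert np.isnan(result.correlations.loc["total", "CYP2D6"])
        assert "CYP2D6" not in result.ranking["total"].index

    def test_report_is_readable(self, mixed_bank):
        text = correlation_analysis(mixed_bank).report()
        assert "CYP2C9" in text and "supported" in text

    def test_too_few_donors_rejected(self):
        with pytest.raises(DonorBankError):
            _bank(np.ones((2, 2)), np.ones((2, 1)), ["a", "b"], ["r"])


class TestGenotypeComparison:
    def test_identical_groups_fold_one_p_one(self):
        rates = pd.DataFrame(
            {"genotype": ["*1/*1"] * 3 + ["*2/*2"] * 3, "rate": [1.0, 1.1, 0.9] * 2}
        )
        result = genotype_rate_comparison(rates)
        assert result.loc["*2/*2", "fold_decrease"] == pytest.approx(1.0)
        assert result.loc["*2/*2", "p_value"] == pytest.approx(1.0)
        assert result.loc["*1/*1", "fold_decrease"] == 1.0

    def test_three_fold_decrease_for_intermediate_genotype(self):
        rng = np.random.default_rng(11)
        wt = 1.0 * np.exp(rng.normal(0, 0.05, 4))
        var = 0.345 * np.exp(rng.normal(0, 0.05, 4))
        rates = pd.DataFrame(
            {"genotype": ["*1/*1"] * 4 + ["*2/*2"] * 4, "rate": np.concatenate([wt, var])}
        )
        result = genotype_rate_comparison(rates)
        assert result.loc["*2/*2", "fold_decrease"] == pytest.approx(1.0 / 0.345, rel=0.1)
        assert 2.5 < result.loc["*2/*2", "fold_decrease"] < 3.5

    def test_welch_p_matches_quadrature_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 0.1, 5)
        b = rng.normal(0.7, 0.2, 4)
        rates = pd.DataFrame(
            {"genotype": ["*1/*1"] * 5 + ["*3/*3"] * 4, "rate": np.concatenate([a, b])}
        )
        p_pkg = genotype_rate_comparison(rates).loc["*3/*3", "p_value"]
        # independent route: Welch statistic + numerically integrated t tail
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_stat = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        tail, _ = integrate.quad(lambda x: stats.t.pdf(x, df), abs(t_stat), np.inf)
        assert p_pkg == pytest.approx(2.0 * tail, rel=1e-6)

    def test_zero_variant_mean_reports_infinite_fold(self):
        rates = pd.DataFrame(
            {"genotype": ["*1/*1"] * 2 + ["*3/*3"] * 2, "rate": [1.0, 1.2, 0.0, 0.0]}
        )
        with pytest.warns(UserWarning, match="infinite"):
            result = genotype_rate_comparison(rates)
        assert np.isinf(result.loc["*3/*3", "fold_decrease"])

    def test_single_replicate_rejected(self):
        rates = pd.DataFrame({"genotype": ["*1/*1", "*2/*2"], "rate": [1.0, 0.4]})
        with pytest.raises(DonorBankError):
            genotype_rate_comparison(rates)

    def test_missing_reference_rejected(self):
        rates = pd.DataFrame({"genotype": ["*2/*2"] * 3, "rate": [1.0, 0.4, 0.5]})
        with pytest.raises(DonorBankError):
            genotype_rate_comparison(rates)


def test_bank_csv_round_trip(tmp_path, mixed_bank):
    path = tmp_path / "bank.csv"
    mixed_bank.to_csv(path)
    back = DonorBank.from_csv(path)
    pd.testing.assert_frame_equal(back.activities, mixed_bank.activities)
    pd.testing.assert_frame_equal(back.rates, mixed_bank.rates)
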