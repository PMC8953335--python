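"""Parameter estimation: screening, rates, visit mixes, cost growth, shares."""

import numpy as np
import pandas as pd
import pytest

from simisim.core import DomainError, clip_renormalize
from simisim.estimation import (
    annual_increment,
    assign_expense_levels,
    average_share,
    estimate_admission_rates,
    estimate_visit_types,
    mean_growth,
    project_mean,
    screen_serious,
)

from conftest import make_config
from simisim.synthetic_data import generate_claims, generate_population


def _toy_claims(serious_values, year=2016):
    n = len(serious_values)
    return pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(n)],
            "year": year,
            "gender": 1,
            "age_band": 1,
            "insurance_type": "URRBMI",
            "visit_type": "BOIMS",
            "total_expense": [s + 1000.0 for s in serious_values],
            "fund_payment": 1000.0,
            "serious_expense": serious_values,
            "total_self_payment": 0.0,
        }
    )


class TestScreenSerious:
    def test_threshold_is_strict(self):
        claims = _toy_claims([10_000.0, 10_000.01])
        kept = screen_serious(claims)
        assert kept["serious_expense"].tolist() == [10_000.01]

    def test_toy_database_count(self):
        claims = _toy_claims([5_000.0, 10_000.0, 10_001.0, 25_000.0, 40_000.0])
        assert len(screen_serious(claims)) == 3

    def test_empty_result_permitted(self):
        assert screen_serious(_toy_claims([1.0, 2.0])).empty

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(DomainError):
            screen_serious(_toy_claims([1.0]), threshold=0.0)


class TestAdmissionRates:
    PUBLISHED_MALE_YOUNG = {2011: 0.1691, 2012: 0.1782, 2013: 0.2128,
                            2014: 0.1937, 2015: 0.6576, 2016: 0.6785}

    def test_increment_formula_on_published_series(self):
        # increment = (rate2015 - rate2011) / 5 = 0.0977 -> rate2017 = 0.7762
        s = pd.Series(self.PUBLISHED_MALE_YOUNG)
        inc = annual_increment(s)
        assert inc == pytest.approx((0.6576 - 0.1691) / 5, abs=1e-12)
        assert 0.6785 + inc == pytest.approx(0.7762, abs=1e-4)

    def test_constant_observed_rates_extrapolate_constant(self):
        claims = pd.concat(
            [_toy_claims([20_000.0] * 10, year=y) for y in range(2011, 2017)],
            ignore_index=True,
        )
        insured = pd.DataFrame(
            [{"gender": 1, "age_band": 1, "year": y, "insured": 1000} for y in range(2011, 2017)]
        )
        table = estimate_admission_rates(claims, insured, horizon=(2017, 2025))
        # 10 screened of 1,000 insured -> 1.0% in every observed and forecast year
        for year in range(2011, 2026):
            assert table.rate(1, 1, year) == pytest.approx(1.0)

    def test_negative_extrapolation_floored_at_zero(self):
        rows = []
        counts = {2011: 50, 2012: 40, 2013: 30, 2014: 20, 2015: 10, 2016: 5}
        for y, k in counts.items():
            rows.append(_toy_claims([20_000.0] * k, year=y))
        insured = pd.DataFrame(
            [{"gender": 1, "age_band": 1, "year": y, "insured": 1000} for y in counts]
        )
        table = estimate_admission_rates(pd.concat(rows, ignore_index=True), insured)
        assert table.rate(1, 1, 2025) == 0.0

    def test_zero_insured_is_domain_error(self):
        insured = pd.DataFrame([{"gender": 1, "age_band": 1, "year": 2016, "insured": 0}])
        with pytest.raises(DomainError):
            estimate_admission_rates(_toy_claims([20_000.0]), insured)


class TestVisitTypes:
    def test_empirical_frequencies_and_flat_extrapolation(self):
        claims = []
        for year in (2015, 2016):
            for vt, k in (("OOMS", 2), ("OIMS", 3), ("BOIMS", 5)):
                df = _toy_claims([20_000.0] * k, year=year)
                df["visit_type"] = vt
                claims.append(df)
        dist = estimate_visit_types(pd.concat(claims, ignore_index=True), horizon=(2017, 2020))
        # zero observed trend -> future triples equal the last observed triple
        np.testing.assert_allclose(dist.probs(1, 1, 2020), [0.2, 0.3, 0.5], atol=1e-12)

    def test_clip_and_renormalize_of_negative_extrapolation(self):
        out = clip_renormalize([-0.01, 0.30, 0.71])
        np.testing.assert_allclose(out, [0.0, 0.30 / 1.01, 0.71 / 1.01], atol=1e-12)
        assert out.sum() == pytest.approx(1.0)

    def test_extrapolated_triples_remain_distributions(self):
        claims = []
        for year, trip in ((2015, (0.6, 0.3, 0.1)), (2016, (0.2, 0.5, 0.3))):
            for vt, p in zip(("OOMS", "OIMS", "BOIMS"), trip):
                df = _toy_claims([20_000.0] * int(p * 100), year=year)
                df["visit_type"] = vt
                claims.append(df)
        dist = estimate_visit_types(pd.concat(claims, ignore_index=True), horizon=(2017, 2030))
        probs = dist.table[["p_ooms", "p_oims", "p_boims"]].to_numpy()
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


class TestExpenseLevels:
    def test_quartile_partition_sizes_differ_by_at_most_one(self):
        config = make_config(n_persons=500, rate=100.0, seed=2)
        claims = generate_claims(generate_population(config), config, years=(2016, 2016))
        levelled = assign_expense_levels(claims)
        for _, grp in levelled.groupby(["gender", "age_band", "year"]):
            sizes = grp["expense_level"].value_counts()
            assert set(sizes.index) <= {1, 2, 3, 4}
            assert sizes.max() - sizes.min() <= 1

    def test_levels_ordered_by_expense(self):
        claims = _toy_claims([20_000.0, 30_000.0, 40_000.0, 50_000.0])
        levelled = assign_expense_levels(claims)
        ordered = levelled.sort_values("total_expense")["expense_level"].tolist()
        assert ordered == [1, 2, 3, 4]


class TestCostGrowth:
    def test_growth_is_arithmetic_mean(self):
        assert mean_growth([0.10, 0.20, 0.30]) == pytest.approx(0.20)

    def test_published_stratum_projection(self):
        # 2016 mean 33,194.15, growth 0.01119 -> 2017 mean ~33,565.7
        assert project_mean(33_194.15, 0.01119, 1) == pytest.approx(33_565.75, abs=0.7)

    def test_zero_growth_keeps_mean_constant(self):
        assert project_mean(42_000.0, 0.0, 8) == 42_000.0


class TestPaymentProportions:
    def test_published_share_averaging(self):
        # yearly fund ratios 0.5270, 0.5785, 0.5660 -> mean 0.5572
        assert average_share([0.5270, 0.5785, 0.5660]) == pytest.approx(0.5572, abs=1e-4)

    def test_identical_ratios_average_to_themselves(self):
        assert average_share([0.61, 0.61, 0.61]) == pytest.approx(0.61)

    def test_simple_mean(self):
        assert average_share([0.60, 0.60, 0.63]) == pytest.approx(0.61)
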