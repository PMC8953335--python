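"""Stochastic engine: admission counts, sampling law, decomposition, determinism."""

import numpy as np
import pandas as pd
import pytest

from simisim.core import ConfigurationError, split_amount
from simisim.estimation import (
    AdmissionRateTable,
    CostModel,
    ProportionModel,
    VisitTypeDistribution,
)
from simisim.simulator import (
    SimulationConfig,
    cell_stream,
    decompose_payment,
    draw_visit_type,
    expected_patients,
    realize_admissions,
    sample_total_cost,
    simulate_cohort,
    split_insured,
)


def _tables(mean=38_909.90, triple=(0.0, 0.0, 1.0), shares=(0.5572, 0.28, 0.1628),
            years=(2017, 2025), growth=0.0):
    rates = AdmissionRateTable(pd.DataFrame(
        [{"gender": g, "age_band": a, "year": y, "rate_pct": 100.0}
         for g in (1, 2) for a in (1, 2) for y in range(years[0], years[1] + 1)]
    ))
    visit = VisitTypeDistribution(pd.DataFrame(
        [{"gender": g, "age_band": a, "year": y,
          "p_ooms": triple[0], "p_oims": triple[1], "p_boims": triple[2]}
         for g in (1, 2) for a in (1, 2) for y in range(years[0], years[1] + 1)]
    ))
    cost = CostModel(
        means=pd.DataFrame(
            [{"gender": g, "age_band": a, "expense_level": lev, "visit_type": vt,
              "year": y, "mean_cost": mean * (1 + growth) ** (y - years[0])}
             for g in (1, 2) for a in (1, 2) for lev in (1, 2, 3, 4)
             for vt in ("OOMS", "OIMS", "BOIMS") for y in range(years[0], years[1] + 1)]
        ),
        growth=pd.DataFrame(
            [{"gender": g, "age_band": a, "expense_level": lev, "visit_type": vt,
              "growth": growth}
             for g in (1, 2) for a in (1, 2) for lev in (1, 2, 3, 4)
             for vt in ("OOMS", "OIMS", "BOIMS")]
        ),
    )
    props = ProportionModel(pd.DataFrame(
        [{"gender": g, "age_band": a, "expense_level": lev, "visit_type": vt,
          "fund_share": shares[0], "serious_share": shares[1], "self_share": shares[2]}
         for g in (1, 2) for a in (1, 2) for lev in (1, 2, 3, 4)
         for vt in ("OOMS", "OIMS", "BOIMS")]
    ))
    return rates, visit, cost, props


class TestRealizeAdmissions:
    def test_zero_rate_gives_zero_patients(self):
        rates = AdmissionRateTable(pd.DataFrame(
            [{"gender": 1, "age_band": 1, "year": 2020, "rate_pct": 0.0}]
        ))
        cells = pd.DataFrame([{"gender": 1, "age_band": 1, "year": 2020, "insured": 10_000}])
        out = realize_admissions(cells, rates, SimulationConfig(years=(2020, 2020)))
        assert out["n_patients"].tolist() == [0]

    def test_expected_count_at_published_2020_scale(self):
        # 3,569,900 insured x 0.6993% -> about 24,964 expected patients
        assert expected_patients(3_569_900, 0.6993) == pytest.approx(24_964.4, abs=0.5)

    def test_deterministic_rounding_mode(self):
        rates = AdmissionRateTable(pd.DataFrame(
            [{"gender": 1, "age_band": 1, "year": 2020, "rate_pct": 1.5}]
        ))
        cells = pd.DataFrame([{"gender": 1, "age_band": 1, "year": 2020, "insured": 1_000}])
        out = realize_admissions(
            cells, rates, SimulationConfig(years=(2020, 2020), count_mode="deterministic")
        )
        assert out["n_patients"].tolist() == [15]

    def test_missing_rate_cell_is_configuration_error(self):
        rates = AdmissionRateTable(pd.DataFrame(
            [{"gender": 1, "age_band": 1, "year": 2020, "rate_pct": 1.0}]
        ))
        cells = pd.DataFrame([{"gender": 2, "age_band": 1, "year": 2020, "insured": 100}])
        with pytest.raises(ConfigurationError):
            realize_admissions(cells, rates, SimulationConfig(years=(2020, 2020)))


class TestDrawVisitType:
    def test_degenerate_triples(self, rng):
        _, visit_ooms, _, _ = _tables(triple=(1.0, 0.0, 0.0))
        assert draw_visit_type(1, 1, 2020, visit_ooms, rng) == "OOMS"
        _, visit_boims, _, _ = _tables(triple=(0.0, 0.0, 1.0))
        assert draw_visit_type(1, 1, 2020, visit_boims, rng) == "BOIMS"

    def test_frequencies_converge_to_published_triple(self):
        # BOIMS probability 0.763499: 3 s.e. band at 100,000 draws
        _, visit, _, _ = _tables(triple=(0.113991, 0.122510, 0.763499))
        rng = np.random.default_rng(42)
        draws = [draw_visit_type(1, 1, 2020, visit, rng) for _ in range(100_000)]
        boims = np.mean([d == "BOIMS" for d in draws])
        assert 0.7595 <= boims <= 0.7675


class TestSampleTotalCost:
    def test_mean_convergence_half_percent(self):
        # (ran02 + 0.5) x 38,909.90: MC mean within 0.5% at 100,000 draws
        _, _, cost, _ = _tables(mean=38_909.90)
        rng = np.random.default_rng(7)
        draws = np.array([
            sample_total_cost(1, 1, 2020, "BOIMS", cost, rng)[1] for _ in range(100_000)
        ])
        assert abs(draws.mean() - 38_909.90) / 38_909.90 < 0.005

    def test_support_bounds(self):
        _, _, cost, _ = _tables(mean=38_909.90)
        rng = np.random.default_rng(3)
        draws = np.array([
            sample_total_cost(1, 1, 2020, "BOIMS", cost, rng)[1] for _ in range(2_000)
        ])
        assert draws.min() >= 19_454.95
        assert draws.max() <= 58_364.85

    def test_midpoint_uniform_returns_mean_exactly(self):
        # ran02 = 0.5 -> cost = mean
        class HalfRng:
            def random(self, n=None):
                return np.full(n, 0.5) if n else 0.5

        _, _, cost, _ = _tables(mean=38_909.90)
        level, value = sample_total_cost(1, 1, 2020, "BOIMS", cost, HalfRng())
        assert value == pytest.approx(38_909.90, abs=0.005)
        assert level == 3  # ran01 = 0.5 falls in the third quartile interval


class TestDecomposePayment:
    def test_exact_proportional_split(self):
        parts = decompose_payment(100_000.0, (0.5572, 0.28, 0.1628))
        assert parts == (55_720.0, 28_000.0, 16_280.0)

    def test_zero_total(self):
        assert decompose_payment(0.0, (0.5, 0.3, 0.2)) == (0.0, 0.0, 0.0)

    def test_all_to_fund(self):
        assert decompose_payment(12_345.67, (1.0, 0.0, 0.0)) == (12_345.67, 0.0, 0.0)

    def test_conservation_under_awkward_shares(self):
        for total in (0.01, 0.02, 99.99, 12_345.67, 1e7 + 0.03):
            parts = split_amount(total, (1 / 3, 1 / 3, 1 / 3))
            assert sum(parts) == pytest.approx(round(total, 2), abs=1e-9)


class TestSimulateCohort:
    def _cells(self, insured=1_000, years=(2020, 2020)):
        return pd.DataFrame(
            [{"gender": 1, "age_band": 1, "year": y, "insured": insured}
             for y in range(years[0], years[1] + 1)]
        )

    def test_closed_form_when_randomness_degenerate(self):
        # rate 100%, deterministic counts, single visit type; totals average the mean
        rates, visit, cost, props = _tables(mean=40_000.0)
        config = SimulationConfig(years=(2020, 2020), seed=1, count_mode="deterministic")
        out = simulate_cohort(self._cells(500), rates, visit, cost, props, config)
        assert len(out) == 500
        assert (out["visit_type"] == "BOIMS").all()
        assert out["total_expense"].between(20_000, 60_000).all()

    def test_seed_determinism(self):
        rates, visit, cost, props = _tables()
        config = SimulationConfig(years=(2017, 2019), seed=12)
        a = simulate_cohort(self._cells(800, (2017, 2019)), rates, visit, cost, props, config)
        b = simulate_cohort(self._cells(800, (2017, 2019)), rates, visit, cost, props, config)
        pd.testing.assert_frame_equal(a, b)

    def test_per_patient_conservation(self):
        rates, visit, cost, props = _tables()
        config = SimulationConfig(years=(2020, 2020), seed=5)
        out = simulate_cohort(self._cells(2_000), rates, visit, cost, props, config)
        resid = (
            out["total_expense"] - out["fund_payment"]
            - out["serious_expense"] - out["total_self_payment"]
        )
        assert (resid.abs() < 1e-9).all()

    def test_batch_engine_matches_naive_per_patient_oracle(self):
        """The vectorised engine must reproduce a plain per-patient loop draw for draw."""
        rates, visit, cost, props = _tables(
            mean=50_000.0, triple=(0.2, 0.3, 0.5), shares=(0.5, 0.3, 0.2), growth=0.01
        )
        config = SimulationConfig(years=(2020, 2020), seed=31)
        cells = self._cells(900)
        batch = simulate_cohort(cells, rates, visit, cost, props, config,
                                disease_prevalence=0.4)

        # independent naive oracle: same substream, four uniforms per patient
        rng = cell_stream(31, 1, 1, 2020)
        n = rng.poisson(900 * 100.0 / 100.0)
        rows = []
        for _ in range(int(n)):
            u_visit, ran01, ran02, u_dis = (rng.random() for _ in range(4))
            vt = ("OOMS" if u_visit <= 0.2 else "OIMS" if u_visit <= 0.5 else "BOIMS")
            lev = 1 + sum(ran01 > q for q in (0.25, 0.5, 0.75))
            mean = 50_000.0 * 1.01 ** (2020 - 2017)
            total = round((ran02 + 0.5) * mean, 2)
            fund, serious, self_pay = split_amount(total, (0.5, 0.3, 0.2))
            rows.append((vt, lev, u_dis < 0.4, total, fund, serious, self_pay))
        naive = pd.DataFrame(rows, columns=[
            "visit_type", "expense_level", "disease_eligible",
            "total_expense", "fund_payment", "serious_expense", "total_self_payment",
        ])
        assert len(batch) == len(naive) <= 1_000
        pd.testing.assert_frame_equal(
            batch[naive.columns].reset_index(drop=True), naive, check_dtype=False
        )

    def test_scale_equivariance_of_costs(self):
        """Multiplying all stratum means by k scales every total by k (to fen rounding)."""
        config = SimulationConfig(years=(2020, 2020), seed=9)
        base = simulate_cohort(self._cells(500), *_tables(mean=40_000.0), config)
        scaled = simulate_cohort(self._cells(500), *_tables(mean=400_000.0), config)
        np.testing.assert_allclose(
            scaled["total_expense"], 10 * base["total_expense"], atol=0.06
        )

    def test_adding_a_cell_does_not_perturb_another(self):
        rates, visit, cost, props = _tables()
        config = SimulationConfig(years=(2020, 2020), seed=17)
        one = simulate_cohort(self._cells(600), rates, visit, cost, props, config)
        two_cells = pd.concat([
            self._cells(600),
            pd.DataFrame([{"gender": 2, "age_band": 2, "year": 2020, "insured": 300}]),
        ], ignore_index=True)
        two = simulate_cohort(two_cells, rates, visit, cost, props, config)
        sub = two[(two["gender"] == 1) & (two["age_band"] == 1)].reset_index(drop=True)
        pd.testing.assert_frame_equal(sub, one)


class TestSplitInsured:
    def test_shares_distribute_and_round(self):
        proj = pd.DataFrame([{"year": 2020, "insured": 1_001, "uninsured": 0}])
        cells = split_insured(proj, {(1, 1): 0.5, (2, 1): 0.5})
        assert cells["insured"].tolist() == [500, 500]

    def test_invalid_shares_rejected(self):
        proj = pd.DataFrame([{"year": 2020, "insured": 100, "uninsured": 0}])
        with pytest.raises(ConfigurationError):
            split_insured(proj, {(1, 1): 0.7})
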