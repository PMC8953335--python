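"""The Shanghai reference scenario: packaged parameter tables and their completion.

The published study estimated its parameters from a confidential claims
sample and printed them only partially.  This module loads the printed
parameter tables shipped as fixtures and completes them into a full
simulation-ready parameter set:

* **admission rates** — printed for 2011–2017 and 2025 per gender × age
  band; intervening forecast years are filled with the constant annual
  increment implied by the printed 2017 and 2025 values (the published
  extrapolation model adds a constant increment each year);
* **visit-type mix** — printed for 2016 and 2017; later years extend the
  2016→2017 annual change, clipped and renormalised;
* **cost model** — the male/<60 BOIMS strata are printed in full (four
  expense levels); the remaining cells are *synthetic completions* obtained
  by scaling that level profile to the two printed anchor strata, and
  OOMS/OIMS means scale the BOIMS means by the published 2020 per-capita
  cost ratios;
* **payment shares** — printed fund shares for six strata; missing cells are
  synthetic completions by level-wise offsets to the printed anchors; the
  serious-expense share is calibrated to the published payment composition;
* **insured-population age mix** — unpublished; calibrated at load time so
  the 2020 expected patient volume under the reference rates matches the
  published 2020 patient count (the ≥60 admission rates are roughly tenfold
  the <60 ones, so the published volume pins down the age mix).

Synthetic completions are scenario fixtures, not estimates from data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CELLS, EXPENSE_LEVELS, VISIT_TYPES
from .estimation import (
    AdmissionRateTable,
    CostModel,
    ProportionModel,
    VisitTypeDistribution,
    extrapolate_triples,
)
from .population import load_reference_projection
from .policy_engine import DISEASE_BASED_SCHEME, LARGE_EXPENSE_SCHEME, PolicyScheme
from .synthetic_data import GeneratorConfig

#: OOMS / OIMS mean-cost multipliers relative to BOIMS, from the published
#: 2020 per-capita costs (97,883 / 137,317 and 173,194 / 137,317).
VISIT_COST_MULTIPLIERS = {"OOMS": 0.713, "OIMS": 1.261, "BOIMS": 1.0}

#: Serious-expense share of total expense, calibrated to the published
#: payment composition (SIMIS payment + self-payment under SIMIS ≈ 28.5%).
SERIOUS_SHARE = 0.285

#: Disease-based-scheme eligibility prevalence among seriously ill patients,
#: calibrated to the published comparison (~18,000 of 25,267 2020 patients).
DISEASE_PREVALENCE = 0.712

#: Annual SIMIS financing amount used in the sustainability comparison (yuan).
FINANCING_YUAN = 190_000_000.0


def _read_fixture(name: str) -> pd.DataFrame:
    with files("simisim").joinpath(f"fixtures/{name}").open("rb") as fh:
        return pd.read_csv(fh)


def load_admission_rate_anchors() -> pd.DataFrame:
    """Printed admission rates (percent): 2011–2017 and 2025 per cell."""
    return _read_fixture("admission_rates.csv")


def load_visit_type_anchors() -> pd.DataFrame:
    """Printed visit-type triples for 2016 and 2017 per cell."""
    return _read_fixture("visit_type_distribution.csv")


def load_cost_anchors() -> pd.DataFrame:
    """Printed BOIMS stratum means for 2016, growth rates and 2017 means."""
    return _read_fixture("boims_cost_strata.csv")


def load_fund_share_anchors() -> pd.DataFrame:
    """Printed per-stratum fund-payment shares, 2014–2016 and their mean."""
    return _read_fixture("fund_payment_shares.csv")


def load_payment_totals() -> pd.DataFrame:
    """Published annual payment components, in 100-million-yuan units."""
    return _read_fixture("annual_payment_totals.csv")


def load_simis_per_capita() -> pd.DataFrame:
    """Published per-capita SIMIS payment table (beneficiaries, payments)."""
    return _read_fixture("simis_per_capita.csv")


def reference_admission_rates(horizon: tuple[int, int] = (2011, 2025)) -> AdmissionRateTable:
    """Printed rates with forecast years filled at a constant annual increment."""
    anchors = load_admission_rate_anchors()
    rows = []
    for (g, a), grp in anchors.groupby(["gender", "age_band"]):
        s = grp.set_index("year")["rate_pct"].sort_index()
        full = s.reindex(range(int(s.index.min()), int(s.index.max()) + 1)).interpolate()
        for year, rate in full.items():
            if horizon[0] <= year <= horizon[1]:
                rows.append({"gender": int(g), "age_band": int(a),
                             "year": int(year), "rate_pct": float(rate)})
    return AdmissionRateTable(pd.DataFrame(rows))


def reference_visit_types(horizon: tuple[int, int] = (2016, 2025)) -> VisitTypeDistribution:
    """Printed 2016/2017 triples, extended by their annual change."""
    return VisitTypeDistribution(extrapolate_triples(load_visit_type_anchors(), horizon))


def _completed_boims_means() -> tuple[dict, dict]:
    """Full 16-stratum BOIMS base means (2016) and growth rates.

    The fully printed male/<60 level profile is scaled to the printed
    anchors of the other cells; cells with no printed anchor reuse the
    profile unscaled.  Synthetic completion — see module docstring.
    """
    anchors = load_cost_anchors()
    printed = {
        (int(r.gender), int(r.age_band), int(r.expense_level)): (float(r.mean_2016), float(r.growth))
        for r in anchors.itertuples()
    }
    profile = {lev: printed[(1, 1, lev)] for lev in EXPENSE_LEVELS}
    scale = {(1, 1): 1.0, (2, 1): 1.0}
    scale[(1, 2)] = printed[(1, 2, 1)][0] / profile[1][0]
    scale[(2, 2)] = printed[(2, 2, 4)][0] / profile[4][0]
    means, growth = {}, {}
    for (g, a) in CELLS:
        for lev in EXPENSE_LEVELS:
            if (g, a, lev) in printed:
                means[(g, a, lev)], growth[(g, a, lev)] = printed[(g, a, lev)]
            else:
                means[(g, a, lev)] = profile[lev][0] * scale[(g, a)]
                growth[(g, a, lev)] = profile[lev][1]
    return means, growth


def reference_cost_model(horizon: tuple[int, int] = (2016, 2025)) -> CostModel:
    """Completed 16-stratum × visit-type cost model over ``horizon``."""
    means16, growth16 = _completed_boims_means()
    mean_rows, growth_rows = [], []
    for (g, a) in CELLS:
        for lev in EXPENSE_LEVELS:
            for vt in VISIT_TYPES:
                base = means16[(g, a, lev)] * VISIT_COST_MULTIPLIERS[vt]
                rate = growth16[(g, a, lev)]
                growth_rows.append((g, a, lev, vt, rate))
                for year in range(horizon[0], horizon[1] + 1):
                    mean_rows.append(
                        (g, a, lev, vt, year, base * (1.0 + rate) ** (year - 2016))
                    )
    return CostModel(
        means=pd.DataFrame(
            mean_rows,
            columns=["gender", "age_band", "expense_level", "visit_type", "year", "mean_cost"],
        ),
        growth=pd.DataFrame(
            growth_rows,
            columns=["gender", "age_band", "expense_level", "visit_type", "growth"],
        ),
    )


def _completed_fund_shares() -> dict:
    """Full 16-stratum fund shares: printed means plus level-wise offsets."""
    anchors = load_fund_share_anchors()
    printed = {
        (int(r.gender), int(r.age_band), int(r.expense_level)): float(r.mean_share)
        for r in anchors.itertuples()
    }
    profile = {lev: printed[(1, 1, lev)] for lev in EXPENSE_LEVELS}
    offset = {(1, 1): 0.0, (2, 1): 0.0}
    offset[(1, 2)] = printed[(1, 2, 1)] - profile[1]
    offset[(2, 2)] = printed[(2, 2, 4)] - profile[4]
    return {
        (g, a, lev): printed.get((g, a, lev), profile[lev] + offset[(g, a)])
        for (g, a) in CELLS
        for lev in EXPENSE_LEVELS
    }


def reference_proportion_model(serious_share: float = SERIOUS_SHARE) -> ProportionModel:
    """Completed payment-share triples (fund, serious, residual self)."""
    fund16 = _completed_fund_shares()
    rows = [
        (g, a, lev, vt, fund16[(g, a, lev)], serious_share,
         1.0 - fund16[(g, a, lev)] - serious_share)
        for (g, a) in CELLS
        for lev in EXPENSE_LEVELS
        for vt in VISIT_TYPES
    ]
    return ProportionModel(
        pd.DataFrame(
            rows,
            columns=["gender", "age_band", "expense_level", "visit_type",
                     "fund_share", "serious_share", "self_share"],
        )
    )


def reference_cell_shares() -> dict[tuple[int, int], float]:
    """Insured-population cell mix, age share calibrated to the 2020 volume.

    Solves for the ≥60 share so that the insured-weighted 2020 admission
    rate equals the published 2020 patient count over the published 2020
    insured population; genders split evenly within each age band.
    """
    rates = reference_admission_rates()
    projection = load_reference_projection().set_index("year")
    per_capita = load_simis_per_capita().set_index("year")
    target = per_capita.loc[2020, "beneficiaries"] / projection.loc[2020, "insured"] * 100.0
    r_young = np.mean([rates.rate(g, 1, 2020) for g in (1, 2)])
    r_old = np.mean([rates.rate(g, 2, 2020) for g in (1, 2)])
    s_old = float((target - r_young) / (r_old - r_young))
    return {(1, 1): (1 - s_old) / 2, (2, 1): (1 - s_old) / 2,
            (1, 2): s_old / 2, (2, 2): s_old / 2}


@dataclass
class Scenario:
    """A complete, simulation-ready parameter set."""

    projection: pd.DataFrame
    cell_shares: Mapping[tuple[int, int], float]
    rates: AdmissionRateTable
    visit_types: VisitTypeDistribution
    cost_model: CostModel
    proportions: ProportionModel
    disease_prevalence: float
    schemes: tuple[PolicyScheme, ...]
    financing_yuan: float


def reference_scenario(scale: float = 1.0) -> Scenario:
    """The Shanghai reference scenario, optionally at reduced population scale.

    ``scale`` multiplies insured counts only (a 1/100-scale run simulates
    1% of the insured population with identical parameters).
    """
    projection = load_reference_projection()
    if scale != 1.0:
        projection = projection.assign(
            insured=(projection["insured"] * scale).round().astype(np.int64),
            uninsured=(projection["uninsured"] * scale).round().astype(np.int64),
        )
    return Scenario(
        projection=projection,
        cell_shares=reference_cell_shares(),
        rates=reference_admission_rates(),
        visit_types=reference_visit_types(),
        cost_model=reference_cost_model(),
        proportions=reference_proportion_model(),
        disease_prevalence=DISEASE_PREVALENCE,
        schemes=(LARGE_EXPENSE_SCHEME, DISEASE_BASED_SCHEME),
        financing_yuan=FINANCING_YUAN,
    )


def default_generator_config(
    n_persons: int = 67_418, seed: int = 0
) -> GeneratorConfig:
    """Generator defaults emulating the study's calibration sample.

    A 2% sample of the ~3.37 million 2016 insured gives the default cohort
    size.  Admission rates and visit-type mixes are the published observed
    2011–2016 values (visit mixes back-cast with the 2016→2017 annual
    change); stratum means/growth and payment shares are the completed
    reference tables; the cell mix is the calibrated reference mix.
    """
    rates_anchor = load_admission_rate_anchors()
    admission = {
        (int(g), int(a)): {
            int(r.year): float(r.rate_pct)
            for r in grp.itertuples() if 2011 <= r.year <= 2016
        }
        for (g, a), grp in rates_anchor.groupby(["gender", "age_band"])
    }
    visits_anchor = load_visit_type_anchors()
    visit_probs: dict = {}
    for (g, a), grp in visits_anchor.groupby(["gender", "age_band"]):
        grp = grp.set_index("year")
        p16 = grp.loc[2016, ["p_ooms", "p_oims", "p_boims"]].to_numpy(dtype=float)
        delta = grp.loc[2017, ["p_ooms", "p_oims", "p_boims"]].to_numpy(dtype=float) - p16
        visit_probs[(int(g), int(a))] = {
            year: tuple(np.clip(p16 + (year - 2016) * delta, 0, 1)
                        / np.clip(p16 + (year - 2016) * delta, 0, 1).sum())
            for year in range(2011, 2017)
        }
    means16, growth16 = _completed_boims_means()
    fund16 = _completed_fund_shares()
    mean_costs, growth, shares = {}, {}, {}
    for (g, a) in CELLS:
        for lev in EXPENSE_LEVELS:
            for vt in VISIT_TYPES:
                key = (g, a, lev, vt)
                mean_costs[key] = means16[(g, a, lev)] * VISIT_COST_MULTIPLIERS[vt]
                growth[key] = growth16[(g, a, lev)]
                fund = fund16[(g, a, lev)]
                shares[key] = (fund, SERIOUS_SHARE, 1.0 - fund - SERIOUS_SHARE)
    return GeneratorConfig(
        n_persons=n_persons,
        admission_rates=admission,
        visit_probs=visit_probs,
        mean_costs=mean_costs,
        growth=growth,
        shares=shares,
        years=(2011, 2016),
        base_year=2016,
        seed=seed,
        cell_probs=reference_cell_shares(),
        disease_prevalence=DISEASE_PREVALENCE,
    )
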