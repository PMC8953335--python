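"""Per-person stochastic simulation of serious-illness medical consumption.

For each (gender × age-band) cell and simulated year the engine

1. realises the number of seriously ill patients from the insured count and
   the cell's admission rate (Poisson by default, deterministic rounding for
   exact tests);
2. draws each patient's visit type from the cell-year OOMS/OIMS/BOIMS mix;
3. draws the annual total expense with the two-random-number rule: ``ran01``
   selects the expense-level quartile, ``ran02 ~ Uniform(0, 1)`` sets the
   dispersion, ``cost = (ran02 + 0.5) × stratum mean`` — so the cost lies in
   [0.5, 1.5] × mean and its expectation is the stratum mean;
4. splits the total into fund payment / serious expense / total self-payment
   with the stratum's fixed share triple, fen-exact.

Randomness contract: each (cell, year) owns an independent substream seeded
``[seed, gender, age_band, year]``; within it, one count draw (Poisson mode
only) is followed by **four uniforms per patient, in order**: visit type,
ran01, ran02, disease-eligibility.  A naive per-patient loop that consumes
uniforms in that order reproduces the batch engine draw for draw.

Simulated patients are anonymous annual draws; no longitudinal linkage
across years is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import ConfigurationError, split_amount, split_amounts, VISIT_TYPES
from .estimation import AdmissionRateTable, CostModel, ProportionModel, VisitTypeDistribution

SIM_COLUMNS = [
    "gender", "age_band", "year", "visit_type", "expense_level", "disease_eligible",
    "total_expense", "fund_payment", "serious_expense", "total_self_payment",
]


@dataclass
class SimulationConfig:
    """Knobs of the stochastic engine.

    ``level_probs`` are the masses of ran01's four quartile intervals
    (equal quarters by default; configurable to empirical frequencies).
    ``count_mode`` is ``"poisson"`` or ``"deterministic"`` (round the
    expected count).
    """

    years: tuple[int, int] = (2017, 2025)
    seed: int = 0
    level_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    count_mode: str = "poisson"

    def validate(self) -> None:
        lp = np.asarray(self.level_probs, dtype=float)
        if lp.size != 4 or (lp < 0).any() or abs(lp.sum() - 1.0) > 1e-9:
            raise ConfigurationError("level_probs must be 4 probabilities summing to 1")
        if self.count_mode not in ("poisson", "deterministic"):
            raise ConfigurationError(f"unknown count_mode {self.count_mode!r}")
        if self.years[0] > self.years[1]:
            raise ConfigurationError("years must be an inclusive (first, last) range")


def cell_stream(seed: int, gender: int, age_band: int, year: int) -> np.random.Generator:
    """The (cell, year) random substream; adding a cell never perturbs another."""
    return np.random.default_rng([seed, gender, age_band, year])


def split_insured(
    projection: pd.DataFrame, cell_shares: Mapping[tuple[int, int], float]
) -> pd.DataFrame:
    """Distribute yearly insured totals over (gender, age_band) cells.

    ``cell_shares`` maps (gender, age_band) → fraction of the insured
    population (must sum to 1).  Returns columns gender, age_band, year,
    insured (whole persons, per-cell rounding).
    """
    total = sum(cell_shares.values())
    if abs(total - 1.0) > 1e-6:
        raise ConfigurationError(f"cell shares sum to {total}, expected 1")
    rows = [
        {"gender": g, "age_band": a, "year": int(r.year),
         "insured": int(round(r.insured * share))}
        for (g, a), share in sorted(cell_shares.items())
        for r in projection.itertuples()
    ]
    return pd.DataFrame(rows)


def expected_patients(insured: int, rate_pct: float) -> float:
    """Expected number of seriously ill patients in a cell-year."""
    return insured * rate_pct / 100.0


def realize_admissions(
    insured_cells: pd.DataFrame,
    rates: AdmissionRateTable,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Realise per-cell-year patient counts from insured counts and rates.

    Poisson mode draws one Poisson variate per cell-year from its substream;
    deterministic mode rounds the expectation.  Missing rate cells raise a
    configuration error.
    """
    config.validate()
    rows = []
    for r in insured_cells.itertuples():
        g, a, year = int(r.gender), int(r.age_band), int(r.year)
        mu = expected_patients(int(r.insured), rates.rate(g, a, year))
        if config.count_mode == "poisson":
            n = int(cell_stream(config.seed, g, a, year).poisson(mu))
        else:
            n = int(round(mu))
        rows.append({"gender": g, "age_band": a, "year": year, "n_patients": n})
    return pd.DataFrame(rows)


def draw_visit_type(
    gender: int, age_band: int, year: int,
    dist: VisitTypeDistribution, rng: np.random.Generator,
) -> str:
    """Draw one visit type, consuming a single uniform from ``rng``."""
    p = dist.probs(gender, age_band, year)
    u = rng.random()
    return VISIT_TYPES[int(np.searchsorted(np.cumsum(p), u, side="right").clip(0, 2))]


def sample_total_cost(
    gender: int, age_band: int, year: int, visit_type: str,
    cost_model: CostModel, rng: np.random.Generator,
    level_probs=(0.25, 0.25, 0.25, 0.25),
) -> tuple[int, float]:
    """Draw (expense_level, total cost) with the two-uniform rule.

    Consumes exactly two uniforms: ran01 picks the expense-level quartile
    (interval masses ``level_probs``), ran02 scales the stratum mean by
    (ran02 + 0.5).
    """
    ran01, ran02 = rng.random(2)
    level = int(np.searchsorted(np.cumsum(level_probs), ran01, side="right").clip(0, 3)) + 1
    mean = cost_model.mean(gender, age_band, level, visit_type, year)
    return level, round((ran02 + 0.5) * mean, 2)


def decompose_payment(total: float, shares) -> tuple[float, float, float]:
    """Split a total expense into (fund, serious, self), fen-exact."""
    fund, serious, self_pay = split_amount(total, shares)
    return fund, serious, self_pay


def _simulate_cell_year(
    gender: int, age_band: int, year: int, insured: int,
    rates: AdmissionRateTable,
    visit_types: VisitTypeDistribution,
    cost_model: CostModel,
    proportions: ProportionModel,
    config: SimulationConfig,
    disease_prevalence: float,
) -> pd.DataFrame | None:
    rng = cell_stream(config.seed, gender, age_band, year)
    mu = expected_patients(insured, rates.rate(gender, age_band, year))
    n = int(rng.poisson(mu)) if config.count_mode == "poisson" else int(round(mu))
    if n == 0:
        return None
    u = rng.random((n, 4))  # visit, ran01, ran02, disease — fixed per-patient order

    vp_cum = np.cumsum(visit_types.probs(gender, age_band, year))
    visit_idx = np.searchsorted(vp_cum, u[:, 0], side="right").clip(0, 2)
    lp_cum = np.cumsum(np.asarray(config.level_probs, dtype=float))
    level = np.searchsorted(lp_cum, u[:, 1], side="right").clip(0, 3) + 1
    disease = u[:, 3] < disease_prevalence

    total = np.empty(n, dtype=float)
    share_mat = np.empty((n, 3), dtype=float)
    for vt_i, vt in enumerate(VISIT_TYPES):
        for lev in (1, 2, 3, 4):
            mask = (visit_idx == vt_i) & (level == lev)
            if not mask.any():
                continue
            mean = cost_model.mean(gender, age_band, lev, vt, year)
            total[mask] = np.round((u[mask, 2] + 0.5) * mean, 2)
            share_mat[mask] = proportions.shares(gender, age_band, lev, vt)
    parts = split_amounts(total, share_mat)

    return pd.DataFrame(
        {
            "gender": gender, "age_band": age_band, "year": year,
            "visit_type": np.array(VISIT_TYPES)[visit_idx],
            "expense_level": level,
            "disease_eligible": disease,
            "total_expense": total,
            "fund_payment": parts[:, 0],
            "serious_expense": parts[:, 1],
            "total_self_payment": parts[:, 2],
        }
    )


def simulate_cohort(
    insured_cells: pd.DataFrame,
    rates: AdmissionRateTable,
    visit_types: VisitTypeDistribution,
    cost_model: CostModel,
    proportions: ProportionModel,
    config: SimulationConfig,
    disease_prevalence: float = 0.0,
) -> pd.DataFrame:
    """Simulate all patient-years for the configured horizon.

    ``insured_cells`` holds columns gender, age_band, year, insured (see
    :func:`split_insured`).  Fully reproducible given the config seed; the
    ``disease_eligible`` flag is drawn per patient with the given prevalence
    for use by the disease-based payment scheme.
    """
    config.validate()
    frames = []
    window = insured_cells[
        (insured_cells["year"] >= config.years[0]) & (insured_cells["year"] <= config.years[1])
    ]
    for r in window.sort_values(["year", "gender", "age_band"]).itertuples():
        frame = _simulate_cell_year(
            int(r.gender), int(r.age_band), int(r.year), int(r.insured),
            rates, visit_types, cost_model, proportions, config, disease_prevalence,
        )
        if frame is not None:
            frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=SIM_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SIM_COLUMNS]
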