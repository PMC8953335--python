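"""Aggregation of simulated payment breakdowns into annual result tables.

Three analogues of the study's result tables are produced:

* **per-capita costs** — visits, visit proportions, per-capita total expense,
  its (population) standard deviation and range, per visit type and year;
* **payment composition** — annual totals of the four payment components in
  100-million-yuan units and their percentage shares of total expense;
* **SIMIS per-capita payments** — beneficiary counts, per-capita SIMIS
  payment and residual self-payment, and the annual payment range.

Display units follow the field's accounting conventions: yuan for per-capita
values, 100 million yuan for annual totals, million yuan for fund-expenditure
comparisons.  Raw CSVs are always written in yuan.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DomainError
from .estimation import (
    SCREEN_THRESHOLD,
    estimate_admission_rates,
    estimate_cost_growth,
    estimate_payment_proportions,
    estimate_visit_types,
    screen_serious,
)
from .policy_engine import apply_scheme_to_cohort
from .scenario import default_generator_config, reference_scenario
from .simulator import SimulationConfig, simulate_cohort, split_insured
from .synthetic_data import generate_claims, generate_population, write_claims_csv

logger = logging.getLogger(__name__)

HUNDRED_MILLION = 1e8

COMPONENTS = ["fund_payment", "simis_payment", "self_under_simis", "total_self_payment"]


@dataclass
class YearSummary:
    """Aggregates of one simulated year under one payment scheme."""

    year: int
    insured: int
    visit_stats: pd.DataFrame  # per visit type: visits, proportion, mean, std, max, min
    payment_amounts: dict  # component -> 100-million-yuan total (incl. "total")
    payment_shares: dict  # component -> percent of total expense
    beneficiaries: int
    per_capita_simis: float
    per_capita_self_under: float
    max_simis: float
    min_simis: float


def summarise_year(breakdowns: pd.DataFrame, insured: int, year: int) -> YearSummary:
    """Summarise one year of payment breakdowns.

    Standard deviations are population SDs.  Per-capita SIMIS figures are
    over beneficiaries; an empty year yields zero counts (logged).
    """
    df = breakdowns
    if "year" in df.columns:
        df = df[df["year"] == year]
    if df.empty:
        logger.warning("no simulated patients in %d", year)
        empty = pd.DataFrame(
            columns=["visit_type", "visits", "proportion", "mean", "std", "max", "min"]
        )
        return YearSummary(year, insured, empty,
                           {c: 0.0 for c in COMPONENTS} | {"total": 0.0},
                           {c: 0.0 for c in COMPONENTS}, 0, 0.0, 0.0, 0.0, 0.0)

    rows = []
    for vt, grp in df.groupby("visit_type"):
        x = grp["total_expense"].to_numpy()
        rows.append({
            "visit_type": vt,
            "visits": len(grp),
            "proportion": len(grp) / insured,
            "mean": x.mean(),
            "std": x.std(ddof=0),
            "max": x.max(),
            "min": x.min(),
        })
    visit_stats = pd.DataFrame(rows)

    total = df["total_expense"].sum()
    amounts = {c: round(df[c].sum() / HUNDRED_MILLION, 2) for c in COMPONENTS}
    amounts["total"] = round(total / HUNDRED_MILLION, 2)
    shares = {c: round(df[c].sum() / total * 100.0, 2) for c in COMPONENTS}

    bens = df[df["beneficiary"]]
    pay = bens["simis_payment"].to_numpy()
    return YearSummary(
        year=year,
        insured=insured,
        visit_stats=visit_stats,
        payment_amounts=amounts,
        payment_shares=shares,
        beneficiaries=len(bens),
        per_capita_simis=float(pay.mean()) if len(bens) else 0.0,
        per_capita_self_under=float(bens["self_under_simis"].mean()) if len(bens) else 0.0,
        max_simis=float(pay.max()) if len(bens) else 0.0,
        min_simis=float(pay.min()) if len(bens) else 0.0,
    )


def aggregate_payment_components(components: pd.DataFrame,
                                 columns=("urrbmi_fund", "simis_fund",
                                          "self_under_simis", "total_self")) -> pd.DataFrame:
    """Add computed totals and percentage shares to a component table.

    Input columns are annual payment components (any money unit, one row per
    year); output adds ``computed_total`` and ``<col>_share_pct`` columns.
    Shares sum to 100 by construction.
    """
    out = components.copy()
    total = out[list(columns)].sum(axis=1)
    out["computed_total"] = total.round(2)
    for c in columns:
        out[f"{c}_share_pct"] = (out[c] / total * 100.0).round(2)
    return out


def per_capita_table(breakdowns: pd.DataFrame, projection: pd.DataFrame) -> pd.DataFrame:
    """Per-visit-type annual cost statistics (per-capita cost table analogue)."""
    insured = projection.set_index("year")["insured"]
    frames = []
    for year in sorted(breakdowns["year"].unique()):
        summ = summarise_year(breakdowns, int(insured.loc[year]), int(year))
        vs = summ.visit_stats.assign(year=year, insured=summ.insured)
        frames.append(vs)
    return pd.concat(frames, ignore_index=True)[
        ["year", "insured", "visit_type", "visits", "proportion", "mean", "std", "max", "min"]
    ]


def payment_table(breakdowns: pd.DataFrame, projection: pd.DataFrame) -> pd.DataFrame:
    """Annual payment composition: 100-million-yuan amounts and percent shares."""
    insured = projection.set_index("year")["insured"]
    rows = []
    for year in sorted(breakdowns["year"].unique()):
        summ = summarise_year(breakdowns, int(insured.loc[year]), int(year))
        row = {"year": year}
        for c in COMPONENTS + ["total"]:
            row[f"{c}_100m"] = summ.payment_amounts[c]
        for c in COMPONENTS:
            row[f"{c}_share_pct"] = summ.payment_shares[c]
        rows.append(row)
    return pd.DataFrame(rows)


def simis_table(breakdowns: pd.DataFrame, projection: pd.DataFrame) -> pd.DataFrame:
    """Annual SIMIS beneficiary counts and per-capita payments."""
    insured = projection.set_index("year")["insured"]
    rows = []
    for year in sorted(breakdowns["year"].unique()):
        summ = summarise_year(breakdowns, int(insured.loc[year]), int(year))
        rows.append({
            "year": year,
            "beneficiaries": summ.beneficiaries,
            "per_capita_payment": round(summ.per_capita_simis, 2),
            "per_capita_self_under": round(summ.per_capita_self_under, 2),
            "max_payment": round(summ.max_simis, 2),
            "min_payment": round(summ.min_simis, 2),
        })
    return pd.DataFrame(rows)


def growth_rate(totals) -> float:
    """Compound annual growth rate of a series of totals, in percent per year."""
    x = np.asarray(list(totals), dtype=float)
    if x.size < 2:
        raise DomainError("growth rate needs at least 2 totals")
    if (x <= 0).any():
        raise DomainError("totals must be positive")
    return float(((x[-1] / x[0]) ** (1.0 / (x.size - 1)) - 1.0) * 100.0)


def compare_schemes(
    breakdowns: dict[str, pd.DataFrame],
    financing_yuan: float,
    year: int | None = None,
) -> pd.DataFrame:
    """Side-by-side scheme comparison, optionally restricted to one year.

    Per scheme: beneficiary count, fund expenditure (yuan and millions),
    per-capita individual burden (self-payments of patients, yuan), overall
    insurance share of total expense (%), and a sustainability flag (fund
    expenditure within the financing amount).
    """
    sizes = {len(df) for df in breakdowns.values()}
    if len(sizes) > 1:
        raise DomainError(f"schemes were applied to different cohort sizes: {sizes}")
    rows = []
    for name, df in breakdowns.items():
        if year is not None:
            df = df[df["year"] == year]
        expenditure = float(df["simis_payment"].sum())
        total = float(df["total_expense"].sum())
        burden = df["self_under_simis"] + df["total_self_payment"]
        rows.append({
            "scheme": name,
            "beneficiaries": int(df["beneficiary"].sum()),
            "fund_expenditure_yuan": round(expenditure, 2),
            "fund_expenditure_million_yuan": round(expenditure / 1e6, 1),
            "per_capita_burden_yuan": round(float(burden.mean()), 2) if len(df) else 0.0,
            "insurance_share_pct": round(
                (df["fund_payment"].sum() + expenditure) / total * 100.0, 2
            ) if total else 0.0,
            "sustainable": expenditure <= financing_yuan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """End-to-end run configuration (YAML-loadable)."""

    seed: int = 0
    scale: float = 1.0
    mode: str = "reference"  # "reference" = packaged parameters; "synthetic" = estimate
    sim_years: tuple[int, int] = (2017, 2025)
    n_persons: int | None = None  # synthetic mode cohort size (default 2% sample)
    screen_threshold: float = SCREEN_THRESHOLD
    count_mode: str = "poisson"
    write_patient_years: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim_years" in raw:
            raw["sim_years"] = tuple(raw["sim_years"])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    parameters_from: str
    claims: pd.DataFrame | None
    patient_years: pd.DataFrame
    breakdowns: dict[str, pd.DataFrame]
    tables: dict[str, pd.DataFrame]
    comparison: pd.DataFrame
    outputs: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run generate → estimate → project → simulate → apply → report.

    Reference mode simulates directly from the packaged parameter tables;
    synthetic mode first generates a claims database, estimates every
    parameter from it, and simulates from the estimates.  All stages derive
    their randomness from ``config.seed``.  When ``outdir`` is given, all
    tables are written there as CSV/JSON plus a plain-text log.
    """
    scenario = reference_scenario(scale=config.scale)
    log_lines = [f"seed={config.seed} scale={config.scale} mode={config.mode}"]

    claims = None
    if config.mode == "synthetic":
        gen = default_generator_config(seed=config.seed)
        if config.n_persons:
            gen.n_persons = config.n_persons
        elif config.scale != 1.0:
            gen.n_persons = max(1, int(round(gen.n_persons * config.scale)))
        persons = generate_population(gen)
        claims = generate_claims(persons, gen)
        log_lines.append(f"generated {len(persons)} persons, {len(claims)} claims")
        screened = screen_serious(claims, config.screen_threshold)
        log_lines.append(f"screened {len(screened)} serious person-years "
                         f"(> {config.screen_threshold:g} yuan)")
        cells = persons.groupby(["gender", "age_band"]).size().rename("insured").reset_index()
        insured_obs = cells.merge(
            pd.DataFrame({"year": sorted(claims["year"].unique())}), how="cross"
        )
        rates = estimate_admission_rates(screened, insured_obs, horizon=config.sim_years)
        visit_types = estimate_visit_types(screened, horizon=config.sim_years)
        cost_model = estimate_cost_growth(screened, horizon=config.sim_years)
        proportions = estimate_payment_proportions(screened)
        parameters_from = "estimated from synthetic claims"
    elif config.mode == "reference":
        rates = scenario.rates
        visit_types = scenario.visit_types
        cost_model = scenario.cost_model
        proportions = scenario.proportions
        parameters_from = "packaged reference tables"
    else:
        raise DomainError(f"unknown pipeline mode {config.mode!r}")
    log_lines.append(f"parameters: {parameters_from}")

    insured_cells = split_insured(scenario.projection, scenario.cell_shares)
    sim_config = SimulationConfig(
        years=config.sim_years, seed=config.seed, count_mode=config.count_mode
    )
    patient_years = simulate_cohort(
        insured_cells, rates, visit_types, cost_model, proportions, sim_config,
        disease_prevalence=scenario.disease_prevalence,
    )
    log_lines.append(f"simulated {len(patient_years)} patient-years "
                     f"for {config.sim_years[0]}–{config.sim_years[1]}")

    breakdowns = {
        scheme.name: apply_scheme_to_cohort(patient_years, scheme)
        for scheme in scenario.schemes
    }
    tables = {}
    for name, bd in breakdowns.items():
        tables[f"per_capita_{name}"] = per_capita_table(bd, scenario.projection)
        tables[f"payments_{name}"] = payment_table(bd, scenario.projection)
        tables[f"simis_{name}"] = simis_table(bd, scenario.projection)
    comparison = compare_schemes(breakdowns, scenario.financing_yuan, year=2020)
    log_lines.append("compared schemes at 2020: "
                     + ", ".join(f"{r.scheme}={r.fund_expenditure_million_yuan}M"
                                 for r in comparison.itertuples()))

    result = PipelineResult(
        config=config, parameters_from=parameters_from, claims=claims,
        patient_years=patient_years, breakdowns=breakdowns,
        tables=tables, comparison=comparison,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if claims is not None:
            write_claims_csv(claims, outdir / "claims.csv")
            result.outputs.append("claims.csv")
        if config.write_patient_years:
            patient_years.to_csv(outdir / "patient_years.csv", index=False,
                                 float_format="%.2f")
            result.outputs.append("patient_years.csv")
        for name, bd in breakdowns.items():
            bd.to_csv(outdir / f"breakdown_{name}.csv", index=False, float_format="%.2f")
            result.outputs.append(f"breakdown_{name}.csv")
        for name, tab in tables.items():
            tab.to_csv(outdir / f"{name}.csv", index=False)
            result.outputs.append(f"{name}.csv")
        comparison.to_csv(outdir / "scheme_comparison.csv", index=False)
        with open(outdir / "scheme_comparison.json", "w") as fh:
            json.dump(comparison.to_dict(orient="records"), fh, indent=2, default=str)
        with open(outdir / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        result.outputs += ["scheme_comparison.csv", "scheme_comparison.json", "run.log"]
    return result
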