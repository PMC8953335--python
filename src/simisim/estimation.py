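"""Estimation of simulation parameters from a claims database.

Given person-year claims, this module reproduces the study's parameter
estimation chain:

1. **Screening** — person-years whose annual serious-illness expense strictly
   exceeds 10,000 yuan are the seriously ill patients.
2. **Admission rates** — screened patients / insured, per gender × age band
   and year, extrapolated by a constant annual increment.
3. **Visit-type mix** — empirical OOMS/OIMS/BOIMS frequencies per cell-year,
   extrapolated linearly and kept a valid distribution.
4. **Cost model** — annual totals are stratified into 16 groups
   (gender × age band × within-cell expense quartile); each stratum's growth
   rate is the mean of the last three year-over-year growth rates, applied
   multiplicatively to project future stratum means.
5. **Payment proportions** — per-stratum fund and serious-expense shares of
   total expense, averaged over 2014–2016 and held fixed thereafter.

Rates are stored in percent as published; probabilities as fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    EXPENSE_LEVELS,
    VISIT_TYPES,
    StratumKey,
    ConfigurationError,
    DomainError,
    clip_renormalize,
)

logger = logging.getLogger(__name__)

#: Annual serious-expense screening threshold (yuan).
SCREEN_THRESHOLD = 10_000.0

PROB_COLUMNS = ["p_ooms", "p_oims", "p_boims"]


def screen_serious(claims: pd.DataFrame, threshold: float = SCREEN_THRESHOLD) -> pd.DataFrame:
    """Keep person-years whose serious-illness expense strictly exceeds ``threshold``.

    The boundary is exclusive: a serious expense exactly equal to the
    threshold is *not* screened in.
    """
    if threshold <= 0:
        raise DomainError(f"screening threshold must be positive, got {threshold}")
    return claims.loc[claims["serious_expense"] > threshold].reset_index(drop=True)


# ---------------------------------------------------------------------------
# admission rates


@dataclass
class AdmissionRateTable:
    """Admission rates in percent per (gender, age_band, year)."""

    table: pd.DataFrame  # columns: gender, age_band, year, rate_pct

    def __post_init__(self) -> None:
        self._lookup = {
            (int(r.gender), int(r.age_band), int(r.year)): float(r.rate_pct)
            for r in self.table.itertuples()
        }

    def rate(self, gender: int, age_band: int, year: int) -> float:
        try:
            return self._lookup[(gender, age_band, year)]
        except KeyError:
            raise ConfigurationError(
                f"no admission rate for cell ({gender}, {age_band}) in {year}"
            ) from None

    def years(self) -> list[int]:
        return sorted(self.table["year"].unique().tolist())


def annual_increment(rates_by_year: pd.Series) -> float:
    """Constant extrapolation increment from an observed rate series.

    The study adds, each forecast year, the mean annual rise over the
    observed window excluding the final observed transition: with
    observations ``y0 … yN``, the increment is
    ``(rate[yN−1] − rate[y0]) / (yN − y0)``.
    """
    s = rates_by_year.sort_index()
    if len(s) < 2:
        raise DomainError("need at least 2 observed years to extrapolate")
    y0, yN = int(s.index[0]), int(s.index[-1])
    return float((s.loc[yN - 1] - s.loc[y0]) / (yN - y0)) if yN - 1 in s.index else 0.0


def estimate_admission_rates(
    screened: pd.DataFrame,
    insured: pd.DataFrame,
    horizon: tuple[int, int] = (2017, 2025),
) -> AdmissionRateTable:
    """Estimate observed admission rates and extrapolate them to ``horizon``.

    ``insured`` holds denominators: columns ``gender, age_band, year,
    insured``.  Observed-year rates are screened patients / insured × 100;
    each horizon year adds the constant increment of
    :func:`annual_increment`, floored at zero.
    """
    if (insured["insured"] <= 0).any():
        bad = insured.loc[insured["insured"] <= 0].iloc[0]
        raise DomainError(
            f"zero insured population in cell ({bad.gender}, {bad.age_band}) "
            f"year {bad.year}"
        )
    counts = (
        screened.groupby(["gender", "age_band", "year"]).size().rename("patients").reset_index()
    )
    obs = insured.merge(counts, on=["gender", "age_band", "year"], how="left")
    obs["patients"] = obs["patients"].fillna(0)
    obs["rate_pct"] = obs["patients"] / obs["insured"] * 100.0

    rows = []
    for (g, a), grp in obs.groupby(["gender", "age_band"]):
        s = grp.set_index("year")["rate_pct"].sort_index()
        if len(s) < 2:
            raise DomainError(f"cell ({g}, {a}) has fewer than 2 observed years")
        inc = annual_increment(s)
        for year, rate in s.items():
            rows.append({"gender": g, "age_band": a, "year": int(year), "rate_pct": rate})
        last = float(s.iloc[-1])
        for year in range(int(s.index[-1]) + 1, horizon[1] + 1):
            last = max(last + inc, 0.0)
            if year >= horizon[0]:
                rows.append({"gender": g, "age_band": a, "year": year, "rate_pct": last})
    return AdmissionRateTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# visit-type distribution


@dataclass
class VisitTypeDistribution:
    """OOMS/OIMS/BOIMS probabilities per (gender, age_band, year)."""

    table: pd.DataFrame  # columns: gender, age_band, year, p_ooms, p_oims, p_boims

    def __post_init__(self) -> None:
        probs = self.table[PROB_COLUMNS].to_numpy()
        if (probs < -1e-9).any() or (np.abs(probs.sum(axis=1) - 1.0) > 1e-6).any():
            raise ConfigurationError("visit-type probabilities are not valid distributions")
        self._lookup = {
            (int(r.gender), int(r.age_band), int(r.year)): np.array(
                [r.p_ooms, r.p_oims, r.p_boims], dtype=float
            )
            for r in self.table.itertuples()
        }

    def probs(self, gender: int, age_band: int, year: int) -> np.ndarray:
        try:
            return self._lookup[(gender, age_band, year)]
        except KeyError:
            raise ConfigurationError(
                f"no visit-type distribution for cell ({gender}, {age_band}) in {year}"
            ) from None


def extrapolate_triples(observed: pd.DataFrame, horizon: tuple[int, int]) -> pd.DataFrame:
    """Extend per-cell probability triples to ``horizon`` by linear trend.

    Each probability moves by its mean annual change over all consecutive
    observed year pairs, then the triple is clipped to [0, 1] and
    renormalised to sum to one.
    """
    rows = []
    for (g, a), grp in observed.groupby(["gender", "age_band"]):
        grp = grp.sort_values("year")
        p = grp[PROB_COLUMNS].to_numpy()
        years = grp["year"].to_numpy()
        delta = np.diff(p, axis=0).mean(axis=0) if len(grp) > 1 else np.zeros(3)
        for year, triple in zip(years, p):
            rows.append((g, a, int(year), *triple))
        last = p[-1]
        for k, year in enumerate(range(int(years[-1]) + 1, horizon[1] + 1), start=1):
            if year >= horizon[0]:
                triple = clip_renormalize(last + k * delta)
                rows.append((g, a, year, *triple))
    return pd.DataFrame(rows, columns=["gender", "age_band", "year", *PROB_COLUMNS])


def estimate_visit_types(
    screened: pd.DataFrame, horizon: tuple[int, int] = (2017, 2025)
) -> VisitTypeDistribution:
    """Empirical visit-type frequencies per cell-year, linearly extrapolated.

    A cell-year with no screened patients carries the previous year's triple
    forward (logged).
    """
    counts = (
        screened.groupby(["gender", "age_band", "year", "visit_type"])
        .size()
        .unstack("visit_type", fill_value=0)
        .reindex(columns=list(VISIT_TYPES), fill_value=0)
    )
    years = sorted(screened["year"].unique().tolist())
    rows = []
    for (g, a) in sorted({(int(g), int(a)) for g, a, _ in counts.index}):
        prev = None
        for year in years:
            try:
                c = counts.loc[(g, a, year)].to_numpy(dtype=float)
            except KeyError:
                c = np.zeros(3)
            if c.sum() == 0:
                if prev is None:
                    continue
                logger.warning(
                    "cell (%d, %d) year %d has no screened patients; carrying forward",
                    g, a, year,
                )
                triple = prev
            else:
                triple = c / c.sum()
            prev = triple
            rows.append((g, a, year, *triple))
    observed = pd.DataFrame(rows, columns=["gender", "age_band", "year", *PROB_COLUMNS])
    if observed.empty:
        raise DomainError("no screened claims to estimate visit types from")
    return VisitTypeDistribution(extrapolate_triples(observed, horizon))


# ---------------------------------------------------------------------------
# expense-level assignment and cost model


def assign_expense_levels(claims: pd.DataFrame) -> pd.DataFrame:
    """Assign within-(gender, age_band, year) expense quartile levels 1–4.

    Quartiles are rank-based with half-open boundaries, so group sizes within
    each cell-year differ by at most one; ties are broken by row order.
    Returns a copy with an ``expense_level`` column.
    """
    out = claims.copy()
    level = np.empty(len(out), dtype=np.int64)
    for _, grp in out.groupby(["gender", "age_band", "year"]):
        n = len(grp)
        order = np.argsort(grp["total_expense"].to_numpy(), kind="stable")
        ranks = np.empty(n, dtype=np.int64)
        ranks[order] = np.arange(n)
        level[out.index.get_indexer(grp.index)] = (4 * ranks) // n + 1
    out["expense_level"] = level
    return out


@dataclass
class CostModel:
    """Per-stratum mean annual expenses with growth rates.

    ``means``: gender, age_band, expense_level, visit_type, year, mean_cost.
    ``growth``: gender, age_band, expense_level, visit_type, growth.
    """

    means: pd.DataFrame
    growth: pd.DataFrame

    def __post_init__(self) -> None:
        self._means = {
            (int(r.gender), int(r.age_band), int(r.expense_level), r.visit_type, int(r.year)):
                float(r.mean_cost)
            for r in self.means.itertuples()
        }
        self._growth = {
            (int(r.gender), int(r.age_band), int(r.expense_level), r.visit_type):
                float(r.growth)
            for r in self.growth.itertuples()
        }

    def mean(self, gender: int, age_band: int, level: int, visit_type: str,
             year: int) -> float:
        try:
            return self._means[(gender, age_band, level, visit_type, year)]
        except KeyError:
            raise ConfigurationError(
                f"no mean cost for stratum ({gender}, {age_band}, {level}, "
                f"{visit_type}) in {year}"
            ) from None

    def growth_rate(self, gender: int, age_band: int, level: int, visit_type: str) -> float:
        return self._growth[(gender, age_band, level, visit_type)]

    def strata(self) -> list[StratumKey]:
        return sorted(
            {StratumKey(g, a, l) for (g, a, l, _vt, _y) in self._means}
        )


def project_mean(base_mean: float, growth: float, n_years: int) -> float:
    """Roll a stratum mean forward ``n_years`` at a constant growth rate."""
    return base_mean * (1.0 + growth) ** n_years


def mean_growth(rates: Iterable[float]) -> float:
    """Estimated growth: the arithmetic mean of year-over-year growth rates."""
    rates = list(rates)
    if not rates:
        raise DomainError("no growth rates to average")
    return float(np.mean(rates))


def estimate_cost_growth(
    screened: pd.DataFrame,
    horizon: tuple[int, int] = (2017, 2025),
    base_years: tuple[int, int] = (2013, 2016),
) -> CostModel:
    """Estimate the stratified cost model from screened claims.

    Expense levels are the within-cell quartiles of annual totals.  Each
    stratum's growth rate is the mean of the year-over-year growth rates over
    ``base_years`` (2013–2014, 2014–2015, 2015–2016 by default); strata with
    fewer than two patients in any base year fall back to the growth pooled
    over expense levels of their (gender, age_band, visit_type) cell
    (logged).  Projected means roll forward multiplicatively from the last
    base year.
    """
    df = screened if "expense_level" in screened.columns else assign_expense_levels(screened)
    span = list(range(base_years[0], base_years[1] + 1))
    if not set(span).issubset(set(df["year"].unique())):
        raise DomainError(f"claims must cover base years {span}")

    stats = (
        df.groupby(["gender", "age_band", "expense_level", "visit_type", "year"])
        ["total_expense"].agg(["mean", "size"]).reset_index()
    )
    pooled = (
        df.groupby(["gender", "age_band", "visit_type", "year"])
        ["total_expense"].agg(["mean", "size"]).reset_index()
    )
    cell_pooled = (
        df.groupby(["gender", "age_band", "year"])
        ["total_expense"].agg(["mean", "size"]).reset_index()
    )
    global_pooled = df.groupby("year")["total_expense"].agg(["mean", "size"])

    def _series(frame, key_cols, key):
        sel = frame
        for c, v in zip(key_cols, key):
            sel = sel[sel[c] == v]
        return sel.set_index("year")

    def _growth_from(means: pd.Series) -> float | None:
        try:
            return mean_growth(
                means.loc[y + 1] / means.loc[y] - 1.0 for y in span[:-1]
            )
        except KeyError:
            return None

    cells = sorted({(int(g), int(a)) for g, a in zip(df["gender"], df["age_band"])})
    mean_rows, growth_rows = [], []
    base = base_years[1]
    for (g, a) in cells:
        cpool = _series(cell_pooled, ["gender", "age_band"], (g, a))
        cpool_growth = _growth_from(cpool["mean"]) if not cpool.empty else None
        if cpool_growth is None:
            cpool_growth = _growth_from(global_pooled["mean"])
        for vt in VISIT_TYPES:
            pool = _series(pooled, ["gender", "age_band", "visit_type"], (g, a, vt))
            pooled_growth = _growth_from(pool["mean"]) if not pool.empty else None
            if pooled_growth is None:
                pooled_growth = cpool_growth
            for lev in EXPENSE_LEVELS:
                s = _series(
                    stats,
                    ["gender", "age_band", "expense_level", "visit_type"],
                    (g, a, lev, vt),
                )
                thin = s.empty or any(
                    y not in s.index or s.loc[y, "size"] < 2 for y in span
                )
                growth = None if thin else _growth_from(s["mean"])
                if growth is None:
                    if pooled_growth is None:
                        logger.warning(
                            "no usable growth data for cell (%d, %d, %s); using 0", g, a, vt
                        )
                        growth = 0.0
                    else:
                        logger.info(
                            "stratum (%d, %d, %d, %s) thin; pooled cell growth used",
                            g, a, lev, vt,
                        )
                        growth = pooled_growth
                if not s.empty and base in s.index:
                    base_mean = float(s.loc[base, "mean"])
                else:
                    logger.info(
                        "stratum (%d, %d, %d, %s) empty in %d; pooled mean used",
                        g, a, lev, vt, base,
                    )
                    source = pool if base in pool.index else (
                        cpool if base in cpool.index else global_pooled
                    )
                    base_mean = float(source.loc[base, "mean"])
                growth_rows.append((g, a, lev, vt, growth))
                for year in s.index:
                    mean_rows.append((g, a, lev, vt, int(year), float(s.loc[year, "mean"])))
                for year in range(base + 1, horizon[1] + 1):
                    if year >= horizon[0]:
                        mean_rows.append(
                            (g, a, lev, vt, year, project_mean(base_mean, growth, year - base))
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


# ---------------------------------------------------------------------------
# payment proportions


@dataclass
class ProportionModel:
    """Per-stratum (fund, serious, self) payment-share triples."""

    table: pd.DataFrame  # gender, age_band, expense_level, visit_type, fund/serious/self_share

    def __post_init__(self) -> None:
        tri = self.table[["fund_share", "serious_share", "self_share"]].to_numpy()
        if (tri < -1e-9).any() or (np.abs(tri.sum(axis=1) - 1.0) > 1e-6).any():
            raise ConfigurationError("payment shares are not valid share triples")
        self._lookup = {
            (int(r.gender), int(r.age_band), int(r.expense_level), r.visit_type):
                np.array([r.fund_share, r.serious_share, r.self_share], dtype=float)
            for r in self.table.itertuples()
        }

    def shares(self, gender: int, age_band: int, level: int, visit_type: str) -> np.ndarray:
        try:
            return self._lookup[(gender, age_band, level, visit_type)]
        except KeyError:
            raise ConfigurationError(
                f"no payment shares for stratum ({gender}, {age_band}, {level}, {visit_type})"
            ) from None


def average_share(yearly_ratios: Iterable[float]) -> float:
    """Share parameter: arithmetic mean of the yearly payment ratios."""
    ratios = list(yearly_ratios)
    if not ratios:
        raise DomainError("no yearly ratios to average")
    return float(np.mean(ratios))


def estimate_payment_proportions(
    screened: pd.DataFrame, years: tuple[int, int] = (2014, 2016)
) -> ProportionModel:
    """Average per-stratum payment shares over ``years`` (2014–2016 default).

    For each stratum × visit type the yearly fund share is aggregate fund
    payment / aggregate total expense; serious shares likewise.  The
    parameter is the arithmetic mean over the years with positive expense
    (zero-expense years are excluded and logged).  The residual self share
    is floored at zero with renormalisation of the triple.
    """
    df = screened if "expense_level" in screened.columns else assign_expense_levels(screened)
    window = df[(df["year"] >= years[0]) & (df["year"] <= years[1])]
    if window.empty:
        raise DomainError(f"no claims in proportion window {years}")
    sums = (
        window.groupby(["gender", "age_band", "expense_level", "visit_type", "year"])
        [["total_expense", "fund_payment", "serious_expense"]].sum().reset_index()
    )
    pooled = (
        window.groupby(["gender", "age_band", "visit_type", "year"])
        [["total_expense", "fund_payment", "serious_expense"]].sum().reset_index()
    )

    def _mean_shares(frame) -> tuple[float, float] | None:
        ok = frame[frame["total_expense"] > 0]
        if ok.empty:
            return None
        fund = average_share(ok["fund_payment"] / ok["total_expense"])
        serious = average_share(ok["serious_expense"] / ok["total_expense"])
        return fund, serious

    cell_pooled = (
        window.groupby(["gender", "age_band", "year"])
        [["total_expense", "fund_payment", "serious_expense"]].sum().reset_index()
    )
    global_pooled = (
        window.groupby("year")[["total_expense", "fund_payment", "serious_expense"]]
        .sum().reset_index()
    )
    global_shares = _mean_shares(global_pooled)
    cells = sorted({(int(g), int(a)) for g, a in zip(df["gender"], df["age_band"])})
    rows = []
    for (g, a) in cells:
        cell_shares = _mean_shares(
            cell_pooled[(cell_pooled["gender"] == g) & (cell_pooled["age_band"] == a)]
        ) or global_shares
        for vt in VISIT_TYPES:
            pool = pooled[
                (pooled["gender"] == g) & (pooled["age_band"] == a)
                & (pooled["visit_type"] == vt)
            ]
            pool_shares = _mean_shares(pool) or cell_shares
            for lev in EXPENSE_LEVELS:
                sel = sums[
                    (sums["gender"] == g) & (sums["age_band"] == a)
                    & (sums["expense_level"] == lev) & (sums["visit_type"] == vt)
                ]
                if len(sel) < len(sel.drop_duplicates("year")):  # pragma: no cover
                    raise AssertionError("duplicate stratum-year aggregation")
                got = _mean_shares(sel)
                if got is None:
                    if pool_shares is None:
                        continue
                    logger.info(
                        "stratum (%d, %d, %d, %s) empty in %s; pooled shares used",
                        g, a, lev, vt, years,
                    )
                    got = pool_shares
                fund, serious = got
                self_share = 1.0 - fund - serious
                if self_share < 0.0:
                    total = fund + serious
                    fund, serious, self_share = fund / total, serious / total, 0.0
                rows.append((g, a, lev, vt, fund, serious, self_share))
    return ProportionModel(
        pd.DataFrame(
            rows,
            columns=["gender", "age_band", "expense_level", "visit_type",
                     "fund_share", "serious_share", "self_share"],
        )
    )
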