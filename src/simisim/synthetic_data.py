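"""Synthetic micro claims database generator.

The real calibration data — an administrative 2% sample of Shanghai
medical-insurance claims, 2011–2016 — is confidential, so the pipeline is
calibrated and tested on a synthetic stand-in generated here.  The generator
reproduces the statistical structure the estimation stage assumes:

* a cohort of insured persons with configurable gender/age-band marginals;
* per (gender, age band) annual admission probabilities ("admission rates")
  that may rise over the window;
* a three-way visit-type mix (OOMS/OIMS/BOIMS) per cell and year;
* annual totals drawn per expense-level stratum as ``(u + 0.5) × mean`` with
  ``u ~ Uniform(0, 1)``, the same sampling law the simulator uses, with the
  stratum mean growing at a constant annual rate;
* a fen-exact three-way payment decomposition with fixed per-stratum shares.

Only person-year aggregates are modelled — no per-visit episodes, diagnosis
codes or providers — matching the unit of analysis of the estimation stage.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AGE_BANDS,
    CELLS,
    CLAIM_COLUMNS,
    GENDERS,
    VISIT_TYPES,
    ClaimsValidationError,
    ConfigurationError,
    split_amounts,
    validate_claims,
)

Cell = tuple[int, int]  # (gender, age_band)
Stratum = tuple[int, int, int, str]  # (gender, age_band, expense_level, visit_type)


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of the synthetic claims database.

    The estimation stage must recover these parameters within Monte-Carlo
    error; they are therefore the reference values of the pipeline's
    end-to-end recovery test.

    Parameters
    ----------
    n_persons
        Cohort size.
    years
        Inclusive calibration window, e.g. ``(2011, 2016)``.
    seed
        Root seed; the whole database is a deterministic function of the
        configuration and this seed.
    cell_probs
        Marginal probability of each (gender, age_band) cell; must sum to 1.
    admission_rates
        ``{(gender, age_band): {year: rate}}`` in percent of the cohort.
    visit_probs
        ``{(gender, age_band): {year: (p_OOMS, p_OIMS, p_BOIMS)}}``.
    mean_costs, growth
        Per ``(gender, age_band, expense_level, visit_type)`` mean annual
        total expense (yuan) at ``base_year``, and the constant annual growth
        rate applied multiplicatively in either direction of ``base_year``.
    shares
        Per-stratum ``(fund, serious, self)`` payment-share triple, each in
        [0, 1] and summing to 1.
    level_probs
        Probability of drawing each expense level (default equal quarters).
    level_mode
        ``"iid"`` (default) draws each claim's expense level independently
        from ``level_probs``; ``"quota"`` assigns levels by the within-cell
        rank quartiles of the level uniform, so exactly a quarter (±1) of
        each cell-year's claims sits in each band — the definition the
        estimation stage's quartile stratification uses.  With well-separated
        level means, quota mode makes the quartile re-estimation of stratum
        means unbiased.
    p_urrbmi
        Fraction of the cohort in the resident scheme (URRBMI) rather than
        the employee scheme.
    disease_prevalence
        Probability that a person is eligible for the disease-based
        serious-illness categories.
    """

    n_persons: int
    admission_rates: Mapping[Cell, Mapping[int, float]]
    visit_probs: Mapping[Cell, Mapping[int, Sequence[float]]]
    mean_costs: Mapping[Stratum, float]
    growth: Mapping[Stratum, float]
    shares: Mapping[Stratum, Sequence[float]]
    years: tuple[int, int] = (2011, 2016)
    base_year: int = 2016
    seed: int = 0
    cell_probs: Mapping[Cell, float] = field(
        default_factory=lambda: {c: 0.25 for c in CELLS}
    )
    level_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    level_mode: str = "iid"
    p_urrbmi: float = 1.0
    disease_prevalence: float = 0.0

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ConfigurationError("n_persons must be >= 1")
        if self.years[0] > self.years[1]:
            raise ConfigurationError("years must be an inclusive (first, last) range")
        for name, p in (("p_urrbmi", self.p_urrbmi),
                        ("disease_prevalence", self.disease_prevalence)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        cp = np.array([self.cell_probs.get(c, 0.0) for c in CELLS], dtype=float)
        if (cp < 0).any() or (cp > 1).any() or abs(cp.sum() - 1.0) > 1e-9:
            raise ConfigurationError("cell_probs must be a distribution over the 4 cells")
        lp = np.asarray(self.level_probs, dtype=float)
        if lp.size != 4 or (lp < 0).any() or abs(lp.sum() - 1.0) > 1e-9:
            raise ConfigurationError("level_probs must be 4 probabilities summing to 1")
        if self.level_mode not in ("iid", "quota"):
            raise ConfigurationError(f"unknown level_mode {self.level_mode!r}")
        for cell, by_year in self.admission_rates.items():
            for year, rate in by_year.items():
                if not 0.0 <= rate <= 100.0:
                    raise ConfigurationError(
                        f"admission rate {rate} for cell {cell} year {year} outside [0, 100]"
                    )
        for cell, by_year in self.visit_probs.items():
            for year, triple in by_year.items():
                t = np.asarray(triple, dtype=float)
                if t.size != 3 or (t < 0).any() or (t > 1).any() or abs(t.sum() - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"visit probabilities {triple} for cell {cell} year {year} invalid"
                    )
        for stratum, triple in self.shares.items():
            t = np.asarray(triple, dtype=float)
            if t.size != 3 or (t < -1e-12).any() or (t > 1 + 1e-12).any() \
                    or abs(t.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"share triple {triple} for {stratum} invalid")
        for stratum, m in self.mean_costs.items():
            if m <= 0:
                raise ConfigurationError(f"mean cost {m} for {stratum} not positive")

    def mean_cost(self, gender: int, age_band: int, level: int, visit_type: str,
                  year: int) -> float:
        """Stratum mean in ``year``: base mean compounded by the growth rate."""
        key = (gender, age_band, level, visit_type)
        try:
            base = self.mean_costs[key]
        except KeyError:
            raise ConfigurationError(f"no mean cost configured for stratum {key}") from None
        g = self.growth.get(key, 0.0)
        return base * (1.0 + g) ** (year - self.base_year)

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the synthetic cohort.

    Returns a frame with columns ``person_id, gender, age_band,
    insurance_type, disease_eligible``; deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_persons
    cp = np.array([config.cell_probs.get(c, 0.0) for c in CELLS], dtype=float)
    cell_idx = rng.choice(len(CELLS), size=n, p=cp / cp.sum())
    gender = np.array([c[0] for c in CELLS])[cell_idx]
    age_band = np.array([c[1] for c in CELLS])[cell_idx]
    insurance = np.where(rng.random(n) < config.p_urrbmi, "URRBMI", "UEBMI")
    disease = rng.random(n) < config.disease_prevalence
    width = max(6, len(str(n)))
    return pd.DataFrame(
        {
            "person_id": [f"P{i:0{width}d}" for i in range(1, n + 1)],
            "gender": gender.astype(np.int64),
            "age_band": age_band.astype(np.int64),
            "insurance_type": insurance,
            "disease_eligible": disease,
        }
    )


def generate_claims(
    persons: pd.DataFrame,
    config: GeneratorConfig,
    years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Generate person-year claims for ``years`` (default the config window).

    For every person and year an admission is drawn with the cell's
    configured rate; admitted person-years get a visit type, an expense
    level, a total drawn as ``(u + 0.5) ×`` the stratum-year mean, and a
    fen-exact split into fund / serious / self parts using the configured
    share triple.  Per-year random substreams make the output invariant to
    the order in which years are generated.
    """
    config.validate()
    years = years or config.years
    if years[0] < config.years[0] or years[1] > config.years[1]:
        raise ConfigurationError(
            f"requested years {years} outside calibration window {config.years}"
        )
    for cell in sorted(set(zip(persons["gender"], persons["age_band"]))):
        if cell not in config.admission_rates:
            raise ConfigurationError(f"no admission rates configured for cell {cell}")
        if cell not in config.visit_probs:
            raise ConfigurationError(f"no visit probabilities configured for cell {cell}")

    gender = persons["gender"].to_numpy()
    age_band = persons["age_band"].to_numpy()
    pid = persons["person_id"].to_numpy()
    insurance = persons["insurance_type"].to_numpy()
    lp_cum = np.cumsum(np.asarray(config.level_probs, dtype=float))

    frames: list[pd.DataFrame] = []
    for year in range(years[0], years[1] + 1):
        rng = np.random.default_rng([config.seed, 1, year])
        rates = np.array(
            [config.admission_rates[(g, a)].get(year, 0.0) for g, a in zip(gender, age_band)]
        )
        admitted = np.flatnonzero(rng.random(len(persons)) < rates / 100.0)
        if admitted.size == 0:
            continue
        u = rng.random((admitted.size, 3))  # visit, ran01, ran02
        g_adm, a_adm = gender[admitted], age_band[admitted]

        visit_idx = np.empty(admitted.size, dtype=np.int64)
        level = np.empty(admitted.size, dtype=np.int64)
        total = np.empty(admitted.size, dtype=float)
        for cell in sorted(set(zip(g_adm, a_adm))):
            mask = (g_adm == cell[0]) & (a_adm == cell[1])
            triple = config.visit_probs[cell].get(year)
            if triple is None:
                raise ConfigurationError(
                    f"no visit probabilities for cell {cell} in year {year}"
                )
            vp_cum = np.cumsum(np.asarray(triple, dtype=float))
            visit_idx[mask] = np.searchsorted(vp_cum, u[mask, 0], side="right").clip(0, 2)
            if config.level_mode == "quota":
                # rank quartiles of the level uniform within the cell-year
                n_cell = int(mask.sum())
                ranks = np.empty(n_cell, dtype=np.int64)
                ranks[np.argsort(u[mask, 1], kind="stable")] = np.arange(n_cell)
                level[mask] = (4 * ranks) // n_cell + 1
            else:
                level[mask] = np.searchsorted(lp_cum, u[mask, 1], side="right").clip(0, 3) + 1
            for lev in np.unique(level[mask]):
                for vt_i, vt in enumerate(VISIT_TYPES):
                    sub = mask & (level == lev) & (visit_idx == vt_i)
                    if sub.any():
                        mean = config.mean_cost(cell[0], cell[1], int(lev), vt, year)
                        total[sub] = (u[sub, 2] + 0.5) * mean

        total = np.round(total, 2)
        share_mat = np.empty((admitted.size, 3))
        for i in range(admitted.size):
            key = (int(g_adm[i]), int(a_adm[i]), int(level[i]), VISIT_TYPES[visit_idx[i]])
            try:
                share_mat[i] = np.asarray(config.shares[key], dtype=float)
            except KeyError:
                raise ConfigurationError(f"no share triple configured for stratum {key}") from None
        parts = split_amounts(total, share_mat)

        frames.append(
            pd.DataFrame(
                {
                    "person_id": pid[admitted],
                    "year": year,
                    "gender": g_adm.astype(np.int64),
                    "age_band": a_adm.astype(np.int64),
                    "insurance_type": insurance[admitted],
                    "visit_type": np.array(VISIT_TYPES)[visit_idx],
                    "total_expense": total,
                    "fund_payment": parts[:, 0],
                    "serious_expense": parts[:, 1],
                    "total_self_payment": parts[:, 2],
                }
            )
        )

    if not frames:
        return pd.DataFrame(columns=CLAIM_COLUMNS)
    claims = pd.concat(frames, ignore_index=True)
    claims = claims.sort_values(["year", "person_id"], kind="stable").reset_index(drop=True)
    return claims[CLAIM_COLUMNS]


def generate_database(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: cohort plus its claims for the full window."""
    persons = generate_population(config)
    return persons, generate_claims(persons, config)


def write_claims_csv(claims: pd.DataFrame, path) -> None:
    """Write claims as comma-separated UTF-8 with a header, money at 0.01 yuan."""
    validate_claims(claims, source="claims to write")
    out = claims.copy()
    for col in ("total_expense", "fund_payment", "serious_expense", "total_self_payment"):
        out[col] = out[col].map(lambda x: f"{x:.2f}")
    out.to_csv(path, index=False, encoding="utf-8")


def read_claims_csv(path) -> pd.DataFrame:
    """Read and validate a claims CSV written by :func:`write_claims_csv`.

    Malformed rows (missing fields, non-numeric or negative money, broken
    conservation identity) raise :class:`ClaimsValidationError` naming the
    offending 1-based data row.
    """
    try:
        claims = pd.read_csv(
            path,
            dtype={"person_id": str, "insurance_type": str, "visit_type": str},
        )
    except pd.errors.EmptyDataError as exc:
        raise ClaimsValidationError(f"{path}: empty file") from exc
    missing = [c for c in CLAIM_COLUMNS if c not in claims.columns]
    if missing:
        raise ClaimsValidationError(f"{path}: missing columns {missing}")
    claims = claims[CLAIM_COLUMNS]
    if claims.empty:
        return claims.astype(
            {"year": np.int64, "gender": np.int64, "age_band": np.int64,
             **{c: float for c in ("total_expense", "fund_payment",
                                   "serious_expense", "total_self_payment")}},
            errors="ignore",
        )
    for col in ("year", "gender", "age_band"):
        vals = pd.to_numeric(claims[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 1
            raise ClaimsValidationError(f"{path}: non-integer {col} at row {row}")
        claims[col] = vals.astype(np.int64)
    for col in ("total_expense", "fund_payment", "serious_expense", "total_self_payment"):
        claims[col] = pd.to_numeric(claims[col], errors="coerce")
    validate_claims(claims, source=str(path))
    return claims


def claims_to_string(claims: pd.DataFrame) -> str:
    """Canonical CSV text of a claims table (used for determinism checks)."""
    buf = io.StringIO()
    write_claims_csv(claims, buf)
    return buf.getvalue()
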