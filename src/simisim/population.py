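"""Projection of the SIMIS-insured population.

The target population of the serious-illness scheme is the registered
population that does not participate in the employee scheme (UEBMI).  It is
projected in three steps: an exponential-trend fit to a registered-population
series, removal of a (configurable, linearly trending) employee-scheme share,
and a basic-insurance participation rate (97% in Shanghai).

Because the registered-population series is external, the module also ships a
packaged fixture of the published 2016–2025 insured/uninsured projection for
the Shanghai scenario; fixture mode bypasses fitting entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from typing import Iterable

import numpy as np
import pandas as pd

from .core import DomainError


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares fit of ``N_t = level · exp(rate · (t − base_year))``.

    Fitted on the log scale by ordinary least squares, so ``rate`` is a
    continuous annual growth rate.
    """

    level: float
    rate: float
    base_year: int

    def predict(self, years) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        return self.level * np.exp(self.rate * (years - self.base_year))


@dataclass(frozen=True)
class LinearTrend:
    """A linearly trending fraction, clipped to [0, 1)."""

    base_year: int
    base_value: float
    annual_change: float = 0.0

    def __call__(self, year: int) -> float:
        return float(np.clip(self.base_value + self.annual_change * (year - self.base_year),
                             0.0, 1.0 - 1e-12))


def _as_series(series) -> pd.Series:
    if isinstance(series, pd.DataFrame):
        series = series.set_index("year")["count"]
    s = pd.Series(series, dtype=float).sort_index()
    s.index = s.index.astype(int)
    return s


def fit_exponential(series) -> ExponentialFit:
    """Fit an exponential growth curve to a population series.

    ``series`` is a mapping/Series of year → count, or a DataFrame with
    ``year`` and ``count`` columns.  Requires at least three positive
    observations.
    """
    s = _as_series(series)
    if len(s) < 3:
        raise DomainError("exponential fit needs at least 3 observations")
    if (s <= 0).any():
        raise DomainError("population counts must be positive")
    t0 = int(s.index[0])
    b, loga = np.polyfit(s.index.to_numpy(dtype=float) - t0, np.log(s.to_numpy()), 1)
    return ExponentialFit(level=float(np.exp(loga)), rate=float(b), base_year=t0)


def project_insured(
    fit: ExponentialFit,
    years: Iterable[int],
    participation_rate: float = 0.97,
    employee_share: LinearTrend | float = 0.0,
) -> pd.DataFrame:
    """Project insured / uninsured counts for ``years``.

    eligible(y) = projected total × (1 − employee-scheme share(y));
    insured(y) = round(eligible × participation_rate); the remainder of the
    eligible population is reported as uninsured.
    """
    if not 0.0 < participation_rate <= 1.0:
        raise DomainError(f"participation_rate {participation_rate} outside (0, 1]")
    years = sorted(int(y) for y in years)
    if years and years[0] < fit.base_year:
        raise DomainError(
            f"projection year {years[0]} precedes the fit window ({fit.base_year})"
        )
    share = employee_share if callable(employee_share) else (lambda y: float(employee_share))
    rows = []
    for y in years:
        total = float(fit.predict(y))
        eligible = total * (1.0 - share(y))
        insured = int(round(eligible * participation_rate))
        rows.append({"year": y, "insured": insured,
                     "uninsured": int(round(eligible)) - insured})
    return pd.DataFrame(rows, columns=["year", "insured", "uninsured"])


def load_reference_projection() -> pd.DataFrame:
    """Published 2016–2025 insured/uninsured projection for the Shanghai scenario.

    Fixture mode: returned verbatim, no fitting involved.
    """
    path = files("simisim").joinpath("fixtures/insured_projection.csv")
    with path.open("rb") as fh:
        df = pd.read_csv(fh)
    return df.astype({"year": np.int64, "insured": np.int64, "uninsured": np.int64})


def write_projection_csv(projection: pd.DataFrame, path) -> None:
    projection.to_csv(path, index=False, columns=["year", "insured", "uninsured"])
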