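"""Application of SIMIS payment schemes to simulated patient-years.

A scheme turns the pre-SIMIS three-way decomposition (fund / serious / self)
into the final four-way one by carving a SIMIS payment out of the serious
expense ``S``:

* **large-expense scheme** — pays only when ``S`` strictly exceeds the
  threshold (25,000 yuan in the designed Shanghai scheme, the 2015 rural per
  capita disposable income); by default the 60% rate applies to the excess
  over the threshold, optionally to the full serious expense; no ceiling.
* **disease-based scheme** — Shanghai's current policy: no threshold or
  ceiling, 60% of the serious expense, but only for patients treated for the
  listed serious-disease categories (severe-uraemia dialysis, renal-transplant
  anti-rejection, part of malignant-tumour and mental-disease treatment).
  Eligibility is a per-person flag; the categories are labels on that flag,
  not clinically modelled.

The scheme never alters consumption: total expense and the fund payment are
passed through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import ConfigurationError

BREAKDOWN_COLUMNS = [
    "total_expense", "fund_payment", "simis_payment",
    "self_under_simis", "total_self_payment", "beneficiary",
]


@dataclass(frozen=True)
class PolicyScheme:
    """A SIMIS payment rule.

    ``base`` selects what the pay rate multiplies once the threshold is
    exceeded: the excess over the threshold (default) or the full serious
    expense.  ``ceiling=None`` means no ceiling.
    """

    name: str
    mode: str  # "large_expense" | "disease_based"
    threshold: float = 0.0
    pay_rate: float = 0.60
    ceiling: float | None = None
    base: str = "excess_over_threshold"

    def validate(self) -> None:
        if self.mode not in ("large_expense", "disease_based"):
            raise ConfigurationError(f"unknown scheme mode {self.mode!r}")
        if not 0.0 <= self.pay_rate <= 1.0:
            raise ConfigurationError(f"pay_rate {self.pay_rate} outside [0, 1]")
        if self.threshold < 0:
            raise ConfigurationError("threshold must be >= 0")
        if self.ceiling is not None and self.ceiling < 0:
            raise ConfigurationError("ceiling must be >= 0 or None")
        if self.base not in ("excess_over_threshold", "full_serious_expense"):
            raise ConfigurationError(f"unknown payment base {self.base!r}")

    def with_(self, **kw) -> "PolicyScheme":
        return replace(self, **kw)


#: The designed large-expense scheme: 25,000-yuan threshold, 60%, no ceiling.
LARGE_EXPENSE_SCHEME = PolicyScheme(
    name="large_expense", mode="large_expense", threshold=25_000.0, pay_rate=0.60,
)

#: Shanghai's current disease-based scheme: no threshold/ceiling, 60%.
DISEASE_BASED_SCHEME = PolicyScheme(
    name="disease_based", mode="disease_based", threshold=0.0, pay_rate=0.60,
    base="full_serious_expense",
)


def simis_payment(serious_expense, scheme: PolicyScheme, disease_eligible=True):
    """SIMIS payment for serious expense(s) ``S`` under ``scheme``.

    Vectorised over numpy arrays.  The threshold is a strict bound: paying
    starts only when ``S`` exceeds it, so ``S == threshold`` pays nothing.
    Payments are rounded to 0.01 yuan and capped at the ceiling.
    """
    scheme.validate()
    s = np.asarray(serious_expense, dtype=float)
    pays = s > scheme.threshold
    if scheme.mode == "disease_based":
        pays = pays & np.asarray(disease_eligible, dtype=bool)
    base = s - scheme.threshold if scheme.base == "excess_over_threshold" else s
    pay = np.where(pays, scheme.pay_rate * base, 0.0)
    if scheme.ceiling is not None:
        pay = np.minimum(pay, scheme.ceiling)
    pay = np.round(pay, 2)
    return float(pay) if np.isscalar(serious_expense) else pay


def apply_simis(patient_year, scheme: PolicyScheme) -> dict:
    """Apply a scheme to one simulated patient-year (mapping/Series).

    Returns the four-way payment breakdown; ``beneficiary`` is true iff the
    SIMIS payment is strictly positive.
    """
    s = float(patient_year["serious_expense"])
    eligible = bool(patient_year.get("disease_eligible", True))
    pay = simis_payment(s, scheme, eligible)
    return {
        "total_expense": float(patient_year["total_expense"]),
        "fund_payment": float(patient_year["fund_payment"]),
        "simis_payment": pay,
        "self_under_simis": round(s - pay, 2),
        "total_self_payment": float(patient_year["total_self_payment"]),
        "beneficiary": pay > 0,
    }


def apply_scheme_to_cohort(patient_years: pd.DataFrame, scheme: PolicyScheme) -> pd.DataFrame:
    """Element-wise scheme application; order and count preserved.

    Pass-through columns (year, gender, age_band, visit_type, …) are kept;
    the scheme name is recorded in a ``scheme`` column.
    """
    scheme.validate()
    eligible = (
        patient_years["disease_eligible"].to_numpy()
        if "disease_eligible" in patient_years.columns
        else np.ones(len(patient_years), dtype=bool)
    )
    s = patient_years["serious_expense"].to_numpy(dtype=float)
    pay = simis_payment(s, scheme, eligible) if len(patient_years) else np.zeros(0)
    out = patient_years.copy()
    out["simis_payment"] = pay
    out["self_under_simis"] = np.round(s - pay, 2)
    out["beneficiary"] = pay > 0
    out["scheme"] = scheme.name
    ordered = [c for c in patient_years.columns if c != "serious_expense"]
    return out[ordered + ["serious_expense", "simis_payment", "self_under_simis",
                          "beneficiary", "scheme"]]
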