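"""Shared domain vocabulary and money arithmetic for the SIMIS micro-simulation.

Conventions used throughout the package:

* ``gender`` is coded 1 = male, 2 = female;
* ``age_band`` is coded 1 = under 60 years, 2 = 60 years and over;
* visit types are ``"OOMS"`` (only outpatient), ``"OIMS"`` (only inpatient)
  and ``"BOIMS"`` (both outpatient and inpatient services within a year);
* expense levels 1–4 are within-cell quartile groups of annual totals;
* all money amounts are yuan, stored to 0.01 yuan (one fen).

A *claim* is one person-year of medical consumption.  Its pre-SIMIS payment
decomposition has three parts that must sum to the total expense:

* ``fund_payment`` — paid by the URRBMI fund;
* ``serious_expense`` — self-payment under the insurance plus the threshold
  portion, i.e. the expenses a serious-illness scheme can reimburse;
* ``total_self_payment`` — expenses outside the benefit package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

GENDERS = (1, 2)
AGE_BANDS = (1, 2)
VISIT_TYPES = ("OOMS", "OIMS", "BOIMS")
EXPENSE_LEVELS = (1, 2, 3, 4)
CELLS = tuple((g, a) for g in GENDERS for a in AGE_BANDS)

#: Columns of a claims table (one row per person-year with a claim).
CLAIM_COLUMNS = [
    "person_id",
    "year",
    "gender",
    "age_band",
    "insurance_type",
    "visit_type",
    "total_expense",
    "fund_payment",
    "serious_expense",
    "total_self_payment",
]

MONEY_COLUMNS = ["total_expense", "fund_payment", "serious_expense", "total_self_payment"]

#: Tolerance on the conservation identity, one fen plus float slack.
CONSERVATION_ATOL = 0.01 + 1e-6


class ConfigurationError(ValueError):
    """A configuration value is missing, out of range or inconsistent."""


class DomainError(ValueError):
    """An input violates a mathematical precondition of an operation."""


class ClaimsValidationError(ValueError):
    """A claims table violates the schema or the conservation identity."""


@dataclass(frozen=True, order=True)
class CellKey:
    """A (gender, age band) demographic cell."""

    gender: int
    age_band: int


@dataclass(frozen=True, order=True)
class StratumKey:
    """A (gender, age band, expense level) stratum.

    The expense level is the within-cell quartile group of annual totals
    (1 = lowest quarter, 4 = highest); together with gender and age band it
    indexes the 16 strata of the cost and payment-share models.
    """

    gender: int
    age_band: int
    expense_level: int


def round_fen(x):
    """Round yuan amounts to 0.01 (scalar or array)."""
    return np.round(x, 2)


def split_amount(total: float, shares: Sequence[float]) -> tuple[float, ...]:
    """Split ``total`` yuan proportionally into fen-exact parts.

    Uses largest-remainder rounding on integer fen so the parts always sum to
    ``round_fen(total)`` exactly.  ``shares`` must be non-negative and sum to
    1 within 1e-6 (they are renormalised before splitting).
    """
    shares = np.asarray(shares, dtype=float)
    if shares.ndim != 1 or shares.size == 0:
        raise ConfigurationError("shares must be a non-empty 1-d sequence")
    if (shares < -1e-12).any():
        raise ConfigurationError(f"negative share in {shares!r}")
    s = shares.sum()
    if abs(s - 1.0) > 1e-6:
        raise ConfigurationError(f"shares sum to {s!r}, expected 1")
    shares = np.clip(shares, 0.0, None) / shares.clip(0.0, None).sum()
    total_fen = int(round(total * 100))
    raw = total_fen * shares
    parts = np.floor(raw).astype(np.int64)
    short = total_fen - int(parts.sum())
    if short > 0:
        order = np.argsort(-(raw - parts), kind="stable")
        parts[order[:short]] += 1
    return tuple(parts / 100.0)


def split_amounts(totals: np.ndarray, shares: np.ndarray) -> np.ndarray:
    """Vectorised :func:`split_amount`: ``totals`` (n,), ``shares`` (n, k).

    Returns an (n, k) array of fen-exact parts whose rows sum to the
    fen-rounded totals.
    """
    totals = np.asarray(totals, dtype=float)
    shares = np.asarray(shares, dtype=float)
    total_fen = np.round(totals * 100).astype(np.int64)
    raw = total_fen[:, None] * shares
    parts = np.floor(raw).astype(np.int64)
    short = total_fen - parts.sum(axis=1)
    frac = raw - parts
    # give the missing fen to the components with the largest remainders
    order = np.argsort(-frac, axis=1, kind="stable")
    take = np.arange(shares.shape[1])[None, :] < short[:, None]
    bump = np.zeros_like(parts)
    np.put_along_axis(bump, order, take.astype(np.int64), axis=1)
    return (parts + bump) / 100.0


def clip_renormalize(probs: Sequence[float]) -> np.ndarray:
    """Clip probabilities to [0, 1] and rescale them to sum to 1.

    A degenerate all-zero vector becomes the uniform distribution.
    """
    p = np.clip(np.asarray(probs, dtype=float), 0.0, 1.0)
    s = p.sum()
    if s <= 0:
        return np.full(p.shape, 1.0 / p.size)
    return p / s


def validate_claims(claims: pd.DataFrame, *, source: str = "claims") -> None:
    """Validate a claims table; raise :class:`ClaimsValidationError` naming rows.

    Checks the schema, enumeration codes, non-negativity of money columns and
    the conservation identity fund + serious + self = total to 0.01 yuan.
    Row numbers in messages are 1-based positions in the table.
    """
    missing = [c for c in CLAIM_COLUMNS if c not in claims.columns]
    if missing:
        raise ClaimsValidationError(f"{source}: missing columns {missing}")
    if claims.empty:
        return

    def _bad_rows(mask: pd.Series, what: str) -> None:
        if mask.any():
            rows = (np.flatnonzero(mask.to_numpy()) + 1)[:5].tolist()
            raise ClaimsValidationError(f"{source}: {what} at row(s) {rows}")

    for col in MONEY_COLUMNS:
        vals = pd.to_numeric(claims[col], errors="coerce")
        _bad_rows(vals.isna(), f"non-numeric {col}")
        _bad_rows(vals < 0, f"negative {col}")
    _bad_rows(~claims["gender"].isin(GENDERS), "invalid gender code")
    _bad_rows(~claims["age_band"].isin(AGE_BANDS), "invalid age_band code")
    _bad_rows(~claims["visit_type"].isin(VISIT_TYPES), "invalid visit_type")
    resid = (
        claims["total_expense"]
        - claims["fund_payment"]
        - claims["serious_expense"]
        - claims["total_self_payment"]
    ).abs()
    _bad_rows(resid > CONSERVATION_ATOL, "payment components do not sum to total_expense")
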