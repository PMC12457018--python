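"""Age and birth-date estimation from early-life body mass.

Bush Karoo rats grow along a Gompertz curve

    M(a) = A * exp(-exp(k * (a - t0)))

with asymptotic mass ``A`` = 88 g, rate constant ``k`` = -0.052 per day and
inflection offset ``t0`` = 15 days.  Inverting the curve gives the age at
first capture from the body mass measured then,

    age(M) = ln(ln(A / M)) / k + t0,

and the date of birth follows as first-capture date minus that age.  The
inversion is only trusted for juveniles (mass up to 65 g, a predicted age of
38 days) where the mass-age relationship is close to linear; heavier animals
are rejected as ineligible rather than extrapolated.

Because daily precision of an estimated birth date can be spurious, the
module also provides coarsened variants that replace the day-scale estimate
by the midpoint of a 14- or 28-day bin, used for robustness re-analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "GompertzParams",
    "BirthRecord",
    "GompertzDomainError",
    "EligibilityError",
    "gompertz_mass",
    "estimate_age",
    "estimate_birth_date",
    "coarsen_birth_date",
    "add_birth_columns",
]


class GompertzDomainError(ValueError):
    """Mass outside the domain of the inverted growth curve."""


class EligibilityError(ValueError):
    """Mass above the juvenile eligibility threshold; age not estimable reliably."""


@dataclass(frozen=True)
class GompertzParams:
    """Fixed growth-curve constants for the study species (female).

    ``rate_constant`` is negative by the curve's parameterisation; the
    inversion divides by it.
    """

    asymptote_mass: float = 88.0
    rate_constant: float = -0.052
    offset_days: float = 15.0
    eligibility_max_mass: float = 65.0

    def __post_init__(self) -> None:
        if not self.asymptote_mass > self.eligibility_max_mass > 0:
            raise ValueError(
                "require asymptote_mass > eligibility_max_mass > 0, got "
                f"{self.asymptote_mass!r} / {self.eligibility_max_mass!r}"
            )
        if not self.rate_constant < 0:
            raise ValueError(f"rate_constant must be negative, got {self.rate_constant!r}")


@dataclass
class BirthRecord:
    """Estimated age and date of birth for one individual."""

    individual_id: str
    first_capture_date: date
    mass_at_first_capture: float
    estimated_age: float  # days, unrounded; analyses use this value
    birth_date: date  # capture date minus age rounded to nearest day
    birth_date_numeric: float = field(default=float("nan"))  # days since season start


def gompertz_mass(age: float, params: GompertzParams | None = None) -> float:
    """Forward growth curve: expected body mass (g) at ``age`` days."""
    p = params or GompertzParams()
    return p.asymptote_mass * math.exp(-math.exp(p.rate_constant * (age - p.offset_days)))


def estimate_age(mass: float, params: GompertzParams | None = None) -> float:
    """Age in days at which the growth curve reaches ``mass`` grams.

    Strictly increasing in mass on (0, asymptote).  Raises
    :class:`EligibilityError` for masses above the juvenile threshold and
    :class:`GompertzDomainError` where the double log is undefined.
    """
    p = params or GompertzParams()
    if not mass > 0:
        raise GompertzDomainError(f"mass must be positive, got {mass!r}")
    if mass >= p.asymptote_mass:
        raise GompertzDomainError(
            f"mass {mass!r} g is at or above the asymptote {p.asymptote_mass} g; "
            "the inverted growth curve is undefined there"
        )
    if mass > p.eligibility_max_mass:
        raise EligibilityError(
            f"mass {mass!r} g exceeds the eligibility threshold "
            f"{p.eligibility_max_mass} g for age estimation"
        )
    return math.log(math.log(p.asymptote_mass / mass)) / p.rate_constant + p.offset_days


def estimate_birth_date(
    individual_id: str,
    capture_date: date,
    mass: float,
    params: GompertzParams | None = None,
    season_start: date | None = None,
) -> BirthRecord:
    """Birth record from first-capture date and mass.

    The calendar birth date uses the age rounded to the nearest whole day;
    ``estimated_age`` and ``birth_date_numeric`` keep the unrounded value so
    downstream analyses are not quantised.  ``season_start`` defaults to
    1 July of the capture year.
    """
    age = estimate_age(mass, params)
    birth = capture_date - timedelta(days=round(age))
    if season_start is None:
        season_start = date(capture_date.year, 7, 1)
        if birth < date(capture_date.year, 1, 1):
            season_start = date(capture_date.year - 1, 7, 1)
    numeric = (capture_date - season_start).days - age
    return BirthRecord(
        individual_id=individual_id,
        first_capture_date=capture_date,
        mass_at_first_capture=mass,
        estimated_age=age,
        birth_date=birth,
        birth_date_numeric=numeric,
    )


def coarsen_birth_date(
    birth_date_numeric: float | np.ndarray,
    interval: int,
    season_start_day: float = 0.0,
    season_length: float = 154.0,
) -> np.ndarray:
    """Replace day-scale numeric birth dates by bin midpoints.

    Bins of ``interval`` days start at ``season_start_day``; a value in
    [start + i*interval, start + (i+1)*interval) maps to the bin midpoint, so
    the coarsened value is always within interval/2 of the daily one.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if season_length / interval < 2:
        raise ValueError(
            f"interval {interval} d leaves fewer than two bins over a "
            f"{season_length}-day season"
        )
    x = np.asarray(birth_date_numeric, dtype=float)
    idx = np.floor((x - season_start_day) / interval)
    return season_start_day + (idx + 0.5) * interval


def add_birth_columns(
    cohort: pd.DataFrame,
    params: GompertzParams | None = None,
    season_start_day: float = 0.0,
    intervals: tuple[int, ...] = (14, 28),
) -> pd.DataFrame:
    """Derive birth-date columns for a cohort/session table.

    Expects per-row ``individual_id``, ``first_capture_day`` (days since
    season start) and ``first_capture_mass_g``; appends ``estimated_age``,
    ``birth_date_numeric`` and one coarsened column per interval
    (``birth_date_14d`` etc.).  Rows of the same individual share one record.
    """
    p = params or GompertzParams()
    out = cohort.copy()
    firsts = out.groupby("individual_id")[["first_capture_day", "first_capture_mass_g"]].first()
    ages = firsts["first_capture_mass_g"].map(lambda m: estimate_age(m, p))
    births = firsts["first_capture_day"] - ages
    out["estimated_age"] = out["individual_id"].map(ages)
    out["birth_date_numeric"] = out["individual_id"].map(births)
    for interval in intervals:
        out[f"birth_date_{interval}d"] = coarsen_birth_date(
            out["birth_date_numeric"].to_numpy(), interval, season_start_day
        )
    return out
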