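"""Gompertz growth model for juvenile tibia length, its inversion to age,
and birth-date back-calculation.

The growth of juvenile garden dormice is modelled with the Gompertz curve

    TL(t) = a * exp(-b * exp(-c * t))

where ``a`` (mm) is the asymptotic adult tibia length, ``b`` a dimensionless
scale describing the exponential decrease, and ``c`` (1/day) the growth rate.
Fitted on a reference litter of known birth date, the curve is inverted
analytically,

    t(TL) = -(1/c) * ln(-ln(TL/a) / b),

to estimate the age of a juvenile from the tibia length at its first
capture; subtracting that age from the capture date yields the birth date,
reported as an ISO week number.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GompertzParams",
    "BirthEstimate",
    "GrowthFitError",
    "GompertzDomainError",
    "gompertz_tl",
    "fit_gompertz",
    "age_from_tl",
    "estimate_birth_weeks",
]


class GrowthFitError(RuntimeError):
    """Nonlinear least-squares fit failed or the data are degenerate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class GompertzDomainError(ValueError):
    """Input outside the valid domain of the curve or its inverse."""


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz parameters with standard errors and goodness of fit."""

    a: float
    b: float
    c: float
    se_a: float = float("nan")
    se_b: float = float("nan")
    se_c: float = float("nan")
    r_squared: float = float("nan")
    n_points: int = 0

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError(f"parameters must be positive: a={self.a}, b={self.b}, c={self.c}")

    @property
    def tl_at_birth(self) -> float:
        """Curve value at t = 0, i.e. a * exp(-b); lower domain bound of the inverse."""
        return self.a * math.exp(-self.b)


#: Published reference-litter parameters (asymptote mm, scale, rate per day).
REFERENCE_PARAMS = GompertzParams(a=31.34, b=1.22, c=0.07, se_a=0.25, se_b=0.03, se_c=0.003, r_squared=0.99, n_points=9)


def gompertz_tl(t, params: GompertzParams):
    """Evaluate the Gompertz curve at age ``t`` days (scalar or array).

    Strictly increasing in ``t`` and bounded above by the asymptote ``a``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise GompertzDomainError("age must be non-negative")
    out = params.a * np.exp(-params.b * np.exp(-params.c * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _gompertz(t, a, b, c):
    return a * np.exp(-b * np.exp(-c * t))


def fit_gompertz(
    ages,
    tls,
    tolerance: float = 1e-8,
    max_iterations: int = 200,
) -> GompertzParams:
    """Fit the Gompertz curve to (age, TL) data by nonlinear least squares.

    Starting values come from a simple heuristic (a0 = 1.05 * max TL,
    b0 = ln(a0 / min TL), c0 = 0.05/day). Standard errors derive from the
    local curvature of the least-squares surface; R^2 = 1 - SS_res/SS_tot.
    """
    ages = np.asarray(ages, dtype=float)
    tls = np.asarray(tls, dtype=float)
    if ages.shape != tls.shape or ages.ndim != 1:
        raise ValueError("ages and tls must be matching 1-d arrays")
    if ages.size < 4:
        raise GrowthFitError("need at least 4 points spanning the rising phase")
    if np.ptp(tls) == 0:
        raise GrowthFitError("degenerate data: constant TL")

    a0 = 1.05 * float(tls.max())
    b0 = math.log(a0 / float(tls.min()))
    c0 = 0.05
    p0 = (a0, max(b0, 1e-3), c0)
    try:
        popt, pcov = curve_fit(
            _gompertz,
            ages,
            tls,
            p0=p0,
            maxfev=max_iterations * (ages.size + 10),
            xtol=tolerance,
            ftol=tolerance,
            bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
        )
    except RuntimeError as exc:
        raise GrowthFitError(f"fit did not converge: {exc}", last_iterate=p0) from exc

    resid = tls - _gompertz(ages, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(((tls - tls.mean()) ** 2).sum())
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return GompertzParams(
        a=float(popt[0]),
        b=float(popt[1]),
        c=float(popt[2]),
        se_a=float(se[0]),
        se_b=float(se[1]),
        se_c=float(se[2]),
        r_squared=1.0 - ss_res / ss_tot,
        n_points=int(ages.size),
    )


def age_from_tl(tl: float, params: GompertzParams) -> float:
    """Analytic inverse of the Gompertz curve: age in days for a given TL.

    Valid for TL strictly between the birth size a*exp(-b) and the
    asymptote a; round-trips with :func:`gompertz_tl` to 1e-9 relative.
    """
    lower = params.tl_at_birth
    if tl >= params.a:
        raise GompertzDomainError(
            f"TL {tl} mm is at or above the asymptote a = {params.a} mm"
        )
    if tl <= lower:
        raise GompertzDomainError(
            f"TL {tl} mm is at or below the birth size a*exp(-b) = {lower:.4f} mm "
            "(age would be negative)"
        )
    return -math.log(-math.log(tl / params.a) / params.b) / params.c


@dataclass(frozen=True)
class BirthEstimate:
    """Back-calculated birth date of one juvenile (from its first capture)."""

    individual_id: str
    first_capture_date: dt.date
    tl_at_first_capture: float
    estimated_age_days: float
    birth_date: dt.date
    birth_week: int
    period: int | None = None


def estimate_birth_weeks(
    captures: pd.DataFrame,
    params: GompertzParams,
    max_age_days: float | None = 60.0,
) -> tuple[list[BirthEstimate], pd.DataFrame]:
    """Estimate the birth week of every juvenile from its first capture.

    Each juvenile individual contributes exactly one estimate, taken at its
    earliest capture with a measured tibia length. Juveniles whose TL lies
    outside the invertible domain of the growth curve are excluded, as are
    those whose estimated age exceeds ``max_age_days``: the reference
    litter was measured up to 60 days of age, and beyond that calibration
    span the curve is nearly flat, so the inverse amplifies measurement
    noise into errors of weeks. Exclusions are listed in the returned
    report (columns: individual_id, first_capture_date, tibia_length,
    reason).

    Returns
    -------
    (estimates, exclusions)
    """
    juv = captures[
        (captures["age_class"] == "juvenile") & captures["tibia_length"].notna()
    ].copy()
    estimates: list[BirthEstimate] = []
    excluded: list[dict] = []
    for ind, grp in juv.groupby("individual_id", sort=True):
        first = grp.loc[grp["capture_date"].idxmin()]
        tl = float(first["tibia_length"])
        date = first["capture_date"]
        if isinstance(date, pd.Timestamp):
            date = date.date()
        try:
            age = age_from_tl(tl, params)
        except GompertzDomainError as exc:
            reason = (
                "above_asymptote" if tl >= params.a else "below_birth_size"
            )
            excluded.append(
                {
                    "individual_id": ind,
                    "first_capture_date": date,
                    "tibia_length": tl,
                    "reason": reason,
                    "detail": str(exc),
                }
            )
            continue
        if max_age_days is not None and age > max_age_days:
            excluded.append(
                {
                    "individual_id": ind,
                    "first_capture_date": date,
                    "tibia_length": tl,
                    "reason": "beyond_calibration",
                    "detail": f"estimated age {age:.1f} d exceeds the "
                    f"{max_age_days:g}-day calibration span",
                }
            )
            continue
        birth_date = date - dt.timedelta(days=round(age))
        estimates.append(
            BirthEstimate(
                individual_id=str(ind),
                first_capture_date=date,
                tl_at_first_capture=tl,
                estimated_age_days=age,
                birth_date=birth_date,
                birth_week=birth_date.isocalendar()[1],
                period=int(first["period"]) if "period" in first and pd.notna(first["period"]) else None,
            )
        )
    exclusions = pd.DataFrame(
        excluded,
        columns=["individual_id", "first_capture_date", "tibia_length", "reason", "detail"],
    )
    return estimates, exclusions
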