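"""Size-corrected body-mass models.

Three named mixed models, each with an individual random intercept:

* adult BM (per sex): BM ~ TL + month + period + month:period + T_aminhib
  + site, month a five-level factor May-September — the model behind the
  September period contrast (pre-hibernation fattening);
* juvenile log BM: ln(BM) ~ TL + birth week + period — TL serves as an age
  proxy, the period offset measures the change in mass gain after weaning;
* adult TL: TL ~ BM + sex + period + month — checks that body size itself
  did not change between the study periods.

Model formulas are fixed (no selection); covariates that are absent or
constant in the supplied table (e.g. a single site, or no attached winter
temperature) are dropped with a warning rather than producing a
rank-deficient design.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .lmm import (
    EMMResult,
    LMMFit,
    ModelSpec,
    estimated_marginal_means,
    fit_lmm,
    tukey_contrasts,
)

__all__ = [
    "MONTH_LEVELS",
    "fit_adult_bm",
    "fit_juvenile_logbm",
    "fit_tl_model",
    "attach_t_aminhib",
    "september_period_contrast",
    "period_difference_from_means",
    "prehibernation_reduction_pct",
]

#: Month factor levels of the adult models (reference: May).
MONTH_LEVELS = ["May", "June", "July", "August", "September"]

_MONTH_NAME = {5: "May", 6: "June", 7: "July", 8: "August", 9: "September", 10: "October"}


def _with_month(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    if "month" not in out.columns:
        out["month"] = [
            _MONTH_NAME.get(pd.Timestamp(d).month, str(pd.Timestamp(d).month))
            for d in out["capture_date"]
        ]
    out["period"] = out["period"].astype(str)
    return out


def attach_t_aminhib(table: pd.DataFrame, winter_medians: dict[int, float]) -> pd.DataFrame:
    """Attach the preceding winter's T_aminhib to each capture.

    A capture in year Y belongs to the active season following the winter
    that started 1 October of year Y-1; ``winter_medians`` maps that start
    year to the median daily-minimum temperature.
    """
    out = table.copy()
    out["t_aminhib"] = [
        winter_medians.get(pd.Timestamp(d).year - 1, np.nan) for d in out["capture_date"]
    ]
    return out


def _prune_optional(table: pd.DataFrame, spec: ModelSpec) -> ModelSpec:
    """Drop optional covariates that are missing or constant in the data."""
    numeric = list(spec.numeric)
    factors = dict(spec.factors)
    for col in ("t_aminhib",):
        if col in numeric and (
            col not in table.columns
            or table[col].isna().all()
            or table[col].nunique(dropna=True) < 2
        ):
            warnings.warn(f"covariate {col!r} absent or constant; dropped from model")
            numeric.remove(col)
    for col in ("site",):
        if col in factors and (
            col not in table.columns or table[col].nunique(dropna=True) < 2
        ):
            warnings.warn(f"factor {col!r} absent or constant; dropped from model")
            del factors[col]
    return ModelSpec(
        response=spec.response,
        group=spec.group,
        numeric=numeric,
        factors=factors,
        interactions=spec.interactions,
        log_response=spec.log_response,
    )


def fit_adult_bm(table: pd.DataFrame, sex: str) -> LMMFit:
    """Adult body-mass model for one sex, size-corrected via tibia length."""
    data = _with_month(table)
    data = data[
        (data["age_class"] == "adult")
        & (data["sex"] == sex)
        & data["tibia_length"].notna()
        & data["month"].isin(MONTH_LEVELS)
    ]
    if data.empty:
        raise ValueError(f"no adult records of sex {sex!r} with TL")
    spec = ModelSpec(
        response="body_mass",
        group="individual_id",
        numeric=["tibia_length", "t_aminhib"],
        factors={"month": MONTH_LEVELS, "period": ["1", "2"], "site": None},
        interactions=[("month", "period")],
    )
    return fit_lmm(data, _prune_optional(data, spec))


def fit_juvenile_logbm(table: pd.DataFrame) -> LMMFit:
    """Log-transformed juvenile body-mass model (TL + birth week + period)."""
    data = _with_month(table)
    data = data[
        (data["age_class"] == "juvenile")
        & data["tibia_length"].notna()
        & data["birth_week"].notna()
    ]
    if data.empty:
        raise ValueError("no juvenile records with TL and birth week")
    if (data["body_mass"] <= 0).any():
        bad = list(data.index[data["body_mass"] <= 0])
        raise ValueError(f"non-positive body mass at row(s) {bad}")
    spec = ModelSpec(
        response="body_mass",
        group="individual_id",
        numeric=["tibia_length", "birth_week"],
        factors={"period": ["1", "2"]},
        log_response=True,
    )
    return fit_lmm(data, spec)


def fit_tl_model(table: pd.DataFrame) -> LMMFit:
    """Adult tibia-length model (BM + sex + period + month)."""
    data = _with_month(table)
    data = data[
        (data["age_class"] == "adult")
        & data["tibia_length"].notna()
        & data["month"].isin(MONTH_LEVELS)
    ]
    if data.empty:
        raise ValueError("no adult records with TL")
    spec = ModelSpec(
        response="tibia_length",
        group="individual_id",
        numeric=["body_mass"],
        factors={
            "sex": ["female", "male"],
            "period": ["1", "2"],
            "month": MONTH_LEVELS,
        },
    )
    return fit_lmm(data, spec)


def september_period_contrast(fit: LMMFit):
    """September period-1 minus period-2 EMM difference (grams).

    Returns the :class:`~quercinus.lmm.EMMContrast` for the September cell
    pair, the model-based measure of the change in pre-hibernation body
    mass between the two study decades.
    """
    emms = estimated_marginal_means(fit, ["month", "period"])
    for con in tukey_contrasts(emms):
        pair = {con.level_a, con.level_b}
        if pair == {("September", "1"), ("September", "2")}:
            if con.level_a == ("September", "2"):
                # orient as period 1 minus period 2
                return con.__class__(
                    level_a=con.level_b,
                    level_b=con.level_a,
                    estimate=-con.estimate,
                    se=con.se,
                    df=con.df,
                    t=-con.t,
                    p_tukey=con.p_tukey,
                    p_unadjusted=con.p_unadjusted,
                )
            return con
    raise ValueError("September cells absent from both periods")


def period_difference_from_means(mean_p1: float, mean_p2: float) -> float:
    """Plain difference of two period means (g), period 1 minus period 2."""
    return float(mean_p1) - float(mean_p2)


def prehibernation_reduction_pct(
    september_means: dict[str, tuple[float, float]]
) -> float:
    """Sex-averaged relative September BM reduction, period 1 -> period 2.

    ``september_means`` maps sex to its (period-1, period-2) September mean
    body masses in grams; the result is the mean over sexes of
    100 * (m1 - m2) / m1.
    """
    if not september_means:
        raise ValueError("no September means supplied")
    rels = [100.0 * (m1 - m2) / m1 for m1, m2 in september_means.values()]
    return float(np.mean(rels))
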