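"""Semi-quantitative fecal diet composition.

Residue areas (mm^2 per food category, measured on millimetre paper under
a stereo microscope) are converted to percentage shares per sample; monthly
composition is summarised by medians and quartiles per stratum, with May
and June pooled for adults because of small sample sizes. The frequency of
occurrence (FoO) of a category is the percentage of samples in a stratum
containing any of its residue. Variation in the main residue counts is
modelled with a log-link negative-binomial GLM (dispersion estimated by
maximum likelihood).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import DIET_CATEGORIES, FecalSample

__all__ = [
    "ADULT_STRATA",
    "JUVENILE_STRATA",
    "DietSummary",
    "sample_proportions",
    "pool_months",
    "monthly_composition",
    "frequency_of_occurrence",
    "fit_nb_glm",
    "NBFit",
]

#: Default monthly strata (adults pool May and June).
ADULT_STRATA = ("May/June", "July", "August", "September")
JUVENILE_STRATA = ("July", "August", "September")

_MONTH_TO_STRATUM_ADULT = {5: "May/June", 6: "May/June", 7: "July", 8: "August", 9: "September"}
_MONTH_TO_STRATUM_JUV = {7: "July", 8: "August", 9: "September"}


def sample_proportions(sample: FecalSample) -> dict[str, float]:
    """Percentage share of each food category within one sample.

    Shares are 100 * area_k / total area and sum to 100 (the miscellaneous
    category holds any unassigned area); invariant to scaling all areas.
    """
    total = sample.total_area
    if total <= 0:
        raise ValueError(
            f"sample {sample.individual_id} {sample.sample_date}: all areas zero"
        )
    return {
        cat: 100.0 * sample.areas.get(cat, 0.0) / total for cat in DIET_CATEGORIES
    }


def pool_months(
    samples: list[FecalSample], pooling_rule: str = "default"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each sample to its monthly stratum.

    Under the default rule adults fall into May/June (pooled), July, August
    or September; juveniles into July, August or September. Samples outside
    the rule (e.g. October, or juveniles before weaning months) are returned
    separately as unassigned.

    Returns
    -------
    (assigned, unassigned) : DataFrames with one row per sample; ``assigned``
    carries a ``stratum`` column plus one percentage column per category.
    """
    if pooling_rule != "default":
        raise ValueError(f"unknown pooling rule {pooling_rule!r}")
    rows, leftovers = [], []
    for s in samples:
        month = s.sample_date.month
        if not (5 <= month <= 10):
            raise ValueError(
                f"sample {s.individual_id} {s.sample_date}: outside the May-October season"
            )
        table = (
            _MONTH_TO_STRATUM_ADULT if s.age_class == "adult" else _MONTH_TO_STRATUM_JUV
        )
        stratum = table.get(month)
        shares = sample_proportions(s)
        base = {
            "individual_id": s.individual_id,
            "sample_date": s.sample_date,
            "age_class": s.age_class,
            "year": s.sample_date.year,
            **shares,
        }
        if stratum is None:
            leftovers.append(base)
        else:
            rows.append({**base, "stratum": stratum})
    cols = ["individual_id", "sample_date", "age_class", "year", "stratum", *DIET_CATEGORIES]
    assigned = pd.DataFrame(rows, columns=cols)
    unassigned = pd.DataFrame(leftovers, columns=[c for c in cols if c != "stratum"])
    return assigned, unassigned


@dataclass(frozen=True)
class DietSummary:
    """Median and quartiles of percentage shares for one stratum."""

    stratum: str
    age_class: str
    n: int
    median: dict[str, float]
    q25: dict[str, float]
    q75: dict[str, float]


def monthly_composition(
    samples: list[FecalSample], age_class: str
) -> list[DietSummary]:
    """Median/quartile diet composition per monthly stratum for one age class.

    Empty strata are omitted (there is nothing to summarise); each summary
    carries its sample size.
    """
    assigned, _ = pool_months([s for s in samples if s.age_class == age_class])
    order = ADULT_STRATA if age_class == "adult" else JUVENILE_STRATA
    out = []
    for stratum in order:
        sub = assigned[assigned["stratum"] == stratum]
        if sub.empty:
            continue
        out.append(
            DietSummary(
                stratum=stratum,
                age_class=age_class,
                n=len(sub),
                median={c: float(sub[c].median()) for c in DIET_CATEGORIES},
                q25={c: float(sub[c].quantile(0.25)) for c in DIET_CATEGORIES},
                q75={c: float(sub[c].quantile(0.75)) for c in DIET_CATEGORIES},
            )
        )
    return out


def frequency_of_occurrence(
    samples: list[FecalSample],
    categories: tuple[str, ...] = ("arthropods", "fruits", "seeds"),
    threshold_area: float = 0.0,
) -> pd.DataFrame:
    """Frequency of occurrence of the main food items per stratum.

    FoO = 100 * (#samples with area strictly above ``threshold_area``) / n,
    computed separately per age class and monthly stratum.

    Returns a long-format DataFrame (age_class, stratum, category, foo_pct, n).
    """
    if threshold_area < 0:
        raise ValueError("threshold_area must be non-negative")
    rows = []
    for age_class, order in (("adult", ADULT_STRATA), ("juvenile", JUVENILE_STRATA)):
        group = [s for s in samples if s.age_class == age_class]
        if not group:
            continue
        assigned_samples: dict[str, list[FecalSample]] = {st: [] for st in order}
        table = (
            _MONTH_TO_STRATUM_ADULT if age_class == "adult" else _MONTH_TO_STRATUM_JUV
        )
        for s in group:
            st = table.get(s.sample_date.month)
            if st is not None:
                assigned_samples[st].append(s)
        for stratum in order:
            members = assigned_samples[stratum]
            if not members:
                continue
            for cat in categories:
                hits = sum(1 for s in members if s.areas.get(cat, 0.0) > threshold_area)
                rows.append(
                    {
                        "age_class": age_class,
                        "stratum": stratum,
                        "category": cat,
                        "foo_pct": 100.0 * hits / len(members),
                        "n": len(members),
                    }
                )
    return pd.DataFrame(rows, columns=["age_class", "stratum", "category", "foo_pct", "n"])


@dataclass(frozen=True)
class NBFit:
    """Negative-binomial GLM fit (log link, ML dispersion)."""

    params: pd.Series
    bse: pd.Series
    alpha: float
    llf: float
    converged: bool


def _nb_design(covariates: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=covariates.index)
    X["(Intercept)"] = 1.0
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            X[col] = s.astype(float)
        else:
            levels = sorted(s.astype(str).unique())
            for lvl in levels[1:]:
                X[f"{col}[{lvl}]"] = (s.astype(str) == lvl).astype(float)
    return X


def fit_nb_glm(response, covariates: pd.DataFrame) -> NBFit:
    """Fit a log-link negative-binomial GLM to non-negative integer counts.

    Percentage shares are rounded half-up to integers upstream before being
    used as counts. The dispersion parameter alpha (variance = mu + alpha
    mu^2) is estimated jointly by maximum likelihood; coefficients carry
    Wald standard errors.
    """
    y = np.asarray(response, dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("response must be non-negative integer counts")
    if np.all(y == 0):
        raise ValueError("degenerate fit: all-zero response")
    X = _nb_design(covariates)
    model = sm.NegativeBinomial(y, X.to_numpy(), loglike_method="nb2")
    res = None
    # near the alpha -> 0 (Poisson) boundary Newton steps can stall; fall
    # back to gradient-free optimisers before declaring failure
    for method in ("newton", "bfgs", "nm"):
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                candidate = model.fit(disp=False, maxiter=500, method=method)
            except Exception:
                continue
        if candidate.mle_retvals.get("converged", False) and np.all(
            np.isfinite(candidate.params)
        ):
            res = candidate
            break
    if res is None:
        raise RuntimeError("negative-binomial fit did not converge")
    names = list(X.columns) + ["alpha"]
    params = pd.Series(res.params, index=names)
    bse = pd.Series(np.asarray(res.bse), index=names)
    return NBFit(
        params=params.drop("alpha"),
        bse=bse.drop("alpha"),
        alpha=float(params["alpha"]),
        llf=float(res.llf),
        converged=True,
    )


def shares_as_counts(shares) -> np.ndarray:
    """Round percentage shares half-up to integers for count modelling."""
    arr = np.asarray(shares, dtype=float)
    return np.floor(arr + 0.5).astype(int)
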