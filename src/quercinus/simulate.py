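"""Seeded synthetic capture-mark-recapture data generator.

Generates populations, capture tables, fecal tables and daily temperature
series carrying the statistical structure the downstream analyses assume:

* two study periods with period-specific birth-week distributions —
  a bimodal mixture (peaks at ISO weeks 23 and 27, support 22-35) in
  period 1 and a unimodal one (peak week 25, support 18-32) in period 2;
* juvenile tibia growth along a Gompertz curve (asymptote 31.34 mm, scale
  1.22, rate 0.07/day) with additive measurement noise;
* juvenile body mass from the log-linear model
  ln BM = -0.32 + 0.11 TL + 0.03 birth_week - 0.23 [period 2] (+ random
  intercept + residual);
* adult body mass from a sex x month x period mean table anchored at the
  printed September means (male 105.1/91.8 g, female 85.5/75.5 g), with a
  tibia-length slope, an individual random intercept and residual noise;
* Dirichlet diet compositions whose expected arthropod share tracks the
  field pattern (adults ~25% rising to ~61% in September; juveniles ~50%);
* a sinusoidal annual temperature cycle with Gaussian noise.

Identical seeds give byte-identical output; changing the seed changes the
draws but never the structure.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GompertzParams, gompertz_tl
from .records import DIET_CATEGORIES, CaptureRecord, FecalSample, TemperatureSeries

__all__ = [
    "BirthWeekMixture",
    "SyntheticConfig",
    "simulate_population",
    "simulate_captures",
    "simulate_fecal",
    "simulate_daily_temperature",
    "simulate_reference_litter",
    "ADULT_BM_MEANS",
    "DIET_CONCENTRATIONS",
]


@dataclass(frozen=True)
class BirthWeekMixture:
    """Mixture of discrete Gaussians over ISO weeks, truncated to a support."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    support: tuple[int, int]

    def __post_init__(self):
        if not self.weights:
            raise ValueError("empty mixture")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(sd < 0 for sd in self.sds):
            raise ValueError("mixture sds must be non-negative")

    def pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Weeks of the support and their normalised probabilities."""
        weeks = np.arange(self.support[0], self.support[1] + 1)
        p = np.zeros(weeks.size)
        for w, mu, sd in zip(self.weights, self.means, self.sds):
            if sd == 0:
                # degenerate component: point mass at the nearest in-support week
                idx = int(np.argmin(np.abs(weeks - mu)))
                p[idx] += w
            else:
                p += w * np.exp(-0.5 * ((weeks - mu) / sd) ** 2)
        total = p.sum()
        if total <= 0:
            raise ValueError("mixture has no mass on its support")
        return weeks, p / total

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        weeks, p = self.pmf()
        return rng.choice(weeks, size=size, p=p)


# --- study-condition defaults -------------------------------------------------

#: Period-specific birth-week distributions (ISO weeks).
DEFAULT_BIRTH_WEEK_MODELS = {
    1: BirthWeekMixture(weights=(0.5, 0.5), means=(23.0, 27.0), sds=(1.5, 1.5), support=(22, 35)),
    2: BirthWeekMixture(weights=(1.0,), means=(25.0,), sds=(2.0,), support=(18, 32)),
}

#: Adult mean BM (g) by sex, month and period. September cells are the
#: printed study means; May and July female and May male cells likewise;
#: remaining cells interpolate the seasonal course (fattening from August).
ADULT_BM_MEANS = {
    ("female", "May"): (64.0, 63.5),
    ("female", "June"): (65.0, 62.0),
    ("female", "July"): (67.9, 60.4),
    ("female", "August"): (75.0, 67.0),
    ("female", "September"): (85.5, 75.5),
    ("female", "October"): (87.0, 77.0),
    ("male", "May"): (66.1, 61.7),
    ("male", "June"): (68.0, 63.0),
    ("male", "July"): (72.0, 66.0),
    ("male", "August"): (88.0, 78.0),
    ("male", "September"): (105.1, 91.8),
    ("male", "October"): (107.0, 93.5),
}

#: Juvenile log-BM model coefficients (natural log grams).
JUVENILE_LOGBM_COEF = {
    "intercept": -0.32,
    "tibia_length": 0.11,  # per mm
    "birth_week": 0.03,  # per ISO week
    "period2": -0.23,
}

#: Dirichlet concentration vectors per (age class, stratum month name),
#: ordered as DIET_CATEGORIES. Total concentration 8; expected arthropod
#: share ~25% for adults (61% in September) and ~50% for juveniles.
def _conc(shares: dict[str, float], total: float = 8.0) -> tuple[float, ...]:
    rest = 1.0 - sum(shares.values())
    n_rest = len(DIET_CATEGORIES) - len(shares)
    return tuple(
        total * shares.get(cat, rest / n_rest) for cat in DIET_CATEGORIES
    )


DIET_CONCENTRATIONS = {
    ("adult", "May"): _conc({"arthropods": 0.25, "seeds": 0.12, "fruits": 0.004}),
    ("adult", "June"): _conc({"arthropods": 0.25, "seeds": 0.12, "fruits": 0.004}),
    ("adult", "July"): _conc({"arthropods": 0.22, "seeds": 0.10, "fruits": 0.004}),
    ("adult", "August"): _conc({"arthropods": 0.25, "seeds": 0.14, "fruits": 0.20}),
    ("adult", "September"): _conc({"arthropods": 0.61, "seeds": 0.12, "fruits": 0.004}),
    ("juvenile", "July"): _conc({"arthropods": 0.40, "seeds": 0.06, "fruits": 0.05}),
    ("juvenile", "August"): _conc({"arthropods": 0.51, "seeds": 0.08, "fruits": 0.06}),
    ("juvenile", "September"): _conc({"arthropods": 0.53, "seeds": 0.10, "fruits": 0.04}),
}

_MONTH_NAME = {5: "May", 6: "June", 7: "July", 8: "August", 9: "September", 10: "October"}


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic population.

    Defaults encode the design of the field study: two periods (2003-2005
    and 2018-2021), three sites, monthly capture occasions May-October, and
    the growth, body-mass and diet models above.
    """

    n_juveniles_per_period: int = 60
    n_adults_per_period: int = 30
    period_years: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {1: (2003, 2005), 2: (2018, 2021)}
    )
    site_weights: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            1: {"RL": 0.8, "ME": 0.2},
            2: {"RL": 0.7, "WK": 0.3},
        }
    )
    birth_week_models: dict[int, BirthWeekMixture] = field(
        default_factory=lambda: dict(DEFAULT_BIRTH_WEEK_MODELS)
    )
    growth_params: GompertzParams = field(
        default_factory=lambda: GompertzParams(a=31.34, b=1.22, c=0.07)
    )
    tl_noise_sd: float = 0.3  # mm, juvenile TL measurement noise
    adult_tl_mean: dict[str, float] = field(
        default_factory=lambda: {"female": 31.7, "male": 32.8}
    )
    adult_tl_sd: float = 0.9
    adult_bm_means: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(ADULT_BM_MEANS)
    )
    adult_tl_slope: float = 1.0  # g per mm, size correction
    adult_intercept_sd: float = 3.0  # g, individual random intercept
    adult_residual_sd: float = 4.0  # g
    juvenile_logbm: dict[str, float] = field(
        default_factory=lambda: dict(JUVENILE_LOGBM_COEF)
    )
    juvenile_intercept_sd: float = 0.04  # log-g
    juvenile_residual_sd: float = 0.05  # log-g
    min_capture_age_days: int = 30  # juveniles capturable once they leave the nest
    capture_months: tuple[int, ...] = (5, 6, 7, 8, 9, 10)
    capture_day: int = 15
    detection_prob: float = 0.75
    round_measurements: bool = True  # nearest-g balance, 0.1 mm caliper
    diet_concentrations: dict[tuple[str, str], tuple[float, ...]] = field(
        default_factory=lambda: dict(DIET_CONCENTRATIONS)
    )
    fecal_sample_prob: float = 0.5
    fecal_total_area_mean: float = 120.0  # mm^2, log-normal scale
    fecal_total_area_sd: float = 0.4  # log scale
    fecal_detection_area_mm2: float = 0.5  # residues below this go unnoticed
    temp_mean_c: float = 4.0
    temp_amplitude_c: float = 8.0
    temp_noise_sd: float = 3.0
    temp_peak_doy: int = 196  # warmest day of year (mid-July)

    def validate(self) -> None:
        if self.detection_prob < 0 or self.detection_prob > 1:
            raise ValueError("detection_prob must be in [0, 1]")
        for period, model in self.birth_week_models.items():
            model.pmf()  # raises on empty/invalid mixture
        for key, conc in self.diet_concentrations.items():
            if any(a <= 0 for a in conc):
                raise ValueError(f"non-positive Dirichlet concentration for {key}")
        if any(
            sd < 0
            for sd in (
                self.tl_noise_sd,
                self.adult_intercept_sd,
                self.adult_residual_sd,
                self.juvenile_intercept_sd,
                self.juvenile_residual_sd,
                self.temp_noise_sd,
            )
        ):
            raise ValueError("all standard deviations must be non-negative")


def _choose_sites(rng, weights: dict[str, float], size: int) -> np.ndarray:
    names = sorted(weights)
    w = np.array([weights[s] for s in names], dtype=float)
    return rng.choice(names, size=size, p=w / w.sum())


def simulate_population(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Draw the individual roster.

    One row per individual: ID, sex (balanced within age class), period,
    cohort year, site, birth week (juveniles; NaN for adults) and the true
    random intercept for its body-mass model.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for period in sorted(config.period_years):
        years = range(
            config.period_years[period][0], config.period_years[period][1] + 1
        )
        years = list(years)
        mixture = config.birth_week_models.get(period)
        if mixture is None:
            raise ValueError(f"no birth-week mixture configured for period {period}")

        n_juv = config.n_juveniles_per_period
        n_ad = config.n_adults_per_period
        juv_weeks = mixture.sample(rng, n_juv)
        juv_years = rng.choice(years, size=n_juv)
        juv_sites = _choose_sites(rng, config.site_weights[period], n_juv)
        ad_years = rng.choice(years, size=n_ad)
        ad_sites = _choose_sites(rng, config.site_weights[period], n_ad)

        for i in range(n_juv):
            rows.append(
                {
                    "individual_id": f"P{period}J{i:03d}",
                    "sex": "female" if i % 2 == 0 else "male",
                    "age_class": "juvenile",
                    "period": period,
                    "year": int(juv_years[i]),
                    "site": juv_sites[i],
                    "birth_week": int(juv_weeks[i]),
                    "random_intercept": float(
                        rng.normal(0.0, config.juvenile_intercept_sd)
                    ),
                }
            )
        for i in range(n_ad):
            rows.append(
                {
                    "individual_id": f"P{period}A{i:03d}",
                    "sex": "female" if i % 2 == 0 else "male",
                    "age_class": "adult",
                    "period": period,
                    "year": int(ad_years[i]),
                    "site": ad_sites[i],
                    "birth_week": np.nan,
                    "random_intercept": float(
                        rng.normal(0.0, config.adult_intercept_sd)
                    ),
                }
            )
    return pd.DataFrame(rows)


def _birth_date(year: int, iso_week: int) -> dt.date:
    """Thursday of the given ISO week (mid-week convention)."""
    return dt.date.fromisocalendar(year, iso_week, 4)


def simulate_captures(
    roster: pd.DataFrame, config: SyntheticConfig, seed: int
) -> list[CaptureRecord]:
    """Simulate monthly capture occasions for every rostered individual.

    Juvenile TL follows the Gompertz curve at age-at-capture plus noise and
    its BM the juvenile log-BM model; adult BM follows the sex x month x
    period mean table with a TL slope centred at the sex's expected TL.
    Occasions before a juvenile's capturable age are skipped. BM is rounded
    to the nearest g when ``config.round_bm`` is set.
    """
    if roster.empty:
        raise ValueError("empty roster")
    config.validate()
    rng = np.random.default_rng(seed)
    records: list[CaptureRecord] = []
    coef = config.juvenile_logbm
    for row in roster.itertuples(index=False):
        # per-individual adult TL (constant across captures)
        if row.age_class == "adult":
            tl_true = rng.normal(
                config.adult_tl_mean[row.sex]
                if row.sex in config.adult_tl_mean
                else np.mean(list(config.adult_tl_mean.values())),
                config.adult_tl_sd,
            )
        else:
            tl_true = None
        birth = (
            _birth_date(row.year, int(row.birth_week))
            if row.age_class == "juvenile"
            else None
        )
        for month in config.capture_months:
            date = dt.date(row.year, month, config.capture_day)
            month_name = _MONTH_NAME[month]
            if rng.random() > config.detection_prob:
                continue
            if row.age_class == "juvenile":
                age = (date - birth).days
                if age < config.min_capture_age_days:
                    continue
                tl = gompertz_tl(float(age), config.growth_params) + rng.normal(
                    0.0, config.tl_noise_sd
                )
                log_bm = (
                    coef["intercept"]
                    + coef["tibia_length"] * tl
                    + coef["birth_week"] * float(row.birth_week)
                    + (coef["period2"] if row.period == 2 else 0.0)
                    + row.random_intercept
                    + rng.normal(0.0, config.juvenile_residual_sd)
                )
                bm = math.exp(log_bm)
            else:
                means = config.adult_bm_means.get((row.sex, month_name))
                if means is None:
                    continue
                mu = means[0] if row.period == 1 else means[1]
                tl = tl_true
                bm = (
                    mu
                    + config.adult_tl_slope * (tl - config.adult_tl_mean[row.sex])
                    + row.random_intercept
                    + rng.normal(0.0, config.adult_residual_sd)
                )
            if config.round_measurements:
                bm = float(np.floor(bm + 0.5))
                tl = float(np.floor(tl * 10.0 + 0.5) / 10.0)
            records.append(
                CaptureRecord(
                    individual_id=row.individual_id,
                    capture_date=date,
                    site=row.site,
                    sex=row.sex,
                    age_class=row.age_class,
                    body_mass=float(bm),
                    tibia_length=float(tl),
                    period=int(row.period),
                )
            )
    return records


def simulate_fecal(
    roster: pd.DataFrame, config: SyntheticConfig, seed: int
) -> list[FecalSample]:
    """Simulate fecal samples with Dirichlet residue compositions.

    Each individual may defecate during handling at each configured month
    with probability ``fecal_sample_prob``; per-sample areas are the total
    area times a Dirichlet draw from the month/age-class concentrations.
    """
    if roster.empty:
        raise ValueError("empty roster")
    config.validate()
    rng = np.random.default_rng(seed)
    samples: list[FecalSample] = []
    months = {
        "adult": (5, 6, 7, 8, 9),
        "juvenile": (7, 8, 9),
    }
    for row in roster.itertuples(index=False):
        for month in months[row.age_class]:
            key = (row.age_class, _MONTH_NAME[month])
            conc = config.diet_concentrations.get(key)
            if conc is None:
                raise ValueError(f"no diet concentrations configured for {key}")
            if rng.random() > config.fecal_sample_prob:
                continue
            total = float(
                np.exp(
                    rng.normal(
                        math.log(config.fecal_total_area_mean),
                        config.fecal_total_area_sd,
                    )
                )
            )
            shares = rng.dirichlet(conc)
            areas = {
                cat: total * float(s) for cat, s in zip(DIET_CATEGORIES, shares)
            }
            # residues smaller than the detection area are not recorded
            floor = config.fecal_detection_area_mm2
            detected = {c: a if a >= floor else 0.0 for c, a in areas.items()}
            if not any(a > 0 for a in detected.values()):
                top = max(areas, key=areas.get)
                detected[top] = areas[top]
            samples.append(
                FecalSample(
                    individual_id=row.individual_id,
                    sample_date=dt.date(row.year, month, config.capture_day),
                    age_class=row.age_class,
                    areas=detected,
                )
            )
    return samples


def temperature_curve(date: dt.date, config: SyntheticConfig) -> float:
    """Deterministic sinusoidal daily-minimum temperature for one date."""
    doy = date.timetuple().tm_yday
    return config.temp_mean_c + config.temp_amplitude_c * math.cos(
        2.0 * math.pi * (doy - config.temp_peak_doy) / 365.25
    )


def simulate_daily_temperature(
    config: SyntheticConfig,
    seed: int,
    start: dt.date | None = None,
    end: dt.date | None = None,
) -> TemperatureSeries:
    """Daily minimum temperatures: annual sinusoid plus Gaussian noise.

    The default span covers every winter preceding and within the
    configured period year ranges, so each capture season has an attached
    hibernation window.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if start is None or end is None:
        years = [y for lo, hi in config.period_years.values() for y in (lo, hi)]
        start = start or dt.date(min(years) - 1, 1, 1)
        end = end or dt.date(max(years), 12, 31)
    n = (end - start).days + 1
    dates = tuple(start + dt.timedelta(days=i) for i in range(n))
    noise = rng.normal(0.0, config.temp_noise_sd, size=n)
    temps = tuple(
        float(temperature_curve(d, config) + e) for d, e in zip(dates, noise)
    )
    return TemperatureSeries(dates=dates, tmin_c=temps)


def simulate_reference_litter(
    config: SyntheticConfig,
    seed: int,
    ages: tuple[int, ...] = (4, 11, 18, 25, 32, 39, 46, 53, 60),
) -> pd.DataFrame:
    """Weekly TL measurements of one reference litter.

    Emulates the calibration data: nine weekly measurement occasions up to
    60 days of age, TL on the configured Gompertz curve plus measurement
    noise.
    """
    rng = np.random.default_rng(seed)
    ages_arr = np.asarray(ages, dtype=float)
    tl = gompertz_tl(ages_arr, config.growth_params) + rng.normal(
        0.0, config.tl_noise_sd, size=ages_arr.size
    )
    return pd.DataFrame({"age_days": ages_arr, "tibia_length": tl})
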