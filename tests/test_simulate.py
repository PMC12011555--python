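import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from quercinus.growth import fit_gompertz, gompertz_tl
from quercinus.io import captures_to_frame, compute_t_aminhib
from quercinus.lmm import ModelSpec, fit_lmm
from quercinus.simulate import (
    BirthWeekMixture,
    SyntheticConfig,
    simulate_captures,
    simulate_daily_temperature,
    simulate_fecal,
    simulate_population,
    simulate_reference_litter,
    temperature_curve,
)


class TestPopulation:
    def test_same_seed_gives_identical_rosters(self, small_config):
        r1 = simulate_population(small_config, 7)
        r2 = simulate_population(small_config, 7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_different_seed_changes_draws_not_structure(self, small_config):
        r1 = simulate_population(small_config, 7)
        r2 = simulate_population(small_config, 8)
        assert list(r1.columns) == list(r2.columns)
        assert len(r1) == len(r2)
        assert not r1["birth_week"].equals(r2["birth_week"])

    def test_period1_birth_weeks_within_support(self, small_config):
        roster = simulate_population(small_config, 1)
        weeks = roster.loc[
            (roster.period == 1) & roster.birth_week.notna(), "birth_week"
        ]
        assert weeks.between(22, 35).all()

    def test_degenerate_mixture_collapses_to_component_means(self):
        cfg = SyntheticConfig(
            birth_week_models={
                1: BirthWeekMixture((0.5, 0.5), (23.0, 27.0), (0.0, 0.0), (22, 35)),
                2: BirthWeekMixture((1.0,), (25.0,), (0.0,), (18, 32)),
            }
        )
        roster = simulate_population(cfg, 3)
        w1 = set(roster.loc[(roster.period == 1) & roster.birth_week.notna(), "birth_week"])
        w2 = set(roster.loc[(roster.period == 2) & roster.birth_week.notna(), "birth_week"])
        assert w1 <= {23, 27}
        assert w2 == {25}

    def test_invalid_mixture_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            BirthWeekMixture((0.5, 0.6), (23.0, 27.0), (1.0, 1.0), (22, 35))


class TestCaptures:
    def test_zero_noise_measurements_equal_model_values(self, zero_noise_config):
        roster = simulate_population(zero_noise_config, 5)
        records = simulate_captures(roster, zero_noise_config, 6)
        juv = [r for r in records if r.age_class == "juvenile"]
        coef = zero_noise_config.juvenile_logbm
        for r in juv[:25]:
            row = roster[roster.individual_id == r.individual_id].iloc[0]
            birth = dt.date.fromisocalendar(row.year, int(row.birth_week), 4)
            age = (r.capture_date - birth).days
            tl_expected = gompertz_tl(float(age), zero_noise_config.growth_params)
            assert r.tibia_length == pytest.approx(tl_expected, abs=1e-9)
            bm_expected = math.exp(
                coef["intercept"]
                + coef["tibia_length"] * tl_expected
                + coef["birth_week"] * row.birth_week
                + (coef["period2"] if row.period == 2 else 0.0)
            )
            assert r.body_mass == pytest.approx(bm_expected, abs=1e-9)

    def test_certain_detection_gives_six_records_per_adult(self, zero_noise_config):
        roster = simulate_population(zero_noise_config, 5)
        records = simulate_captures(roster, zero_noise_config, 6)
        counts = pd.Series(
            [r.individual_id for r in records if r.age_class == "adult"]
        ).value_counts()
        n_adults = (roster.age_class == "adult").sum()
        assert len(counts) == n_adults
        assert (counts == len(zero_noise_config.capture_months)).all()

    def test_occasions_before_capturable_age_skipped(self, zero_noise_config):
        roster = simulate_population(zero_noise_config, 5)
        records = simulate_captures(roster, zero_noise_config, 6)
        for r in records:
            if r.age_class != "juvenile":
                continue
            row = roster[roster.individual_id == r.individual_id].iloc[0]
            birth = dt.date.fromisocalendar(row.year, int(row.birth_week), 4)
            assert (r.capture_date - birth).days >= zero_noise_config.min_capture_age_days

    def test_zero_noise_juvenile_logbm_fit_recovers_coefficients_to_1e6(
        self, zero_noise_config
    ):
        roster = simulate_population(zero_noise_config, 9)
        frame = captures_to_frame(simulate_captures(roster, zero_noise_config, 10))
        frame = frame.merge(
            roster[["individual_id", "birth_week"]], on="individual_id", how="left"
        )
        juv = frame[frame.age_class == "juvenile"].copy()
        juv["period"] = juv["period"].astype(str)
        fit = fit_lmm(
            juv,
            ModelSpec(
                response="body_mass",
                group="individual_id",
                numeric=["tibia_length", "birth_week"],
                factors={"period": ["1", "2"]},
                log_response=True,
            ),
        )
        coef = zero_noise_config.juvenile_logbm
        assert fit.params["(Intercept)"] == pytest.approx(coef["intercept"], abs=1e-6)
        assert fit.params["tibia_length"] == pytest.approx(coef["tibia_length"], abs=1e-6)
        assert fit.params["birth_week"] == pytest.approx(coef["birth_week"], abs=1e-6)
        assert fit.params["period[2]"] == pytest.approx(coef["period2"], abs=1e-6)

    def test_noisy_juvenile_logbm_recovery_within_2_se(self):
        cfg = SyntheticConfig(n_juveniles_per_period=150, n_adults_per_period=5)
        roster = simulate_population(cfg, 21)
        frame = captures_to_frame(simulate_captures(roster, cfg, 22))
        frame = frame.merge(
            roster[["individual_id", "birth_week"]], on="individual_id", how="left"
        )
        juv = frame[frame.age_class == "juvenile"].copy()
        juv["period"] = juv["period"].astype(str)
        fit = fit_lmm(
            juv,
            ModelSpec(
                response="body_mass",
                group="individual_id",
                numeric=["tibia_length", "birth_week"],
                factors={"period": ["1", "2"]},
                log_response=True,
            ),
        )
        truth = cfg.juvenile_logbm
        se = fit.bse
        assert abs(fit.params["tibia_length"] - truth["tibia_length"]) < 2 * se["tibia_length"]
        assert abs(fit.params["birth_week"] - truth["birth_week"]) < 2 * se["birth_week"]
        assert abs(fit.params["period[2]"] - truth["period2"]) < 2 * se["period[2]"]


class TestFecal:
    def test_symmetric_concentrations_give_equal_mean_shares(self):
        cfg = SyntheticConfig(
            n_adults_per_period=150,
            n_juveniles_per_period=2,
            fecal_sample_prob=1.0,
            fecal_detection_area_mm2=0.0,
            diet_concentrations={
                ("adult", m): tuple([1.0] * 8)
                for m in ("May", "June", "July", "August", "September")
            }
            | {("juvenile", m): tuple([1.0] * 8) for m in ("July", "August", "September")},
        )
        roster = simulate_population(cfg, 2)
        samples = simulate_fecal(roster, cfg, 3)
        shares = np.array(
            [
                [s.areas[c] / s.total_area for c in sorted(s.areas)]
                for s in samples
                if s.age_class == "adult"
            ]
        )
        assert shares.shape[0] > 500
        assert np.allclose(shares.mean(axis=0), 1 / 8, atol=0.01)

    def test_dominant_concentration_dominates_shares(self):
        conc = {"arthropods": 0.97}
        cfg = SyntheticConfig(
            n_adults_per_period=50,
            n_juveniles_per_period=2,
            fecal_sample_prob=1.0,
            diet_concentrations={
                ("adult", m): tuple(
                    800.0 if c == "arthropods" else 0.1 for c in
                    ("arthropods", "fruits", "seeds", "blossoms", "buds", "leaves", "moss", "miscellaneous")
                )
                for m in ("May", "June", "July", "August", "September")
            }
            | {("juvenile", m): tuple([1.0] * 8) for m in ("July", "August", "September")},
        )
        roster = simulate_population(cfg, 2)
        samples = [s for s in simulate_fecal(roster, cfg, 3) if s.age_class == "adult"]
        med = np.median([s.areas["arthropods"] / s.total_area for s in samples])
        assert med > 0.99

    def test_september_adult_arthropod_median_tracks_configuration(self):
        cfg = SyntheticConfig(n_adults_per_period=100, fecal_sample_prob=1.0)
        roster = simulate_population(cfg, 12)
        samples = [
            s
            for s in simulate_fecal(roster, cfg, 13)
            if s.age_class == "adult" and s.sample_date.month == 9
        ]
        assert len(samples) >= 200
        med = 100 * np.median([s.areas["arthropods"] / s.total_area for s in samples])
        conc = cfg.diet_concentrations[("adult", "September")]
        expected = 100 * conc[0] / sum(conc)
        assert abs(med - expected) <= 5.0

    def test_missing_month_concentration_is_a_config_error(self, small_config):
        cfg = SyntheticConfig(
            diet_concentrations={("adult", "May"): tuple([1.0] * 8)}
        )
        roster = simulate_population(cfg, 2)
        with pytest.raises(ValueError, match="no diet concentrations"):
            simulate_fecal(roster, cfg, 3)


class TestTemperature:
    def test_zero_noise_zero_amplitude_is_constant(self):
        cfg = SyntheticConfig(temp_noise_sd=0.0, temp_amplitude_c=0.0)
        series = simulate_daily_temperature(cfg, 4)
        assert set(series.tmin_c) == {cfg.temp_mean_c}

    def test_same_seed_identical_series(self, small_config):
        s1 = simulate_daily_temperature(small_config, 4)
        s2 = simulate_daily_temperature(small_config, 4)
        assert s1 == s2

    def test_zero_noise_winter_median_matches_analytic_sinusoid(self):
        cfg = SyntheticConfig(temp_noise_sd=0.0)
        series = simulate_daily_temperature(cfg, 4)
        summary = compute_t_aminhib(series, 2018)
        window = [
            dt.date(2018, 10, 1) + dt.timedelta(days=i)
            for i in range((dt.date(2019, 4, 30) - dt.date(2018, 10, 1)).days + 1)
        ]
        oracle = float(np.median([temperature_curve(d, cfg) for d in window]))
        assert summary.t_aminhib_c == pytest.approx(oracle, abs=1e-9)


class TestParameterRecovery:
    def test_gompertz_asymptote_recovered_with_small_bias_over_replicates(self):
        """Replicated litter fits recover the asymptote with |mean bias| < 1%."""
        cfg = SyntheticConfig()
        truth = cfg.growth_params.a
        estimates = []
        for seed in range(200):
            litter = simulate_reference_litter(cfg, seed)
            fit = fit_gompertz(litter["age_days"], litter["tibia_length"])
            estimates.append(fit.a)
        bias = np.mean(estimates) - truth
        assert abs(bias) / truth < 0.01
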