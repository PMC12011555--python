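# quercinus

Analysis toolkit for long-term capture-mark-recapture (CMR) studies of the
garden dormouse (*Eliomys quercinus*), a small fat-storing hibernator whose
pre-hibernation body mass is an early-warning indicator of population
health. The package reconstructs juvenile ages and birth weeks from a
growth curve, compares size-corrected body mass across study periods with
mixed models, summarises fecal diet composition, and projects the
consequences of a pre-hibernation mass deficit on the hibernation energy
budget. A seeded synthetic-data generator reproduces the statistical
structure of such a study, so the full pipeline runs and is tested without
any field data.

## What it computes

* **Growth & age**: Gompertz growth of juvenile tibia length,
  TL(t) = a·e^(−b·e^(−c·t)), fitted by nonlinear least squares and inverted
  analytically to estimate age from TL at first capture; birth dates are
  back-calculated and reported as ISO birth weeks, with peak detection on
  the weekly histogram (bimodal vs unimodal reproduction patterns).
* **Body mass**: random-intercept linear mixed models (profiled REML,
  Satterthwaite df) for adult BM with a month × period interaction, for
  juvenile log BM (TL + birth week + period), and for adult TL; estimated
  marginal means and Tukey contrasts give the size-corrected September
  period differences.
* **Diet**: percentage shares of residue areas per fecal sample, monthly
  median/quartile composition (May/June pooled for adults), frequency of
  occurrence of the main food items, and negative-binomial GLMs for residue
  counts.
* **Energy budget**: daily and relative body-mass loss over the 1 Oct –
  30 Apr hibernation window (212 days) and the number of days earlier a
  given mass deficit exhausts the reserves, with a projected emergence date.
* **Winter temperature**: the median of daily minimum temperatures over a
  hibernation window (T_aminhib), used as a covariate in the adult model.

See `docs/methods.md` for the models, assumptions and defaults.

## Worked example

The energy-budget chain from published September and May male means:

```sh
$ quercinus energy --entry 105.1 --exit 66.1 \
    --window-start 2003-10-01 --window-end 2004-04-30 --deficit 10
window 2003-10-01 - 2004-04-30 (212 d): loss 39.0 g, 0.18 g/day (0.17 %/day); 10 g deficit -> reserves gone 54 d earlier, projected emergence 2004-03-07
```

Reading: a male entering hibernation at 105.1 g and emerging at 66.1 g loses
39 g over the 212-day window — 0.18 g/day, i.e. 0.17% of entry mass per day.
Starting 10 g lighter exhausts the same reserves 54 days sooner, moving the
projected emergence from the end of April to 7 March, when food is still
scarce.

The full synthetic pipeline (simulate → growth fit → birth weeks → mixed
models → diet → energy budget):

```python
from quercinus.pipeline import PipelineConfig, run_pipeline

metrics = run_pipeline(PipelineConfig(mode="synthetic", seed=1,
                                      output_dir="demo_out"))
print(metrics["stages"]["phenology"]["per_period"])
# {'1': {'n': 43, 'peak_weeks': [23, 26], 'earliest_week': 21, 'latest_week': 30},
#  '2': {'n': 47, 'peak_weeks': [25],     'earliest_week': 20, 'latest_week': 29}}
print(metrics["stages"]["body_mass"]["male"]["september_period_difference_g"])
# 10.724097492019188   (model EMM contrast; generator truth is 13.3 g)
```

The period-1 cohort shows two birth peaks and the period-2 cohort one — the
qualitative reproduction-pattern contrast between the two study decades.
Stage CSVs (`birth_estimates.csv`, `adult_bm_*_coefficients.csv`,
`diet_composition.csv`, `energy_budget.csv`, ...), a `metrics.json` index
and a markdown report are written to the output directory; `files` mode
ingests real capture/fecal/temperature CSVs instead (headers documented in
`quercinus.io`).

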