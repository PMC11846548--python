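# equicast

Equity measurement and dual-model demand forecasting for regional
health-workforce panels.

Given a region-by-year panel (population, land area, registered nurses,
doctors, health technicians, hospital beds), `equicast`:

- derives the standard allocation indicators (nurses per 1,000
  population, nurses per km², doctor-to-nurse and bed-to-nurse ratios,
  nurse share of health technicians, average annual growth rate);
- measures allocation equity per year with Lorenz curves, Gini
  coefficients (two independent computation routes, five fairness
  bands) and the Theil index with its within/between-group
  decomposition and contribution rates;
- forecasts demand with two models side by side: a from-scratch
  GM(1,1) grey model (least-squares parameter estimation,
  posterior-difference C/P test, four accuracy levels, extrapolation
  gated on level ≤ 2) and an ARIMA stage (KPSS-based differencing
  order, deterministic information-criterion grid search over (p, q),
  95% forecast intervals);
- ships a synthetic panel generator with known ground truth, so the
  whole pipeline is testable without external data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence of the two Gini routes, closed-form fixtures, GM(1,1)
parameter recovery, grading bands, ARIMA Monte-Carlo recovery,
end-to-end determinism), one test per criterion.

## CLI

```sh
# write a synthetic 11-region x 20-year panel
equicast simulate --seed 1 --out panel.csv

# per-year Gini (both bases), Theil, and Lorenz points
equicast equity --panel panel.csv --out equity_out/
# add --grouping groups.csv (columns: region_id,group) for the
# within/between Theil decomposition

# GM(1,1) + ARIMA forecasts of the whole-province total series
equicast forecast --panel panel.csv --horizon 5 --out forecast_out/

# full pipeline: indicators -> equity -> dual forecasts + manifest
equicast report --panel panel.csv --seed 1 --out report_out/
# or run directly on a synthetic panel:
equicast report --seed 1 --out report_out/
```

The report bundle contains `indicators.csv`, `gini.csv` (with fairness
labels), `theil.csv`, `totals.csv`, `equity_trend.csv`,
`forecast_arima.csv`, `forecast_grey.csv` (with the grade gate column)
and `manifest.json`. Re-running with the same seed reproduces every
output byte for byte. Grey forecasts are always reported; when the
model grades worse than level 2 they are flagged
`unqualified - extrapolation unreliable`, never dropped.

Panel CSV schema (comma default, tab accepted, header required):

```
region_id,year,stratum,population,area_km2,nurses,doctors,health_technicians,beds
```

`stratum` is one of `urban`, `county`, `whole`. Variant column names
can be mapped via `read_panel(column_map=...)`.

## Library sketch

```python
from equicast import (
    SyntheticConfig, generate_panel, build_lorenz, gini_summation,
    classify_gini, theil_decompose, fit_gm11, gm11_diagnose, gm11_forecast,
)

panel = generate_panel(SyntheticConfig(seed=1))
curve = build_lorenz([(r.population, r.nurses)
                      for r in panel.records if r.year == 2022])
g = gini_summation(curve)            # two-route Gini: see gini_trapezoid
label = classify_gini(g)             # fairness band

fit = fit_gm11(panel.total_series("nurses").to_numpy())
diag = gm11_diagnose(fit)            # C, P, grade 1-4, extrapolation gate
forecast = gm11_forecast(fit, horizon=5)
```
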