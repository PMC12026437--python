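# shelfkin

Kinetic and Arrhenius shelf-life modelling for food quality indicators
(spoilage markers such as TVB-N, total viable count and acid value, and
texture attributes such as springiness and hardness).

The package implements the classical accelerated shelf-life workflow:

1. **Kinetic fitting** (`shelfkin.kinetics`) — fit zero-, first- and
   second-order rate laws to each indicator time series at each storage
   temperature by OLS in transformed space (identity / log / reciprocal),
   and select the best order per indicator by the summed R² across
   temperatures (ties broken by summed RMSE, then lower order).
2. **Arrhenius regression** (`shelfkin.arrhenius`) — regress ln|k| on 1/T
   to obtain the activation energy `Ea = -slope·R/1000` (R = 8.3144
   J K⁻¹ mol⁻¹) and pre-exponential factor `K0 = exp(intercept)`; signs of
   decaying indicators are stored and restored on prediction.
3. **Shelf-life prediction** (`shelfkin.shelf_life`) — predict indicator
   values at any time/temperature, compute time-to-critical-limit
   (`SL = (limit − A0)/k` or `(ln limit − ln A0)/k`), combine indicators
   into an overall shelf life, and validate predictions against measured
   series via relative deviations (predicted value as denominator).
4. **Ancillary analyses** (`shelfkin.quality`) — acid-value titration
   arithmetic, single-factor sensory optimum selection, Pearson
   correlation screening, and acceptability assessment against critical
   limits.
5. **Synthetic data** (`shelfkin.synthetic`) — forward simulation of
   trajectories with temperature-dependent rates plus Gaussian noise, and
   parameter-recovery experiments that exercise the whole chain against a
   known ground truth.

Units: time is internally in **days** (hour-denominated input is converted
on read), temperatures are **°C** at the API surface and Kelvin internally
(offset 273.15). TVC is modelled directly on the log10 CFU/g scale.

## CLI

The console script `shelfkin` chains the stages:

```sh
# full pipeline: fit -> select order -> Arrhenius -> shelf life -> report
shelfkin run --input data.csv --config config.json --temps 10 \
    --output out/ --seed 1

# individual stages
shelfkin fit --input data.csv --indicator TVB-N --orders 0,1,2 --output fits.json
shelfkin arrhenius --fits fits.json --output arrhenius.json
shelfkin predict --model out/models.json --indicator TVB-N --temp 10 --times 2,4,6,8,10
shelfkin validate --model out/models.json --indicator TVB-N \
    --measured measured.csv --temp 10 --output validation.csv

# synthetic data and recovery experiments
shelfkin simulate --config synth.json --seed 42 --output sim.csv
shelfkin recover --config synth.json --replicates 200 --seed 7

# ancillary analyses
shelfkin optimum --table table.csv
shelfkin correlate --input data.csv --temp 4
```

Input CSV dialect: UTF-8, comma-separated, header
`indicator,temperature_c,time,time_unit,value` with `time_unit` per row in
`{hours, days}`. Config JSON:

```json
{
  "limits": {"TVB-N": {"value": 35, "side": "upper"}},
  "directions": {"myoglobin": "increasing"},
  "units": {"myoglobin": "mg/g"}
}
```

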