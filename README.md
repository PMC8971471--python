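# safyassim

Wheat growth monitoring and yield estimation by assimilating remotely
sensed leaf area index (LAI) into a light-use-efficiency crop model.

The package provides:

- **`safyassim.safy_core`** — a daily SAFY-style simulator of LAI, dry
  aerial mass (DAM) and grain yield, driven by mean temperature and global
  radiation. Growth is ELUE × temperature stress × absorbed PAR; a
  declining fraction of each biomass increment goes to leaves; senescence
  starts once accumulated thermal time passes a threshold; yield is a
  harvest-index fraction of peak biomass.
- **`safyassim.veg_inversion`** — six vegetation indices (EVI, EVI2, MSR,
  NDVI, OSAVI, RVI) from band reflectance, univariate LAI inversion models
  (linear / power / exponential), a NIPALS partial-least-squares
  regression, and a seeded ⅔/⅓ split-sample evaluation.
- **`safyassim.spuci`** — a shuffled-complex-evolution global optimizer
  with PCA dimension monitoring, simplex (reflection / contraction /
  mutation) complex evolution and multivariate-normal resampling.
- **`safyassim.assimilation`** — per-plot estimation of the three
  sensitive parameters (emergence day D0, effective light-use efficiency
  ELUE, senescence temperature threshold STT) by minimizing the RMS LAI
  misfit with the optimizer; partition-coefficient calibration; experiment
  runner with R²/RMSE/nRMSE evaluation.
- **`safyassim.synthetic_data`** — deterministic synthetic field trials
  (48 plots: 2 varieties × 4 nitrogen × 3 water × 2 replicates, 7
  acquisition dates, 6 sampling stages) with known ground truth, used by
  the test suite in place of undeposited field data.
- **`safyassim.metrics`**, **`safyassim.io`**, **`safyassim.cli`** —
  evaluation statistics with consistency classes, CSV readers/writers and
  the command-line interface.

## CLI

```bash
# generate a synthetic 48-plot trial
safyassim synth --seed 7 --out trial/

# fit vegetation-index inversion models and predict LAI
safyassim invert-lai --reflectance trial/reflectance.csv \
    --lai-obs trial/lai_obs.csv --out inversion/

# one forward simulation
safyassim simulate --weather trial/weather.csv --out traj.csv --elue 2.0 --stt 1000

# per-plot assimilation and evaluation
safyassim assimilate --weather trial/weather.csv --plots trial/plots.csv \
    --lai-obs trial/lai_obs.csv --dam-obs trial/dam_obs.csv --out results/ --seed 1
safyassim evaluate --results results/results.csv --truth trial/truth.csv --out eval.csv
```

All tables are plain CSV; dates are integer day-of-season. Weather CSV
needs `day, rg_mj_m2` plus either `ta_c` or `tmin_c`/`tmax_c` (the daily
mean is the min/max average).

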