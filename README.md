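# biochar-ghg

A greenhouse-gas inventory model for biochar additions to mineral soils.
Given activity data for an application event — biochar mass, feedstock,
production conditions (or direct measurements of organic carbon content and
molar H/C_org), area, nitrogen inputs, mean annual soil temperature and an
accounting timeframe — it computes net avoided GHG in CO2-equivalents:

```
total CO2e = M_bc * F_C * 44/12 * F_perm  +  0.23 * n * GWP_N2O
```

where `F_C` is the organic-carbon fraction of the biochar (dry-matter
basis), `F_perm` the fraction of that carbon still unmineralized after the
chosen timeframe at the chosen soil temperature, and `n` the tier-1 baseline
annual N2O from the amended land (first-year credit only, and only for
application rates above 10 Mg C/ha). CH4 and soil-organic-carbon priming are
explicit zero line items. The method applies to mineral soils only.

## Components

- `biochar_ghg.parameters` — packaged parameter tables (feedstock
  composition, class-level F_C, the 21-cell permanence grid) and constants,
  with validated lookups.
- `biochar_ghg.carbon_fraction` — F_C estimation: measured passthrough,
  class-table lookup (default), or an opt-in continuous regression chain
  (DAF carbon content vs temperature, char yield vs lignin and temperature,
  ash conservation).
- `biochar_ghg.decay` — multi-pool exponential decay: Q10 temperature
  response (`1.1 + 12.0 e^(-0.19 T)`), rate rescaling between soil
  temperatures by integrating the log-sensitivity, nonlinear fitting of
  2/3-pool models to incubation series, calibration of per-class decay
  surfaces to the permanence grid, and synthetic-series generation.
- `biochar_ghg.permanence` — F_perm via the temperature-class
  parameterization (printed cells served verbatim; calibrated surfaces
  off-grid), the H/C_org linear regression, or the conservative
  (low-temperature class) fallback.
- `biochar_ghg.n2o` — tier-1 baseline N2O and the first-year credit.
- `biochar_ghg.inventory` — per-event balance, batch processing of activity
  CSVs, JSON/CSV reports with full parameter provenance.

## CLI

```sh
# carbon fraction from the class table (or --continuous with --temp)
biochar-ghg fc --feedstock "maize stover" --temp 500

# permanence factor (class, H/C, or conservative default)
biochar-ghg permanence --temp-class medium --timeframe 100 --soil-temp 10
biochar-ghg permanence --hc 0.5

# batch inventory from an activity CSV
biochar-ghg inventory --activity activity.csv --config config.yaml --out out/

# decay-model utilities
biochar-ghg simulate-decay --pools pools.json --noise-sd 0.01 --seed 1 --out series.csv
biochar-ghg fit-decay --series series.csv

# dump the packaged feedstock tables
biochar-ghg list-feedstocks
```

The activity CSV columns are `event_id, feedstock, process,
pyrolysis_temp_c, temp_class, measured_fc, measured_hc, mass_mg, area_ha,
soil_temp_c, timeframe_years, n_rate_mg_per_ha, soil_kind` (kg variants are
converted with a warning). Config keys (YAML/JSON): `gwp_n2o` (default 273;
use 298 to reproduce older AR4-based arithmetic), `include_n2o`,
`n2o_reduction`, `round_intermediates`, `display_rounding`, `extrapolate`,
`continuous_fc`, `default_timeframe`, `default_soil_temp`.

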