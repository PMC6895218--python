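# opdpipe

A stereological fecundity pipeline for fish ovaries: from grid-point counts
on histological micrograph fields and oocyte axis measurements to
stage-specific **oocyte packing densities** (oocytes per gram of ovary),
whole-ovary oocyte numbers, size-standardized numbers, spawning-season
phenology and a batch/potential-fecundity report per length class and
season.  A seeded synthetic ovary generator provides exact ground truth for
every estimator, so the whole chain is testable without laboratory data.

## What is implemented

| module | contents |
| --- | --- |
| `opdpipe.synthetic` | seeded oocyte populations with exact per-stage counts and volume fractions; virtual section fields (periodic non-overlap sphere packing, planar cuts); point-grid counting; axis measurements with a shrinkage model; year-spanning fish cohorts with allometric length–weight scaling and three spawning seasons |
| `opdpipe.stereology` | volume fractions by pooled point counts (Delesse), cumulative-mean stabilization diagnostics, shape factors, volume-based diameters, shrinkage correction and correction-model comparison, pilot grid selection |
| `opdpipe.opd_engine` | the log10 packing-density formula (printed and exact constant modes), ovary specific gravity by most-advanced stage, stage density tables and oocyte numbers |
| `opdpipe.standardization` | log-log length–weight power fits, length- and weight-relative oocyte numbers, phase-dependent gonad-weight model and predicted numbers, half-open length classes |
| `opdpipe.dynamics` | spawning fraction, cyclic season calendars with edge-of-season assignment overrides, batch fecundity, potential/accumulated batches, spawning duration, the length-class x season fecundity report |
| `opdpipe.io_tables`, `opdpipe.pipeline`, `opdpipe.cli` | validated CSV schemas, YAML config, full deterministic pipeline runs with manifests, and a `click` CLI |

## CLI

```sh
opdpipe simulate --seed 7 --out data/            # synthetic input tables
opdpipe stereology --grid-counts data/grid_counts.csv \
    --measurements data/measurements.csv --out summary.csv
opdpipe opd --summary summary.csv --females data/females.csv --out densities.csv
opdpipe standardize --densities densities.csv --females data/females.csv --out std.csv
opdpipe dynamics --females data/females.csv --out sf.csv
opdpipe report --no-table no_table.csv --out table1.csv
opdpipe run --seed 7 --out run/                  # everything + manifest
```

`opdpipe run` writes `females.csv`, `grid_counts.csv`, `measurements.csv`,
`stage_densities.csv`, `standardized.csv`, `spawning_fraction.csv`,
`report_table1.csv`, `report_unrounded.csv` and a `manifest.txt` whose
config hash, seed and output digests make reruns byte-reproducible.

## File formats

Comma-separated text with documented headers; missing values are empty
fields; stages and phases are fixed uppercase tokens.

- `females.csv`: `female_id, month, TL_cm, WW_g, EW_g, GW_g, GWf_g, MAT, MAO, POF_present`
- `grid_counts.csv`: `female_id, field_id, component, hits, n_points` (hits per field sum to `n_points`)
- `measurements.csv`: `female_id, stage, L_um, S_um, through_nucleus`

Stage tokens: `PVO1 PVO2 PVO3 PVO4A PVO4B PVO4C CAO EVTO VTO MNO HYO`;
other grid components: `ATR_EA ATR_LA ATR_B POF BLOOD MISSING TISSUE EMPTY
OUTSIDE`.  Phases: `IM DV SC AS RS RT`.

## Notes on defaults

- Shrinkage correction defaults to identity **with a warning**: the
  published correction coefficients for resin- and paraffin-embedded tissue
  are not reproduced here and must be supplied by the user
  (`ShrinkageModel("multiplicative", (factor,))`).
- The formula's additive constant defaults to the printed two-decimal value
  (12.28); `constant_mode="exact"` uses `12 + log10(6/pi)` and is what the
  closed-form oracles assert against.
- The three-season calendar (Dec–May, Jun–Aug, Sep–Nov) and the synthetic
  stage geometry/density tables are declared, configurable defaults.
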