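# planperturb

Beam-model sensitivity analysis for IMRT/VMAT treatment plans.

`planperturb` generates seeded synthetic plan cohorts, perturbs ten
treatment-planning-system beam-model parameters at community percentile
values, computes dose-proxy deviations in target/organ regions through a 2D
aperture-fluence surrogate, scores every plan with 18 complexity metrics,
and ranks the metrics by how well they predict plan sensitivity to modeling
errors (including derivation of complexity decision thresholds).

## Layout

| subpackage | contents |
| --- | --- |
| `planperturb.machine_plan` | machine geometry, `Plan`/`Beam`/`ControlPoint` domain model, DICOM RT Plan + JSON I/O, validation |
| `planperturb.synthetic_cohort` | analytic fixtures (static field, sliding window), seeded plan/cohort generator, calibration |
| `planperturb.complexity` | the 18 complexity metrics (MU-weighted, beam-averaged) |
| `planperturb.fluence_surrogate` | beam-model parameters, percentile table, fluence grid, ROI derivation, endpoint deviations |
| `planperturb.study` | perturbation grid, deviation summaries, parameter filter, metric regressions, ranking, thresholds |
| `planperturb.cli_reports` | `planperturb` CLI, YAML study configuration, resumable pipeline, figures/tables |

Notes on scope and conventions:

* Leaf tips are x-positions in mm at isocenter; bank A (left) tips never
  pass bank B, so the gap is `bank_b - bank_a`.
* The fluence surrogate is a shared isocenter-plane beam's-eye-view proxy:
  gantry rotation and anatomy are ignored, so only signs, orderings and
  correlation structure — not absolute dose — are meaningful.
* The default percentile table seeds the offset / transmission / tip-width
  rows from published community data (the transmission row is interpreted
  as fractions, 0.7%–2.5%); all other rows are clearly-marked PLACEHOLDER
  values.
* The DICOM layer is a minimal self-contained explicit-VR-little-endian
  codec (no external DICOM dependency); plans also round-trip through a
  documented JSON dialect for text fixtures.

## CLI

```sh
# 25-plan seeded synthetic cohort (5 sites x 5 plans)
planperturb generate --out plans/ --seed 0

# 18 complexity metrics per plan
planperturb metrics --plans plans/ --out metrics.csv

# one perturbation: deviations per plan/endpoint
planperturb simulate --plans plans/ --param mlc_offset --pct 97.5 --out dev.csv

# full study pipeline (generate -> metrics -> simulate -> study), resumable
planperturb study --out results/ --seed 0

# figures + CSV twins from a completed study directory
planperturb report --results results/

# everything, including figures
planperturb run-all --out results/ --seed 0
```

`planperturb study` writes `metrics.csv`, `deviations.csv`,
`deviation_summary.csv`, `deviation_summary_by_site.csv`,
`regressions.csv`, `ranking.csv`, `thresholds.csv` and a `study.log`
recording the master seed and config hash. A YAML config (see
`planperturb.cli_reports.config`) can pin the cohort spec, percentile
table, parameter/percentile grid, grid resolution and binary-fluence mode.

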