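# File formats

All artifacts are plain text (CSV, YAML, JSON, markdown). Units: mm for
lengths and displacements, Hz for frequencies, cm³ for volumes.

## Recording bundle (one directory per breast × run)

| file | columns / keys |
|---|---|
| `metadata.yaml` | `breast_id`, `side` (left/right), `label` (healthy/cancerous), `input_frequency_hz`, `sampling_rate_hz`, `n_points`, `n_samples` |
| `points.csv` | `point_id`, `x_mm`, `y_mm`, `z_mm` — rest positions; z = 0 at the chest-wall rim, z max at the apex |
| `displacements.csv` | `point_id`, `t_index`, `dx_mm`, `dy_mm`, `dz_mm` — long format, every point carries exactly `n_samples` rows |

Readers validate key presence, numeric types, point-id agreement between the
two CSVs, and equal series lengths; violations are hard errors naming the
offending ids.

## Cohort manifest (`manifest.csv`)

`breast_id`, `side`, `label`, `tumor_clock` (hours, 12 = superior),
`tumor_diameter_mm`, `tumor_depth_mm`, `volume_cm3`, `stiffness_ratio`
(tumour/healthy; 1.0 for healthy breasts). Tumour fields are empty for
healthy breasts.

## Frequency-of-interest table (`foi.csv`)

`point_id`, `status` (retained/excluded), `branch`
(second_dominant/irregular_dominant, empty when excluded), `foi_hz`,
`dominant_hz`, `dominant_mag`, `second_hz`, `second_mag`, `degenerate`.
The optional frequency map export has `point_id, x, y, z, foi_hz` for
external 3-D viewers.

## Segment table (`segments.csv`, long format)

`breast_id`, (`run_hz` for per-run tables), `radial` (0–3; quadrants centred
on 12/3/6/9 o'clock, side-mirrored), `zband` (0–3, 0 nearest the chest
wall), `mean_foi_hz` (empty when the segment holds no retained point),
`count`.

## Diagnosis (`diagnosis.csv`)

`breast_id`, `configuration` (or comma-joined list when OR-combined),
`tolerance`, `positive` (True/False, empty when indeterminate), `label`
(when known).

## Evaluation

* `roc_points.csv`: `configuration`, `trial`, `tolerance`, `fpr`, `tpr`
  (empty rate when a bootstrap resample lacked the class).
* `fits.json`: per configuration — `a`, `auc`, `n_points`, operating-point
  percentages, and the three criteria flags.
* `report.md`: the per-configuration summary table (AUC, optimal
  sensitivity/specificity, the two 80% criteria columns) plus exclusion
  counts.

## Pipeline configuration

`PipelineConfig.to_yaml`/`from_yaml` round-trips every threshold and cohort
setting; see `dietfreq/config.py` for the full field list and defaults.
Configuration presets can be overridden by a YAML mapping
`{id: [c0, c1, c2, c3]}` giving each band's control quadrant.
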