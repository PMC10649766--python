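# File formats

All files are plain text: CSV (RFC-4180, header required) for tables,
JSON for model artifacts, INI-style key/value files for cohort specs.
Floats are written with round-trip precision (`repr`), and the readers
parse them with Python's `float()`, so write→read is lossless.

## Patient table (CSV)

Columns, in order:

| column | units | notes |
|---|---|---|
| `patient_id` | — | opaque label |
| `age` | yr | > 0 |
| `kvp` | kVp | tube voltage |
| `bsa` | m² | body surface area |
| `hr` | /min | heart rate |
| `co` | L/min | cardiac output |
| `cm` | c.c. | injected contrast volume; may be blank (unknown dose) |
| `dtt` | s | trigger delay |
| `cta_la` | CT number | observed CTA number of the LA; may be blank |

Rows failing validation are reported with their line numbers.

## Model artifact (JSON)

```json
{
 "term_labels": ["A", "B", ..., "FxG", "Constant"],
 "coefficients": [ ...29 floats... ],
 "bounds": {"age": [24.0, 90.0], ..., "cta_la_over_400": [0.61, 2.17]},
 "target_cta": 400.0,
 "diagnostics": {"loss_phi": ..., "variance": ..., "r": ..., "n": ..., "rank": ...},
 "metadata": { ... }
}
```

`term_labels` must equal the canonical 29-term order (main effects A–G,
pairwise products AxB … FxG, Constant); files that disagree are rejected,
as are files missing any of the eight bounds entries. `diagnostics` and
`metadata` are optional. The packaged `reference_model.json` carries the
published coefficient set with its derivation-cohort bounds.

## Cohort spec (cfg)

```ini
[cohort]
n = 450
residual_sd = 0.084
kvp_steps = 70 80 100 120 140

[age]
mean = 56
sd = 13.3
min = 24
max = 90
...
```

One section per factor (`age`, `kvp`, `bsa`, `hr`, `co`, `cm`, `dtt`),
each with `mean`, `sd`, `min`, `max` in raw units. `kvp_steps` lists the
discrete tube-voltage settings; omit it for a continuous draw. The
ground-truth coefficients and scaling bounds are not part of the spec
file — they come from a model artifact, so generation and refitting share
one scaling.

## Outputs

- predictions CSV: `patient_id, cta_la, predicted_cta`
- agreement CSV: `patient_id, actual, predicted, at_percent`; agreement
  JSON: `n, at_avg_percent, at_sd_percent, bin_edges_percent, bin_counts`
- dose-plan CSV: `patient_id, cm_min, cm_max, v8_at_cm_min, v8_at_cm_max,
  target_cta, cm_expect, achievable, clipped`
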