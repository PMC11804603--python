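# File formats

All artifacts are plain text. Floats are written with 12 significant
digits (`%.12g`) so regenerated files are byte-identical across
platforms.

## Behavioral data (CSV)

One row per subject × trial, written by `latentsim simulate-behavior`
and `latentsim.io.save_behavior`:

| column         | meaning                                                   |
|----------------|-----------------------------------------------------------|
| `subject`      | subject identifier                                        |
| `trial`        | 1-based trial index                                       |
| `choice`       | chosen option (0 or 1; 0 is the designated option in pavlovian mode) |
| `outcome`      | delivered outcome on the objective scale                  |
| `value_chosen` | value of the chosen option *before* the trial's update    |
| `pe`           | prediction error `gamma*outcome - value_chosen`           |

## BOLD-like time series (TSV + JSON sidecar)

`bold_<subject>.tsv` with columns `time_s` (scan onset, seconds) and
`signal` (dimensionless amplitude). A sidecar `bold_<subject>.tsv.json`
carries the full generating `NeuralConfig` (phi, tr, trial_duration,
event_duration, noise_sd/cnr, HRF parameters) and the realized
`noise_sd_used`. No neuroimaging volume formats are produced.

## Fit and GLM results (JSON)

`fits.json`: input path and content hash, model family, and per-subject
`estimates`, `neg_log_likelihood` (nats), `converged`,
`n_restarts_used`, `non_identified`.

`glm.json`: per-subject `phi_hat`, `se`, `residual_sd`,
`standardize_pe`, `assumed_duration`, and `pe_sd_used` (present iff the
regressor was standardized).

## Scenario summaries (CSV + JSON)

`scenario<N>_<table>.csv` — replicate-level and cell-level tables (cell
tables carry `cell`, `mean`, `sd`, `se`, `n`).
`scenario<N>_summary.json` — scenario id, master seed, scalar `stats`,
and boolean contrast `flags`.

## Configs (YAML) and manifests (JSON)

Configs are flat YAML mappings mirroring the dataclass fields
(`TaskConfig`, `RLParams`, `NeuralConfig`). Every CLI run writes
`manifest.json` with the tool version, command, master seed, config and
its sha256 hash, input/output paths, and a timestamp — enough to
re-execute the run exactly.
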