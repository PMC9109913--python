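# File formats

All artifacts are plain-text CSV (UTF-8); plate configurations may also
be YAML. Well identifiers are normalized on read to a letter plus a
zero-padded two-digit column (`A1` → `A01`).

## Droplet amplitudes

One row per droplet. Default column names follow the QuantaSoft-style
export; they can be remapped with the `columns` argument of
`read_amplitudes`.

| column | meaning |
| --- | --- |
| `Well` | plate-well label (omitted in one-file-per-well layout; pass `well_id=` instead) |
| `Ch1 Amplitude` | FAM fluorescence amplitude (target assay), arbitrary units |
| `Ch2 Amplitude` | HEX fluorescence amplitude (reference assay), arbitrary units |

Locale variants with decimal `","` and separator `";"` are supported via
the `decimal=` and `sep=` arguments.

## Plate configuration (CSV)

One row per well.

| column | meaning |
| --- | --- |
| `well` | plate-well label |
| `sample_id` | sample identifier; may be empty for NTC wells |
| `assay_id` | one of `exon_IV`, `exon_VIII`, `custom` |
| `experiment_id` | groups runs into experiments for replicate analysis |
| `is_ntc` | `true`/`false`; no-template control flag |
| `exclusion_flags` | `;`-separated subset of `wga`, `mosaic`, `other_cnv` |
| `acgh_cn` | optional aCGH-assigned integer CN for concordance |

The YAML form is a mapping of well label to the same fields.

## Cluster counts

`well, n_pp, n_pn, n_np, n_nn` — the four quadrant counts
(FAM±/HEX±); their sum is the accepted droplet count.

## Results table

Written by `write_results`, read back losslessly by `read_results`
(floats stored with full `repr` precision):

`sample_id, assay_id, experiment_id, well_id, n_pp, n_pn, n_np, n_nn,
lambda_target, lambda_ref, ratio, cn_estimate, ci_low, ci_high,
n_total, concentration_target, concentration_ref, exclusion_flags,
acgh_cn, qc_status`

`qc_status` is `pass` or `fail:<reason>` with one primary reason
(`excluded_flag:<flag>`, `min_cluster:<n>`, `total_droplets:<n>`,
`saturation`, `reference_failure`).

## aCGH probes

4 columns — `chrom, start, end, log2` — tab-separated (BED-like) or
CSV; a header row is tolerated. Coordinates are 1-based inclusive by
default; pass `coords="bed"` for 0-based half-open input.
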