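# assayval

Analytical-validation toolkit for quantitative assays: linearity,
within/between-run imprecision, spike-recovery bias, Passing–Bablok and
Bland–Altman inter-laboratory comparison, and observed total analytical
error.

## Who it is for

Clinical-chemistry and veterinary-endocrinology labs validating a
quantitative assay on a new sample matrix — the motivating application is a
chemiluminescent immunoassay for progesterone (P4) in ovine serum, where
the instrument is marketed for human samples and performance in sheep serum
must be established before circulating P4 (the luteal-phase marker,
threshold 1 ng/mL) can be interpreted. The same computations apply to any
replicates-by-days spike panel plus paired two-laboratory data.

## The statistics at its core

Given a spike panel (levels L with nominal concentration `x_L`, replicate ×
day measurements, censoring outside the calibrated range 0.2–40 ng/mL):

- **Imprecision**: within-run CV% from one day's replicates; between-run
  CV% from the SD of the daily means.
- **Linearity**: OLS `y = a + bx` of measured level means on nominal, with
  R² and t-tests; paired-t deviation check.
- **Recovery**: `%R = 100·(x̄_L − L1)/spike` with the matrix floor
  `L1 = 0.1` ng/mL, and spiking-recovery bias `SRB = %R − 100`.
- **Method comparison**: Passing–Bablok slope = K-offset median of all
  pairwise slopes with the 1983 rank CI; CUSUM linearity check against
  Kolmogorov–Smirnov bounds; Spearman ρ; Bland–Altman mean bias with
  limits of agreement `bias ± 1.96·SD` in absolute and percent form.
- **Total observed error**: `TEo(%) = 2·CV% + |bias%|`, with the bias taken
  per level from spike recovery (TEo_SR), from the matching concentration
  group of the inter-lab comparison (TEo_RB), or from the single overall
  inter-lab percent bias (TEo_AB).

A synthetic-data module generates seeded spike panels and paired-lab
datasets with this exact error structure, and `assayval.fixtures` packages
the published per-level values of the ovine P4 validation study the toolkit
reproduces. See `docs/methods.md` for assumptions and limitations.

## Worked example

```bash
assayval simulate panel    --out panel.csv --seed 7
assayval simulate interlab --out pairs.csv --seed 7
assayval precision --panel panel.csv
assayval linearity --panel panel.csv
assayval compare   --pairs pairs.csv
assayval teo       --panel panel.csv --pairs pairs.csv
assayval report    --panel panel.csv --pairs pairs.csv --out report.json
```

With seed 7 the precision table reports `average_within_cv 3.11` and
`average_between_cv 2.42` over the eight quantifiable levels, excluding
`L1` ("matrix blank (nominal 0)") and `L10` ("all measurements censored" —
the 40 ng/mL spike reads above range after the 1.28× over-read, exactly as
in the study). The linearity fit returns slope `1.281`, intercept `-0.044`,
R² `0.9998`: the generator's proportional read-through recovered. The lab
comparison gives a Passing–Bablok slope of `1.143` with 95% CI
`(1.119, 1.165)` — excluding 1, so proportional bias between the
instruments is flagged — and a Bland–Altman mean percent bias of `25.3%`.
The total-error table combines these: column averages
`TEo_SR 31.3`, `TEo_RB 27.3`, `TEo_AB 31.5` percent, e.g. the 0.5 ng/mL
row reads `teo_sr 31.7, teo_rb 66.0, teo_ab 37.7` (low concentrations
carry the largest range-based error, as in the study).

The same functions are importable directly
(`from assayval import precision_table, passing_bablok, ...`), operating on
`SpikePanel` / `PairedMeasurements` objects built from CSV
(`assayval.io.read_panel`, `read_pairs`) or generated in memory.

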