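# Methods

`assayval` implements the analytical-validation computation used to qualify a
quantitative assay over its reportable range, in the form applied to a
chemiluminescent immunoassay for progesterone (P4) in ovine serum: linearity,
within/between-run imprecision, spike-recovery accuracy, inter-laboratory
method comparison, and three decompositions of observed total analytical
error. This note records the models, the parameter choices, and the places
where the design was genuinely open.

## Study design the toolkit assumes

A *spike panel*: analyte-free pooled serum (the matrix) spiked to a ladder of
nominal concentrations — by default 0, 0.5, 1, 2, 5, 10, 15, 20, 30 and
40 ng/mL, labelled L1–L10 — each measured in 5 replicates per day over 5
consecutive days. The instrument's calibrated range is 0.2–40 ng/mL; readings
outside it arrive as "<0.2" / ">40" and are carried as censored values
holding the limit. Censored values are excluded with a logged count, never
imputed; a level that is entirely censored (in this design the blank, which
reads below range, and the 40 ng/mL spike, which reads above range after the
assay's proportional over-read) is dropped from every table with its reason
recorded. All summary averages therefore run over the 8 quantifiable levels.

A *paired comparison set*: the same samples measured on the in-house
instrument (lab1) and by an external reference laboratory (lab2), all values
quantified and positive.

## Statistics

**Imprecision.** Within-run (repeatability) is the sample SD and CV%
(100·sd/mean, n−1 denominator) of one day's replicates — day 1 by default,
matching the reportable-range design; configurable. Between-run
(reproducibility) is the SD/CV% *of the daily replicate means*. This is the
literal run-to-run spread of per-run averages, not a nested-ANOVA variance
component; the two coincide only when within-run noise is negligible
relative to the day effect (a dedicated property test checks the opposite
limit: with no day effect, between-run CV ≈ within-run CV/√replicates). Daily
quality control passes when each QC level's triplicate CV% is strictly below
10%.

**Linearity.** OLS of measured level means on nominal concentrations
(`y = a + bx`), R² as squared Pearson correlation, two-sided t-tests of
slope ≠ 0 and intercept ≠ 0. A paired t-test on (measured − nominal) gives a
rough overall deviation check. Both can run on level means (8 points,
default) or on individual replicates (40 points, `--replicates`): the means
mode reproduces the published slope 1.28 / R² 0.99, but its deviation test
is underpowered (p ≈ 0.06 on the 8 rounded means) — the published
significance of the deviation requires replicate-level data. Identical
columns are a well-defined null (t = 0, p = 1); constant non-zero
differences leave t undefined and raise an error.

**Spike recovery.** %R = 100·(level mean − matrix floor)/spike and
SRB = %R − 100, signed; the absolute value enters total error only. The
matrix floor defaults to 0.1 ng/mL — a nominal stand-in for endogenous
analyte in the blank pool, whose own reading is below the quantification
limit. Since the floor appears in both the generated signal and the
recovery formula, it cancels: a proportional read-through of ×m yields
SRB = 100·(m − 1) at every level.

**Passing–Bablok regression.** All pairwise slopes S_ij = (y_j − y_i)/(x_j −
x_i), i < j; two-way ties contribute nothing; tied x with differing y enter
as signed infinities; slopes exactly −1 are discarded. The estimate is the
median of the sorted slopes offset by K = #{S < −1}, which makes the
estimator symmetric in the axes. The 95% CI is the original
normal-approximation rank method: C = 1.96·√(n(n−1)(2n+5)/18) ranks either
side of the median (the choice MedCalc defaults to; no bootstrap CI). The
intercept is median(y − b·x), its CI evaluated at the slope CI endpoints.
Proportional/constant bias is flagged when the slope/intercept CI excludes
1/0. In `compare_labs` the in-house instrument is regressed on the external
laboratory (comparator on x, the method-comparison convention); a
`direction` switch swaps the axes.

*Known limitation, quantified by the test suite:* the analytic rank CI
assumes homoscedastic errors. Under constant-CV (proportional) measurement
error spread over the full reportable range — the realistic immunoassay
regime and the synthetic generator's model — the slope CI undercovers
(≈86% rather than 95% in seeded simulations at n = 200, CV 3%), while the
point estimator remains unbiased. Under additive error the same CI covers
at its nominal rate. Users comparing heteroscedastic data should treat the
analytic CI as optimistic, or log-transform before fitting.

**CUSUM linearity check.** Each point scores ±1 by its side of the fitted
line (0 when exactly on it), points are ordered by their projection along
the line, and the score path is cumulated. Curvature produces long
same-sign runs and a large excursion; max|cusum| normalised by
√(n⁺n⁻/(n⁺+n⁻)) is compared against Kolmogorov–Smirnov critical values
(1.22/1.36/1.48/1.63 at α = 0.10/0.05/0.025/0.01), so the p-value is
reported as a tabulated bound, not a continuous number. An all-on-line
configuration is flagged as trivially non-rejecting.

**Bland–Altman.** Differences d = lab1 − lab2 (in-house minus external, so
an external lab reading low gives positive bias); mean bias, SD, limits of
agreement mean ± 1.96·SD, t-based CI of the mean bias; a percent variant
divides by the pair mean; proportional error is the OLS slope of d on the
pair mean with its p-value. Spearman rank correlation (tie-aware, Fisher
transform CI with SE √(1.06/(n−3))) summarises monotone agreement.

**Total observed error.** Bias(%) = 100·(target − measured)/target, signed.
TEo(%) = 2·CV% + |bias%| with the within-run CV of each spike level and one
of three bias sources: per-level spiking-recovery bias (TEo_SR); range-based
inter-lab bias (TEo_RB), where the comparison samples are sorted by in-house
concentration, split into 5 equal-size groups (the design names the count
but no boundaries; equal-occupancy bins are the assumption-free choice),
each group carrying the mean Bland–Altman percent difference of its members,
and each spike level mapping to the group whose concentration interval
contains it (extremes clamped, gaps to the nearer interval); and the single
overall Bland–Altman percent bias applied to every level (TEo_AB). The
defining signature of the average-bias variant — TEo_AB − 2·CV identical
across levels — is asserted on the published table.

## Synthetic data generator

Spike panels: measurement = (floor + m·nominal)·(1 + δ)·(1 + ε) with
recovery multiplier m (default 1.28, the published proportional over-read),
per-(level, day) run effect δ ~ N(0, 2%) (chosen so between-run CV lands in
the published 2–8% band, close to within-run as observed), and replicate
noise ε ~ N(0, CV_level) with the published within-run CV profile as the
default (edge levels borrow their neighbour's CV). Noise is multiplicative —
constant CV — because the published CV column is roughly level-independent.
Values outside 0.2–40 ng/mL are emitted censored, which reproduces the
blank's below-range and the top spike's above-range behaviour by
construction. Paired labs: true concentrations log-uniform over
0.22–30 ng/mL (dense at the low, clinically relevant end, matching the
study-sample spread), lab1 = truth·(1 + ε₁), lab2 = (truth −
intercept)/slope·(1 + ε₂) with independent per-lab noise (deriving lab2
from the *noisy* lab1 would correlate the labs' errors and bias the
comparison — simulations showed a +0.3% slope bias and coverage loss) and
defaults slope 1.14, intercept 0.1 ng/mL, CV 3%, n = 39. Identical seeds
give byte-identical CSV output.

What the generator does *not* emulate: cross-reactivity (e.g. DHEA),
lot-to-lot drift, freeze–thaw degradation, carry-over, and non-Gaussian
error tails. Passing tests on synthetic data therefore demonstrate
estimator correctness under the stated error model, not robustness to those
real-data phenomena.

## Published-value fixtures and the reconstructed panel

The packaged fixtures carry the study's printed per-level values (measured
means, CV columns, SRB list, TEo columns, column averages), the in-house
concentrations of the 30 comparison study samples, and the QC level means.
The raw replicate readings were never published, so
`fixtures.reconstruct_panel()` builds a synthetic stand-in: five replicates
per day placed deterministically so that each level's day-1 mean, within-run
CV and between-run CV equal the printed values to machine precision.
Running the full pipeline on it regenerates the published precision columns
and averages exactly, the linearity slope 1.284/R² 0.996, and the SRB
values at the levels where the printed means carry enough precision (10,
15, 20 ng/mL exactly; the low levels were evidently computed from unrounded
means — 0.5 ng/mL gives 40 from the rounded mean vs the published 38 — so
the printed SRB list itself is the bias input for total-error work). The
inter-laboratory raw data of the external laboratory were likewise never
published; those results are covered by oracle equivalence and synthetic
parameter recovery rather than numeric reproduction.

## Numerical conventions

Concentrations in ng/mL throughout; no unit layer. Full precision
internally; rounding only at presentation (CSV report, one decimal).
Sample (n−1) SD everywhere. Strict inequality in the QC gate. CV undefined
at non-positive means (error, not NaN). Problem sizes in simulations —
replicate counts of a few hundred for parameter-recovery checks, 100–500
seeded replications for coverage characterisation, n = 4000–5000 for
limits-of-agreement coverage — were chosen so Monte-Carlo error sits well
inside the asserted tolerances; tolerances themselves are set from the
analytic sampling SD of the quantity under test (typically 3σ).
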