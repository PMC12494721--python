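# Methods

## Data model

All stages operate on tidy long-format tables: one row per measured well
(growth) or per well × metabolite (metabolomics). Batch identity and the
acquisition index — the position of an injection in its batch's
measurement order — are carried on every row because the drift correction
is a function of acquisition order; a plate-matrix importer would lose it.
Sample roles distinguish compound-treated wells, DMSO solvent controls
(10–13 per 96-well plate), the single tetracycline control per plate, and
the blank/QC/standard injections interleaved in the acquisition sequence
(one blank + QC block after every 12 culture samples, a six-level standard
series at batch start). Validation reports violations of the plate-control
structure but never mutates data.

## Growth analysis

Raw 595 nm absorbance → OD: `od = max(0, raw − blank − background) × 5`.
The multiplier converts plate-reader absorbance to conventional OD units;
the clip at zero removes slightly negative readings from fully inhibited
wells. The optional per-compound background column accounts for coloured
compounds that absorb at 595 nm; absent, it defaults to 0 with a logged
notice. The blank is taken per plate, falling back to a per-run value when
a plate column is missing.

Growth fold change divides each well's OD by the linear-interpolation
median OD of the plate's DMSO controls. Fold changes **strictly above
1.5** are set to missing: growth cannot plausibly rise that far over the
solvent control, and such values arise from cell aggregation that confounds
the OD readout (most prominently in *R. gnavus*). Missing fold changes are
serialised as empty fields, never sentinels.

## Drift correction

Within each batch × species × metabolite group: values flagged by the
standard boxplot fences (beyond Q1 − 1.5·IQR or Q3 + 1.5·IQR, quartiles by
linear interpolation) and all non-culture injections are excluded, and a
trend over acquisition index is fit with scikit-learn's
`RadiusNeighborsRegressor` — the unweighted mean of included values within
the radius (20 index units by default, 30 for dose–response batches, where
effects spread across plates make a smoother trend appropriate). Positions
with an empty neighbourhood inherit the nearest defined trend value; this
fallback is our choice for isolated samples. Each value is corrected by
its ratio to the trend and rescaled by the screen-wide median raw
concentration of that species × metabolite so corrected values remain in
absolute µM; the screen median is computed over compound-treated samples
only (controls excluded; configurable). Corrected concentrations are
floored at 0.01 µM. Fitting per metabolite (not jointly) is forced by the
orders-of-magnitude differences between metabolite baselines.

## Hit calling

Per plate × metabolite, the z-score is the difference between a well's
corrected concentration and the plate reference median, divided by the
**sample** (n−1) standard deviation of the plate's DMSO controls; plates
with fewer than three finite DMSO values, or zero DMSO SD, are flagged and
yield missing statistics. Two reference modes exist: the plate-wide median
(default) and the DMSO-control median. For the large screen the two nearly
coincide (a few treated wells barely move a 96-well median); for small
dose–response panels the plate-wide median is dominated by the treated
wells themselves, so the dose pipeline defaults to the DMSO median.

P-values are the two-sided normal survival function of the z-score
(one-sided upper is available by config) and are BH-adjusted within
species × metabolite, separately per replicate. The hit rule — adjusted
p < 0.05 in both replicates, consistent direction, |mean log2 FC| > 0.32 —
composes two independent significance requirements with an effect-size
floor, which is what controls the final false-call rate (see *Calibration*
below).

Concordance compares the mean growth fold change with the mean metabolite
fold change on the **linear** scale (the threshold, 0.25, is stated as a
raw fold-change difference) with a strict `<`; a 0.25 difference is
non-concordant. When growth is missing (artifact-filtered in both
replicates) the concordance label is missing, not false.

## Downstream summaries

Class enrichment builds the 2×2 table (class membership × hit status) over
the full tested library and applies the two-sided Fisher exact test, with
BH adjustment across classes within each stratum (species × metabolite ×
direction × concordance, or pooled). "Positively enriched" means the
class's hit frequency exceeds the background frequency; the direction
filter is applied after testing. Fisher p-values are discrete, hence
conservative under permutation — the calibration test checks validity
(rejection ≤ nominal level), not exact uniformity.

Hit rate per class counts compounds active against ≥1 species ×
metabolite pair. Cross-species correlation is the Pearson coefficient over
pairwise-complete per-compound mean log2 fold changes (≥3 pairs required).
Dose–response "stimulated" means dual-replicate adjusted p < 0.05 with
mean fold change > 1 (the fold-change floor is optional by config); the
fractions are taken over compounds tested at every dose, and a compound is
"monotone" when |mean log2 FC| is non-decreasing in dose. The monotone flag
is descriptive and noise-sensitive at low doses, where true effects are
smaller than measurement noise; the noise-free tests pin down its logic.

QC metrics: per plate × metabolite CV (sample SD / mean) of corrected
DMSO concentrations, and per species × metabolite Pearson correlation of
per-compound corrected concentrations between the two replicates, each
summarised by its median.

## Synthetic screens

The generator's defaults are the study conditions: 1772 compounds (1518
drugs, 166 pesticides, 47 industrial chemicals, 41 sweeteners), four
species with their amine panels, two biological replicates acquired in
separate batches, plates with 10–13 DMSO controls and one tetracycline
well, measurement noise at 9.4% CV, an OD-artifact rate of 7.7%, baseline
concentrations log-uniform between 35 and 1100 µM, and blocks of 12
culture samples interleaved with blank/QC injections.

Observed concentration = baseline · 2^(true log2 FC) · plate effect ·
drift(acquisition index) · mean-one lognormal noise. Choices the source
data do not pin down, made once: drift is a smooth random curve (two
random-phase low-frequency sinusoids plus a ramp) rescaled to a maximum
deviation of 0.2 and exact mean 1 — the ratio correction assumes only
smoothness and multiplicativity; noise is lognormal because concentrations
are positive and the empirical scatter is reported as a CV; plate effects
are lognormal with σ = 0.1; growth noise has 5% CV. Five percent of
compounds are active; an active compound perturbs one randomly chosen
metabolite per species with |log2 FC| drawn from U(0.5, 2) (a fixed
magnitude of 1.0 in the recovery benchmarks), a simplification that trades
the observed species-specificity of real hits for a larger per-species
truth set. With probability 0.66 the compound's growth response equals its
metabolite fold change, capped at 1.4 — growth cannot double the way a
metabolite concentration can, and values above 1.5 would be removed as
artifacts — otherwise growth is unaffected (decoupled). Active compounds
are drawn with a 3× weight on antibacterial-annotated drugs so enrichment
analyses have signal. Artifact wells replace the growth observation with a
uniform fold change in (1.6, 3) without touching metabolite values.

What the generator does **not** emulate: chromatography and calibration
(concentrations are emitted directly), correlated metabolite panels within
a species, compound-specific assay interference beyond the OD background
column, batch-to-batch baseline shifts beyond the drift curve, and
dose-dependent toxicity beyond a linear growth decline in the dose module.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated noise model, not robustness to every failure
mode of real LC-MS screens.

## Calibration of the plate z-test

The z-statistic's denominator is estimated from 10–13 DMSO wells, but
p-values use the normal survival function, so under the null the statistic
is approximately t-distributed with ~10 degrees of freedom: its true
per-test rejection rate at nominal p < 0.05 is ≈ 0.075, not 0.05. This is
a property of the method, faithfully implemented, and the acceptance test
that asserts a 0.05 rate documents it by failing. The screen's error
control does not rest on the per-test level: requiring BH-adjusted
significance in **two** independent replicates plus a 0.32 |log2 FC| floor
(≈ 2.8 noise SDs at 9.4% CV) drives the realised null hit rate to ≈ 0
(measured < 10⁻⁴), and the realised false-discovery proportion among calls
in the spike-in benchmark stays well under 0.10.

## Benchmark problem sizes

The study-scale benchmarks simulate the full design — 1772 compounds × 4
species × 2 replicates ≈ 28,000 tests per screen — which the pipeline
processes in a few seconds; the spike-in recovery averages five seeded
screens. Unit tests use 90–150-compound screens with the same structure.
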