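# aminescreen

Analysis pipeline for high-throughput plate screens that measure how
xenobiotics — therapeutic drugs, pesticides, industrial chemicals and
sweeteners — change the **biogenic-amine output of gut bacteria**. Four
amine producers motivate the defaults: *Escherichia coli* and *Klebsiella
aerogenes* (polyamines, histamine) and *Clostridium sporogenes* and
*Ruminococcus gnavus* (tryptamine, 2-phenylethylamine). Each compound is
applied at 20 µM to cultures in 96-well plates carrying 10–13 DMSO control
wells and one tetracycline control; growth is read as endpoint 595 nm
absorbance and amine concentrations are measured by targeted LC-MS in
large acquisition batches.

The package is for screen analysts: it takes long-format concentration and
absorbance tables and produces drift-corrected concentrations, plate-matched
hit calls with growth-concordance classes, therapeutic-class enrichments,
dose–response summaries and QC metrics. A synthetic screen generator with
full ground truth makes every stage testable without any instrument data.

## The statistics at the core

**Drift correction** (per batch × species × metabolite): a trend line is
fit to the culture samples over acquisition order — boxplot outliers
(outside Q1 − 1.5·IQR, Q3 + 1.5·IQR) and blank/QC/standard injections
excluded — as a radius-neighbour local regression (unweighted mean within
radius 20 acquisition positions; 30 for dose–response batches). Each
measurement is corrected by its ratio to the trend, rescaled to the
screen-wide median concentration, and floored at 0.01 µM:

    corrected_i = (x_i / trend_i) · median_screen,  clipped at 0.01 µM

**Hit calling** (per well, against its own 96-well plate):

    z = (corrected − plate median) / sd(DMSO controls on the plate)

Two-sided p-values come from the normal survival function, p = 2·Φ̄(|z|),
and are Benjamini–Hochberg adjusted within each species × metabolite,
separately per biological replicate. A compound × species × metabolite
triple is a **hit** when p_adj < 0.05 in both replicates, both replicates
change in the same direction, and |mean log2 fold change| > 0.32 (fold
change outside ≈ 0.8–1.25). A hit is **growth-concordant** when
|mean growth FC − mean metabolite FC| < 0.25 on the linear scale.

**Growth**: OD = max(0, absorbance − blank − compound background) × 5,
fold changes relative to the plate's DMSO median; fold changes above 1.5
are cell-aggregation artifacts and set to missing.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
screen (1772 compounds × 4 species × 2 replicates):

```bash
python analysis/01_simulate_screen.py --seed 1
python analysis/02_normalise_and_growth.py
python analysis/03_call_hits.py
```

which prints (seed 1):

```
drift correction and growth analysis:
  DMSO CV lowered by correction in 100.0% of 32 batch x metabolite units
  median corrected DMSO CV: 9.1%
  median replicate correlation r: 0.81
  growth artifact filter removed 7.8% of experimental wells
hit calling:
  338 hit triples out of 14176 tested (91 active compounds)
  growth-concordant hits: 37% (of 333 with growth data)
  recovery vs ground truth: sensitivity 0.944, false-discovery proportion 0.006
```

The drift correction brings the DMSO coefficient of variation back down to
the generator's 9.4% noise floor in every batch; the dual-replicate hit
rule recovers 94% of the spiked effects while mis-calling fewer than 1% of
its hits. `analysis/04_enrichment_and_correlation.py` adds class
enrichments and cross-species response correlations, and
`analysis/05_dose_response.py` runs a six-dose panel and flags
non-monotonic responders. The same stages are available as a CLI
(`aminescreen simulate|normalise|call-hits|enrich|dose|qc`) and as library
functions (`aminescreen.run_screen`, `aminescreen.run_dose_screen`).

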