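"""Study-scale benchmark experiments on synthetic screens.

These routines run the full pipeline on screens generated at the study's
conditions (1772 compounds, four species, two biological replicates, 9.4%
measurement CV, drift amplitude 0.2, 7.7% OD artifact rate) and measure the
pipeline's operating characteristics against the generator's ground truth:

* null calibration — per-test rejection rate and dual-replicate hit rate
  on a screen with zero true effects;
* drift benefit — how often the drift correction lowers the CV of the
  plate-matched DMSO controls within a batch;
* spike-in recovery — sensitivity and realised false-discovery proportion
  when 5% of compounds carry a |log2 fold change| of 1.0;
* noise-free concordance — agreement of growth-concordance labels with
  ground truth in the absence of noise;
* QC metrics of the corrected screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ScreenConfig
from .downstream import qc_metrics
from .pipeline import run_screen
from .simulate import SimulationScenario, generate_screen


def null_calibration(seed: int, scenario: SimulationScenario | None = None) -> dict:
    """Zero-effect screen: rejection rate, hit rate, drift benefit, QC."""
    scenario = scenario or SimulationScenario(fraction_hits=0.0, rng_seed=seed)
    measurements, growth, _, _ = generate_screen(scenario, seed=seed)
    result = run_screen(measurements, growth)
    stats = result["stats"]
    exp = stats[(stats["role"] == "experimental") & stats["p"].notna()]
    hits = result["hits"]
    corrected = result["corrected"]
    drift = drift_benefit(corrected)
    qc = qc_metrics(corrected)
    gexp = result["growth"][result["growth"]["role"] == "experimental"]
    return {
        "growth_artifact_fraction": float(gexp["growth_fc"].isna().mean()),
        "n_growth_wells": int(len(gexp)),
        "rejection_rate": float((exp["p"] < 0.05).mean()),
        "n_tests": int(len(exp)),
        "hit_rate": float(hits["is_hit"].mean()),
        "n_triples": int(len(hits)),
        "drift_benefit_fraction": drift["fraction_improved"],
        "n_batch_units": drift["n_units"],
        "median_dmso_cv": qc["median_dmso_cv"],
        "median_replicate_r": qc["median_replicate_r"],
    }


def drift_benefit(corrected: pd.DataFrame) -> dict:
    """Per batch x species x metabolite: does correction lower the DMSO CV?

    Compares the coefficient of variation of the DMSO-control concentrations
    across each batch before (raw) and after (corrected) drift correction.
    """
    dmso = corrected[
        (corrected["role"] == "dmso_control") & corrected["corrected_conc_uM"].notna()
    ]
    improved = 0
    n_units = 0
    for _, sub in dmso.groupby(["batch_id", "species", "metabolite"], observed=True):
        raw = sub["raw_conc_uM"].to_numpy(dtype=float)
        cor = sub["corrected_conc_uM"].to_numpy(dtype=float)
        if len(raw) < 3:
            continue
        cv_raw = raw.std(ddof=1) / raw.mean()
        cv_cor = cor.std(ddof=1) / cor.mean()
        n_units += 1
        improved += int(cv_cor < cv_raw)
    return {
        "fraction_improved": improved / n_units if n_units else float("nan"),
        "n_units": n_units,
    }


def spike_scenario(seed: int, noise_free: bool = False) -> SimulationScenario:
    """Study-condition scenario with 5% of compounds spiked at |log2 FC| = 1."""
    kwargs = dict(
        fraction_hits=0.05,
        effect_log2_min=1.0,
        effect_log2_max=1.0,
        rng_seed=seed,
    )
    if noise_free:
        kwargs.update(
            noise_cv=0.0, growth_noise_cv=0.0, drift_amplitude=0.0, artifact_rate=0.0
        )
    return SimulationScenario(**kwargs)


def spike_recovery(seeds, config: ScreenConfig | None = None) -> dict:
    """Sensitivity and realised false-discovery proportion over seeds."""
    sens, fdps = [], []
    n_spiked = n_called = 0
    for seed in seeds:
        scenario = spike_scenario(int(seed))
        measurements, growth, _, truth = generate_screen(scenario)
        hits = run_screen(measurements, growth, config)["hits"]
        key = ["compound_id", "species", "metabolite"]
        merged = hits.merge(truth.effects[key + ["is_spiked"]], on=key, how="left")
        spiked = merged[merged["is_spiked"]]
        called = merged[merged["is_hit"]]
        sens.append(float(spiked["is_hit"].mean()))
        fdps.append(float((~called["is_spiked"]).mean()) if len(called) else 0.0)
        n_spiked += int(len(spiked))
        n_called += int(len(called))
    return {
        "sensitivity": float(np.mean(sens)),
        "false_discovery_proportion": float(np.mean(fdps)),
        "per_seed_sensitivity": sens,
        "per_seed_fdp": fdps,
        "n_spiked": n_spiked,
        "n_called": n_called,
    }


def noise_free_concordance(seed: int) -> dict:
    """Agreement of concordance labels with ground truth, noise-free.

    Ground truth per spiked triple: concordant iff
    ``|true_growth_fc - 2**true_log2_fc| < 0.25``.
    """
    scenario = spike_scenario(seed, noise_free=True)
    measurements, growth, _, truth = generate_screen(scenario)
    hits = run_screen(measurements, growth)["hits"]
    key = ["compound_id", "species", "metabolite"]
    spiked = truth.effects[truth.effects["is_spiked"]]
    merged = spiked.merge(hits, on=key)
    truth_label = (
        np.abs(merged["true_growth_fc"] - 2.0 ** merged["true_log2_fc"]) < 0.25
    )
    observed = merged["concordant"]
    comparable = observed.notna()
    match = (observed[comparable].astype(bool).to_numpy() == truth_label[comparable].to_numpy())
    return {
        "match_fraction": float(match.mean()) if comparable.any() else float("nan"),
        "n_compared": int(comparable.sum()),
        "n_spiked": int(len(merged)),
    }
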