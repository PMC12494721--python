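"""Synthetic multi-batch plate screens with known ground truth.

The generator emulates the structure of a targeted-metabolomics xenobiotic
screen against amine-producing gut bacteria: a compound library laid out on
96-well plates with 10-13 DMSO control wells and one tetracycline control
per plate, two biological replicates acquired on separate simulated days,
acquisition sequences in which blocks of 12 culture samples are interleaved
with blank and QC injections (calibration standards open each batch),
smooth multiplicative signal drift along acquisition order, lognormal
per-plate effects and lognormal measurement noise, spike-in compound
effects on metabolite output and growth, and rare OD-aggregation artifacts
that inflate the growth readout without touching metabolite values.

Observed concentration model, per culture well and metabolite::

    conc = baseline(species, metabolite)
           * 2 ** true_log2_fc
           * plate_effect
           * drift(acquisition_index)
           * lognormal_noise(cv)

The noise is mean-one lognormal; with ``noise_cv = 0`` and a flat drift the
model is exact, which the noise-free tests exploit. Ground truth (true
effect sizes per triple, true growth fold changes, drift curves, plate
effects, baselines) is returned alongside the data so recovery is always
measured against the generating truth, never re-derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SPECIES_METABOLITES: dict[str, tuple[str, ...]] = {
    "Escherichia coli": ("putrescine", "cadaverine"),
    "Klebsiella aerogenes": ("histamine", "putrescine", "cadaverine"),
    "Clostridium sporogenes": ("tryptamine",),
    "Ruminococcus gnavus": ("tryptamine", "2-phenylethylamine"),
}

#: library composition of the screened chemical collection
LIBRARY_COMPOSITION = {"drug": 1518, "pesticide": 166, "industrial": 47, "sweetener": 41}

THERAPEUTIC_LABELS = (
    "antibacterial",
    "antifungal",
    "antipsychotic",
    "antihistamine",
    "antiinflammatory",
    "antihypertensive",
    "antineoplastic",
    "analgesic",
)

ANTIBIOTIC_CLASSES = (
    "beta-lactam",
    "fluoroquinolone",
    "macrolide",
    "tetracycline",
    "aminoglycoside",
)

WELLS_96 = tuple(f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13))


class SizingError(ValueError):
    """The compound set does not fit the requested plate layout."""


@dataclass
class SimulationScenario:
    """Parameters of a simulated screen.

    Defaults reproduce the study conditions: 1772 compounds across four
    library classes, four species with their amine panels, two biological
    replicates, measurement noise at 9.4% CV, drift amplitude 0.2, an OD
    artifact rate of 7.7%, a 5% active-compound fraction and a 66%
    probability that an active compound's growth response tracks its
    metabolite response (growth concordance).
    """

    n_compounds: int = 1772
    species_metabolites: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_METABOLITES)
    )
    n_plates_per_batch: int = 11
    n_batches: int | None = None  # per species x replicate; derived when None
    fraction_hits: float = 0.05
    effect_log2_min: float = 0.5
    effect_log2_max: float = 2.0
    p_effect_up: float = 0.5
    growth_coupling: float = 0.66
    artifact_rate: float = 0.077
    noise_cv: float = 0.094
    growth_noise_cv: float = 0.05
    drift_amplitude: float = 0.2
    plate_effect_sigma: float = 0.1
    baseline_min_uM: float = 35.0
    baseline_max_uM: float = 1100.0
    max_true_growth_fc: float = 1.4  # growth cannot rise much; >1.5 is an OD artifact
    dose_uM: float = 20.0
    enrichment_bias: float = 3.0  # sampling weight of antibacterial drugs among actives
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_hits", "growth_coupling", "artifact_rate", "p_effect_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if not 0.0 <= self.drift_amplitude < 1.0:
            raise ValueError("drift_amplitude must lie in [0, 1)")
        if self.noise_cv < 0 or self.growth_noise_cv < 0:
            raise ValueError("noise CVs must be non-negative")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")


@dataclass
class ScreenTruth:
    """Ground truth of a simulated screen."""

    effects: pd.DataFrame  # compound_id x species x metabolite: true_log2_fc, true_growth_fc
    baselines: pd.DataFrame  # species x metabolite baseline concentration (uM)
    plate_effects: pd.DataFrame  # batch_id, plate_id -> multiplicative effect
    drift: dict[str, np.ndarray]  # batch_id -> drift curve over acquisition index
    noise_cv: float


def drift_profile(batch_size: int, amplitude: float, seed) -> np.ndarray:
    """Smooth multiplicative drift curve over a batch's acquisition order.

    A low-frequency random curve (two random-phase sinusoids plus a linear
    ramp) rescaled so its maximum deviation from 1 equals ``amplitude`` and
    its mean is exactly 1. Values therefore lie in
    ``[1 - amplitude, 1 + amplitude]``; ``amplitude = 0`` gives a constant
    vector of ones. Deterministic given the seed.
    """
    if not 0.0 <= amplitude < 1.0:
        raise ValueError(f"amplitude must lie in [0, 1), got {amplitude!r}")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = np.linspace(0.0, 1.0, batch_size)
    g = (
        rng.normal() * np.sin(2 * np.pi * (rng.uniform(0.5, 1.5) * t + rng.uniform()))
        + rng.normal() * np.sin(2 * np.pi * (rng.uniform(1.5, 3.0) * t + rng.uniform()))
        + rng.normal() * t
    )
    g = g - g.mean()
    peak = np.max(np.abs(g))
    if amplitude == 0.0 or peak == 0.0:
        return np.ones(batch_size)
    return 1.0 + amplitude * g / peak


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _make_library(scenario: SimulationScenario, rng: np.random.Generator) -> pd.DataFrame:
    """Compound metadata with library classes in the study's proportions."""
    total = sum(LIBRARY_COMPOSITION.values())
    counts = {
        cls: max(1, round(scenario.n_compounds * n / total))
        for cls, n in LIBRARY_COMPOSITION.items()
    }
    # adjust the largest class so counts sum exactly
    counts["drug"] += scenario.n_compounds - sum(counts.values())
    rows = []
    i = 0
    for cls, n in counts.items():
        for _ in range(n):
            i += 1
            cid = f"C{i:05d}"
            if cls == "drug":
                k = rng.integers(1, 3)
                classes = frozenset(rng.choice(THERAPEUTIC_LABELS, size=k, replace=False))
                abx = (
                    str(rng.choice(ANTIBIOTIC_CLASSES))
                    if "antibacterial" in classes
                    else None
                )
            else:
                classes, abx = frozenset(), None
            rows.append(
                {
                    "compound_id": cid,
                    "name": f"compound-{i:05d}",
                    "library_class": cls,
                    "therapeutic_classes": classes,
                    "antibiotic_class": abx,
                }
            )
    return pd.DataFrame(rows)


def _plate_layouts(
    compounds: list[str], scenario: SimulationScenario, rng: np.random.Generator
) -> list[list[tuple[str, str, str | None]]]:
    """Assign compounds, DMSO and tetracycline wells to 96-well plates.

    Returns one list of ``(well, role, compound_id)`` per plate. The layout
    is shared across species and replicates, mirroring shared compound
    aliquot plates. Remaining empty positions are filled with DMSO, so
    plates carry between 10 and 13 DMSO controls.
    """
    plates = []
    todo = list(compounds)
    while todo:
        n_dmso = int(rng.integers(10, 14))
        capacity = 96 - n_dmso - 1
        batch_compounds = todo[:capacity]
        todo = todo[capacity:]
        wells = list(WELLS_96)
        rng.shuffle(wells)
        layout = [(wells.pop(), "tetracycline_control", None)]
        layout += [(wells.pop(), "experimental", cid) for cid in batch_compounds]
        layout += [(wells.pop(), "dmso_control", None) for _ in range(n_dmso)]
        # a short final plate leaves its remaining wells unused
        plates.append(sorted(layout))
    if scenario.n_batches is not None:
        capacity_plates = scenario.n_batches * scenario.n_plates_per_batch
        if len(plates) > capacity_plates:
            raise SizingError(
                f"{len(compounds)} compounds need {len(plates)} plates but "
                f"n_batches * n_plates_per_batch = {capacity_plates}"
            )
    return plates


def _draw_truth(
    scenario: SimulationScenario, library: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """True log2 metabolite effects and growth fold changes per triple."""
    compounds = library["compound_id"].tolist()
    weights = np.ones(len(compounds))
    is_abx = library["therapeutic_classes"].map(lambda s: "antibacterial" in s).to_numpy()
    weights[is_abx] = scenario.enrichment_bias
    n_active = int(round(scenario.fraction_hits * len(compounds)))
    active = set()
    if n_active:
        p = weights / weights.sum()
        active = set(rng.choice(compounds, size=n_active, replace=False, p=p))

    rows = []
    for species, metabolites in scenario.species_metabolites.items():
        for cid in compounds:
            lfc = {m: 0.0 for m in metabolites}
            growth_fc = 1.0
            if cid in active:
                target = str(rng.choice(metabolites))
                mag = rng.uniform(scenario.effect_log2_min, scenario.effect_log2_max)
                sign = 1.0 if rng.uniform() < scenario.p_effect_up else -1.0
                lfc[target] = sign * mag
                if rng.uniform() < scenario.growth_coupling:
                    growth_fc = min(2.0 ** lfc[target], scenario.max_true_growth_fc)
            for m in metabolites:
                rows.append(
                    {
                        "compound_id": cid,
                        "species": species,
                        "metabolite": m,
                        "true_log2_fc": lfc[m],
                        "true_growth_fc": growth_fc,
                        "is_spiked": cid in active and lfc[m] != 0.0,
                    }
                )
    return pd.DataFrame(rows)


def generate_screen(scenario: SimulationScenario | None = None, seed: int | None = None):
    """Simulate a full multi-batch screen.

    Returns ``(measurements, growth, library, truth)``: the long-format
    metabolite table, the growth (absorbance) table, the compound-library
    metadata, and a :class:`ScreenTruth`. ``seed`` overrides the scenario's
    ``rng_seed``.
    """
    scenario = scenario or SimulationScenario()
    rng = np.random.default_rng(scenario.rng_seed if seed is None else seed)

    library = _make_library(scenario, rng)
    compounds = library["compound_id"].tolist()
    layouts = _plate_layouts(compounds, scenario, rng)
    truth_effects = _draw_truth(scenario, library, rng)
    lfc_map = {
        (r.compound_id, r.species, r.metabolite): r.true_log2_fc
        for r in truth_effects.itertuples()
    }
    growth_map = {
        (r.compound_id, r.species): r.true_growth_fc
        for r in truth_effects.drop_duplicates(["compound_id", "species"]).itertuples()
    }

    baselines = pd.DataFrame(
        [
            {
                "species": sp,
                "metabolite": m,
                "baseline_uM": float(
                    np.exp(
                        rng.uniform(
                            math.log(scenario.baseline_min_uM),
                            math.log(scenario.baseline_max_uM),
                        )
                    )
                ),
            }
            for sp, mets in scenario.species_metabolites.items()
            for m in mets
        ]
    )
    base_map = {(r.species, r.metabolite): r.baseline_uM for r in baselines.itertuples()}

    meas_rows: list[dict] = []
    growth_rows: list[dict] = []
    plate_effect_rows: list[dict] = []
    drift_curves: dict[str, np.ndarray] = {}

    for species, metabolites in scenario.species_metabolites.items():
        code = "".join(w[0] for w in species.split()).upper()
        for rep in (1, 2):
            n_batches = (
                scenario.n_batches
                if scenario.n_batches is not None
                else math.ceil(len(layouts) / scenario.n_plates_per_batch)
            )
            plate_batches = [
                layouts[b * scenario.n_plates_per_batch : (b + 1) * scenario.n_plates_per_batch]
                for b in range(n_batches)
            ]
            plate_no = 0
            for b, batch_plates in enumerate(plate_batches):
                if not batch_plates:
                    continue
                batch_id = f"{code}_r{rep}_b{b + 1}"
                batch_rows: list[dict] = []  # one per injection (acquisition position)
                for level in range(1, 7):
                    batch_rows.append({"role": "standard", "standard_level": level})
                culture_count = 0
                for layout in batch_plates:
                    plate_no += 1
                    plate_id = f"{code}_r{rep}_p{plate_no:02d}"
                    plate_effect = float(
                        rng.lognormal(
                            -0.5 * scenario.plate_effect_sigma**2, scenario.plate_effect_sigma
                        )
                        if scenario.plate_effect_sigma > 0
                        else 1.0
                    )
                    plate_effect_rows.append(
                        {"batch_id": batch_id, "plate_id": plate_id, "effect": plate_effect}
                    )
                    od_base = 0.8 * float(_lognormal_noise(rng, 0.05, ()))
                    blank_abs = 0.04
                    for well, role, cid in layout:
                        batch_rows.append(
                            {
                                "role": role,
                                "plate_id": plate_id,
                                "well": well,
                                "compound_id": cid,
                                "plate_effect": plate_effect,
                            }
                        )
                        culture_count += 1
                        if culture_count % 12 == 0:
                            batch_rows.append({"role": "blank"})
                            batch_rows.append({"role": "qc"})
                        # growth well
                        if role == "tetracycline_control":
                            g_true = 0.05
                        elif role == "experimental":
                            g_true = growth_map[(cid, species)]
                        else:
                            g_true = 1.0
                        g_obs = g_true * float(_lognormal_noise(rng, scenario.growth_noise_cv, ()))
                        if role == "experimental" and rng.uniform() < scenario.artifact_rate:
                            g_obs = float(rng.uniform(1.6, 3.0))
                        od = od_base * g_obs
                        growth_rows.append(
                            {
                                "batch_id": batch_id,
                                "plate_id": plate_id,
                                "well": well,
                                "role": role,
                                "species": species,
                                "replicate": rep,
                                "compound_id": cid,
                                "raw_absorbance": blank_abs + od / 5.0,
                                "blank": blank_abs,
                                "compound_background": 0.0,
                            }
                        )

                drift = drift_profile(len(batch_rows), scenario.drift_amplitude, rng)
                drift_curves[batch_id] = drift
                for acq, row in enumerate(batch_rows):
                    role = row["role"]
                    for m in metabolites:
                        base = base_map[(species, m)]
                        noise = float(_lognormal_noise(rng, scenario.noise_cv, ()))
                        if role in ("experimental", "dmso_control", "tetracycline_control"):
                            if role == "experimental":
                                lfc = lfc_map[(row["compound_id"], species, m)]
                            elif role == "tetracycline_control":
                                lfc = -2.0
                            else:
                                lfc = 0.0
                            conc = base * 2.0**lfc * row["plate_effect"] * drift[acq] * noise
                        elif role == "qc":
                            conc = base * drift[acq] * noise
                        elif role == "standard":
                            conc = base * row["standard_level"] / 3.0 * noise
                        else:  # blank
                            conc = 0.001 * base * noise
                        meas_rows.append(
                            {
                                "batch_id": batch_id,
                                "acquisition_index": acq,
                                "plate_id": row.get("plate_id"),
                                "well": row.get("well"),
                                "role": role,
                                "standard_level": row.get("standard_level"),
                                "species": species,
                                "replicate": rep,
                                "compound_id": row.get("compound_id"),
                                "dose_uM": scenario.dose_uM if role == "experimental" else 0.0,
                                "metabolite": m,
                                "raw_conc_uM": conc,
                            }
                        )

    measurements = pd.DataFrame(meas_rows)
    growth = pd.DataFrame(growth_rows)
    for df in (measurements, growth):
        for col in ("batch_id", "plate_id", "well", "role", "species", "compound_id"):
            if col in df.columns:
                df[col] = df[col].astype("string")
        df["replicate"] = df["replicate"].astype("Int64")
    measurements["metabolite"] = measurements["metabolite"].astype("string")
    truth = ScreenTruth(
        effects=truth_effects,
        baselines=baselines,
        plate_effects=pd.DataFrame(plate_effect_rows),
        drift=drift_curves,
        noise_cv=scenario.noise_cv,
    )
    return measurements, growth, library, truth


@dataclass
class DoseResponseScenario:
    """A dose-response panel: one species x metabolite, several doses.

    ``fraction_interior`` of the compounds respond maximally at an interior
    dose (a log-Gaussian response profile peaking at ``peak_dose_uM``); the
    rest respond monotonically (effect proportional to dose). Growth
    responses are monotone for all compounds.
    """

    n_compounds: int = 13
    doses_uM: tuple[float, ...] = (0.625, 1.25, 2.5, 5.0, 10.0, 20.0)
    species: str = "Escherichia coli"
    metabolite: str = "putrescine"
    fraction_interior: float = 0.5
    peak_dose_uM: float = 2.5
    effect_log2: float = 1.5
    noise_cv: float = 0.094
    growth_noise_cv: float = 0.05
    rng_seed: int = 0


def generate_dose_screen(scenario: DoseResponseScenario | None = None, seed: int | None = None):
    """Simulate a dose-response screen for one species x metabolite panel.

    Every compound is tested at every dose in both replicates; each dose
    level occupies its own plates so each dose is compared with plate-
    matched DMSO controls. Returns ``(measurements, growth, truth_df)``
    where ``truth_df`` carries the per compound x dose true log2 effect and
    the per-compound response type (``interior`` or ``monotone``).
    """
    scenario = scenario or DoseResponseScenario()
    rng = np.random.default_rng(scenario.rng_seed if seed is None else seed)
    doses = tuple(scenario.doses_uM)
    if list(doses) != sorted(doses) or len(set(doses)) != len(doses):
        raise ValueError("doses_uM must be strictly increasing")

    compounds = [f"D{i:03d}" for i in range(1, scenario.n_compounds + 1)]
    n_interior = int(round(scenario.fraction_interior * len(compounds)))
    kinds = ["interior"] * n_interior + ["monotone"] * (len(compounds) - n_interior)
    rng.shuffle(kinds)

    truth_rows = []
    lfc_map: dict[tuple[str, float], float] = {}
    dmax = max(doses)
    for cid, kind in zip(compounds, kinds):
        for d in doses:
            if kind == "interior":
                lfc = scenario.effect_log2 * math.exp(
                    -((math.log(d / scenario.peak_dose_uM)) ** 2) / (2 * 0.5**2)
                )
            else:
                lfc = scenario.effect_log2 * d / dmax
            lfc_map[(cid, d)] = lfc
            truth_rows.append(
                {
                    "compound_id": cid,
                    "dose_uM": d,
                    "response_type": kind,
                    "true_log2_fc": lfc,
                }
            )

    meas_rows: list[dict] = []
    growth_rows: list[dict] = []
    baseline = 200.0
    for rep in (1, 2):
        batch_id = f"DR_r{rep}_b1"
        batch_rows: list[dict] = []
        for dose_i, d in enumerate(doses):
            n_dmso = int(rng.integers(10, 14))
            wells = list(WELLS_96)
            rng.shuffle(wells)
            plate_id = f"DR_r{rep}_d{dose_i + 1}"
            layout = [(wells.pop(), "tetracycline_control", None)]
            layout += [(wells.pop(), "experimental", cid) for cid in compounds]
            layout += [(wells.pop(), "dmso_control", None) for _ in range(n_dmso)]
            for well, role, cid in sorted(layout):
                batch_rows.append(
                    {"role": role, "plate_id": plate_id, "well": well,
                     "compound_id": cid, "dose_uM": d}
                )
                if len(batch_rows) % 12 == 0:
                    batch_rows.append({"role": "blank", "dose_uM": 0.0})
                g_true = 1.0
                if role == "tetracycline_control":
                    g_true = 0.05
                elif role == "experimental":
                    g_true = max(0.1, 1.0 - 0.4 * d / dmax)
                g_obs = g_true * float(_lognormal_noise(rng, scenario.growth_noise_cv, ()))
                growth_rows.append(
                    {
                        "batch_id": batch_id,
                        "plate_id": plate_id,
                        "well": well,
                        "role": role,
                        "species": scenario.species,
                        "replicate": rep,
                        "compound_id": cid,
                        "dose_uM": d,
                        "raw_absorbance": 0.04 + 0.8 * g_obs / 5.0,
                        "blank": 0.04,
                        "compound_background": 0.0,
                    }
                )
        for acq, row in enumerate(batch_rows):
            role = row["role"]
            noise = float(_lognormal_noise(rng, scenario.noise_cv, ()))
            if role == "experimental":
                conc = baseline * 2.0 ** lfc_map[(row["compound_id"], row["dose_uM"])] * noise
            elif role == "tetracycline_control":
                conc = baseline * 0.25 * noise
            elif role == "blank":
                conc = 0.001 * baseline * noise
            else:
                conc = baseline * noise
            meas_rows.append(
                {
                    "batch_id": batch_id,
                    "acquisition_index": acq,
                    "plate_id": row.get("plate_id"),
                    "well": row.get("well"),
                    "role": role,
                    "standard_level": None,
                    "species": scenario.species,
                    "replicate": rep,
                    "compound_id": row.get("compound_id"),
                    "dose_uM": row.get("dose_uM", 0.0),
                    "metabolite": scenario.metabolite,
                    "raw_conc_uM": conc,
                }
            )

    measurements = pd.DataFrame(meas_rows)
    growth = pd.DataFrame(growth_rows)
    for df in (measurements, growth):
        for col in ("batch_id", "plate_id", "well", "role", "species", "compound_id"):
            if col in df.columns:
                df[col] = df[col].astype("string")
        df["replicate"] = df["replicate"].astype("Int64")
    measurements["metabolite"] = measurements["metabolite"].astype("string")
    return measurements, growth, pd.DataFrame(truth_rows)
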