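"""Screen-wide analysis configuration.

All thresholds of the hit-calling pipeline live here so that every stage
(growth, drift normalisation, hit calling, downstream summaries) reads the
same numbers. Defaults follow the screen's published analysis settings:
an FDR of 0.05, an absolute log2 fold-change cut of 0.32 (fold change
outside roughly 0.8-1.25), a growth-concordance window of 0.25 on the
linear fold-change scale, an OD-artifact cut at growth fold change 1.5,
an absorbance-to-OD multiplier of 5, a 0.01 uM concentration floor, and a
trend radius of 20 acquisition positions (30 for dose-response batches).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Literal

import yaml

Sidedness = Literal["two_sided", "one_sided_upper"]
PlateReference = Literal["plate_median", "dmso_median"]


@dataclass
class ScreenConfig:
    """Tunable parameters of the screen analysis.

    Parameters
    ----------
    alpha
        FDR level applied to Benjamini-Hochberg adjusted p-values.
    lfc_threshold
        Minimum absolute mean log2 fold change for a hit.
    concordance_threshold
        Maximum absolute difference between mean growth fold change and mean
        metabolite fold change (linear scale) for a growth-concordant hit.
    growth_artifact_threshold
        Growth fold changes strictly above this are treated as OD aggregation
        artifacts and set to missing.
    od_multiplier
        Conversion factor from blank-subtracted 595 nm absorbance to OD.
    conc_clip_uM
        Floor applied to corrected concentrations (uM).
    trend_radius
        Radius, in acquisition-index units, of the drift-trend neighbourhood.
    sidedness
        How z-scores convert to p-values.
    plate_reference
        Reference median for fold changes and z-scores: the full 96-well
        plate median (default, the Methods' literal reading) or the median
        of the plate's DMSO controls.
    rng_seed
        Seed for any stochastic step (none in the deterministic pipeline;
        kept for provenance in emitted configs).
    """

    alpha: float = 0.05
    lfc_threshold: float = 0.32
    concordance_threshold: float = 0.25
    growth_artifact_threshold: float = 1.5
    od_multiplier: float = 5.0
    conc_clip_uM: float = 0.01
    trend_radius: float = 20.0
    sidedness: Sidedness = "two_sided"
    plate_reference: PlateReference = "plate_median"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "alpha",
            "lfc_threshold",
            "concordance_threshold",
            "growth_artifact_threshold",
            "od_multiplier",
            "conc_clip_uM",
            "trend_radius",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if self.sidedness not in ("two_sided", "one_sided_upper"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")
        if self.plate_reference not in ("plate_median", "dmso_median"):
            raise ValueError(f"unknown plate_reference {self.plate_reference!r}")

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {f.name: getattr(self, f.name) for f in fields(self)},
                fh,
                sort_keys=False,
            )


DOSE_RESPONSE_TREND_RADIUS = 30.0
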