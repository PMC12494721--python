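"""Growth (optical density) analysis.

Raw 595 nm absorbances are blank-subtracted, corrected for the intrinsic
absorbance of coloured compounds, scaled to conventional OD units and
clipped at zero. Growth fold changes are computed relative to the median of
the DMSO control wells on the same 96-well plate. Implausibly high fold
changes (> 1.5) are cell-aggregation artifacts that confound the OD readout
and are set to missing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import ScreenConfig

logger = logging.getLogger(__name__)


def absorbance_to_od(raw, blank, compound_background=0.0, od_multiplier: float = 5.0):
    """Convert raw 595 nm absorbance to OD.

    ``od = max(0, raw - blank - compound_background) * od_multiplier``.
    The clip at zero removes slightly negative values that occur when a
    compound fully inhibits growth and the well reads just below blank.
    Accepts scalars or arrays; NaN inputs propagate to NaN.
    """
    if not od_multiplier > 0:
        raise ValueError(f"od_multiplier must be > 0, got {od_multiplier!r}")
    raw = np.asarray(raw, dtype=float)
    blank = np.asarray(blank, dtype=float)
    bg = np.asarray(compound_background, dtype=float)
    if np.isinf(raw).any() or np.isinf(blank).any() or np.isinf(bg).any():
        raise ValueError("absorbance inputs must be finite")
    od = np.maximum(raw - blank - bg, 0.0) * od_multiplier
    if od.ndim == 0:
        return float(od)
    return od


def growth_fold_change(
    od: np.ndarray,
    roles: np.ndarray,
    artifact_threshold: float = 1.5,
) -> np.ndarray:
    """Plate-relative growth fold changes for one 96-well plate.

    Each well's OD is divided by the median OD of the plate's DMSO control
    wells (linear-interpolation median over finite values). Fold changes
    strictly above ``artifact_threshold`` are set to NaN (aggregation
    artifact). DMSO wells themselves receive fold changes, which the QC
    metrics use. If the DMSO median is zero or no finite DMSO OD exists the
    whole plate is flagged and every fold change is missing.
    """
    od = np.asarray(od, dtype=float)
    roles = np.asarray(roles)
    dmso_od = od[(roles == "dmso_control") & np.isfinite(od)]
    if dmso_od.size == 0:
        logger.warning("plate has no finite DMSO control OD; all fold changes missing")
        return np.full_like(od, np.nan)
    ref = float(np.median(dmso_od))
    if ref == 0.0:
        logger.warning("plate DMSO median OD is 0; all fold changes missing")
        return np.full_like(od, np.nan)
    fc = od / ref
    fc[fc > artifact_threshold] = np.nan
    return fc


def compute_growth(growth_df: pd.DataFrame, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Run the full growth analysis on a long-format absorbance table.

    Adds ``od`` and ``growth_fc`` columns. Fold changes are computed per
    (batch, plate); artifact filtering follows the configured threshold.
    """
    config = config or ScreenConfig()
    df = growth_df.copy()
    bg = df["compound_background"] if "compound_background" in df.columns else 0.0
    df["od"] = absorbance_to_od(
        df["raw_absorbance"].to_numpy(dtype=float),
        df["blank"].to_numpy(dtype=float),
        np.nan_to_num(np.asarray(bg, dtype=float)),
        config.od_multiplier,
    )
    df["growth_fc"] = np.nan
    for _, idx in df.groupby(["batch_id", "plate_id"], observed=True).groups.items():
        sub = df.loc[idx]
        df.loc[idx, "growth_fc"] = growth_fold_change(
            sub["od"].to_numpy(),
            sub["role"].to_numpy(),
            config.growth_artifact_threshold,
        )
    return df
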