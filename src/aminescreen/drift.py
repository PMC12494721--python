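"""Within-batch signal-drift correction of metabolite concentrations.

LC-MS signal intensity drifts slowly over a batch's acquisition order. The
correction fits a local trend to the culture samples of each batch x
species x metabolite group (standards, blanks and QC injections excluded,
boxplot outliers removed), takes each sample's ratio to the trend, and
rescales by the screen-wide median concentration of that metabolite so the
corrected values stay in absolute concentration units (uM). Corrected
concentrations are floored at 0.01 uM to remove negative and zero values.

The trend is a radius-neighbour local regression over the acquisition
index: the unweighted mean of included samples within ``radius`` index
units, the default radius being 20 (30 for dose-response batches).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.neighbors import RadiusNeighborsRegressor

from .config import ScreenConfig
from .io import CULTURE_ROLES

logger = logging.getLogger(__name__)


def boxplot_outlier_mask(values: np.ndarray) -> np.ndarray:
    """Flag values outside the standard boxplot fences.

    A value is an outlier iff it lies below ``Q1 - 1.5*IQR`` or above
    ``Q3 + 1.5*IQR``, with quartiles computed by linear interpolation over
    the finite values. With fewer than 4 finite values no masking is done
    (a warning is logged). NaNs are never flagged.
    """
    values = np.asarray(values, dtype=float)
    mask = np.zeros(values.shape, dtype=bool)
    finite = np.isfinite(values)
    if finite.sum() < 4:
        logger.warning("fewer than 4 finite values; skipping outlier fences")
        return mask
    q1, q3 = np.percentile(values[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask[finite] = (values[finite] < lo) | (values[finite] > hi)
    return mask


def fit_drift_trend(
    acq_index: np.ndarray,
    values: np.ndarray,
    radius: float = 20.0,
    include_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Radius-neighbour drift trend over acquisition order.

    ``trend[i]`` is the unweighted mean of included values whose
    acquisition index lies within ``radius`` of ``acq_index[i]``. Positions
    with no included neighbour inherit the trend of the nearest position
    that has one (logged). Raises if nothing is included at all.
    """
    if not radius > 0:
        raise ValueError(f"radius must be > 0, got {radius!r}")
    acq = np.asarray(acq_index, dtype=float)
    vals = np.asarray(values, dtype=float)
    if include_mask is None:
        include_mask = np.ones(vals.shape, dtype=bool)
    include_mask = np.asarray(include_mask, dtype=bool) & np.isfinite(vals) & np.isfinite(acq)
    if not include_mask.any():
        raise ValueError("no included values to fit a drift trend")
    x_fit = acq[include_mask].reshape(-1, 1)
    y_fit = vals[include_mask]
    reg = RadiusNeighborsRegressor(radius=radius, weights="uniform")
    reg.fit(x_fit, y_fit)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on empty neighbourhoods
        trend = reg.predict(acq.reshape(-1, 1))
    empty = ~np.isfinite(trend)
    if empty.any():
        logger.info("%d positions had no neighbour within radius; using nearest trend", empty.sum())
        defined = np.flatnonzero(~empty)
        for i in np.flatnonzero(empty):
            nearest = defined[np.argmin(np.abs(acq[defined] - acq[i]))]
            trend[i] = trend[nearest]
    return trend


def correct_concentrations(
    values: np.ndarray,
    trend: np.ndarray,
    screen_median: float,
    clip: float = 0.01,
) -> np.ndarray:
    """Ratio-based drift correction rescaled to the screen-wide median.

    ``corrected[i] = max(values[i] / trend[i] * screen_median, clip)``.
    The screen median keeps corrected values in absolute uM units.
    """
    values = np.asarray(values, dtype=float)
    trend = np.asarray(trend, dtype=float)
    if not screen_median > 0:
        raise ValueError(f"screen_median must be > 0, got {screen_median!r}")
    bad = np.flatnonzero(np.isfinite(trend) & (trend <= 0))
    if bad.size:
        raise ValueError(f"non-positive trend value at position {bad[0]}")
    corrected = values / trend * screen_median
    return np.where(np.isfinite(corrected), np.maximum(corrected, clip), corrected)


def normalise_screen(
    measurements: pd.DataFrame,
    config: ScreenConfig | None = None,
    screen_median_roles: tuple[str, ...] = ("experimental",),
) -> pd.DataFrame:
    """Drift-correct a full long-format metabolite table.

    Outlier fences and trend fitting run per batch x species x metabolite
    (batches are acquired and analysed separately; metabolites differ by
    orders of magnitude in concentration). The fit excludes standards,
    blanks and QC injections as well as fence outliers, but the correction
    is applied to every culture sample. The rescaling median is computed per
    species x metabolite over the whole screen's ``screen_median_roles``
    samples (compound-treated samples by default; configurable).

    Adds ``trend_value`` and ``corrected_conc_uM`` columns; non-culture
    rows keep NaN in both.
    """
    config = config or ScreenConfig()
    df = measurements.copy()
    df["trend_value"] = np.nan
    df["corrected_conc_uM"] = np.nan

    is_culture = df["role"].isin(CULTURE_ROLES).to_numpy()
    med_rows = df[df["role"].isin(screen_median_roles)]
    screen_medians = (
        med_rows.groupby(["species", "metabolite"], observed=True)["raw_conc_uM"]
        .median()
        .to_dict()
    )

    for (batch, species, metabolite), idx in df.groupby(
        ["batch_id", "species", "metabolite"], observed=True
    ).groups.items():
        sub = df.loc[idx]
        culture = is_culture[df.index.get_indexer(idx)]
        values = sub["raw_conc_uM"].to_numpy(dtype=float)
        acq = sub["acquisition_index"].to_numpy(dtype=float)
        include = culture.copy()
        fence = boxplot_outlier_mask(np.where(include, values, np.nan))
        include &= ~fence
        if not (include & np.isfinite(values)).any():
            logger.warning(
                "batch %s %s/%s: no usable samples for drift trend; left uncorrected",
                batch, species, metabolite,
            )
            continue
        trend = fit_drift_trend(acq, values, radius=config.trend_radius, include_mask=include)
        median = screen_medians.get((species, metabolite), np.nan)
        if not np.isfinite(median) or median <= 0:
            logger.warning(
                "no positive screen median for %s/%s; left uncorrected", species, metabolite
            )
            continue
        corrected = correct_concentrations(values, trend, median, clip=config.conc_clip_uM)
        df.loc[idx, "trend_value"] = np.where(culture, trend, np.nan)
        df.loc[idx, "corrected_conc_uM"] = np.where(culture, corrected, np.nan)
    return df
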