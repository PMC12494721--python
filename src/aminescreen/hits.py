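"""Plate-matched z-score hit calling and growth-concordance classification.

Each compound-treated well is scored against its own 96-well plate: the
z-score is the difference between the well's drift-corrected concentration
and the plate reference median, divided by the sample standard deviation of
the plate's DMSO controls. Z-scores convert to p-values through the normal
survival function (two-sided by default), which are Benjamini-Hochberg
adjusted within each species x metabolite, separately per biological
replicate. A compound x species x metabolite triple is a hit when both
replicates are significant (adjusted p < alpha), agree in direction, and
the absolute mean log2 fold change exceeds the threshold (default 0.32,
i.e. a fold change outside roughly 0.8-1.25).

A hit is growth-concordant when the absolute difference between the mean
growth fold change and the mean metabolite fold change (both on the linear
scale) is below the concordance threshold (default 0.25); non-concordant
hits indicate decoupling of metabolite output from biomass.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import ScreenConfig
from .io import CULTURE_ROLES

logger = logging.getLogger(__name__)


def plate_zscore(corrected, plate_reference_median: float, dmso_sd: float):
    """z = (corrected - plate reference median) / DMSO standard deviation.

    Returns NaN (and logs) when ``dmso_sd`` is zero or not finite — a
    degenerate plate rather than an error.
    """
    corrected = np.asarray(corrected, dtype=float)
    if not np.isfinite(dmso_sd) or dmso_sd <= 0:
        logger.warning("plate flagged: DMSO standard deviation is %r; z-scores missing", dmso_sd)
        out = np.full_like(corrected, np.nan)
        return float(out) if out.ndim == 0 else out
    z = (corrected - plate_reference_median) / dmso_sd
    return float(z) if z.ndim == 0 else z


def z_to_pvalue(z, sidedness: str = "two_sided"):
    """Convert z-scores to p-values via the standard-normal survival function.

    ``two_sided``: p = min(2 * SF(|z|), 1); ``one_sided_upper``: p = SF(z).
    """
    z = np.asarray(z, dtype=float)
    if sidedness == "two_sided":
        p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    elif sidedness == "one_sided_upper":
        p = stats.norm.sf(z)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    p = np.where(np.isfinite(z), p, np.nan)
    return float(p) if p.ndim == 0 else p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, output in input order.

    NaN p-values stay NaN and do not count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def replicate_stats(corrected: pd.DataFrame, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Per-well z, p, adjusted p and fold change for experimental samples.

    Operates plate by plate (per metabolite) on a drift-corrected
    measurement table, then BH-adjusts within species x metabolite x
    replicate across all experimental wells. Plates with fewer than 3
    finite DMSO-control values are flagged and yield missing statistics.
    """
    config = config or ScreenConfig()
    df = corrected[corrected["role"].isin(CULTURE_ROLES)].copy()
    df["z"] = np.nan
    df["fc"] = np.nan
    for (_, _, metab), idx in df.groupby(
        ["batch_id", "plate_id", "metabolite"], observed=True
    ).groups.items():
        sub = df.loc[idx]
        vals = sub["corrected_conc_uM"].to_numpy(dtype=float)
        roles = sub["role"].to_numpy()
        dmso = vals[(roles == "dmso_control") & np.isfinite(vals)]
        if config.plate_reference == "plate_median":
            ref_pool = vals[np.isfinite(vals)]
        else:
            ref_pool = dmso
        if ref_pool.size == 0:
            continue
        ref = float(np.median(ref_pool))
        if dmso.size < 3:
            logger.warning("plate %s/%s: <3 finite DMSO controls; stats missing",
                           sub["plate_id"].iloc[0], metab)
            continue
        sd = float(dmso.std(ddof=1))
        df.loc[idx, "z"] = plate_zscore(vals, ref, sd)
        if ref > 0:
            df.loc[idx, "fc"] = vals / ref
    df["p"] = z_to_pvalue(df["z"].to_numpy(), config.sidedness)
    df["p_adj"] = np.nan
    is_exp = df["role"] == "experimental"
    for _, idx in df[is_exp].groupby(
        ["species", "metabolite", "replicate"], observed=True
    ).groups.items():
        df.loc[idx, "p_adj"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    return df


def classify_concordance(mean_growth_fc, mean_metab_fc, threshold: float = 0.25):
    """Growth-concordance on the linear fold-change scale.

    Concordant iff ``|mean_growth_fc - mean_metab_fc| < threshold``
    (strict). Missing inputs propagate to missing output (NaN).
    """
    g = np.asarray(mean_growth_fc, dtype=float)
    m = np.asarray(mean_metab_fc, dtype=float)
    diff = np.abs(g - m)
    out = np.where(np.isfinite(diff), diff < threshold, np.nan)
    if out.ndim == 0:
        return bool(out) if np.isfinite(diff) else None
    return out


def call_hits(
    stats_df: pd.DataFrame,
    growth_df: pd.DataFrame | None = None,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Combine two biological replicates into per-triple hit calls.

    Input: per-well statistics from :func:`replicate_stats` (experimental
    rows). Output: one row per compound x species x metabolite with both
    replicates' z/p/p_adj/fc, the mean log2 fold change, direction, hit
    flag, mean growth fold change and concordance class. Triples without
    exactly two replicates are skipped with a warning.
    """
    config = config or ScreenConfig()
    exp = stats_df[stats_df["role"] == "experimental"].copy()

    growth_means = None
    if growth_df is not None:
        gexp = growth_df[growth_df["role"] == "experimental"]
        growth_means = (
            gexp.groupby(["compound_id", "species"], observed=True)["growth_fc"]
            .mean()  # mean over replicates with finite fc; NaN if all missing
            .rename("mean_growth_fc")
        )

    records = []
    for (compound, species, metab), sub in exp.groupby(
        ["compound_id", "species", "metabolite"], observed=True
    ):
        sub = sub.sort_values("replicate")
        reps = sub["replicate"].tolist()
        if reps != [1, 2]:
            logger.warning(
                "compound %s %s/%s: replicates %s != [1, 2]; skipped",
                compound, species, metab, reps,
            )
            continue
        fc1, fc2 = sub["fc"].to_numpy(dtype=float)
        padj1, padj2 = sub["p_adj"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            l1, l2 = np.log2(fc1), np.log2(fc2)
        mean_lfc = (l1 + l2) / 2.0
        same_dir = np.sign(l1) == np.sign(l2) and np.sign(l1) != 0
        is_hit = bool(
            np.isfinite(padj1)
            and np.isfinite(padj2)
            and padj1 < config.alpha
            and padj2 < config.alpha
            and same_dir
            and np.isfinite(mean_lfc)
            and abs(mean_lfc) > config.lfc_threshold
        )
        records.append(
            {
                "compound_id": compound,
                "species": species,
                "metabolite": metab,
                "z_rep1": sub["z"].iloc[0],
                "z_rep2": sub["z"].iloc[1],
                "p_rep1": sub["p"].iloc[0],
                "p_rep2": sub["p"].iloc[1],
                "p_adj_rep1": padj1,
                "p_adj_rep2": padj2,
                "fc_rep1": fc1,
                "fc_rep2": fc2,
                "mean_log2_fc": mean_lfc,
                "mean_metab_fc": (fc1 + fc2) / 2.0,
                "direction": "up" if mean_lfc > 0 else "down",
                "is_hit": is_hit,
            }
        )
    hits = pd.DataFrame.from_records(records)
    if hits.empty:
        return hits
    if growth_means is not None:
        hits = hits.merge(
            growth_means, left_on=["compound_id", "species"], right_index=True, how="left"
        )
    else:
        hits["mean_growth_fc"] = np.nan
    conc = classify_concordance(
        hits["mean_growth_fc"].to_numpy(),
        hits["mean_metab_fc"].to_numpy(),
        config.concordance_threshold,
    )
    hits["concordant"] = pd.array(
        [bool(c) if np.isfinite(c) else pd.NA for c in np.asarray(conc, dtype=float)],
        dtype="boolean",
    )
    return hits
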