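"""Downstream summaries: enrichment, hit rates, cross-species correlation,
dose-response stimulation fractions and screen QC metrics.

Therapeutic-class enrichment uses a two-sided Fisher's exact test on the
2x2 table (class membership x hit status) within each stratum of
species x metabolite x direction x concordance (or pooled), with
Benjamini-Hochberg adjustment across classes inside each stratum; only
positive enrichments (class hit frequency above background) are typically
reported. QC metrics follow the screen's quality indicators: the
coefficient of variation of corrected DMSO-control concentrations per
plate x metabolite, and the Pearson correlation of per-compound corrected
concentrations between the two biological replicates.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .hits import bh_adjust

logger = logging.getLogger(__name__)


def fisher_enrichment(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    Returns (odds_ratio, p). a = class & hit, b = class & non-hit,
    c = non-class & hit, d = non-class & non-hit.
    """
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def class_enrichment(
    hit_flags: Mapping[str, bool] | pd.Series,
    class_membership: Mapping[str, frozenset] | pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-class Fisher enrichment of hits within one stratum.

    ``hit_flags``: compound_id -> bool. ``class_membership``: compound_id ->
    set of class labels. The compound universes must agree. Classes with no
    members are skipped. BH adjustment runs across the tested classes.
    """
    hit_flags = pd.Series(hit_flags, dtype=bool)
    membership = pd.Series(class_membership)
    if set(hit_flags.index) != set(membership.index):
        raise ValueError("hit flags and class membership cover different compound sets")
    membership = membership.reindex(hit_flags.index)
    n = len(hit_flags)
    n_hits = int(hit_flags.sum())
    background = n_hits / n if n else 0.0
    labels = sorted(set().union(*membership))
    rows = []
    for label in labels:
        in_class = membership.map(lambda s: label in s)
        a = int((in_class & hit_flags).sum())
        b = int((in_class & ~hit_flags).sum())
        c = n_hits - a
        d = n - a - b - c
        odds, p = fisher_enrichment(a, b, c, d)
        hit_rate = a / (a + b) if (a + b) else np.nan
        rows.append(
            {
                "class_label": label,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds,
                "p": p,
                "hit_rate": hit_rate,
                "positively_enriched": bool(hit_rate > background),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    return out


def stratified_enrichment(
    hits: pd.DataFrame,
    library: pd.DataFrame,
    alpha: float = 0.05,
    pooled: bool = False,
) -> pd.DataFrame:
    """Run class enrichment within species x metabolite x direction x
    concordance strata (or pooled over everything).

    ``hits`` is the hit table from :func:`aminescreen.hits.call_hits`;
    ``library`` supplies ``therapeutic_classes`` per compound. Within each
    stratum a compound counts as a hit if it has a hit of that stratum's
    direction/concordance for that species x metabolite; the universe is
    the full tested library.
    """
    membership = library.set_index("compound_id")["therapeutic_classes"]
    universe = membership.index
    pieces = []
    if pooled:
        strata = [(("pooled",), hits)]
    else:
        hit_rows = hits[hits["is_hit"]].copy()
        hit_rows["concordance"] = hit_rows["concordant"].map(
            {True: "concordant", False: "non_concordant"}
        )
        strata = [
            (key, sub)
            for key, sub in hit_rows.groupby(
                ["species", "metabolite", "direction", "concordance"], observed=True
            )
        ]
    for key, sub in strata:
        hit_compounds = set(sub.loc[sub["is_hit"], "compound_id"])
        flags = pd.Series({cid: cid in hit_compounds for cid in universe})
        table = class_enrichment(flags, membership, alpha=alpha)
        if table.empty:
            continue
        table.insert(0, "stratum", " | ".join(str(k) for k in key))
        pieces.append(table)
    if not pieces:
        return pd.DataFrame()
    return pd.concat(pieces, ignore_index=True)


def hit_rate_by_class(
    hits: pd.DataFrame, library: pd.DataFrame, by: str = "library_class"
) -> pd.DataFrame:
    """Fraction of active compounds per compound class.

    A compound is active if it hits at least one species x metabolite pair.
    ``by`` may be ``"library_class"`` (one class per compound) or
    ``"therapeutic_classes"`` (set-valued; compounds count in each class).
    Empty classes do not appear.
    """
    active = set(hits.loc[hits["is_hit"], "compound_id"])
    rows = []
    if by == "therapeutic_classes":
        exploded = library[["compound_id", "therapeutic_classes"]].explode("therapeutic_classes")
        exploded = exploded.dropna(subset=["therapeutic_classes"])
        groups = exploded.groupby("therapeutic_classes")["compound_id"]
    else:
        groups = library.groupby(by)["compound_id"]
    for label, compounds in groups:
        n_class = compounds.nunique()
        if n_class == 0:
            continue
        n_active = int(compounds.isin(active).sum())
        rows.append(
            {
                "class": label,
                "n_class": n_class,
                "n_active": n_active,
                "hit_rate": n_active / n_class,
            }
        )
    return pd.DataFrame(rows).sort_values("hit_rate", ascending=False, ignore_index=True)


def cross_species_correlation(
    responses_a: pd.Series, responses_b: pd.Series
) -> tuple[float, float, int]:
    """Pearson correlation of per-compound responses between two species.

    Inputs are compound-indexed mean log2 fold changes (growth or
    metabolite); pairing is by compound id over pairwise-complete values.
    Returns (r, two-sided p, n pairs). Requires at least 3 pairs.
    """
    joined = pd.concat({"a": responses_a, "b": responses_b}, axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(f"need >= 3 paired finite values, got {len(joined)}")
    r, p = stats.pearsonr(joined["a"], joined["b"])
    return float(r), float(p), len(joined)


def dose_response_fractions(
    dose_hits: pd.DataFrame,
    alpha: float = 0.05,
    require_lfc: bool = False,
    lfc_threshold: float = 0.32,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stimulation fractions per dose and per-compound monotonicity.

    A compound is *stimulated* at a dose when both replicates are
    significant (adjusted p < alpha) and the mean fold change exceeds 1
    (optionally also clearing the log2 fold-change threshold). Compounds
    missing any dose level are excluded from the fractions at every level
    (logged). The monotone flag is true iff the response magnitude
    |mean log2 fc| is non-decreasing with dose.

    Returns ``(fractions, compound_flags)``.
    """
    df = dose_hits.copy()
    n_doses = df.groupby(["species", "metabolite"], observed=True)["dose_uM"].nunique()
    keep = []
    for (sp, met), sub in df.groupby(["species", "metabolite"], observed=True):
        full = sub.groupby("compound_id", observed=True)["dose_uM"].nunique()
        complete = set(full[full == n_doses.loc[(sp, met)]].index)
        dropped = set(full.index) - complete
        if dropped:
            logger.warning(
                "%s/%s: %d compound(s) missing dose levels excluded", sp, met, len(dropped)
            )
        keep.append(sub[sub["compound_id"].isin(complete)])
    df = pd.concat(keep, ignore_index=True) if keep else df

    stim = (
        (df["p_adj_rep1"] < alpha)
        & (df["p_adj_rep2"] < alpha)
        & (df["mean_metab_fc"] > 1.0)
    )
    if require_lfc:
        stim &= df["mean_log2_fc"].abs() > lfc_threshold
    df["stimulated"] = stim.fillna(False)

    fractions = (
        df.groupby(["species", "metabolite", "dose_uM"], observed=True)
        .agg(n_tested=("compound_id", "nunique"), n_stimulated=("stimulated", "sum"))
        .reset_index()
    )
    fractions["fraction_stimulated"] = fractions["n_stimulated"] / fractions["n_tested"]

    flag_rows = []
    for (sp, met, cid), sub in df.groupby(
        ["species", "metabolite", "compound_id"], observed=True
    ):
        sub = sub.sort_values("dose_uM")
        mags = sub["mean_log2_fc"].abs().to_numpy()
        monotone = bool(np.all(np.diff(mags) >= 0))
        flag_rows.append(
            {"species": sp, "metabolite": met, "compound_id": cid, "monotone": monotone}
        )
    return fractions, pd.DataFrame(flag_rows)


def qc_metrics(
    corrected: pd.DataFrame, stats_df: pd.DataFrame | None = None
) -> dict[str, object]:
    """Screen quality indicators.

    * per plate x metabolite CV (sample SD / mean) of corrected DMSO-control
      concentrations, and their median;
    * per species x metabolite Pearson correlation of per-compound corrected
      concentrations between biological replicates 1 and 2, and their median.

    Groups with fewer than 2 DMSO controls (CV) or 3 compounds
    (correlation) are skipped with a log message.
    """
    dmso = corrected[
        (corrected["role"] == "dmso_control") & corrected["corrected_conc_uM"].notna()
    ]
    cv_rows = []
    for (batch, plate, met), sub in dmso.groupby(
        ["batch_id", "plate_id", "metabolite"], observed=True
    ):
        vals = sub["corrected_conc_uM"].to_numpy(dtype=float)
        if len(vals) < 2 or vals.mean() == 0:
            logger.info("plate %s/%s: <2 DMSO controls; CV skipped", plate, met)
            continue
        cv_rows.append(
            {
                "batch_id": batch,
                "plate_id": plate,
                "metabolite": met,
                "cv": vals.std(ddof=1) / vals.mean(),
            }
        )
    cv_table = pd.DataFrame(cv_rows)

    corr_rows = []
    exp = corrected[(corrected["role"] == "experimental") & corrected["corrected_conc_uM"].notna()]
    for (sp, met), sub in exp.groupby(["species", "metabolite"], observed=True):
        wide = sub.pivot_table(
            index="compound_id", columns="replicate", values="corrected_conc_uM"
        )
        if not {1, 2}.issubset(wide.columns):
            continue
        wide = wide[[1, 2]].dropna()
        if len(wide) < 3:
            logger.info("%s/%s: <3 compounds for replicate correlation; skipped", sp, met)
            continue
        r, _ = stats.pearsonr(wide[1], wide[2])
        corr_rows.append({"species": sp, "metabolite": met, "replicate_r": float(r), "n": len(wide)})
    corr_table = pd.DataFrame(corr_rows)

    return {
        "dmso_cv": cv_table,
        "median_dmso_cv": float(cv_table["cv"].median()) if not cv_table.empty else np.nan,
        "replicate_correlation": corr_table,
        "median_replicate_r": (
            float(corr_table["replicate_r"].median()) if not corr_table.empty else np.nan
        ),
    }
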