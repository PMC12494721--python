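"""Therapeutic-class enrichment, per-class hit rates and cross-species
response correlation.

Reads the hit calls and the compound library, tests each therapeutic class
for enrichment among hits (Fisher's exact test, BH-adjusted within
strata), tabulates per-class hit rates, and correlates per-compound mean
log2 metabolite responses between the two Enterobacteriaceae.

Run analysis/03_call_hits.py first.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from aminescreen.downstream import (
    cross_species_correlation,
    hit_rate_by_class,
    stratified_enrichment,
)
from aminescreen.io import read_compound_library, write_results

ROOT = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "screen"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SCRATCH / "all_triples.csv").exists():
        sys.exit("no hit statistics found; run analysis/03_call_hits.py first")
    hits = pd.read_csv(SCRATCH / "all_triples.csv")
    library = read_compound_library(SCRATCH / "library.csv")

    enrichment = stratified_enrichment(hits, library, pooled=True)
    rates_lib = hit_rate_by_class(hits, library, by="library_class")
    rates_ther = hit_rate_by_class(hits, library, by="therapeutic_classes")
    write_results(
        {
            "enrichment": enrichment,
            "hit_rates_library": rates_lib,
            "hit_rates_therapeutic": rates_ther,
        },
        RESULTS,
    )

    print("class enrichment (pooled across species/metabolites):")
    sig = enrichment[enrichment["significant"] & enrichment["positively_enriched"]]
    if sig.empty:
        print("  no class clears adjusted p < 0.05 at this seed; top classes:")
        sig = enrichment[enrichment["positively_enriched"]].nsmallest(3, "p")
    for row in sig.itertuples():
        print(f"  {row.class_label}: hit rate {row.hit_rate:.2f}, "
              f"odds ratio {row.odds_ratio:.1f}, adjusted p {row.p_adj:.2e}")
    print("hit rate by library class:")
    for row in rates_lib.itertuples():
        print(f"  {row._1}: {row.n_active}/{row.n_class} = {100 * row.hit_rate:.1f}%")

    # cross-species comparison of the shared polyamine readouts
    ec = hits[(hits["species"] == "Escherichia coli") & (hits["metabolite"] == "putrescine")]
    ka = hits[(hits["species"] == "Klebsiella aerogenes") & (hits["metabolite"] == "putrescine")]
    r, p, n = cross_species_correlation(
        ec.set_index("compound_id")["mean_log2_fc"],
        ka.set_index("compound_id")["mean_log2_fc"],
    )
    print(f"putrescine response correlation E. coli vs K. aerogenes: "
          f"r = {r:.2f} (p = {p:.1e}, n = {n} compounds)")


if __name__ == "__main__":
    main()
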