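"""Call hits and classify growth concordance.

Reads the drift-corrected tables from scratch/screen/, computes the
plate-matched z-scores, BH-adjusted p-values and dual-replicate hit calls,
compares the calls against the simulation's ground truth, and writes the
called-hit table to results/hits.csv (the full per-triple statistics stay
in scratch/, they are large).

Run analysis/02_normalise_and_growth.py first.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from aminescreen.hits import call_hits, replicate_stats
from aminescreen.io import write_results

ROOT = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "screen"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SCRATCH / "corrected.csv").exists():
        sys.exit("no corrected table found; run analysis/02_normalise_and_growth.py first")
    corrected = pd.read_csv(SCRATCH / "corrected.csv")
    growth = pd.read_csv(SCRATCH / "growth_fc.csv")
    truth = pd.read_csv(SCRATCH / "truth.csv")

    stats = replicate_stats(corrected)
    hits = call_hits(stats, growth)
    write_results({"all_triples": hits}, SCRATCH)

    called = hits[hits["is_hit"]]
    key = ["compound_id", "species", "metabolite"]
    merged = hits.merge(truth[key + ["is_spiked"]], on=key, how="left")
    spiked = merged[merged["is_spiked"]]
    sensitivity = spiked["is_hit"].mean()
    fdp = (~merged.loc[merged["is_hit"], "is_spiked"]).mean()

    write_results({"hits": called}, RESULTS)
    print("hit calling:")
    print(f"  {len(called)} hit triples out of {len(hits)} tested "
          f"({called['compound_id'].nunique()} active compounds)")
    by_species = called.groupby("species")["compound_id"].nunique()
    for sp, n in by_species.items():
        print(f"    {sp}: {n} active compounds")
    conc = called["concordant"].dropna()
    if len(conc):
        print(f"  growth-concordant hits: {100 * conc.mean():.0f}% "
              f"(of {len(conc)} with growth data)")
    print(f"  recovery vs ground truth: sensitivity {sensitivity:.3f}, "
          f"false-discovery proportion {fdp:.3f}")
    print(f"  hit table written to {RESULTS / 'hits.csv'}")


if __name__ == "__main__":
    main()
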