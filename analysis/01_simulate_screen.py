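"""Simulate the xenobiotic screen at study conditions.

Generates a 1772-compound, four-species, two-replicate plate screen with
signal drift, plate effects, lognormal measurement noise, spike-in compound
effects and OD artifacts, and writes the raw tables (plus ground truth) to
scratch/screen/ for the downstream steps. Summary counts go to stdout.

Run from the repository root: python analysis/01_simulate_screen.py [--seed N]
"""

import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from aminescreen.io import write_results
from aminescreen.simulate import SimulationScenario, generate_screen

SCRATCH = pathlib.Path(__file__).resolve().parents[1] / "scratch" / "screen"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    scenario = SimulationScenario(rng_seed=args.seed)
    measurements, growth, library, truth = generate_screen(scenario)
    write_results(
        {
            "measurements": measurements,
            "growth": growth,
            "library": library,
            "truth": truth.effects,
        },
        SCRATCH,
    )
    n_spiked = int(truth.effects["is_spiked"].sum())
    print(f"simulated screen with seed {args.seed}:")
    print(f"  {measurements['compound_id'].nunique()} compounds, "
          f"{measurements['species'].nunique()} species, "
          f"{measurements['batch_id'].nunique()} batches")
    print(f"  {len(measurements)} metabolite measurements, {len(growth)} growth wells")
    print(f"  {n_spiked} spiked compound x species x metabolite effects (ground truth)")
    print(f"  tables written to {SCRATCH}")


if __name__ == "__main__":
    main()
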