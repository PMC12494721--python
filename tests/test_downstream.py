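import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from aminescreen.downstream import (
    class_enrichment,
    cross_species_correlation,
    dose_response_fractions,
    fisher_enrichment,
    hit_rate_by_class,
    qc_metrics,
    stratified_enrichment,
)
from aminescreen.pipeline import run_dose_screen
from aminescreen.simulate import DoseResponseScenario, generate_dose_screen


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by hypergeometric enumeration (rationals)."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    total = math.comb(n, col1)

    def pmf(k):
        return Fraction(math.comb(row1, k) * math.comb(row2, col1 - k), total)

    kmin, kmax = max(0, col1 - row2), min(col1, row1)
    cutoff = pmf(a) * Fraction(10**7 + 1, 10**7)  # tolerance for float ties
    s = sum(pmf(k) for k in range(kmin, kmax + 1) if pmf(k) <= cutoff)
    return float(min(s, Fraction(1)))


class TestFisher:
    def test_exhaustive_small_tables(self):
        """All 2x2 tables with total <= 12 match the enumeration oracle."""
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        _, p = fisher_enrichment(a, b, c, d)
                        assert p == pytest.approx(
                            fisher_two_sided_oracle(a, b, c, d), abs=1e-10
                        )

    def test_permutation_calibration(self, rng):
        """Permuting class labels gives valid (conservative) p-values."""
        n, n_class, n_hits = 200, 30, 25
        hits = np.zeros(n, dtype=bool)
        hits[:n_hits] = True
        pvals = []
        for _ in range(1000):
            members = rng.choice(n, size=n_class, replace=False)
            in_class = np.zeros(n, dtype=bool)
            in_class[members] = True
            a = int((in_class & hits).sum())
            b = n_class - a
            c = n_hits - a
            d = n - a - b - c
            pvals.append(fisher_enrichment(a, b, c, d)[1])
        pvals = np.asarray(pvals)
        for alpha in (0.05, 0.1, 0.2):
            margin = 3 * math.sqrt(alpha * (1 - alpha) / len(pvals))
            assert (pvals <= alpha).mean() <= alpha + margin


class TestClassEnrichment:
    def make_inputs(self, n=100, n_hits=10, class_members=5, class_hits=5):
        compounds = [f"C{i}" for i in range(n)]
        hits = {c: i < n_hits for i, c in enumerate(compounds)}
        member_ids = compounds[:class_hits] + compounds[n_hits : n_hits + class_members - class_hits]
        membership = {
            c: frozenset({"target"}) if c in member_ids else frozenset({"other"})
            for c in compounds
        }
        return hits, membership

    def test_fully_hit_class(self):
        hits, membership = self.make_inputs()
        out = class_enrichment(hits, membership).set_index("class_label")
        row = out.loc["target"]
        assert (row["a"], row["b"], row["c"], row["d"]) == (5, 0, 5, 90)
        assert row["p"] == pytest.approx(fisher_two_sided_oracle(5, 0, 5, 90), abs=1e-12)
        assert row["positively_enriched"]
        assert row["hit_rate"] == 1.0

    def test_zero_hit_class_never_positively_enriched(self):
        hits, membership = self.make_inputs(class_hits=0)
        out = class_enrichment(hits, membership).set_index("class_label")
        assert not out.loc["target", "positively_enriched"]

    def test_class_equal_to_library_is_degenerate(self):
        compounds = [f"C{i}" for i in range(20)]
        hits = {c: i < 4 for i, c in enumerate(compounds)}
        membership = {c: frozenset({"everything"}) for c in compounds}
        out = class_enrichment(hits, membership).set_index("class_label")
        assert out.loc["everything", "p"] == pytest.approx(1.0)

    def test_mismatched_universe_rejected(self):
        hits, membership = self.make_inputs()
        membership.pop("C0")
        with pytest.raises(ValueError):
            class_enrichment(hits, membership)

    def test_stratified_enrichment_finds_spiked_class(self, small_screen, small_result):
        """Actives are drawn with an antibacterial bias, so pooled enrichment
        should rank antibacterial near the top."""
        library = small_screen[2]
        hits = small_result["hits"]
        pooled = stratified_enrichment(hits, library, pooled=True)
        assert not pooled.empty
        top = pooled.sort_values("p").iloc[0]
        assert top["class_label"] == "antibacterial"
        assert top["positively_enriched"]


class TestHitRates:
    def test_known_rate(self):
        library = pd.DataFrame(
            {
                "compound_id": [f"P{i}" for i in range(166)],
                "library_class": ["pesticide"] * 166,
                "therapeutic_classes": [frozenset()] * 166,
            }
        )
        hits = pd.DataFrame(
            {
                "compound_id": [f"P{i}" for i in range(10)],
                "species": "Escherichia coli",
                "metabolite": "putrescine",
                "is_hit": True,
            }
        )
        out = hit_rate_by_class(hits, library)
        assert out.loc[0, "hit_rate"] == pytest.approx(10 / 166, abs=1e-4)

    def test_all_active(self):
        library = pd.DataFrame(
            {
                "compound_id": ["A", "B"],
                "library_class": ["drug", "sweetener"],
                "therapeutic_classes": [frozenset(), frozenset()],
            }
        )
        hits = pd.DataFrame(
            {"compound_id": ["A", "B"], "species": "x", "metabolite": "m", "is_hit": True}
        )
        out = hit_rate_by_class(hits, library)
        assert (out["hit_rate"] == 1.0).all()


class TestCrossSpeciesCorrelation:
    def test_identical_and_antiequal(self, rng):
        x = pd.Series(rng.normal(size=30), index=[f"C{i}" for i in range(30)])
        r, _, n = cross_species_correlation(x, x)
        assert r == pytest.approx(1.0)
        r, _, _ = cross_species_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        idx = [f"C{i}" for i in range(50)]
        x = pd.Series(rng.normal(size=50), index=idx)
        y = pd.Series(0.5 * x.to_numpy() + rng.normal(size=50), index=idx)
        r, p, n = cross_species_correlation(x, y)
        xa, ya = x.to_numpy(), y.to_numpy()
        expected = ((xa - xa.mean()) * (ya - ya.mean())).sum() / math.sqrt(
            ((xa - xa.mean()) ** 2).sum() * ((ya - ya.mean()) ** 2).sum()
        )
        assert r == pytest.approx(expected, abs=1e-12)
        assert n == 50

    def test_too_few_pairs(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            cross_species_correlation(x, x)


def make_dose_table(n=13, stimulated_at_low=5):
    rows = []
    for i in range(n):
        for dose in (2.5, 20.0):
            stim = dose == 2.5 and i < stimulated_at_low
            rows.append(
                {
                    "species": "Escherichia coli",
                    "metabolite": "putrescine",
                    "compound_id": f"D{i}",
                    "dose_uM": dose,
                    "p_adj_rep1": 0.001 if stim else 0.5,
                    "p_adj_rep2": 0.001 if stim else 0.5,
                    "mean_metab_fc": 2.0 if stim else 1.0,
                    "mean_log2_fc": 1.0 if stim else 0.0,
                }
            )
    return pd.DataFrame(rows)


class TestDoseResponse:
    def test_fraction_five_of_thirteen(self):
        fractions, _ = dose_response_fractions(make_dose_table())
        low = fractions[fractions["dose_uM"] == 2.5].iloc[0]
        assert low["fraction_stimulated"] == pytest.approx(5 / 13, abs=1e-9)
        high = fractions[fractions["dose_uM"] == 20.0].iloc[0]
        assert high["fraction_stimulated"] == 0.0

    def test_ordering_invariance(self):
        table = make_dose_table()
        f1, _ = dose_response_fractions(table)
        f2, _ = dose_response_fractions(table.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(
            f1.sort_values(["dose_uM"]).reset_index(drop=True),
            f2.sort_values(["dose_uM"]).reset_index(drop=True),
        )

    def test_incomplete_compound_excluded_everywhere(self):
        table = make_dose_table()
        table = table.drop(table[(table["compound_id"] == "D0") & (table["dose_uM"] == 20.0)].index)
        fractions, _ = dose_response_fractions(table)
        assert (fractions["n_tested"] == 12).all()

    def test_monotone_flags_from_noise_free_dose_screen(self):
        """Interior-peak compounds are non-monotone; ramp compounds monotone."""
        scenario = DoseResponseScenario(
            n_compounds=12, fraction_interior=0.5, noise_cv=0.0, growth_noise_cv=0.0, rng_seed=3
        )
        measurements, growth, truth = generate_dose_screen(scenario)
        dose_hits = run_dose_screen(measurements, growth)
        _, flags = dose_response_fractions(dose_hits)
        kinds = truth.drop_duplicates("compound_id").set_index("compound_id")["response_type"]
        merged = flags.set_index("compound_id").join(kinds)
        assert (~merged.loc[merged["response_type"] == "interior", "monotone"]).all()
        assert merged.loc[merged["response_type"] == "monotone", "monotone"].all()


class TestQCMetrics:
    @staticmethod
    def corrected_frame(dmso_values):
        return pd.DataFrame(
            {
                "batch_id": "b1",
                "plate_id": "p1",
                "metabolite": "putrescine",
                "species": "Escherichia coli",
                "replicate": 1,
                "role": "dmso_control",
                "compound_id": None,
                "corrected_conc_uM": dmso_values,
            }
        )

    def test_identical_dmso_values_zero_cv(self):
        metrics = qc_metrics(self.corrected_frame([100.0] * 5))
        assert metrics["median_dmso_cv"] == 0.0

    def test_known_cv(self):
        metrics = qc_metrics(self.corrected_frame([90.0, 100.0, 110.0]))
        assert metrics["median_dmso_cv"] == pytest.approx(0.10)

    def test_identical_replicates_correlate_perfectly(self, rng):
        vals = rng.uniform(50, 150, size=10)
        rows = []
        for rep in (1, 2):
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "batch_id": f"b{rep}",
                        "plate_id": f"p{rep}",
                        "metabolite": "putrescine",
                        "species": "Escherichia coli",
                        "replicate": rep,
                        "role": "experimental",
                        "compound_id": f"C{i}",
                        "corrected_conc_uM": v,
                    }
                )
        metrics = qc_metrics(pd.DataFrame(rows))
        assert metrics["median_replicate_r"] == pytest.approx(1.0)

    def test_screen_level_qc_close_to_generator_noise(self, small_result):
        """Median DMSO CV of the corrected screen tracks the simulated 9.4%."""
        metrics = qc_metrics(small_result["corrected"])
        assert 0.05 < metrics["median_dmso_cv"] < 0.15
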