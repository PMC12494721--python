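import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aminescreen.config import ScreenConfig
from aminescreen.hits import (
    bh_adjust,
    call_hits,
    classify_concordance,
    plate_zscore,
    replicate_stats,
    z_to_pvalue,
)
from aminescreen.pipeline import run_screen


def bh_by_hand(pvalues):
    """Independent step-up BH: sort, q_i = p_i * n / rank, enforce
    monotonicity from the largest rank down, cap at 1."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    q = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * n / rank_from_top)
        q[i] = min(running, 1.0)
    return q


class TestPlateZscore:
    def test_at_reference_median(self):
        assert plate_zscore(10.0, 10.0, 2.0) == 0.0

    def test_two_sd_above(self):
        assert plate_zscore(14.0, 10.0, 2.0) == pytest.approx(2.0)

    def test_zero_sd_flags_plate(self):
        assert math.isnan(plate_zscore(14.0, 10.0, 0.0))


class TestZToPvalue:
    def test_zero_z_two_sided(self):
        assert z_to_pvalue(0.0) == pytest.approx(1.0)

    def test_critical_value(self):
        assert z_to_pvalue(1.959964) == pytest.approx(0.05, abs=1e-6)

    def test_symmetry(self):
        assert z_to_pvalue(-3.0) == z_to_pvalue(3.0)

    def test_matches_erfc_oracle(self, rng):
        for z in rng.normal(0, 2, size=100):
            expected = min(math.erfc(abs(z) / math.sqrt(2)), 1.0)
            assert z_to_pvalue(z) == pytest.approx(expected, abs=1e-12)
        for z in rng.normal(0, 2, size=100):
            expected = 0.5 * math.erfc(z / math.sqrt(2))
            assert z_to_pvalue(z, "one_sided_upper") == pytest.approx(expected, abs=1e-12)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5, 1.0], [1.0, 1.0]),
        ],
    )
    def test_known_cases(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-15)

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 50))
            np.testing.assert_allclose(bh_adjust(p), bh_by_hand(p.tolist()), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 1), min_size=2, max_size=20),
        st.data(),
    )
    def test_monotone_in_inputs(self, p, data):
        """Raising one p-value never lowers any adjusted value."""
        i = data.draw(st.integers(0, len(p) - 1))
        bump = data.draw(st.floats(0, 1))
        q1 = bh_adjust(p)
        p2 = list(p)
        p2[i] = min(1.0, p2[i] + bump)
        q2 = bh_adjust(p2)
        assert (np.asarray(q2) >= np.asarray(q1) - 1e-12).all()


def make_stats(fc_pairs, p_adj_pairs):
    rows = []
    for i, ((fc1, fc2), (q1, q2)) in enumerate(zip(fc_pairs, p_adj_pairs)):
        for rep, fc, q in ((1, fc1, q1), (2, fc2, q2)):
            rows.append(
                {
                    "role": "experimental",
                    "compound_id": f"C{i}",
                    "species": "Escherichia coli",
                    "metabolite": "putrescine",
                    "replicate": rep,
                    "z": 0.0,
                    "p": q,
                    "p_adj": q,
                    "fc": fc,
                }
            )
    return pd.DataFrame(rows)


class TestCallHits:
    def test_hit_rules(self):
        stats = make_stats(
            fc_pairs=[(1.5, 1.4), (1.2, 1.2), (1.6, 0.7)],
            p_adj_pairs=[(0.01, 0.02), (0.001, 0.001), (0.01, 0.01)],
        )
        hits = call_hits(stats).set_index("compound_id")
        # mean log2 fc of (1.5, 1.4) ~ 0.536 > 0.32, both significant, same direction
        assert bool(hits.loc["C0", "is_hit"]) and hits.loc["C0", "direction"] == "up"
        assert hits.loc["C0", "mean_log2_fc"] == pytest.approx(0.536, abs=1e-3)
        # |log2 1.2| = 0.263 <= 0.32 despite tiny p-values
        assert not hits.loc["C1", "is_hit"]
        # opposite directions never qualify
        assert not hits.loc["C2", "is_hit"]

    def test_nonsignificant_replicate_blocks_hit(self):
        stats = make_stats([(1.5, 1.5)], [(0.01, 0.2)])
        assert not call_hits(stats)["is_hit"].iloc[0]

    def test_wrong_replicate_count_skipped(self):
        stats = make_stats([(1.5, 1.5)], [(0.01, 0.01)])
        stats = stats[stats["replicate"] == 1]
        assert call_hits(stats).empty

    def test_unit_invariance(self, small_screen):
        """Scaling every concentration by a constant leaves hit calls fixed."""
        measurements, growth, _, _ = small_screen
        res1 = run_screen(measurements, growth)
        scaled = measurements.copy()
        scaled["raw_conc_uM"] = scaled["raw_conc_uM"] * 3.1
        res2 = run_screen(scaled, growth)
        key = ["compound_id", "species", "metabolite"]
        h1 = res1["hits"].sort_values(key).reset_index(drop=True)
        h2 = res2["hits"].sort_values(key).reset_index(drop=True)
        pd.testing.assert_series_equal(h1["is_hit"], h2["is_hit"])
        np.testing.assert_allclose(h1["mean_log2_fc"], h2["mean_log2_fc"], rtol=1e-9)


class TestConcordance:
    @pytest.mark.parametrize(
        "growth_fc,metab_fc,expected",
        [
            (0.5, 0.5, True),  # identical fold changes
            (1.0, 2.0, False),  # difference 1.0
            (1.0, 1.25, False),  # boundary: 0.25 is not < 0.25
            (1.0, 1.24, True),
        ],
    )
    def test_strict_threshold(self, growth_fc, metab_fc, expected):
        assert classify_concordance(growth_fc, metab_fc, 0.25) is expected

    def test_missing_growth_propagates(self):
        assert classify_concordance(float("nan"), 1.0, 0.25) is None


class TestReplicateStats:
    def test_bh_applied_within_species_metabolite_replicate(self, small_result):
        stats = small_result["stats"]
        exp = stats[stats["role"] == "experimental"]
        for _, grp in exp.groupby(["species", "metabolite", "replicate"], observed=True):
            finite = grp.dropna(subset=["p", "p_adj"])
            np.testing.assert_allclose(
                finite["p_adj"], bh_by_hand(finite["p"].tolist()), atol=1e-10
            )

    def test_dmso_wells_receive_stats_but_not_hits(self, small_result):
        stats = small_result["stats"]
        dmso = stats[stats["role"] == "dmso_control"]
        assert dmso["z"].notna().any()
        assert dmso["p_adj"].isna().all()  # adjustment covers compounds only
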