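import numpy as np
import pandas as pd
import pytest
from scipy import stats

from colonyarray import interaction_analysis as ia


class TestRatioAndDiff:
    def test_ratio_reflects_relative_interaction_strength(self):
        # wild-type-like strain 1.0 -> 0.8 and slow strain 0.4 -> 0.2:
        # the ratio separates them (0.8 vs 0.5) while the diff does not
        assert ia.ratio_score(1.0, 0.8) == pytest.approx(0.8)
        assert ia.ratio_score(0.4, 0.2) == pytest.approx(0.5)

    def test_ratio_identity_and_errors(self):
        for c in (0.2, 1.0, 3.7):
            assert ia.ratio_score(c, c) == pytest.approx(1.0)
        assert ia.ratio_score(0.5, 0.25) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            ia.ratio_score(0.0, 0.5)

    def test_diff_magnitudes_equal_for_both_strains(self):
        assert ia.diff_score(1.0, 0.8) == pytest.approx(-0.2)
        assert ia.diff_score(0.4, 0.2) == pytest.approx(-0.2)
        assert ia.diff_score(0.3, 0.9) == pytest.approx(0.6)
        assert ia.diff_score(1.1, 1.1) == 0.0

    def test_diff_equals_ctrl_times_ratio_minus_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = rng.uniform(0.05, 2.0)
            e = rng.uniform(0.0, 2.0)
            assert ia.diff_score(c, e) == pytest.approx(
                c * (ia.ratio_score(c, e) - 1.0))


class TestPairedTTest:
    def test_closed_form_three_replicates(self):
        # d = (-0.5, -0.4, -0.3): mean -0.4, sd 0.1,
        # t = -0.4/(0.1/sqrt(3)) = -6.928 on 2 df
        p = ia.paired_t_test([1.0, 1.0, 1.0], [0.5, 0.6, 0.7])
        t = -0.4 / (0.1 / np.sqrt(3))
        expected = 2 * stats.t.cdf(t, df=2)
        assert p == pytest.approx(expected, rel=1e-6)
        assert p == pytest.approx(0.0202, abs=5e-4)

    def test_identical_pairs_give_p_one(self):
        assert ia.paired_t_test([1.0, 1.1, 0.9], [1.0, 1.1, 0.9]) == 1.0

    def test_constant_nonzero_difference_gives_p_zero(self):
        assert ia.paired_t_test([1, 2], [2, 3]) == 0.0

    def test_single_replicate_gives_nan(self):
        assert np.isnan(ia.paired_t_test([1.0], [0.5]))


def _toy_table(ctrl, exp, orf=None):
    n = len(ctrl[0])
    data = {"plate": [], "row": [], "col": [], "orf": [], "gene": []}
    for i in range(len(ctrl)):
        data["plate"].append(1)
        data["row"].append(1)
        data["col"].append(i + 1)
        data["orf"].append(orf[i] if orf else f"Y{i:03d}W")
        data["gene"].append("")
    table = pd.DataFrame(data)
    for j in range(n):
        table[f"ctrl_{j + 1}"] = [c[j] for c in ctrl]
        table[f"exp_{j + 1}"] = [e[j] for e in exp]
    table["excluded"] = False
    table["exclude_reason"] = ""
    return table


class TestFilters:
    def test_clamp_floor_makes_lethal_interactions_equal(self):
        table = _toy_table([(1.0, 1.0, 1.0)] * 3,
                           [(0.0, 0.0, 0.0), (0.01, 0.01, 0.01),
                            (0.02, 0.02, 0.02)])
        out = ia.clamp_sizes(table, min_value=0.05, max_value=4.0)
        out = ia.compute_scores(out)
        # the 0.01/0.02 rows clamp to 0.05 -> identical ratios; exact
        # zeros are empty positions, not clamped
        assert out.loc[1, "ratio"] == pytest.approx(0.05)
        assert out.loc[2, "ratio"] == pytest.approx(0.05)

    def test_clamp_ceiling(self):
        table = _toy_table([(1.0, 1.0)], [(3.0, 3.0)])
        out = ia.clamp_sizes(table, min_value=0.05, max_value=2.0)
        assert (out[["exp_1", "exp_2"]].to_numpy() == 2.0).all()

    def test_clamp_within_bounds_unchanged(self):
        table = _toy_table([(1.0, 0.9)], [(1.1, 1.2)])
        out = ia.clamp_sizes(table, min_value=0.05, max_value=4.0)
        pd.testing.assert_frame_equal(out, table)

    def test_slow_growth_zeroes_both_sides_of_pair(self):
        table = _toy_table([(0.05, 1.0, 1.0)], [(0.9, 1.0, 1.1)])
        out = ia.slow_growth_filter(table, threshold=0.1, apply_to="control")
        assert out.loc[0, "ctrl_1"] == 0.0 and out.loc[0, "exp_1"] == 0.0
        assert out.loc[0, "ctrl_2"] == 1.0

    def test_slow_growth_experiment_side(self):
        table = _toy_table([(1.0, 1.0)], [(0.05, 1.0)])
        out = ia.slow_growth_filter(table, threshold=0.1,
                                    apply_to="experiment")
        assert out.loc[0, "ctrl_1"] == 0.0 and out.loc[0, "exp_1"] == 0.0

    def test_slow_growth_above_threshold_unchanged(self):
        table = _toy_table([(0.5, 0.6)], [(0.7, 0.8)])
        out = ia.slow_growth_filter(table, threshold=0.1)
        pd.testing.assert_frame_equal(out, table)

    def test_linkage_exclusion_marks_only_listed_orfs(self):
        table = _toy_table([(1, 1)] * 3, [(1, 1)] * 3,
                           orf=["YAL001C", "YBL002W", "YCL003C"])
        out = ia.linkage_exclude(table, ["YAL001C"])
        assert out.loc[0, "excluded"]
        assert out.loc[0, "exclude_reason"] == "linkage"
        assert not out.loc[1, "excluded"]
        # empty exclusion list is the identity
        out2 = ia.linkage_exclude(table, [])
        assert not out2["excluded"].any()


class TestEstimateCutoffs:
    def test_analytic_central_line_extrapolation(self):
        # central 80% of ranks exactly linear from 0.9 to 1.1; the line
        # has slope 0.2/(0.8*(N-1)) so its value at rank 0 is
        # 0.9 - 0.2*(0.1/0.8) = 0.875 and at rank N-1 is 1.125
        n = 1000
        ranks = np.arange(n)
        lo, hi = int(0.1 * n), int(0.9 * n)
        slope = 0.2 / (hi - 1 - lo)
        y = 0.9 + (ranks - lo) * slope
        y[:lo] = 0.9 - (lo - ranks[:lo]) * 0.01  # steep aggravating tail
        y[hi:] = 1.1 + (ranks[hi:] - hi + 1) * 0.01  # steep alleviating tail
        cut = ia.estimate_cutoffs(np.sort(y))
        p_expected = 0.9 - lo * slope
        q_expected = 0.9 + (n - 1 - lo) * slope
        assert cut.low == pytest.approx(p_expected, abs=0.01)
        assert cut.high == pytest.approx(q_expected, abs=0.01)
        assert p_expected == pytest.approx(0.875, abs=1e-3)

    def test_degenerate_ratios_rejected(self):
        with pytest.raises(ValueError):
            ia.estimate_cutoffs(np.ones(500))

    def test_outliers_fall_outside_band(self):
        rng = np.random.default_rng(42)
        ratios = rng.normal(1.0, 0.02, 950)
        outliers = np.r_[np.full(25, 0.4), np.full(25, 1.6)]
        cut = ia.estimate_cutoffs(np.r_[ratios, outliers])
        assert 0 < cut.low < 1 < cut.high
        assert (0.4 < cut.low) and (1.6 > cut.high)

    def test_too_few_ratios_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            ia.estimate_cutoffs(np.linspace(0.9, 1.1, 50))


class TestCallHits:
    CUT = ia.CutoffPair(0.895, 1.106)

    def _scored(self, ctrl, exp):
        return ia.compute_scores(_toy_table(ctrl, exp))

    def test_all_three_criteria_met_is_aggravating(self):
        table = self._scored([(1.0, 1.0, 1.0)], [(0.5, 0.55, 0.52)])
        out = ia.call_hits(table, self.CUT, min_replicates=3, max_p=0.05)
        assert out.loc[0, "hit"] == "aggravating"
        assert out.loc[0, "n_below"] == 3

    def test_replicate_criterion_blocks_hit(self):
        # ratio below the cut-off in only 2 of 3 replicates
        table = self._scored([(1.0, 1.0, 1.0)], [(0.5, 0.55, 0.95)])
        out = ia.call_hits(table, self.CUT, min_replicates=3, max_p=0.05)
        assert out.loc[0, "n_below"] == 2
        assert out.loc[0, "hit"] == "none"

    def test_p_value_criterion_blocks_hit(self):
        # extreme spread -> ratio criterion met but p-value large
        table = self._scored([(1.0, 1.0, 1.0)], [(0.1, 0.85, 0.6)])
        assert table.loc[0, "p_value"] > 0.05
        out = ia.call_hits(table, self.CUT, min_replicates=2, max_p=0.05)
        assert out.loc[0, "hit"] == "none"

    def test_alleviating_side_symmetric(self):
        table = self._scored([(1.0, 1.0, 1.0)], [(1.5, 1.45, 1.55)])
        out = ia.call_hits(table, self.CUT, min_replicates=3, max_p=0.05)
        assert out.loc[0, "hit"] == "alleviating"
        assert out.loc[0, "n_above"] == 3

    def test_excluded_records_never_hits(self):
        table = _toy_table([(1.0, 1.0, 1.0)], [(0.5, 0.55, 0.52)])
        table = ia.linkage_exclude(table, [table.loc[0, "orf"]])
        table = ia.compute_scores(table)
        out = ia.call_hits(table, self.CUT, min_replicates=3, max_p=0.05)
        assert (out["hit"] == "none").all()

    def test_monotone_in_min_replicates_and_max_p(self):
        rng = np.random.default_rng(1)
        ctrl = [tuple(rng.uniform(0.8, 1.2, 3)) for _ in range(200)]
        exp = [tuple(rng.uniform(0.4, 1.6, 3)) for _ in range(200)]
        table = self._scored(ctrl, exp)

        def n_hits(min_reps, max_p):
            out = ia.call_hits(table, self.CUT, min_reps, max_p)
            return (out["hit"] != "none").sum()

        assert n_hits(3, 0.05) <= n_hits(2, 0.05) <= n_hits(1, 0.05)
        assert n_hits(2, 0.01) <= n_hits(2, 0.05) <= n_hits(2, 0.2)

    def test_hits_sorted_first_strongest_first(self):
        table = self._scored(
            [(1.0, 1.0, 1.0)] * 3,
            [(0.5, 0.52, 0.51), (0.98, 1.0, 1.02), (1.5, 1.52, 1.51)])
        out = ia.call_hits(table, self.CUT, min_replicates=3, max_p=0.05)
        assert list(out["hit"][:2]) == ["aggravating", "alleviating"]
        assert out["hit"].iloc[2] == "none"


class TestDescriptionsAndExport:
    def test_description_filter_substring(self):
        table = _toy_table([(1, 1)] * 3, [(1, 1)] * 3,
                           orf=["YA", "YB", "YC"])
        table = ia.attach_descriptions(table, {
            "YA": "protein retention in Golgi apparatus",
            "YB": "nuclear migration along microtubule",
        })
        assert len(ia.description_filter(table, "golgi")) == 1
        assert len(ia.description_filter(table, "")) == 3
        assert len(ia.description_filter(table, "zzz")) == 0

    def test_export_round_trip(self, tmp_path):
        table = ia.compute_scores(_toy_table(
            [(1.0, 1.0, 1.0)] * 2, [(0.5, 0.55, 0.52), (1.0, 1.0, 1.0)]))
        table = ia.call_hits(table, ia.CutoffPair(0.895, 1.106), 3, 0.05)
        path = tmp_path / "out.tsv"
        ia.export_table(table, path)
        back = ia.read_exported(path)
        assert len(back) == 2
        assert back["hit"].iloc[0] == "aggravating"
        np.testing.assert_allclose(back["ratio"], table["ratio"], rtol=1e-5)

    def test_export_empty_table_header_only(self, tmp_path):
        table = ia.compute_scores(_toy_table([(1.0, 1.0)], [(1.0, 1.0)]))
        table = table.iloc[0:0]
        path = tmp_path / "empty.csv"
        ia.export_table(table, path, fmt="csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
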