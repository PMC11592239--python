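"""Nonparametric statistics against brute-force oracles, and the
end-to-end pipeline report."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from spinefea.report import (
    PipelineConfig,
    PipelineError,
    donor_bmi,
    kruskal_wallis,
    mean_ci95,
    pairwise_mwu_bonferroni,
    run_pipeline,
    spearman,
)
from spinefea.specimens import SpineSpec, default_donor_spine


# ---------------------------------------------------------------------------
# brute-force oracles (independent of scipy)


def kruskal_h_by_hand(groups):
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-ranks, 1-based
        i = j
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def mwu_exact_p_by_hand(x, y):
    """Two-sided exact p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_stat(ix):
        xs = pooled[list(ix)]
        ys = pooled[[i for i in range(n + m) if i not in ix]]
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return gt + 0.5 * eq

    observed = u_stat(tuple(range(n)))
    n_total = 0
    n_extreme = 0
    mean_u = n * m / 2.0
    for ix in combinations(range(n + m), n):
        u = u_stat(ix)
        n_total += 1
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            n_extreme += 1
    return n_extreme / n_total


class TestKruskalWallis:
    def test_no_tie_fixture_gives_h_7_2(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = kruskal_wallis(groups)
        assert res.h == pytest.approx(7.2)
        assert res.h == pytest.approx(kruskal_h_by_hand([np.array(g, float) for g in groups]))
        assert res.df == 2

    def test_identical_groups_degenerate(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5], [5, 5, 5, 5]])
        assert res.h == 0.0 and res.p == 1.0

    def test_group_order_invariance(self):
        a = kruskal_wallis([[1, 5, 9], [2, 4, 8], [3, 6, 7]])
        b = kruskal_wallis([[3, 6, 7], [1, 5, 9], [2, 4, 8]])
        assert a.h == pytest.approx(b.h)

    def test_tied_data_matches_hand_computation(self):
        groups = [np.array([1.0, 2.0, 2.0]), np.array([2.0, 3.0, 4.0])]
        res = kruskal_wallis(groups)
        # tie correction: H / (1 - sum(t^3 - t)/(N^3 - N))
        h_raw = kruskal_h_by_hand(groups)
        correction = 1 - (3**3 - 3) / (6**3 - 6)
        assert res.h == pytest.approx(h_raw / correction)


class TestMannWhitney:
    def test_disjoint_three_vs_three_exact_p(self):
        mat = pairwise_mwu_bonferroni([[1, 2, 3], [10, 11, 12]], ["a", "b"])
        # single pair: bonferroni multiplier 1, exact two-sided p = 2/20
        assert mat.loc["a", "b"] == pytest.approx(0.1)
        assert mat.loc["a", "b"] == pytest.approx(
            mwu_exact_p_by_hand(np.array([1.0, 2, 3]), np.array([10.0, 11, 12]))
        )

    def test_identical_groups_adjusted_to_one(self):
        mat = pairwise_mwu_bonferroni([[3, 3, 3], [3, 3, 3]], ["a", "b"])
        assert mat.loc["a", "b"] == 1.0

    def test_three_groups_use_multiplier_three(self):
        g1, g2, g3 = [1, 2, 3], [10, 11, 12], [20, 21, 22]
        mat = pairwise_mwu_bonferroni([g1, g2, g3], ["a", "b", "c"])
        raw = 0.1  # exact two-sided p for each disjoint pair
        for i, j in (("a", "b"), ("a", "c"), ("b", "c")):
            assert mat.loc[i, j] == pytest.approx(min(1.0, raw * 3))

    def test_undersized_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            mat = pairwise_mwu_bonferroni([[1, 2, 3], [9], [4, 5, 6]], ["a", "b", "c"])
        assert list(mat.index) == ["a", "c"]


class TestSpearman:
    def test_monotone_perfect_correlation(self):
        res = spearman([1, 2, 3, 4], [10, 20, 40, 80])
        assert res.r_s == pytest.approx(1.0)
        res = spearman([1, 2, 3, 4], [80, 40, 20, 10])
        assert res.r_s == pytest.approx(-1.0)

    def test_rank_formula_fixture(self):
        """x=1..5, y=[2,1,4,3,5]: d = (-1,1,-1,1,0), sum d^2 = 4,
        r_S = 1 - 6*4/(5*24) = 0.8 (hand rank-difference formula)."""
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        d2 = sum((xi - yi) ** 2 for xi, yi in zip(x, y))
        hand = 1 - 6 * d2 / (5 * (25 - 1))
        res = spearman(x, y)
        assert hand == pytest.approx(0.8)
        assert res.r_s == pytest.approx(hand)

    def test_zero_rank_variance_reported(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(res.r_s) and res.note


class TestMeanCi95:
    def test_constant_samples_zero_width(self):
        mean, lo, hi = mean_ci95([4.0, 4.0, 4.0])
        assert mean == lo == hi == 4.0

    def test_hand_computed_t_interval(self):
        mean, lo, hi = mean_ci95([1.0, 2.0, 3.0, 4.0])
        assert mean == pytest.approx(2.5)
        assert hi - mean == pytest.approx(2.0542, abs=2e-3)  # 3.1824*1.2910/2

    def test_interval_widens_with_fewer_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        _, lo6, hi6 = mean_ci95(x)
        _, lo3, hi3 = mean_ci95([1.0, 3.5, 6.0])  # similar sd, n=3
        assert (hi3 - lo3) > (hi6 - lo6)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            mean_ci95([1.0])


class TestDonorBmi:
    @pytest.mark.parametrize(
        "mass,height,expected",
        [(104.5, 1.61, 40.3), (100.0, 1.0, 100.0), (72.0, 1.2, 50.0)],
    )
    def test_values(self, mass, height, expected):
        assert donor_bmi(mass, height) == expected

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            donor_bmi(0.0, 1.6)


# ---------------------------------------------------------------------------
# pipeline


def _small_spine(seed=4):
    full = default_donor_spine(noise_seed=seed)
    return SpineSpec(
        vertebrae=[full["C3"], full["Th8"], full["L1"]],
        body_mass=full.body_mass,
        body_height_m=full.body_height_m,
        noise_seed=seed,
    )


class TestPipeline:
    def test_small_run_structure(self):
        rep = run_pipeline(_small_spine(), PipelineConfig(edge_target=2.5))
        assert len(rep.fe_table) == 3
        assert len(rep.thickness.samples) == 3 * 4 * 30
        assert set(rep.fe_table["section"]) == {"CS", "TS", "LS"}
        assert (rep.fe_table["crth_source"] == "measured").all()
        assert rep.provenance["bmi_kg_m2"] == 40.3
        assert (rep.fe_table["cortical_stress"] > rep.fe_table["cancellous_stress"]).all()

    def test_rerun_same_seed_byte_identical_csv(self, tmp_path):
        cfg = PipelineConfig(edge_target=3.0)
        rep1 = run_pipeline(_small_spine(9), cfg)
        rep2 = run_pipeline(_small_spine(9), cfg)
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        rep1.write_csv(d1)
        rep2.write_csv(d2)
        for name in ("fe_summaries.csv", "thickness_samples.csv", "hu_table.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_stage_error_names_vertebra_and_stage(self):
        cfg = PipelineConfig(roi_radius_frac=2.0)  # ROI larger than the body
        with pytest.raises(PipelineError, match="roi_mean_hu.*C3"):
            run_pipeline(_small_spine(), cfg)

    def test_summary_text_and_plot(self, tmp_path):
        rep = run_pipeline(_small_spine(), PipelineConfig(edge_target=3.0))
        text = rep.summary()
        assert "Cortical thickness" in text and "Assumptions" in text
        rep.plot_summaries(tmp_path / "fig.png")
        assert (tmp_path / "fig.png").stat().st_size > 0


class TestFullDonorRun:
    """Properties of the complete 22-vertebra reference run."""

    def test_counts(self, donor_report):
        assert len(donor_report.fe_table) == 22
        assert len(donor_report.thickness.samples) == 1800

    def test_cortical_stress_medians_increase_craniocaudally(self, donor_report):
        med = donor_report.fe_table.groupby("section")["cortical_stress"].median()
        assert med["CS"] < med["TS"] < med["LS"]

    def test_cortical_to_cancellous_ratio_at_least_ten(self, donor_report):
        t = donor_report.fe_table
        assert ((t["cortical_stress"] / t["cancellous_stress"]) >= 10).all()

    def test_cancellous_stress_within_one_order_across_sections(self, donor_report):
        med = donor_report.fe_table.groupby("section")["cancellous_stress"].median()
        assert med.max() / med.min() < 10.0

    def test_thickness_interpolated_for_levels_without_micro_ct(self, donor_report):
        t = donor_report.fe_table.set_index("vertebra")
        assert t.loc["Th3", "crth_source"] == "section_median"
        assert t.loc["Th9", "crth_source"] == "measured"

    def test_statistics_block_complete(self, donor_report):
        s = donor_report.stats
        assert 0 <= s["kw_thickness_sections"].p <= 1
        mat = s["mwu_hu_sections"]
        assert isinstance(mat, pd.DataFrame)
        assert set(mat.index) == {"CS", "TS", "LS"}
        assert s["spearman_hu_vs_crth"].n == 15
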