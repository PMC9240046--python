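"""Statistical routines against hand-worked and simulation oracles."""

import numpy as np
import pandas as pd
import pytest

from onhmorph.stats import (
    StatsError,
    build_tables,
    compare_three_groups,
    compare_two_groups,
    dunn_posthoc,
    icc_two_observers,
    regress_hrw_on_lcci,
)


class TestThreeGroups:
    def test_kruskal_wallis_hand_worked_example(self):
        """A={1,2}, B={3,4}, C={5,6}: rank sums 3/7/11 give H = 32/7."""
        groups = {"A": np.array([1.0, 2]), "B": np.array([3.0, 4]), "C": np.array([5.0, 6])}
        res = compare_three_groups(groups)
        assert res.test_used == "KruskalWallis"  # n < 3 per group: gate refuses ANOVA
        assert res.statistic == pytest.approx(32 / 7, abs=1e-9)

    def test_identical_distributions_give_flat_pattern(self):
        rng = np.random.default_rng(7)
        groups = {g: rng.normal(0, 1, 31) for g in ("A", "B", "C")}
        res = compare_three_groups(groups)
        assert "<" not in res.pattern
        assert res.omnibus_p > 0.05

    def test_separated_groups_ordered_pattern(self):
        rng = np.random.default_rng(8)
        groups = {
            "A": rng.normal(0, 1, 31),
            "B": rng.normal(3, 1, 31),
            "C": rng.normal(6, 1, 31),
        }
        res = compare_three_groups(groups)
        assert res.test_used == "ANOVA"
        assert res.pattern == "A < B < C"
        assert res.omnibus_p < 1e-6

    def test_non_normal_data_takes_kruskal_wallis(self):
        rng = np.random.default_rng(9)
        groups = {g: rng.standard_cauchy(31) for g in ("A", "B", "C")}
        res = compare_three_groups(groups)
        assert res.test_used == "KruskalWallis"

    def test_tukey_pairwise_invariant_to_relabeling(self):
        rng = np.random.default_rng(10)
        data = {g: rng.normal(i, 1, 31) for i, g in enumerate(("A", "B", "C"))}
        res1 = compare_three_groups(data)
        relabeled = {"C": data["A"], "A": data["B"], "B": data["C"]}
        res2 = compare_three_groups(relabeled)
        assert sorted(res1.pairwise.values()) == pytest.approx(
            sorted(res2.pairwise.values())
        )

    def test_pattern_requires_significance_and_mean_order(self):
        means = {"A": 1.0, "B": 2.0, "C": 3.0}
        pairwise = {("A", "B"): 0.01, ("B", "C"): 0.5, ("A", "C"): 0.01}
        from onhmorph.stats import _pattern

        assert _pattern(means, pairwise, 0.05) == "A < B = C"

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError):
            compare_three_groups({"A": [1.0], "B": [1.0, 2], "C": [1.0, 2]})
        with pytest.raises(StatsError):
            compare_three_groups(
                {g: np.ones(5) for g in ("A", "B", "C")}
            )

    def test_type_one_error_calibration_quick(self):
        """Null rejection rate at alpha=0.05 stays near nominal (200 reps)."""
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 200
        for _ in range(reps):
            groups = {g: rng.normal(50, 10, 31) for g in ("A", "B", "C")}
            rejections += compare_three_groups(groups).omnibus_p < 0.05
        assert 0.01 <= rejections / reps <= 0.10

    def test_dunn_bonferroni_p_clipped_at_one(self):
        rng = np.random.default_rng(12)
        groups = {g: rng.normal(0, 1, 20) for g in ("A", "B", "C")}
        ps = dunn_posthoc(groups)
        assert all(0 <= p <= 1 for p in ps.values())


class TestTwoGroups:
    def test_identical_paired_samples_p_one(self):
        x = np.array([1.0, 2, 3, 4, 5])
        p, name = compare_two_groups(x, x.copy(), paired=True)
        assert p == 1.0
        assert name == "wilcoxon"

    def test_paired_length_mismatch(self):
        with pytest.raises(StatsError):
            compare_two_groups([1.0, 2, 3], [1.0, 2], paired=True)

    def test_heavy_tailed_samples_use_mann_whitney(self):
        rng = np.random.default_rng(13)
        x, y = rng.standard_cauchy(40), rng.standard_cauchy(40)
        _, name = compare_two_groups(x, y)
        assert name == "mannwhitney"

    def test_normal_samples_use_t(self):
        rng = np.random.default_rng(14)
        _, name = compare_two_groups(rng.normal(0, 1, 31), rng.normal(0, 1, 31))
        assert name == "t"

    def test_power_with_three_sd_gap(self):
        """n=31 with a 3-SD mean gap: p < 0.001 in effectively every draw."""
        rng = np.random.default_rng(15)
        hits = 0
        reps = 100
        for _ in range(reps):
            p, _ = compare_two_groups(rng.normal(0, 1, 31), rng.normal(3, 1, 31))
            hits += p < 0.001
        assert hits / reps >= 0.99


class TestICC:
    def test_duplicated_data_gives_exact_one(self):
        x = np.array([3.0, 5, 9, 2, 7, 4])
        res = icc_two_observers(x, x.copy())
        assert res.icc == 1.0
        assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_mean_squares_oracle(self):
        """ICC(2,1) from the classical mean-squares decomposition, n=6."""
        obs1 = np.array([9.0, 6, 8, 7, 10, 6])
        obs2 = np.array([2.0, 1, 4, 1, 5, 2])
        data = np.column_stack([obs1, obs2])
        n, k = data.shape
        grand = data.mean()
        row_means = data.mean(axis=1)
        col_means = data.mean(axis=0)
        ss_rows = k * np.sum((row_means - grand) ** 2)
        ss_cols = n * np.sum((col_means - grand) ** 2)
        ss_total = np.sum((data - grand) ** 2)
        ss_err = ss_total - ss_rows - ss_cols
        msr = ss_rows / (n - 1)
        msc = ss_cols / (k - 1)
        mse = ss_err / ((n - 1) * (k - 1))
        icc_oracle = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        res = icc_two_observers(obs1, obs2)
        assert res.icc == pytest.approx(icc_oracle, abs=1e-6)

    def test_noise_drowns_agreement(self):
        rng = np.random.default_rng(16)
        x = rng.normal(100, 5, 60)
        res = icc_two_observers(x, x + rng.normal(0, 100, 60))
        assert res.icc < 0.3
        assert res.ci_low <= res.icc <= res.ci_high

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            icc_two_observers(np.ones(6), np.ones(6))


class TestRegression:
    def _table(self, x, y):
        return pd.DataFrame(
            {"group": "NTG", "mean_lcci": x, "mean_hrw": y}
        )

    def test_collinear_r_squared_one(self):
        x = np.linspace(5, 13, 20)
        res = regress_hrw_on_lcci(self._table(x, 400 - 20 * x), groups=("NTG",))
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(-20)

    def test_independent_noise_near_zero_r_squared(self):
        rng = np.random.default_rng(17)
        res = regress_hrw_on_lcci(
            self._table(rng.normal(9, 2, 500), rng.normal(250, 80, 500)),
            groups=("NTG",),
        )
        assert res["r_squared"] < 0.02
        assert res["p_value"] > 0.01

    def test_constant_predictor_rejected(self):
        with pytest.raises(StatsError):
            regress_hrw_on_lcci(self._table(np.ones(10), np.arange(10.0)), groups=("NTG",))


class TestBuildTables:
    def _merged(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        rows = []
        for g, (hrw, mrw, lcci) in {
            "NTG": (160, 110, 10.8),
            "CRAO": (330, 134, 7.1),
            "healthy": (362, 218, 7.1),
        }.items():
            for i in range(n):
                rows.append(
                    {
                        "eye_id": f"{g}-{i}",
                        "group": g,
                        "age": rng.normal(62, 17),
                        "spherical_equivalent": rng.normal(0, 1.5),
                        "iop_at_oct": rng.normal(11, 2),
                        "disc_area": rng.normal(2.5, 0.4),
                        "ovality": rng.normal(1.06, 0.07),
                        "mean_hrw": rng.normal(hrw, 30),
                        "mean_mrw": rng.normal(mrw, 20),
                        "mean_hmr": rng.normal(hrw / mrw, 0.2),
                        "mean_lcci": rng.normal(lcci, 1),
                        "temporal_hrw": rng.normal(hrw, 30),
                        "temporal_mrw": rng.normal(mrw, 20),
                        "temporal_hmr": rng.normal(hrw / mrw, 0.3),
                        **{
                            f"rnfl_{s}": rng.normal(60, 12)
                            for s in (
                                "global", "temporal_superior", "temporal",
                                "temporal_inferior", "nasal_inferior", "nasal",
                                "nasal_superior",
                            )
                        },
                    }
                )
        return pd.DataFrame(rows)

    def test_schema_has_expected_variable_rows(self):
        frames = build_tables(self._merged())
        onh_vars = list(frames["onh"]["variable"])
        assert onh_vars == [
            "Disc area, mm2", "Disc ovality", "Mean HRW, um", "Mean MRW, um",
            "Mean HMR", "Mean LCCI",
        ]
        assert list(frames["temporal"]["variable"]) == [
            "Mean temporal HRW, um", "Mean temporal MRW, um", "Mean temporal HMR",
        ]

    def test_group_means_reported_exactly(self):
        merged = self._merged()
        frames = build_tables(merged)
        row = frames["onh"].set_index("variable").loc["Mean MRW, um"]
        expected = merged[merged.group == "NTG"]["mean_mrw"].mean()
        assert row["NTG_mean"] == pytest.approx(expected)

    def test_missing_variable_column_named(self):
        bad = self._merged().drop(columns=["mean_lcci"])
        with pytest.raises(StatsError, match="mean_lcci"):
            build_tables(bad)
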