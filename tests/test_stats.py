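"""Fatigue classification, ANCOVA, partial correlations, TFCE, permutations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from helpers import brute_force_tfce, naive_partial_correlation, projection_f_test
from hemiacm.phantom import ValidationError
from hemiacm.stats import (
    TfceParams,
    adjusted_correlation,
    classify_fatigue,
    group_ancova,
    permutation_test,
    slice_group_test,
    tfce_transform,
)


class TestClassifyFatigue:
    @pytest.mark.parametrize("score,expected", [(27, "FMS"), (26, "NFMS"), (10, "NFMS"),
                                                (50, "FMS")])
    def test_cutoff(self, score, expected):
        assert classify_fatigue(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_fatigue(9)
        with pytest.raises(ValidationError):
            classify_fatigue(51)


def _toy_table(rng, n_per_group=10, groups=("A", "B"), left_shift=None):
    rows = []
    for g in groups:
        u = rng.normal(0, 1.0, n_per_group)
        left = u + rng.normal(0, 0.5, n_per_group)
        right = u + rng.normal(0, 0.5, n_per_group)
        if left_shift and g == left_shift[0]:
            left = left + left_shift[1]
        for i in range(n_per_group):
            rows.append(
                {"group": g, "left": left[i], "right": right[i],
                 "age": rng.uniform(20, 50), "sex": rng.choice(["F", "M"]),
                 "total_acm": rng.normal(100, 10)}
            )
    return pd.DataFrame(rows)


class TestGroupAncova:
    def test_cloned_groups_have_null_group_effect(self):
        rng = np.random.default_rng(0)
        base = _toy_table(rng, 12, groups=("A",))
        clone = base.copy()
        clone["group"] = "B"
        table = pd.concat([base, clone], ignore_index=True)
        res = group_ancova(table, "left", "right", covariates=("age", "total_acm"))
        assert res["group"]["F"] == pytest.approx(0.0, abs=1e-18)
        assert res["group"]["p"] > 0.999

    def test_f_statistics_match_projection_matrix_oracle(self):
        rng = np.random.default_rng(4)
        table = _toy_table(rng, 8, groups=("A", "B", "C"), left_shift=("B", 1.0))
        res = group_ancova(table, "left", "right", covariates=("age",))

        y_mean = (table["left"] + table["right"]).to_numpy() / 2.0
        y_diff = (table["left"] - table["right"]).to_numpy()
        age = table["age"].to_numpy()
        age_c = age - age.mean()
        d_b = (table["group"] == "B").to_numpy(float)
        d_c = (table["group"] == "C").to_numpy(float)
        ones = np.ones(len(table))
        X_full = np.column_stack([ones, d_b, d_c, age_c])
        X_nogrp = np.column_stack([ones, age_c])
        X_noint = np.column_stack([d_b, d_c, age_c])
        assert res["group"]["F"] == pytest.approx(
            projection_f_test(y_mean, X_full, X_nogrp), rel=1e-8
        )
        assert res["side_by_group"]["F"] == pytest.approx(
            projection_f_test(y_diff, X_full, X_nogrp), rel=1e-8
        )
        assert res["side"]["F"] == pytest.approx(
            projection_f_test(y_diff, X_full, X_noint), rel=1e-8
        )

    def test_interaction_power_with_planted_side_by_group_effect(self):
        # left mean shifted in one group only (d = 1.5 vs observation SD)
        hits = 0
        n_reps = 200
        shift = 1.5 * np.sqrt(1.0 + 0.25)
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            table = _toy_table(rng, 20, groups=("A", "B"), left_shift=("B", shift))
            res = group_ancova(table, "left", "right",
                               covariates=("age", "sex", "total_acm"))
            if res["side_by_group"]["p"] < 0.05:
                hits += 1
        assert hits >= 0.9 * n_reps

    def test_posthoc_runs_only_on_significant_omnibus(self):
        rng = np.random.default_rng(7)
        strong = _toy_table(rng, 15, groups=("A", "B", "C"), left_shift=("B", 3.0))
        res = group_ancova(strong, "left", "right", covariates=("age",))
        assert res["posthoc"]["side_by_group"]
        assert set(res["posthoc"]["side_by_group"]) == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_collinear_design_lists_aliased_columns(self):
        rng = np.random.default_rng(2)
        table = _toy_table(rng, 6)
        table["age2"] = table["age"] * 2.0
        with pytest.raises(ValidationError, match="aliased.*age"):
            group_ancova(table, "left", "right", covariates=("age", "age2"))

    def test_too_small_groups_rejected(self):
        rng = np.random.default_rng(3)
        table = _toy_table(rng, 2)
        with pytest.raises(ValidationError, match="n >= 2"):
            group_ancova(table.iloc[[0, 1, 2]], "left", "right", covariates=())


class TestAdjustedCorrelation:
    def test_identity_gives_r_one(self):
        x = np.arange(10.0)
        res = adjusted_correlation(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_covariate_driven_association_removed(self):
        rng = np.random.default_rng(0)
        n = 500
        z = rng.normal(size=n)
        x = rng.normal(size=n)
        y = z.copy()  # y IS the covariate
        res = adjusted_correlation(x, y, covariates=z)
        assert abs(res.r) < 0.1

    def test_matches_naive_residualization_oracle(self):
        x = np.array([3.1, 4.2, 5.9, 2.6, 5.3, 9.7, 9.3, 2.3, 8.4, 6.2])
        y = np.array([1.0, 2.2, 1.9, 0.6, 3.3, 4.7, 5.3, 1.3, 4.4, 3.2])
        z = np.array([0.4, 0.5, 0.9, 0.1, 0.8, 1.7, 1.3, 0.3, 1.4, 1.0])
        res = adjusted_correlation(x, y, covariates=z)
        assert res.r == pytest.approx(naive_partial_correlation(x, y, z[:, None]), abs=1e-10)
        assert res.df == 10 - 1 - 2

    def test_agrees_with_pingouin_partial_corr(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n = 40
        df = pd.DataFrame(
            {"x": rng.normal(size=n), "y": rng.normal(size=n),
             "c1": rng.normal(size=n), "c2": rng.normal(size=n)}
        )
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        ours = adjusted_correlation(df["x"], df["y"], covariates=df[["c1", "c2"]].to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError, match="n >"):
            adjusted_correlation([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValidationError, match="zero-variance"):
            adjusted_correlation(np.ones(10), np.arange(10.0))


class TestTfce:
    def test_zero_map_maps_to_zero(self):
        assert tfce_transform(np.zeros((5, 5, 5))).sum() == 0.0

    def test_single_voxel_matches_closed_form_sum(self):
        stat = np.zeros((7, 7, 7))
        stat[3, 3, 3] = 0.73
        params = TfceParams(dh=0.1)
        out = tfce_transform(stat, params)
        hs = np.arange(1, 8) * 0.1  # 0.1 .. 0.7
        expected = np.sum(1.0**0.5 * hs**2 * 0.1)
        assert out[3, 3, 3] == pytest.approx(expected, rel=1e-12)
        assert out.sum() == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_random_maps_match_brute_force(self, connectivity):
        rng = np.random.default_rng(9)
        for _ in range(3):
            stat = rng.normal(0.2, 1.0, size=(6, 6, 6))
            peak = stat.max()
            dh = peak / 40.0
            params = TfceParams(dh=dh, connectivity=connectivity)
            got = tfce_transform(stat, params)
            want = brute_force_tfce(stat, dh, 2.0, 0.5, connectivity)
            assert np.allclose(got, want, atol=1e-9)

    def test_monotone_in_voxel_height(self):
        rng = np.random.default_rng(11)
        stat = rng.normal(0.5, 1.0, size=(6, 6, 6))
        params = TfceParams(dh=0.05)
        base = tfce_transform(stat, params)
        bumped_map = stat.copy()
        bumped_map[2, 2, 2] += 0.5
        bumped = tfce_transform(bumped_map, params)
        assert bumped[2, 2, 2] >= base[2, 2, 2] - 1e-12


class TestPermutationTest:
    def test_exhaustive_case_matches_enumeration_oracle(self):
        import itertools

        rng = np.random.default_rng(21)
        maps = rng.normal(size=(7, 3, 3, 3))
        maps[:4] += 0.8
        labels = np.array(["a"] * 4 + ["b"] * 3)
        params = TfceParams(dh=0.4, n_permutations=5000, connectivity=26)
        res = permutation_test(maps, labels, params)
        assert res.exhaustive and res.n_permutations_used == 35

        flat = maps.reshape(7, -1)
        null = []
        for combo in itertools.combinations(range(7), 4):
            g1 = flat[list(combo)]
            g2 = flat[[i for i in range(7) if i not in combo]]
            t = sps.ttest_ind(g1, g2, axis=0, equal_var=True).statistic
            null.append(brute_force_tfce(t.reshape(3, 3, 3), 0.4, 2.0, 0.5, 26).max())
        null = np.asarray(null)
        assert np.allclose(np.sort(null), np.sort(res.null_max), atol=1e-9)
        t_obs = sps.ttest_ind(flat[:4], flat[4:], axis=0, equal_var=True).statistic
        tfce_obs = brute_force_tfce(t_obs.reshape(3, 3, 3), 0.4, 2.0, 0.5, 26)
        p_expected = (1.0 + (null[None, :] >= tfce_obs.reshape(-1, 1) - 1e-12).sum(axis=1)) / 36.0
        assert np.allclose(res.fwe_p.reshape(-1), p_expected, atol=1e-12)

    def test_p_values_bounded_and_scale_invariant(self):
        rng = np.random.default_rng(2)
        maps = rng.normal(size=(12, 4, 4, 4))
        labels = np.array(["x"] * 6 + ["y"] * 6)
        params = TfceParams(n_permutations=200, rng_seed=3)
        res = permutation_test(maps, labels, params)
        lo = 1.0 / (res.n_permutations_used + 1)
        assert np.all(res.fwe_p >= lo - 1e-12) and np.all(res.fwe_p <= 1.0)
        res_scaled = permutation_test(maps * 11.3, labels, params)
        assert np.allclose(res.fwe_p, res_scaled.fwe_p)

    def test_planted_cluster_detected_reliably(self):
        # strong 8-voxel cluster effect (d = 2), n = 15 per group
        hits = 0
        n_reps = 100
        for rep in range(n_reps):
            rng = np.random.default_rng(3000 + rep)
            maps = rng.normal(size=(30, 6, 6, 6))
            maps[:15, 2:4, 2:4, 2:4] += 2.0
            labels = np.array(["p"] * 15 + ["c"] * 15)
            params = TfceParams(n_permutations=199, dh=0.5, rng_seed=rep)
            res = permutation_test(maps, labels, params)
            if res.fwe_p.min() < 0.05:
                hits += 1
        assert hits >= 80

    def test_group_size_validation(self):
        maps = np.zeros((4, 2, 2, 2))
        with pytest.raises(ValidationError, match="n >= 2"):
            permutation_test(maps, ["a", "a", "a", "b"])


class TestSliceGroupTest:
    def test_null_flag_rate_within_binomial_bounds(self):
        flags, total = 0, 0
        for rep in range(100):
            rng = np.random.default_rng(500 + rep)
            profiles = rng.normal(size=(12, 20))
            groups = np.array(["a"] * 6 + ["b"] * 6)
            out = slice_group_test(profiles, groups)
            flags += int(out["significant"].sum())
            total += len(out)
        lo = sps.binom.ppf(0.005, total, 0.05)
        hi = sps.binom.ppf(0.995, total, 0.05)
        assert lo <= flags <= hi

    def test_planted_shift_flags_concentrate_on_affected_slices(self):
        rng = np.random.default_rng(17)
        profiles = rng.normal(size=(30, 30))
        profiles[:15, 10:21] += 2.5
        groups = np.array(["p"] * 15 + ["c"] * 15)
        out = slice_group_test(profiles, groups)
        flagged = set(out.loc[out["significant"], "slice"])
        assert len(flagged & set(range(10, 21))) >= 9
        assert len(flagged - set(range(10, 21))) <= 3

    def test_degenerate_variance_slice_skipped_with_warning(self):
        profiles = np.random.default_rng(0).normal(size=(8, 3))
        profiles[:, 1] = 5.0  # zero variance in both groups
        groups = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.warns(UserWarning, match="degenerate"):
            out = slice_group_test(profiles, groups)
        assert 1 not in set(out["slice"])

    def test_undefined_slices_skipped(self):
        profiles = np.full((8, 2), np.nan)
        profiles[:, 0] = np.random.default_rng(1).normal(size=8)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        out = slice_group_test(profiles, groups)
        assert set(out["slice"]) == {0}
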