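"""Rank tests, effect sizes, the mixed model and report plumbing."""

import itertools
import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from hyperph.cohort import make_voxel_table
from hyperph.stats import (
    CohortTable,
    cohens_d,
    fit_mixed_model,
    mann_whitney_u,
    per_mouse_aggregate,
    spearman,
    write_report,
)


def mw_oracle(a, b):
    """Exhaustive label-assignment enumeration of the U distribution."""
    pooled = np.concatenate([a, b])
    n = pooled.size
    n1 = len(a)

    def u_stat(idx_a):
        ranks = sps.rankdata(pooled)
        return ranks[list(idx_a)].sum() - n1 * (n1 + 1) / 2.0

    obs = u_stat(range(n1))
    us = [u_stat(c) for c in itertools.combinations(range(n), n1)]
    us = np.asarray(us)
    lo = np.mean(us <= obs + 1e-12)
    hi = np.mean(us >= obs - 1e-12)
    return obs, min(1.0, 2.0 * min(lo, hi))


def spearman_oracle_p(x, y):
    """Exhaustive permutation p for the rank correlation."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)

    def corr(yy):
        return np.corrcoef(rx, yy)[0, 1]

    obs = abs(corr(ry))
    count = sum(
        abs(corr(np.asarray(p))) >= obs - 1e-12
        for p in itertools.permutations(ry)
    )
    return count / math.factorial(len(x))


class TestMannWhitney:
    def test_separated_triplets_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_identical_groups_p_one(self):
        assert mann_whitney_u([2.0, 2.0], [2.0, 2.0])[1] == 1.0

    def test_exact_agrees_with_oracle_small_samples(self, rng):
        for trial in range(12):
            n1 = int(rng.integers(1, 5))
            n2 = int(rng.integers(1, 9 - n1))
            a = rng.integers(0, 5, n1).astype(float)  # ties likely
            b = rng.integers(0, 5, n2).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            u, p = mann_whitney_u(a, b)
            u_o, p_o = mw_oracle(a, b)
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_exact_and_normal_approximation_agree(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 1, 6)
        _, p_exact = mann_whitney_u(a, b)
        p_approx = sps.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert p_exact == pytest.approx(p_approx, abs=0.02)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_invariance_under_monotone_transform(self, scale, shift):
        a = np.array([0.3, 1.2, 2.7, 0.9])
        b = np.array([1.9, 3.4, 2.2])
        u1, p1 = mann_whitney_u(a, b)
        u2, p2 = mann_whitney_u(scale * a + shift, scale * b + shift)
        assert u1 == u2 and p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho_r, _ = spearman([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho_r == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])

    def test_permutation_p_matches_enumeration_oracle(self, rng):
        x = rng.normal(size=6)
        y = 0.8 * x + rng.normal(0, 0.5, 6)
        _, p = spearman(x, y)
        assert p == pytest.approx(spearman_oracle_p(x, y), abs=1e-12)

    def test_large_sample_t_approximation_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(0, 1, 30)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestCohensD:
    def test_printed_group_statistics_give_two_point_oh_three(self):
        """Groups constructed to exactly the reported means/SDs: d = 2.03."""

        def sample(mean, sd, n):
            base = np.arange(n, dtype=float)
            base -= base.mean()
            base *= sd / base.std(ddof=1)
            return base + mean

        d = cohens_d(sample(7.53, 0.17, 5), sample(7.22, 0.14, 7))
        assert d == pytest.approx(2.03, abs=0.005)

    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_swapping_groups_flips_sign(self, rng):
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 7)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestMixedModel:
    def test_noiseless_linear_data_recovers_slope_exactly(self):
        df = make_voxel_table(n_voxels=60, n_lesions=6, n_mice=6,
                              slope=-0.15, lesion_sd=0.0, resid_sd=0.0,
                              seed=3)
        fit = fit_mixed_model(df)
        assert fit.slope == pytest.approx(-0.15, abs=1e-6)

    def test_single_lesion_reduces_to_ols(self, rng):
        x = rng.uniform(0, 3, 20)
        y = 7.5 - 0.2 * x + rng.normal(0, 0.05, 20)
        df = pd.DataFrame({"mouse_id": "M0", "lesion_id": "L0",
                           "voxel_id": range(20), "ph": y, "lacpyr": x})
        fit = fit_mixed_model(df)
        ref = sps.linregress(x, y)
        assert fit.method == "ols"
        assert fit.slope == pytest.approx(ref.slope, rel=1e-12)

    def test_variance_components_recovered(self):
        df = make_voxel_table(n_voxels=600, n_lesions=12, n_mice=12,
                              slope=-0.151, lesion_sd=0.10, resid_sd=0.05,
                              seed=11)
        fit = fit_mixed_model(df)
        assert fit.method == "reml"
        assert fit.lesion_var + fit.mouse_var == pytest.approx(0.10**2, rel=0.6)
        assert fit.residual_var == pytest.approx(0.05**2, rel=0.3)

    def test_monte_carlo_slope_coverage(self):
        """Planted slope inside ±2 SE in at least 95% of 200 replicates."""
        hits = 0
        for seed in range(200):
            df = make_voxel_table(n_voxels=153, n_lesions=12, n_mice=10,
                                  slope=-0.151, lesion_sd=0.10,
                                  resid_sd=0.05, seed=seed)
            fit = fit_mixed_model(df)
            if abs(fit.slope - (-0.151)) <= 2.0 * fit.slope_se:
                hits += 1
        assert hits >= 190

    def test_too_few_voxels_rejected(self):
        df = make_voxel_table(n_voxels=20, seed=1).head(5)
        with pytest.raises(ValueError):
            fit_mixed_model(df)


class TestCohortPlumbing:
    def lesion_frame(self):
        return pd.DataFrame([
            {"lesion_id": "L00", "mouse_id": "M00", "grade": "low",
             "histology_index": 1.0, "mean_ph": 7.5, "min_ph": 7.4,
             "mean_lacpyr": 0.8, "max_lacpyr": 1.0, "mean_adc": 1.3e-3,
             "n_voxels_ph": 10},
            {"lesion_id": "L01", "mouse_id": "M00", "grade": "high",
             "histology_index": 2.5, "mean_ph": 7.1, "min_ph": 7.0,
             "mean_lacpyr": 2.0, "max_lacpyr": 2.6, "mean_adc": 0.8e-3,
             "n_voxels_ph": 14},
            {"lesion_id": "L02", "mouse_id": "M01", "grade": "high",
             "histology_index": 2.8, "mean_ph": 7.2, "min_ph": 7.1,
             "mean_lacpyr": 1.8, "max_lacpyr": 2.2, "mean_adc": 0.9e-3,
             "n_voxels_ph": 12},
        ])

    def test_per_mouse_keeps_largest_lesion(self):
        table = CohortTable(lesions=self.lesion_frame())
        out = per_mouse_aggregate(table)
        assert sorted(out.lesions["lesion_id"]) == ["L01", "L02"]

    def test_per_mouse_identity_when_all_single(self):
        df = self.lesion_frame()
        df.loc[1, "mouse_id"] = "M02"
        out = per_mouse_aggregate(CohortTable(lesions=df))
        assert len(out.lesions) == 3

    def test_per_mouse_matches_brute_force_rule(self, rng):
        rows = []
        for i in range(12):
            rows.append({"lesion_id": f"L{i:02d}",
                         "mouse_id": f"M{int(rng.integers(0, 6)):02d}",
                         "grade": "low", "histology_index": 1.0,
                         "n_voxels_ph": int(rng.integers(1, 30))})
        df = pd.DataFrame(rows)
        out = per_mouse_aggregate(CohortTable(lesions=df))
        expected = set()
        for mouse, g in df.groupby("mouse_id"):
            g = g.sort_values(["n_voxels_ph", "lesion_id"],
                              ascending=[False, True], kind="stable")
            expected.add(g.iloc[0]["lesion_id"])
        assert set(out.lesions["lesion_id"]) == expected

    def test_duplicate_voxel_keys_rejected(self):
        vox = pd.DataFrame({"mouse_id": ["M00"] * 2, "lesion_id": ["L00"] * 2,
                            "voxel_id": [1, 1], "ph": [7.1, 7.2],
                            "lacpyr": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicated"):
            CohortTable(lesions=self.lesion_frame(), voxels=vox)

    def test_empty_cohort_report_is_schema_valid(self, tmp_path):
        table = CohortTable(lesions=pd.DataFrame(
            columns=["lesion_id", "mouse_id", "grade"]))
        report = write_report(table, tmp_path)
        assert report["n_lesions"] == 0
        assert (tmp_path / "report.json").exists()

    def test_report_rerun_is_byte_identical(self, tmp_path):
        table = CohortTable(lesions=self.lesion_frame())
        write_report(table, tmp_path / "a")
        write_report(table, tmp_path / "b")
        assert (tmp_path / "a" / "report.json").read_bytes() == (
            tmp_path / "b" / "report.json"
        ).read_bytes()

    def test_report_slope_field_equals_fit(self, tmp_path):
        vox = make_voxel_table(n_voxels=60, n_lesions=6, n_mice=6, seed=5)
        lesions = pd.DataFrame(
            {"lesion_id": sorted(vox["lesion_id"].unique()),
             "mouse_id": "M00", "grade": "low", "histology_index": 1.0})
        table = CohortTable(lesions=lesions, voxels=vox)
        report = write_report(table, tmp_path)
        fit = fit_mixed_model(table)
        assert report["mixed_model"]["slope"] == pytest.approx(fit.slope)
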