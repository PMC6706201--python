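"""Bootstrap, kernel density and the rank-based comparison battery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from seedshadow.core import DistanceSample
from seedshadow.stats import (
    bootstrap_mean,
    compare_methods,
    kernel_density,
    kruskal_wallis,
    ks_two_sample,
    pairwise_wilcoxon,
)


class TestBootstrapMean:
    def test_constant_sample_zero_width_ci(self):
        mean, (lo, hi) = bootstrap_mean([50.0, 50.0, 50.0], n_boot=500, seed=1)
        assert mean == 50.0 and lo == hi == 50.0

    def test_close_to_arithmetic_mean(self, rng):
        x = rng.exponential(200, size=100)
        n_boot = 10_000
        mean, _ = bootstrap_mean(x, n_boot=n_boot, seed=2)
        se_mean = x.std(ddof=1) / math.sqrt(x.size)
        assert abs(mean - x.mean()) < 3 * se_mean / math.sqrt(n_boot) * 10

    def test_deterministic(self, rng):
        x = rng.exponential(200, size=40)
        assert bootstrap_mean(x, seed=9) == bootstrap_mean(x, seed=9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean([])

    def test_coverage_near_nominal(self):
        """Percentile CI covers the true mean ~95% of the time (normal, n=50)."""
        hits = 0
        n_rep = 250
        for i in range(n_rep):
            r = np.random.default_rng(1000 + i)
            x = r.normal(100, 20, size=50)
            _, (lo, hi) = bootstrap_mean(x, n_boot=1000, seed=r)
            hits += lo <= 100 <= hi
        se = math.sqrt(0.95 * 0.05 / n_rep)
        assert abs(hits / n_rep - 0.95) < 3 * se + 0.01


class TestKernelDensity:
    def test_integrates_to_one(self, rng):
        for _ in range(20):
            x = rng.exponential(200, size=int(rng.integers(20, 300)))
            k = kernel_density(x, n_boot=10, seed=rng)
            assert k.integral() == pytest.approx(1.0, abs=0.01)
            assert (k.density >= 0).all()

    def test_bimodal_sample_shows_two_modes(self, rng):
        x = np.concatenate([rng.normal(100, 10, 300), rng.normal(300, 10, 300)])
        x = np.abs(x)
        k = kernel_density(x, n_boot=10, seed=1)
        d = k.density
        interior_max = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])
        modes = k.grid_m[1:-1][interior_max]
        assert any(abs(m - 100) < 30 for m in modes)
        assert any(abs(m - 300) < 30 for m in modes)

    def test_envelope_contains_point_estimate(self, rng):
        x = rng.exponential(150, size=80)
        k = kernel_density(x, n_boot=50, seed=3)
        assert (k.envelope_low <= k.density + 1e-12).all()
        assert (k.envelope_high >= k.density - 1e-12).all()

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError, match="≥5"):
            kernel_density([1.0, 2.0])
        with pytest.raises(ValueError, match="zero-variance"):
            kernel_density([5.0] * 10)


def brute_force_ks(a, b):
    thresholds = np.concatenate([a, b])
    d = 0.0
    for t in thresholds:
        d = max(d, abs(np.mean(a <= t) - np.mean(b <= t)))
    return d


class TestKs:
    def test_identical_samples(self, rng):
        x = rng.uniform(0, 100, size=30)
        d, p = ks_two_sample(x, x)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_fully_separated_samples(self):
        d, _ = ks_two_sample([1, 2, 3, 4], [10, 11, 12, 13])
        assert d == 1.0

    def test_matches_bruteforce_ecdf_sweep(self, rng):
        a = rng.normal(0, 1, size=8)
        b = rng.normal(0.5, 1.2, size=8)
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(brute_force_ks(a, b))


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, df, p = kruskal_wallis([[1, 2], [1, 2]])
        assert h == pytest.approx(0.0) and df == 1

    def test_all_tied_data(self):
        h, df, p = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_df_for_five_methods(self, rng):
        groups = [rng.uniform(0, 1, 10) for _ in range(5)]
        _, df, _ = kruskal_wallis(groups)
        assert df == 4

    def test_p_matches_permutation_oracle(self, rng):
        """Chi-square p agrees with a Monte-Carlo permutation distribution of H."""
        groups = [[12.0, 15.0, 9.0, 22.0], [18.0, 25.0, 30.0], [7.0, 8.0, 16.0, 11.0]]
        h_obs, df, p_chi2 = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        n_perm = 4000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            h_perm, _, _ = kruskal_wallis([list(x) for x in parts])
            count += h_perm >= h_obs - 1e-12
        p_perm = count / n_perm
        se = math.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_chi2 - p_perm) < 4 * se + 0.02


def brute_force_u(a, b):
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else 0.5 if x == y else 0.0
    return u


class TestPairwiseWilcoxon:
    def test_identical_groups_all_ones(self, rng):
        x = list(rng.uniform(0, 1, 12))
        mat = pairwise_wilcoxon({"a": x, "b": x, "c": x})
        off_diag = mat.values[~np.eye(3, dtype=bool)]
        assert (off_diag == 1.0).all()

    def test_five_groups_ten_comparisons(self, rng):
        groups = {m: list(rng.uniform(0, 1, 8)) for m in "abcde"}
        mat = pairwise_wilcoxon(groups)
        assert (~mat.isna()).values.sum() == 20  # 10 pairs, mirrored

    def test_u_statistic_matches_bruteforce(self, rng):
        a = list(rng.integers(0, 50, size=10).astype(float))
        b = list(rng.integers(0, 50, size=12).astype(float))
        u_scipy = float(sps.mannwhitneyu(a, b, alternative="two-sided").statistic)
        assert u_scipy == pytest.approx(brute_force_u(a, b))

    def test_bonferroni_cap(self, rng):
        groups = {m: list(rng.uniform(0, 1, 5)) for m in "abcd"}
        mat = pairwise_wilcoxon(groups)
        assert np.nanmax(mat.values) <= 1.0

    def test_symmetry(self, rng):
        groups = {m: list(rng.uniform(0, 1, 8)) for m in "abc"}
        mat = pairwise_wilcoxon(groups)
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)


def _sample(method, values):
    return DistanceSample(method=method, species="test", values=list(values))


class TestCompareMethods:
    def test_identical_samples_all_null(self, rng):
        x = rng.uniform(50, 400, size=40)
        samples = [_sample(m, x) for m in ("OSD", "GSC", "PAS", "CMG", "IBM")]
        report = compare_methods(samples, n_boot_mean=500, n_boot_kernel=10, seed=1)
        h, df, p = report.kruskal
        assert h == pytest.approx(0.0, abs=1e-9) and df == 4
        off = report.wilcoxon_p.values[~np.eye(5, dtype=bool)]
        assert (off == 1.0).all()

    def test_shifted_samples_detected(self):
        """Power check: a 100 m shift at n = 200 is nearly always significant."""
        detected = 0
        n_seeds = 20
        for i in range(n_seeds):
            r = np.random.default_rng(500 + i)
            a = r.normal(200, 60, 200)
            b = r.normal(300, 60, 200)
            samples = [_sample("OSD", np.abs(a)), _sample("CMG", np.abs(b))]
            report = compare_methods(samples, n_boot_mean=200, n_boot_kernel=10, seed=r)
            detected += report.kruskal[2] < 0.05
        assert detected >= int(0.95 * n_seeds)

    def test_empty_sample_named_in_error(self):
        good = _sample("OSD", [1.0, 2.0])
        bad = DistanceSample(method="GSC", species="test", values=[])
        with pytest.raises(ValueError, match="GSC"):
            compare_methods([good, bad])

    def test_report_round_trips_through_csv(self, tmp_path, rng):
        samples = [
            _sample(m, rng.exponential(200, 50)) for m in ("OSD", "GSC", "CMG")
        ]
        report = compare_methods(samples, n_boot_mean=200, n_boot_kernel=10, seed=2)
        written = report.write_csvs(tmp_path)
        assert all(p.exists() for p in written)
        means = pd.read_csv(tmp_path / "means.csv")
        assert list(means["method"]) == ["OSD", "GSC", "CMG"]
        wil = pd.read_csv(tmp_path / "wilcoxon_matrix.csv", index_col=0)
        assert np.allclose(wil.values, report.wilcoxon_p.values, equal_nan=True, atol=1e-6)
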