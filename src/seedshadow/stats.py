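"""Kernel estimation and method-comparison statistics for SDD samples.

Per-method distance samples are summarised by bootstrap means with
percentile confidence intervals, smoothed into nonparametric dispersal
kernels (reflected-boundary Gaussian KDE with the classic rule-of-thumb
bandwidth) with bootstrap envelopes, and compared with a rank-based
battery: a Kruskal–Wallis omnibus test across methods, pairwise
Wilcoxon rank-sum tests with Bonferroni correction, and pairwise
two-sample Kolmogorov–Smirnov tests on the empirical CDFs (sensitive to
location and shape alike).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DistanceSample

__all__ = [
    "KernelEstimate",
    "ComparisonReport",
    "bootstrap_mean",
    "ecdf",
    "kernel_density",
    "ks_two_sample",
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "compare_methods",
]


@dataclass
class KernelEstimate:
    """Nonparametric dispersal kernel on a fixed distance grid."""

    grid_m: np.ndarray
    density: np.ndarray
    bandwidth: float
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    n_boot: int

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid_m))


@dataclass
class ComparisonReport:
    methods: list[str]
    means: pd.DataFrame          # method, n, mean, boot_mean, ci_low, ci_high
    kruskal: tuple[float, int, float]  # H, df, p
    wilcoxon_p: pd.DataFrame     # Bonferroni-adjusted p, symmetric
    ks_d: pd.DataFrame
    ks_p: pd.DataFrame
    kernels: dict[str, KernelEstimate]

    def write_csvs(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        p = out / "means.csv"
        self.means.to_csv(p, index=False, float_format="%.6f")
        written.append(p)
        h, df, pval = self.kruskal
        p = out / "kw.csv"
        pd.DataFrame({"H": [h], "df": [df], "p": [pval]}).to_csv(p, index=False, float_format="%.6g")
        written.append(p)
        for name, frame in (
            ("wilcoxon_matrix.csv", self.wilcoxon_p),
            ("ks_matrix.csv", self.ks_d),
            ("ks_p_matrix.csv", self.ks_p),
        ):
            p = out / name
            frame.to_csv(p, float_format="%.6g")
            written.append(p)
        for method, k in self.kernels.items():
            p = out / f"kernel_{method}.csv"
            pd.DataFrame(
                {
                    "distance_m": k.grid_m,
                    "density": k.density,
                    "lo": k.envelope_low,
                    "hi": k.envelope_high,
                }
            ).to_csv(p, index=False, float_format="%.8g")
            written.append(p)
        return written

    def summary(self) -> str:
        h, df, pval = self.kruskal
        lines = ["Method comparison", "=================", ""]
        for row in self.means.itertuples():
            lines.append(
                f"  {row.method:>4s}: n={row.n:<5d} mean={row.mean:7.1f} m "
                f"(bootstrap {row.boot_mean:.1f} m, 95% CI {row.ci_low:.1f}–{row.ci_high:.1f})"
            )
        lines.append("")
        lines.append(f"Kruskal–Wallis: H({df}) = {h:.1f}, p = {pval:.3g}")
        lines.append(
            f"Pairwise Wilcoxon (Bonferroni ×{len(self.methods) * (len(self.methods) - 1) // 2}) "
            "and KS matrices written alongside."
        )
        return "\n".join(lines)


def bootstrap_mean(
    sample: Sequence[float],
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Bootstrap mean and percentile CI (resampling with replacement).

    Returns ``(mean_of_bootstrap_means, (ci_low, ci_high))``.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if x.size < 2:
        return float(x[0]), (float(x[0]), float(x[0]))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(means.mean()), (float(lo), float(hi))


def ecdf(sample: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Sorted values and empirical CDF heights (right-continuous)."""
    x = np.sort(np.asarray(sample, dtype=float))
    return x, np.arange(1, x.size + 1) / x.size


def _rot_bandwidth(x: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5)."""
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * x.size ** (-0.2)


def kernel_density(
    sample: Sequence[float],
    n_boot: int = 100,
    seed: int | np.random.Generator = 0,
    n_grid: int = 512,
) -> KernelEstimate:
    """Gaussian KDE of a distance sample with a bootstrap envelope.

    Distances live on [0, ∞), so mass the Gaussian kernels would place
    below zero is reflected at the origin.  The grid spans 0 to
    1.1 × max(sample); the envelope holds pointwise 2.5/97.5 percentiles
    of ``n_boot`` resampled density curves.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError(f"need ≥5 values for a kernel estimate, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample: kernel density undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h = _rot_bandwidth(x)
    grid = np.linspace(0.0, float(x.max()) * 1.1, n_grid)

    norm_const = 1.0 / math.sqrt(2.0 * math.pi)

    def kde(values: np.ndarray) -> np.ndarray:
        z = (grid[:, None] - values[None, :]) / h
        zr = (grid[:, None] + values[None, :]) / h  # reflection at the origin
        dens = (np.exp(-0.5 * z * z) + np.exp(-0.5 * zr * zr)).sum(axis=1)
        return dens * norm_const / (values.size * h)

    density = kde(x)
    boot = np.empty((n_boot, n_grid))
    for b in range(n_boot):
        boot[b] = kde(rng.choice(x, size=x.size, replace=True))
    lo, hi = np.quantile(boot, [0.025, 0.975], axis=0)
    lo = np.minimum(lo, density)
    hi = np.maximum(hi, density)
    return KernelEstimate(
        grid_m=grid,
        density=density,
        bandwidth=h,
        envelope_low=lo,
        envelope_high=hi,
        n_boot=n_boot,
    )


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov: D = sup |ECDF_a − ECDF_b| and p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n ≥ 2")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H, df = k−1, chi-square p.

    Fully tied data (every value identical) gives H = 0, p = 1 rather
    than an error.
    """
    if len(groups) < 2:
        raise ValueError("need ≥2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), df, float(p)


def pairwise_wilcoxon(
    groups: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Bonferroni-adjusted Wilcoxon rank-sum p-values for all pairs.

    Mann–Whitney U with the normal approximation (tie-corrected,
    continuity-corrected); the adjustment multiplies each raw p by
    C(k, 2) and caps at 1.  The diagonal is NaN; the matrix is symmetric.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need ≥2 groups")
    k = len(names)
    n_comparisons = k * (k - 1) // 2
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            a = np.asarray(groups[names[i]], dtype=float)
            b = np.asarray(groups[names[j]], dtype=float)
            if np.ptp(np.concatenate([a, b])) == 0:
                raw = 1.0
            else:
                raw = float(
                    sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
                )
            adj = min(1.0, raw * n_comparisons)
            mat.iloc[i, j] = adj
            mat.iloc[j, i] = adj
    return mat


def compare_methods(
    samples: Sequence[DistanceSample],
    n_boot_mean: int = 10_000,
    n_boot_kernel: int = 100,
    seed: int | np.random.Generator = 0,
) -> ComparisonReport:
    """Full comparison battery over per-method distance samples."""
    if len(samples) < 2:
        raise ValueError("need ≥2 method samples to compare")
    for s in samples:
        if not s.values:
            raise ValueError(f"empty distance sample for method {s.method}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    methods = [s.method for s in samples]
    groups = {s.method: list(s.values) for s in samples}

    rows = []
    for s in samples:
        bmean, (lo, hi) = bootstrap_mean(s.values, n_boot=n_boot_mean, seed=rng)
        rows.append(
            {
                "method": s.method,
                "n": len(s.values),
                "mean": float(np.mean(s.values)),
                "boot_mean": bmean,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    means = pd.DataFrame(rows)

    kw = kruskal_wallis(list(groups.values()))
    wil = pairwise_wilcoxon(groups)

    ks_d = pd.DataFrame(np.nan, index=methods, columns=methods)
    ks_p = pd.DataFrame(np.nan, index=methods, columns=methods)
    for i in range(len(methods)):
        for j in range(i + 1, len(methods)):
            d, p = ks_two_sample(groups[methods[i]], groups[methods[j]])
            ks_d.iloc[i, j] = ks_d.iloc[j, i] = d
            ks_p.iloc[i, j] = ks_p.iloc[j, i] = p

    kernels = {}
    for s in samples:
        if len(s.values) >= 5 and np.ptp(s.values) > 0:
            kernels[s.method] = kernel_density(s.values, n_boot=n_boot_kernel, seed=rng)

    return ComparisonReport(
        methods=methods,
        means=means,
        kruskal=kw,
        wilcoxon_p=wil,
        ks_d=ks_d,
        ks_p=ks_p,
        kernels=kernels,
    )
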