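"""Univariate arm: voxelwise group tests with FDR control, demographic
comparisons, and covariate-adjusted symptom-severity correlations.

Voxelwise inference is a pooled-variance two-sample t-test per in-mask
voxel with Benjamini-Hochberg correction applied separately for each map
kind (four families, mirroring per-parameter reporting). Demographic
tables are checked with summary-statistic t-tests (Welch by default) and
Pearson chi-square without continuity correction. Symptom correlations are
partial Pearson correlations after residualizing on covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .types import ParameterMap


@dataclass
class StatMap:
    """Voxelwise t / p maps with the post-correction significance mask."""

    t_values: np.ndarray
    p_values: np.ndarray
    df: int
    mask: np.ndarray
    sig_mask: np.ndarray
    q: float
    p_cutoff: float


def voxelwise_ttest(
    group1_maps: list[ParameterMap],
    group2_maps: list[ParameterMap],
    q: float = 0.05,
) -> StatMap:
    """Pooled-variance two-sample t per in-mask voxel (group1 - group2),
    BH-corrected at level ``q`` over in-mask voxels.

    Voxels with zero pooled variance get t = 0, p = 1.
    """
    if len(group1_maps) < 2 or len(group2_maps) < 2:
        raise ValueError("need at least 2 subjects per group")
    kinds = {m.kind for m in group1_maps + group2_maps}
    states = {m.state for m in group1_maps + group2_maps}
    if len(kinds) > 1 or len(states) > 1:
        raise ValueError("all maps must share kind and state")
    mask = group1_maps[0].mask
    x1 = np.stack([m.values[mask] for m in group1_maps])
    x2 = np.stack([m.values[mask] for m in group2_maps])
    n1, n2 = x1.shape[0], x2.shape[0]
    df = n1 + n2 - 2
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    s1 = x1.var(axis=0, ddof=1)
    s2 = x2.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2.0 * sp_stats.t.sf(np.abs(t), df), 1.0)
    rejected, cutoff = fdr_bh(p, q)

    t_grid = np.zeros(mask.shape)
    p_grid = np.ones(mask.shape)
    sig_grid = np.zeros(mask.shape, dtype=bool)
    t_grid[mask] = t
    p_grid[mask] = p
    sig_grid[mask] = rejected
    return StatMap(t_values=t_grid, p_values=p_grid, df=df, mask=mask,
                   sig_mask=sig_grid, q=q, p_cutoff=cutoff)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up. Returns (rejected bool array, adaptive
    p cutoff: the largest p among rejections, 0.0 if none)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    rejected = rejected.reshape(p.shape)
    cutoff = float(p[rejected].max()) if rejected.any() else 0.0
    return rejected, cutoff


def two_sample_t_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variance_mode: str = "welch",
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics; returns (t, df, two-sided p).

    ``variance_mode`` selects pooled-variance or Welch (unequal-variance,
    Welch-Satterthwaite df).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    if variance_mode not in ("pooled", "welch"):
        raise ValueError("variance_mode must be 'pooled' or 'welch'")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if variance_mode == "pooled":
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        se = np.sqrt(v1 + v2)
    t = (mean1 - mean2) / se
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], df = 1,
    no continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    res = sp_stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def partial_correlation(
    values: np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson correlation between ``values`` and ``scores`` after
    residualizing both on covariates (plus intercept).

    p is two-sided from t = r sqrt(df / (1 - r^2)) with df = n - k - 2.
    With no covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and scores must be equal-length vectors")
    n = x.shape[0]
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariate rows must match observations")
        k = C.shape[1]
        Z = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("rank-deficient covariate matrix")
    df = n - k - 2
    if df < 1:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        raise ValueError("a residualized variable is constant")
    r = float(np.clip(rx @ ry / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return r, float(p)


def extract_region_means(
    maps: list[ParameterMap], region_mask: np.ndarray
) -> np.ndarray:
    """Per-subject mean of in-region voxel values."""
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ValueError("empty region mask")
    for m in maps:
        if region.shape != m.values.shape:
            raise ValueError("region mask does not match map grid")
        if np.any(region & ~m.mask):
            raise ValueError("region extends outside the analysis mask")
    return np.array([m.values[region].mean() for m in maps])


def symptom_correlations(
    region_values: dict[str, np.ndarray],
    scores: dict[str, np.ndarray],
    covariates: np.ndarray | None,
    correction: str = "bonferroni",
) -> list[dict]:
    """Partial correlations for every region x score pair, with family-wise
    correction over all tested pairs (Bonferroni by default)."""
    results = []
    for region_name, vals in region_values.items():
        for score_name, sc in scores.items():
            r, p = partial_correlation(vals, sc, covariates)
            results.append({"region": region_name, "score": score_name,
                            "r": r, "p": p})
    n_tests = len(results)
    for res in results:
        if correction == "bonferroni":
            res["p_corrected"] = min(1.0, res["p"] * n_tests)
        elif correction == "none":
            res["p_corrected"] = res["p"]
        else:
            raise ValueError(f"unknown correction {correction!r}")
    return results
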