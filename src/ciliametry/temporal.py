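"""Time-of-day statistics on section-level summaries.

One-way ANOVA across zeitgeber times, two-stage linear step-up FDR
correction, region-pair Pearson correlation matrices, and a fixed-period
cosinor fit.  The cosinor is an explicitly labeled stand-in for the
external deep-learning rhythmicity tool used in the original analysis; it
fits a 24-h harmonic by least squares and tests it with a classical F-test,
it does NOT reproduce that tool's null-distribution machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ZT_GRID = tuple(range(0, 24, 2))  # 12 two-hour time points


@dataclass(frozen=True)
class RegionProfile:
    """Per-region section summaries grouped by zeitgeber time."""

    region_label: str
    measure: str                       # "length" or "angle"
    groups: Mapping[float, np.ndarray]  # zt -> section-level values

    def zt_means(self, grid: Sequence[float] = ZT_GRID) -> np.ndarray:
        return np.array([np.mean(self.groups[t]) for t in grid])


@dataclass(frozen=True)
class RhythmFit:
    mesor: float
    amplitude: float
    phase_zt: float
    period_h: float
    p_value: float


def profiles_from_sections(df: pd.DataFrame, measure: str = "length") -> dict[str, RegionProfile]:
    """Build per-region profiles from a section-summary table
    (columns region_label, zt, mean_length_um / circ_mean_angle_deg)."""
    col = {"length": "mean_length_um", "angle": "circ_mean_angle_deg"}[measure]
    out: dict[str, RegionProfile] = {}
    for region, sub in df.groupby("region_label"):
        groups = {float(zt): g[col].to_numpy(float) for zt, g in sub.groupby("zt")}
        out[str(region)] = RegionProfile(str(region), measure, groups)
    return out


def anova_time_effect(profile: RegionProfile) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across ZT groups of section means."""
    groups = [np.asarray(v, float) for v in profile.groups.values()]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 ZT groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each ZT group needs at least 2 sections")
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # all values identical in every group -> no variance at all
        return 0.0, 1.0
    return float(f), float(p)


def fdr_bky(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, int]:
    """Two-stage linear step-up FDR procedure.

    Stage 1 runs a linear step-up test at level alpha/(1+alpha) to estimate
    the number of true nulls m0 = m - r1; stage 2 reruns the step-up test at
    level alpha * m / m0.  Returns (boolean rejection mask, estimated m0).
    Rejections are a superset of the plain step-up (BH) rejections at alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    alpha_prime = alpha / (1.0 + alpha)
    r1 = _stepup_count(p, alpha_prime)
    m0 = m - r1
    if m0 == 0:
        return np.ones(m, dtype=bool), 0
    r2 = _stepup_count(p, alpha * m / m0)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    reject[order[:r2]] = True
    return reject, m0


def _stepup_count(p: np.ndarray, level: float) -> int:
    """Number of rejections of the linear (BH) step-up test at ``level``."""
    m = p.size
    ps = np.sort(p)
    below = ps <= level * np.arange(1, m + 1) / m
    if not below.any():
        return 0
    return int(np.flatnonzero(below).max() + 1)


def fdr_bh(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Plain Benjamini-Hochberg step-up rejection mask (reference method)."""
    p = np.asarray(pvalues, dtype=float)
    k = _stepup_count(p, alpha)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(p.size, dtype=bool)
    reject[order[:k]] = True
    return reject


def region_pair_correlations(profiles: Mapping[str, RegionProfile],
                             grid: Sequence[float] = ZT_GRID,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and p matrices between per-ZT mean profiles of all regions.

    Matrices are symmetric with unit diagonal (p diagonal 0).  A region with
    zero variance across the grid yields NaN entries (flagged via log).
    """
    regions = list(profiles)
    series = {r: profiles[r].zt_means(grid) for r in regions}
    n = len(regions)
    rmat = pd.DataFrame(np.eye(n), index=regions, columns=regions)
    pmat = pd.DataFrame(np.zeros((n, n)), index=regions, columns=regions)
    for i, a in enumerate(regions):
        for j in range(i + 1, n):
            b = regions[j]
            xa, xb = series[a], series[b]
            if np.std(xa) == 0 or np.std(xb) == 0:
                r_val, p_val = np.nan, np.nan
            else:
                r_val, p_val = stats.pearsonr(xa, xb)
            rmat.iloc[i, j] = rmat.iloc[j, i] = r_val
            pmat.iloc[i, j] = pmat.iloc[j, i] = p_val
    return rmat, pmat


def cosinor_fit(times_h, values, period_h: float = 24.0) -> RhythmFit:
    """Least-squares fit of y = M + A*cos(2*pi*(t - phi)/period).

    Linearized as M + b1*cos(wt) + b2*sin(wt); A = sqrt(b1^2 + b2^2) and
    phi = atan2(b2, b1) * period / (2*pi), reduced to [0, period).  The
    p-value is the F-test of the two harmonic terms against the
    intercept-only model.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 4:
        raise ValueError("need matched time/value arrays with >= 4 points")
    if np.unique(t).size < 3:
        raise ValueError("degenerate design: need >= 3 distinct time points")
    w = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, b1, b2 = beta
    amplitude = float(np.hypot(b1, b2))
    phase = float((np.arctan2(b2, b1) * period_h / (2.0 * np.pi)) % period_h)
    resid = y - X @ beta
    rss = float(resid @ resid)
    rss0 = float(((y - y.mean()) ** 2).sum())
    df_num, df_den = 2, t.size - 3
    if df_den <= 0 or rss0 <= 1e-300:
        p_value = 1.0
    elif rss <= 0:
        p_value = 0.0
    else:
        f = ((rss0 - rss) / df_num) / (rss / df_den)
        p_value = float(stats.f.sf(f, df_num, df_den))
    return RhythmFit(mesor=float(mesor), amplitude=amplitude, phase_zt=phase,
                     period_h=period_h, p_value=p_value)


def cosinor_fit_profile(profile: RegionProfile) -> RhythmFit:
    """Cosinor fit on all section-level values of a region profile."""
    ts, ys = [], []
    for zt, vals in profile.groups.items():
        ts.extend([zt] * len(vals))
        ys.extend(vals)
    if len(set(ts)) < 6:
        raise ValueError("need >= 6 distinct ZT points")
    return cosinor_fit(ts, ys)
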