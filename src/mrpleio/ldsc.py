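"""LD-score regression: SNP heritability, cross-trait genetic correlation,
the heritability z-score gate, and intercept diagnostics.

Single-trait model: E[chi2_j] = 1 + N a + (N h2 / M) l_j, fitted as a
weighted regression of chi2 on N_j l_j / M with a free intercept.
Cross-trait model: E[z1_j z2_j] = rho_intercept + (sqrt(N1 N2) gencov / M) l_j,
and rg = gencov / sqrt(h2_1 h2_2).  Standard errors come from a
delete-one-block jackknife over contiguous SNP blocks; heteroskedasticity
weights are updated in two passes (initial slope guess from the mean
statistic, then refit with model-based variances):

    w_j = 1 / (max(l_j, 1) * v_j)   with
    v_j = (1 + N h2 l_j / M)^2                       (single trait)
    v_j = e1_j e2_j + (rho_int + sqrt(N1 N2) gencov l_j / M)^2   (cross),
    e_i,j = 1 + N_i h2_i l_j / M

the first factor correcting for LD-induced overcounting and the second for
the variance of a chi2 / product-normal variate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SummaryStats

DEFAULT_N_BLOCKS = 200
#: chi2 cap before regression: drop SNPs with chi2 > max(80, 0.001 N)
CHI2_CAP_CONST = 80.0
CHI2_CAP_N_FRAC = 0.001


class LDSCError(ValueError):
    pass


@dataclass
class HeritabilityResults:
    """SNP-heritability fit for one trait."""

    trait_name: str
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    mean_chi2: float
    m_snps_used: int
    n_blocks_used: int

    @property
    def z_score(self) -> float:
        return self.h2 / self.h2_se

    def summary(self) -> str:
        return (f"LD-score regression: {self.trait_name}\n"
                f"  h2        {self.h2:.4f} ({self.h2_se:.4f})   z = {self.z_score:.1f}\n"
                f"  intercept {self.intercept:.4f} ({self.intercept_se:.4f})\n"
                f"  mean chi2 {self.mean_chi2:.4f}   snps {self.m_snps_used}   "
                f"jackknife blocks {self.n_blocks_used}")


@dataclass
class GeneticCorrelationResults:
    """Cross-trait LD-score regression fit."""

    trait_pair: tuple
    rg: float
    rg_se: float
    gencov: float
    gencov_intercept: float
    gencov_intercept_se: float
    h2_1: float
    h2_2: float
    defined: bool = True
    m_snps_used: int = 0
    n_blocks_used: int = 0

    @property
    def p_value(self) -> float:
        """Two-sided normal p on rg / rg_se."""
        if not self.defined or self.rg_se <= 0:
            return np.nan
        return 2.0 * stats.norm.sf(abs(self.rg / self.rg_se))

    def summary(self) -> str:
        return (f"Cross-trait LD-score regression: {self.trait_pair[0]} ~ {self.trait_pair[1]}\n"
                f"  rg        {self.rg:.4f} ({self.rg_se:.4f})   p = {self.p_value:.2e}\n"
                f"  intercept {self.gencov_intercept:.4f} ({self.gencov_intercept_se:.4f})\n"
                f"  h2_1 {self.h2_1:.4f}  h2_2 {self.h2_2:.4f}  snps {self.m_snps_used}")


def _wls_sums(x, y, w):
    return np.array([w.sum(), (w * x).sum(), (w * x * x).sum(),
                     (w * y).sum(), (w * x * y).sum()])


def _wls_from_sums(s):
    S, Sx, Sxx, Sy, Sxy = s
    det = S * Sxx - Sx * Sx
    slope = (S * Sxy - Sx * Sy) / det
    intercept = (Sxx * Sy - Sx * Sxy) / det
    return slope, intercept


def _block_bounds(m, n_blocks):
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return list(zip(edges[:-1], edges[1:]))


def _jackknife_wls(x, y, w, n_blocks):
    """Delete-one-block WLS slope/intercept pseudo-estimates.

    Returns (slope, intercept, slope_se, intercept_se, n_blocks_used).
    Weights are held fixed across deletions.
    """
    m = len(x)
    total = _wls_sums(x, y, w)
    slope, intercept = _wls_from_sums(total)
    bounds = _block_bounds(m, n_blocks)
    est = []
    for lo, hi in bounds:
        part = _wls_sums(x[lo:hi], y[lo:hi], w[lo:hi])
        est.append(_wls_from_sums(total - part))
    est = np.array(est)
    g = len(bounds)
    se = np.sqrt((g - 1) / g * ((est - est.mean(axis=0)) ** 2).sum(axis=0))
    return slope, intercept, se[0], se[1], g


class LDScoreRegression:
    """Single-trait LD-score regression model.

    Parameters
    ----------
    sumstats : SummaryStats
    ld_scores : pd.Series
        Per-SNP LD scores indexed by snp id.
    m_total : int
        Number of reference SNPs M in the h2 denominator.
    n_blocks : int
        Jackknife blocks (contiguous in genome order).
    """

    def __init__(self, sumstats: SummaryStats, ld_scores: pd.Series,
                 m_total: int, n_blocks: int = DEFAULT_N_BLOCKS,
                 chi2_cap: bool = True):
        self.sumstats = sumstats
        self.ld_scores = ld_scores
        self.m_total = m_total
        self.n_blocks = n_blocks
        self.chi2_cap = chi2_cap

    def _prepare(self):
        df = self.sumstats.df
        merged = df.loc[df["snp"].isin(self.ld_scores.index),
                        ["snp", "chrom", "pos", "beta", "se", "n"]].copy()
        merged["l2"] = self.ld_scores.loc[merged["snp"]].values
        merged["chi2"] = (merged["beta"] / merged["se"]) ** 2
        n = merged["n"].to_numpy(float)
        if np.isnan(n).any():
            raise LDSCError("per-SNP sample size required for LD-score regression")
        if self.chi2_cap:
            cap = np.maximum(CHI2_CAP_CONST, CHI2_CAP_N_FRAC * n)
            merged = merged[merged["chi2"].to_numpy() <= cap]
        if len(merged) < 200:
            raise LDSCError(f"only {len(merged)} SNPs with LD scores after QC (need >= 200)")
        if len(merged) < 2 * self.n_blocks:
            raise LDSCError("fewer SNPs than 2 x jackknife blocks")
        return merged.reset_index(drop=True)

    def fit(self) -> HeritabilityResults:
        df = self._prepare()
        l2 = np.maximum(df["l2"].to_numpy(float), 0.0)
        n = df["n"].to_numpy(float)
        chi2 = df["chi2"].to_numpy(float)
        M = self.m_total
        x = n * l2 / M

        # pass 1: crude slope from the mean statistic
        h2_rough = np.clip((chi2.mean() - 1.0) * M / (n.mean() * l2.mean()), 0.0, 1.0)
        w = 1.0 / (np.maximum(l2, 1.0) * (1.0 + h2_rough * n * l2 / M) ** 2)
        h2_1, int_1 = _wls_from_sums(_wls_sums(x, chi2, w))
        # pass 2: model-based variances from the pass-1 fit
        h2_w = np.clip(h2_1, 0.0, 1.0)
        w = 1.0 / (np.maximum(l2, 1.0) * (max(int_1, 0.0) + h2_w * n * l2 / M) ** 2)
        h2, intercept, h2_se, int_se, g = _jackknife_wls(x, chi2, w, self.n_blocks)
        return HeritabilityResults(
            trait_name=self.sumstats.trait_name, h2=h2, h2_se=h2_se,
            intercept=intercept, intercept_se=int_se,
            mean_chi2=float(chi2.mean()), m_snps_used=len(df), n_blocks_used=g)


class CrossTraitLDScoreRegression:
    """Cross-trait LD-score regression on the SNP intersection of two traits."""

    def __init__(self, sumstats_1: SummaryStats, sumstats_2: SummaryStats,
                 ld_scores: pd.Series, m_total: int,
                 n_blocks: int = DEFAULT_N_BLOCKS, chi2_cap: bool = True):
        self.ss1 = sumstats_1
        self.ss2 = sumstats_2
        self.ld_scores = ld_scores
        self.m_total = m_total
        self.n_blocks = n_blocks
        self.chi2_cap = chi2_cap

    def fit(self) -> GeneticCorrelationResults:
        d1 = self.ss1.df.set_index("snp")
        d2 = self.ss2.df.set_index("snp")
        common = d1.index.intersection(d2.index).intersection(self.ld_scores.index)
        d1 = d1.loc[common]
        d2 = d2.loc[common]
        l2 = np.maximum(self.ld_scores.loc[common].to_numpy(float), 0.0)
        z1 = (d1["beta"] / d1["se"]).to_numpy(float)
        z2 = (d2["beta"] / d2["se"]).to_numpy(float)
        n1 = d1["n"].to_numpy(float)
        n2 = d2["n"].to_numpy(float)
        M = self.m_total
        if self.chi2_cap:
            keep = ((z1**2 <= np.maximum(CHI2_CAP_CONST, CHI2_CAP_N_FRAC * n1)) &
                    (z2**2 <= np.maximum(CHI2_CAP_CONST, CHI2_CAP_N_FRAC * n2)))
            z1, z2, n1, n2, l2 = z1[keep], z2[keep], n1[keep], n2[keep], l2[keep]
        m_used = len(z1)
        if m_used < max(200, 2 * self.n_blocks):
            raise LDSCError("too few intersection SNPs for cross-trait regression")

        def _h2(z, n, name):
            x = n * l2 / M
            chi2 = z**2
            h2_rough = np.clip((chi2.mean() - 1.0) * M / (n.mean() * l2.mean()), 0.0, 1.0)
            w = 1.0 / (np.maximum(l2, 1.0) * (1.0 + h2_rough * n * l2 / M) ** 2)
            h2_1, int_1 = _wls_from_sums(_wls_sums(x, chi2, w))
            w = 1.0 / (np.maximum(l2, 1.0) * (max(int_1, 0.0) + np.clip(h2_1, 0, 1) * n * l2 / M) ** 2)
            return x, chi2, w

        x1, chi1, w1 = _h2(z1, n1, self.ss1.trait_name)
        x2, chi2_, w2 = _h2(z2, n2, self.ss2.trait_name)
        y = z1 * z2
        xg = np.sqrt(n1 * n2) * l2 / M

        gencov_rough = y.mean() * M / (np.sqrt(n1 * n2).mean() * l2.mean())
        h2a_0, inta_0 = _wls_from_sums(_wls_sums(x1, chi1, w1))
        h2b_0, intb_0 = _wls_from_sums(_wls_sums(x2, chi2_, w2))
        e1 = np.maximum(inta_0, 0.0) + np.clip(h2a_0, 0, 1) * n1 * l2 / M
        e2 = np.maximum(intb_0, 0.0) + np.clip(h2b_0, 0, 1) * n2 * l2 / M
        wg = 1.0 / (np.maximum(l2, 1.0) * (e1 * e2 + (gencov_rough * xg) ** 2))
        g_1, gi_1 = _wls_from_sums(_wls_sums(xg, y, wg))
        wg = 1.0 / (np.maximum(l2, 1.0) * (e1 * e2 + (gi_1 + g_1 * xg) ** 2))

        # joint delete-one-block jackknife of the rg ratio; the h2 slopes in
        # the ratio use the same weights as the gencov slope so that rg of a
        # trait with itself is exactly 1 (weights affect efficiency only)
        totals = {
            "a": _wls_sums(x1, chi1, wg),
            "b": _wls_sums(x2, chi2_, wg),
            "g": _wls_sums(xg, y, wg),
        }
        h2_1_full, _ = _wls_from_sums(totals["a"])
        h2_2_full, _ = _wls_from_sums(totals["b"])
        gencov, g_int = _wls_from_sums(totals["g"])

        if h2_1_full <= 0 or h2_2_full <= 0:
            warnings.warn("non-positive h2 estimate: rg undefined for "
                          f"({self.ss1.trait_name}, {self.ss2.trait_name})")
            return GeneticCorrelationResults(
                trait_pair=(self.ss1.trait_name, self.ss2.trait_name),
                rg=np.nan, rg_se=np.nan, gencov=gencov, gencov_intercept=g_int,
                gencov_intercept_se=np.nan, h2_1=h2_1_full, h2_2=h2_2_full,
                defined=False, m_snps_used=m_used, n_blocks_used=0)

        rg_full = gencov / np.sqrt(h2_1_full * h2_2_full)
        bounds = _block_bounds(m_used, self.n_blocks)
        rg_del, gi_del = [], []
        for lo, hi in bounds:
            pa = totals["a"] - _wls_sums(x1[lo:hi], chi1[lo:hi], wg[lo:hi])
            pb = totals["b"] - _wls_sums(x2[lo:hi], chi2_[lo:hi], wg[lo:hi])
            pg = totals["g"] - _wls_sums(xg[lo:hi], y[lo:hi], wg[lo:hi])
            h2a, _ = _wls_from_sums(pa)
            h2b, _ = _wls_from_sums(pb)
            gc, gi = _wls_from_sums(pg)
            denom = np.sqrt(max(h2a, 1e-12) * max(h2b, 1e-12))
            rg_del.append(gc / denom)
            gi_del.append(gi)
        rg_del = np.array(rg_del)
        gi_del = np.array(gi_del)
        g = len(bounds)
        rg_se = np.sqrt((g - 1) / g * ((rg_del - rg_del.mean()) ** 2).sum())
        gi_se = np.sqrt((g - 1) / g * ((gi_del - gi_del.mean()) ** 2).sum())
        return GeneticCorrelationResults(
            trait_pair=(self.ss1.trait_name, self.ss2.trait_name),
            rg=rg_full, rg_se=rg_se, gencov=gencov, gencov_intercept=g_int,
            gencov_intercept_se=gi_se, h2_1=h2_1_full, h2_2=h2_2_full,
            defined=True, m_snps_used=m_used, n_blocks_used=g)


def estimate_h2(sumstats, ld_scores, m_total, n_blocks=DEFAULT_N_BLOCKS,
                **kw) -> HeritabilityResults:
    return LDScoreRegression(sumstats, ld_scores, m_total, n_blocks, **kw).fit()


def estimate_rg(sumstats_1, sumstats_2, ld_scores, m_total,
                n_blocks=DEFAULT_N_BLOCKS, **kw) -> GeneticCorrelationResults:
    return CrossTraitLDScoreRegression(sumstats_1, sumstats_2, ld_scores,
                                       m_total, n_blocks, **kw).fit()


def heritability_gate(estimates, z_threshold: float = 4.0):
    """Partition traits into (kept, excluded) by the strict rule z > threshold.

    Accepts any iterable of objects with ``trait_name`` and ``z_score``
    attributes (HeritabilityResults or ad-hoc records).  Output lists are
    sorted by trait name, so the partition is invariant to input order.
    """
    ests = sorted(estimates, key=lambda e: e.trait_name)
    kept = [e for e in ests if e.z_score > z_threshold]
    excluded = [e for e in ests if not (e.z_score > z_threshold)]
    return kept, excluded
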