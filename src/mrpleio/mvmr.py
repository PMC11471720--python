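"""Multivariable MR: joint causal effects of several exposures on one
outcome from overlapping instrument sets.

The design matrix holds each instrument's effects on every exposure; the
outcome effects are regressed on it with inverse-variance weights.  MV-IVW
(zero intercept) is the primary estimator, MV-Egger adds a free intercept
(directional pleiotropy), and the MV-median replaces the squared loss with a
weighted absolute loss for robustness to a contaminated minority.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import IVSelectionConfig, ld_clump
from .ld import LDReference
from .mr import MREstimate, MRError, Z95
from .sumstats import SummaryStats, harmonize, kept_pairs

logger = logging.getLogger(__name__)


class MVMRError(ValueError):
    pass


@dataclass
class MVInstrumentSet:
    """Instruments with complete effect rows across all exposures.

    ``bx`` and ``bx_se`` are (k x p); ``by``/``by_se`` length k.
    """

    snp: np.ndarray
    exposures: list
    bx: np.ndarray
    bx_se: np.ndarray
    by: np.ndarray
    by_se: np.ndarray
    px: np.ndarray
    py: np.ndarray
    trace: list = field(default_factory=list)
    stage: str = "initial"

    @property
    def k(self) -> int:
        return len(self.snp)

    @property
    def p(self) -> int:
        return len(self.exposures)

    def conditional_f(self) -> pd.Series:
        """Per-exposure conditional instrument-strength statistic.

        For exposure j, the effects are regressed on the other exposures'
        effects; the statistic is the mean squared residual over the
        squared SE, scaled by (k - p)/k.  Informational only (no filtering).
        """
        k, p = self.k, self.p
        out = {}
        for j, name in enumerate(self.exposures):
            others = np.delete(self.bx, j, axis=1)
            target = self.bx[:, j]
            if others.shape[1] == 0:
                resid = target
            else:
                coef, *_ = np.linalg.lstsq(others, target, rcond=None)
                resid = target - others @ coef
            out[name] = float(np.mean(resid**2 / self.bx_se[:, j] ** 2) * (k - p) / k)
        return pd.Series(out, name="conditional_F")


def build_mv_instruments(exposures: list, outcome: SummaryStats,
                         ld_reference: LDReference,
                         config: IVSelectionConfig = IVSelectionConfig(),
                         p_threshold: float | None = None,
                         pleiotropic_snps: set | None = None,
                         stage: str = "initial") -> MVInstrumentSet:
    """Construct a complete-case multivariable instrument set.

    Union of each exposure's sub-threshold candidates, re-clumped jointly
    (per LD clique the SNP with the smallest minimum p across exposures
    survives), intersected with every exposure and the outcome table, and
    harmonized to the first exposure's effect alleles.  Instruments with
    outcome p below the p of every exposure are removed (the outcome-
    correlation rule), as are instruments weak for all exposures
    (max F < f_min).  With ``stage='final'``, ``pleiotropic_snps`` are
    removed too.
    """
    if len(exposures) < 2:
        raise MVMRError("multivariable MR needs >= 2 exposures")
    thr = p_threshold if p_threshold is not None else config.p_threshold_relaxed
    frames = []
    for ss in exposures:
        d = ss.df
        frames.append(d.loc[d["p"] < thr, ["snp", "chrom", "pos", "p"]])
    cand = pd.concat(frames).sort_values("p").drop_duplicates("snp")
    cand = cand.groupby("snp", as_index=False).agg(
        {"chrom": "first", "pos": "first", "p": "min"})
    if len(cand) == 0:
        raise MVMRError("no candidate instruments below threshold for any exposure")
    clumped = set(ld_clump(cand, ld_reference, config.clump_r2,
                           config.clump_window_kb))
    trace = [("candidates", len(cand)), ("step1_clump", len(clumped))]

    ref = exposures[0]
    sub = SummaryStats(trait_name=ref.trait_name,
                       df=ref.df[ref.df["snp"].isin(clumped)].reset_index(drop=True))
    pairs_out = kept_pairs(harmonize(sub, outcome,
                                     palindrome_eaf_window=config.palindrome_eaf_window))
    merged = pairs_out.rename(columns={"bx": "bx_0", "bx_se": "bx_se_0", "px": "px_0"})
    for j, ss in enumerate(exposures[1:], start=1):
        pj = kept_pairs(harmonize(sub, ss,
                                  palindrome_eaf_window=config.palindrome_eaf_window))
        pj = pj[["snp", "by", "by_se", "py"]].rename(
            columns={"by": f"bx_{j}", "by_se": f"bx_se_{j}", "py": f"px_{j}"})
        merged = merged.merge(pj, on="snp", how="inner")
    trace.append(("step2_harmonize", len(merged)))

    p = len(exposures)
    px = merged[[f"px_{j}" for j in range(p)]].to_numpy(float)
    keep = ~(merged["py"].to_numpy(float)[:, None] < px).all(axis=1)
    merged = merged[keep]
    bx = merged[[f"bx_{j}" for j in range(p)]].to_numpy(float)
    bx_se = merged[[f"bx_se_{j}" for j in range(p)]].to_numpy(float)
    fstat = bx**2 / bx_se**2
    merged = merged[(fstat >= config.f_min).any(axis=1)]
    trace.append(("step3_filters", len(merged)))

    if stage == "final" and pleiotropic_snps:
        merged = merged[~merged["snp"].isin(pleiotropic_snps)]
    trace.append(("step4_pleiotropy", len(merged)))

    if len(merged) <= p:
        raise MVMRError(f"only {len(merged)} complete instruments for "
                        f"{p} exposures (need k > p)")
    merged = merged.reset_index(drop=True)
    return MVInstrumentSet(
        snp=merged["snp"].to_numpy(),
        exposures=[ss.trait_name for ss in exposures],
        bx=merged[[f"bx_{j}" for j in range(p)]].to_numpy(float),
        bx_se=merged[[f"bx_se_{j}" for j in range(p)]].to_numpy(float),
        by=merged["by"].to_numpy(float), by_se=merged["by_se"].to_numpy(float),
        px=merged[[f"px_{j}" for j in range(p)]].to_numpy(float),
        py=merged["py"].to_numpy(float), trace=trace, stage=stage)


def _check_design(X: np.ndarray):
    norms = np.linalg.norm(X, axis=0)
    active = norms > 1e-12
    Xa = X[:, active]
    if Xa.shape[1]:
        cond = np.linalg.cond(Xa)
        if cond > 1e10:
            raise MVMRError(f"collinear exposure effects (condition number "
                            f"{cond:.3g})")
    return active


def _wls(X, y, w):
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    return coef, np.linalg.inv(xtwx)


class MultivariableMR:
    """Estimator suite over one multivariable instrument set."""

    def __init__(self, mvset: MVInstrumentSet):
        self.mvset = mvset

    def _design(self, intercept: bool, orient: bool):
        m = self.mvset
        X = m.bx.copy()
        y = m.by.copy()
        if orient:
            sign = np.where(X[:, 0] < 0, -1.0, 1.0)
            X = X * sign[:, None]
            y = y * sign
        w = 1.0 / m.by_se**2
        if intercept:
            X = np.column_stack([np.ones(m.k), X])
        return X, y, w

    def mv_ivw(self) -> list:
        """Per-exposure IVW estimates (zero intercept); heterogeneity Q on
        k - p df; multiplicative random-effects SE inflation when Q demands."""
        m = self.mvset
        X, y, w = self._design(intercept=False, orient=False)
        active = _check_design(X)
        coef_a, cov_a = _wls(X[:, active], y, w)
        coef = np.zeros(m.p)
        ses = np.full(m.p, np.nan)
        coef[active] = coef_a
        resid = y - X @ coef
        dof = m.k - int(active.sum())
        q = float(np.sum(w * resid**2))
        q_p = float(stats.chi2.sf(q, dof))
        scale = max(1.0, np.sqrt(q / dof)) if q_p < 0.05 else 1.0
        ses[active] = np.sqrt(np.diag(cov_a)) * scale
        out = []
        for j, name in enumerate(m.exposures):
            b, s = coef[j], ses[j]
            p = 2 * stats.norm.sf(abs(b) / s) if np.isfinite(s) and s > 0 else np.nan
            out.append(MREstimate(f"mv_ivw[{name}]", float(b), float(s), float(p),
                                  m.k, extra={"q": q, "q_df": dof, "q_p": q_p}))
        return out

    def mv_egger(self):
        """MV-Egger: free intercept, first exposure's effects oriented
        positive; returns (per-exposure estimates, intercept, intercept_se,
        intercept_p) with t inference on k - p - 1 df."""
        m = self.mvset
        if m.k <= m.p + 1:
            raise MVMRError("MV-Egger needs k > p + 1")
        X, y, w = self._design(intercept=True, orient=True)
        active = _check_design(X)
        coef_a, cov_a = _wls(X[:, active], y, w)
        coef = np.zeros(X.shape[1])
        coef[active] = coef_a
        resid = y - X @ coef
        dof = m.k - int(active.sum())
        sigma2 = float(np.sum(w * resid**2) / dof)
        scale = max(1.0, sigma2)
        ses = np.full(X.shape[1], np.nan)
        ses[active] = np.sqrt(np.diag(cov_a) * scale)
        tvals = coef / ses
        pvals = 2 * stats.t.sf(np.abs(tvals), dof)
        out = []
        for j, name in enumerate(m.exposures):
            out.append(MREstimate(f"mv_egger[{name}]", float(coef[j + 1]),
                                  float(ses[j + 1]), float(pvals[j + 1]), m.k,
                                  extra={"sigma2": sigma2}))
        return out, float(coef[0]), float(ses[0]), float(pvals[0])

    def mv_median(self, n_boot: int = 1000, seed: int = 0) -> list:
        """Weighted median (quantile 0.5) regression on the same design.

        Solved by iteratively reweighted least squares to 1e-8; SEs by
        seeded parametric bootstrap of (bx, by).
        """
        m = self.mvset

        def _l1_fit(X, y, w):
            coef, _ = _wls(X, y, w)
            for _ in range(200):
                r = y - X @ coef
                wi = w / np.maximum(np.abs(r), 1e-8)
                new, _ = _wls(X, y, wi)
                if np.max(np.abs(new - coef)) < 1e-8:
                    return new
                coef = new
            return coef

        X, y, w = self._design(intercept=False, orient=False)
        active = _check_design(X)
        coef = np.zeros(m.p)
        coef[active] = _l1_fit(X[:, active], y, w)
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, m.p))
        for i in range(n_boot):
            bx_i = rng.normal(m.bx, m.bx_se)
            by_i = rng.normal(m.by, m.by_se)
            ci = np.zeros(m.p)
            ci[active] = _l1_fit(bx_i[:, active], by_i, w)
            boots[i] = ci
        ses = boots.std(axis=0, ddof=1)
        out = []
        for j, name in enumerate(m.exposures):
            b, s = float(coef[j]), float(ses[j])
            p = 2 * stats.norm.sf(abs(b) / s) if s > 0 else np.nan
            out.append(MREstimate(f"mv_median[{name}]", b, s, float(p), m.k))
        return out

    def fit(self, n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
        """All three estimators as one tidy per-exposure table."""
        rows = []
        ivw_est = self.mv_ivw()
        try:
            egger_est, b0, b0_se, b0_p = self.mv_egger()
        except MVMRError:
            egger_est, b0, b0_se, b0_p = [], np.nan, np.nan, np.nan
        med_est = self.mv_median(n_boot=n_boot, seed=seed)
        for est in [*ivw_est, *egger_est, *med_est]:
            method, _, exposure = est.method.partition("[")
            rows.append({"METHOD": method, "EXPOSURE": exposure.rstrip("]"),
                         "NSNP": est.n_snp, "BETA": est.beta, "SE": est.se,
                         "P": est.p_value, "Q": est.extra.get("q", np.nan),
                         "Q_P": est.extra.get("q_p", np.nan),
                         "EGGER_INT": b0 if method == "mv_egger" else np.nan,
                         "EGGER_INT_P": b0_p if method == "mv_egger" else np.nan})
        return pd.DataFrame(rows)
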