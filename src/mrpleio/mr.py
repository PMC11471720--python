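"""Univariable two-sample MR estimators and sensitivity diagnostics.

Operates on a harmonized instrument frame (columns bx, bx_se, by, by_se,
optionally snp/px/py/nx/ny).  Per-variant causal estimates are Wald ratios
by/bx; the estimators differ in how the ratios are pooled and which
assumption violations they tolerate:

- IVW: inverse-variance weighted pooling (first-order, second-order, or
  modified second-order weights, the latter iterating the fitted slope into
  the weights); multiplicative random effects inflate the SE by
  max(1, sqrt(Q/(k-1))) when heterogeneity demands it.
- Radial IVW: the same fit in radial coordinates, giving per-variant
  Cochran Q contributions and outlier flags.
- MR-Egger: weighted regression with a free intercept (directional
  pleiotropy test; t reference with k-2 df).
- Weighted median / weighted mode: order- and mode-based estimators robust
  to a minority (median: < 50% of weight) of invalid instruments; SEs by
  seeded parametric bootstrap.
- RAPS: robust adjusted profile score with Huber loss and an optional
  overdispersion parameter.
- MR-PRESSO: simulation-based global heterogeneity test, per-variant
  outlier test, and distortion test comparing the estimate before and after
  outlier removal.
- Steiger directionality, leave-one-out, and funnel-plot data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)


class MRError(ValueError):
    pass


@dataclass
class MREstimate:
    """One method's causal estimate: outcome units per exposure unit."""

    method: str
    beta: float
    se: float
    p_value: float
    n_snp: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
            self.ci_high = self.beta + Z95 * self.se


@dataclass
class RadialResult:
    estimate: MREstimate
    q_total: float
    q_p: float
    q_contributions: pd.DataFrame
    outliers: set


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_p: pd.Series
    outliers: set
    raw: MREstimate
    corrected: MREstimate
    distortion_p: float
    n_simulations: int
    seed: int


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    steiger_p: float


def _cols(ivs: pd.DataFrame):
    return (ivs["bx"].to_numpy(float), ivs["bx_se"].to_numpy(float),
            ivs["by"].to_numpy(float), ivs["by_se"].to_numpy(float))


def wald_ratio(pair) -> MREstimate:
    """Single-variant estimate: beta = by/bx, first-order se = by_se/|bx|."""
    bx, by, by_se = float(pair["bx"]), float(pair["by"]), float(pair["by_se"])
    if bx == 0:
        raise MRError("wald ratio undefined for bx = 0")
    beta = by / bx
    se = by_se / abs(bx)
    p = 2 * stats.norm.sf(abs(beta) / se)
    return MREstimate("wald_ratio", beta, se, p, 1)


def _ratio_variances(bx, bx_se, by, by_se, weighting: str, theta: float | None = None):
    """Variance of each Wald ratio under the chosen weighting scheme."""
    if weighting == "first":
        return by_se**2 / bx**2
    if weighting == "second":
        return by_se**2 / bx**2 + by**2 * bx_se**2 / bx**4
    if weighting == "modified_second":
        if theta is None:
            raise MRError("modified second-order weights need theta")
        return (by_se**2 + theta**2 * bx_se**2) / bx**2
    raise MRError(f"unknown weighting {weighting!r}")


def _ivw_point(ratios, var):
    w = 1.0 / var
    theta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    return theta, se_fixed, w


def ivw(ivs: pd.DataFrame, weighting: str = "modified_second",
        model: str = "auto") -> MREstimate:
    """Inverse-variance weighted estimate (zero-intercept weighted
    regression of by on bx).

    ``weighting``: first | second | modified_second (iterated to
    |dtheta| < 1e-10, <= 100 iterations).  ``model``: fixed | random |
    auto (random-effects SE inflation max(1, sqrt(Q/(k-1))) when the
    Cochran Q p-value is below 0.05).
    """
    if len(ivs) < 2:
        raise MRError("IVW needs >= 2 instruments")
    bx, bx_se, by, by_se = _cols(ivs)
    if np.any(bx == 0):
        raise MRError("bx = 0 instrument present; drop before fitting")
    ratios = by / bx
    if weighting == "modified_second":
        var = _ratio_variances(bx, bx_se, by, by_se, "first")
        theta, se_fixed, w = _ivw_point(ratios, var)
        for _ in range(100):
            var = _ratio_variances(bx, bx_se, by, by_se, "modified_second", theta)
            new, se_fixed, w = _ivw_point(ratios, var)
            if abs(new - theta) < 1e-10:
                theta = new
                break
            theta = new
    else:
        var = _ratio_variances(bx, bx_se, by, by_se, weighting)
        theta, se_fixed, w = _ivw_point(ratios, var)
    k = len(ratios)
    q = float(np.sum(w * (ratios - theta) ** 2))
    q_p = float(stats.chi2.sf(q, k - 1))
    se = se_fixed
    used = "fixed"
    if model == "random" or (model == "auto" and q_p < 0.05):
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
        used = "random"
    p = 2 * stats.norm.sf(abs(theta) / se)
    return MREstimate(f"ivw_{weighting}", theta, se, p, k,
                      extra={"q": q, "q_df": k - 1, "q_p": q_p, "model": used,
                             "se_fixed": se_fixed})


def cochran_q(ivs: pd.DataFrame, estimate: MREstimate | float | None = None,
              weighting: str = "first"):
    """Cochran heterogeneity statistic Q = sum w_j (ratio_j - theta)^2
    against chi2 with k-1 df."""
    if len(ivs) < 2:
        raise MRError("Cochran Q needs >= 2 instruments")
    bx, bx_se, by, by_se = _cols(ivs)
    ratios = by / bx
    if estimate is None:
        estimate = ivw(ivs, weighting=weighting if weighting != "modified_second"
                       else "modified_second")
    theta = estimate.beta if isinstance(estimate, MREstimate) else float(estimate)
    var = _ratio_variances(bx, bx_se, by, by_se, weighting,
                           theta if weighting == "modified_second" else None)
    q = float(np.sum((ratios - theta) ** 2 / var))
    df = len(ratios) - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw_radial(ivs: pd.DataFrame, outlier_alpha: float = 0.05) -> RadialResult:
    """Radial IVW with modified second-order weights.

    Regresses ratio_j * sqrt(w_j) on sqrt(w_j) without intercept; the point
    estimate coincides with modified-second-order IVW.  Per-variant
    Q contributions w_j (ratio_j - theta)^2 are referred to chi2(1); those
    with upper-tail p < ``outlier_alpha`` are flagged as outliers.
    """
    est = ivw(ivs, weighting="modified_second", model="auto")
    bx, bx_se, by, by_se = _cols(ivs)
    ratios = by / bx
    var = _ratio_variances(bx, bx_se, by, by_se, "modified_second", est.beta)
    w = 1.0 / var
    qj = w * (ratios - est.beta) ** 2
    pj = stats.chi2.sf(qj, 1)
    snps = ivs["snp"] if "snp" in ivs else pd.Series(range(len(ivs)), name="snp")
    contrib = pd.DataFrame({"snp": snps.values, "ratio": ratios,
                            "weight": w, "q": qj, "q_p": pj})
    outliers = set(contrib.loc[contrib["q_p"] < outlier_alpha, "snp"])
    q_total = float(qj.sum())
    q_p = float(stats.chi2.sf(q_total, len(ratios) - 1))
    est = MREstimate("ivw_radial", est.beta, est.se, est.p_value, est.n_snp,
                     extra=est.extra)
    return RadialResult(estimate=est, q_total=q_total, q_p=q_p,
                        q_contributions=contrib, outliers=outliers)


def egger(ivs: pd.DataFrame):
    """MR-Egger: weighted regression of by on bx with a free intercept.

    Instruments are oriented so bx > 0 (both signs flipped per variant);
    weights are 1/by_se^2; inference uses t with k-2 df and multiplicative
    SE inflation max(1, sigma).  Returns (slope estimate, intercept,
    intercept_se, intercept_p).
    """
    if len(ivs) < 3:
        raise MRError("Egger needs >= 3 instruments")
    bx, bx_se, by, by_se = _cols(ivs)
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / by_se**2
    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    k = len(x)
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov_unscaled = np.linalg.inv(xtwx)
    scale = max(1.0, sigma2)
    ses = np.sqrt(np.diag(cov_unscaled) * scale)
    tvals = coef / ses
    pvals = 2 * stats.t.sf(np.abs(tvals), k - 2)
    slope = MREstimate("egger", float(coef[1]), float(ses[1]), float(pvals[1]), k,
                       extra={"sigma2": sigma2})
    return slope, float(coef[0]), float(ses[0]), float(pvals[0])


def _weighted_median_point(ratios, weights):
    order = np.argsort(ratios)
    b = ratios[order]
    w = weights[order] / weights.sum()
    cw = np.cumsum(w) - 0.5 * w
    if cw[0] >= 0.5:
        return float(b[0])
    if cw[-1] < 0.5:
        return float(b[-1])
    j = int(np.searchsorted(cw, 0.5))
    return float(b[j - 1] + (b[j] - b[j - 1]) * (0.5 - cw[j - 1]) / (cw[j] - cw[j - 1]))


def weighted_median(ivs: pd.DataFrame, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Inverse-variance weighted median of the Wald ratios.

    Linear interpolation at cumulative weight 0.5; consistent when valid
    instruments carry > 50% of the weight.  SE by seeded parametric
    bootstrap of (bx, by).
    """
    if len(ivs) < 3:
        raise MRError("weighted median needs >= 3 instruments")
    bx, bx_se, by, by_se = _cols(ivs)
    ratios = by / bx
    weights = bx**2 / by_se**2
    point = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    k = len(bx)
    bxs = rng.normal(bx, bx_se, size=(n_boot, k))
    bys = rng.normal(by, by_se, size=(n_boot, k))
    rs = bys / bxs
    ws = bxs**2 / by_se**2
    boots = np.array([_weighted_median_point(rs[i], ws[i]) for i in range(n_boot)])
    se = float(boots.std(ddof=1))
    p = 2 * stats.norm.sf(abs(point) / se)
    return MREstimate("weighted_median", point, se, p, k)


def _weighted_mode_point(ratios, weights, phi, grid_size: int = 2048):
    s = 0.9 * min(np.std(ratios, ddof=1), stats.iqr(ratios) / 1.349 or np.inf)
    if not np.isfinite(s) or s <= 0:
        s = np.std(ratios, ddof=1)
    if s <= 0:
        return float(ratios[0])
    h = phi * s * len(ratios) ** (-0.2)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    dens = (weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)).sum(axis=0)
    return float(grid[int(np.argmax(dens))])


def _weighted_mode_points(ratios, weights, phi, grid_size: int = 512):
    """Vectorized KDE mode per row of (n, k) ratio/weight matrices."""
    n, k = ratios.shape
    sd = np.std(ratios, axis=1, ddof=1)
    iqr = stats.iqr(ratios, axis=1) / 1.349
    s = 0.9 * np.where(iqr > 0, np.minimum(sd, iqr), sd)
    s = np.where(s > 0, s, 1e-12)
    h = phi * s * k ** (-0.2)
    lo = ratios.min(axis=1) - 3 * h
    hi = ratios.max(axis=1) + 3 * h
    out = np.empty(n)
    chunk = max(1, int(2e7 // (grid_size * k)))
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        g = lo[sl, None] + (hi[sl] - lo[sl])[:, None] * \
            np.linspace(0.0, 1.0, grid_size)[None, :]
        d = (weights[sl, :, None] *
             np.exp(-0.5 * ((g[:, None, :] - ratios[sl, :, None]) /
                            h[sl, None, None]) ** 2)).sum(axis=1)
        out[sl] = g[np.arange(g.shape[0]), d.argmax(axis=1)]
    return out


def weighted_mode(ivs: pd.DataFrame, bandwidth_phi: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode of the smoothed weighted empirical density of Wald ratios.

    Normal kernel with a Silverman-type bandwidth scaled by
    ``bandwidth_phi``; consistent when the largest group of instruments
    sharing one causal estimate is valid.  Bootstrap SE, seeded.
    """
    if len(ivs) < 3:
        raise MRError("weighted mode needs >= 3 instruments")
    bx, bx_se, by, by_se = _cols(ivs)
    ratios = by / bx
    weights = bx**2 / by_se**2
    point = _weighted_mode_point(ratios, weights, bandwidth_phi)
    rng = np.random.default_rng(seed)
    k = len(bx)
    bxs = rng.normal(bx, bx_se, size=(n_boot, k))
    bys = rng.normal(by, by_se, size=(n_boot, k))
    boots = _weighted_mode_points(bys / bxs, bxs**2 / by_se[None, :]**2,
                                  bandwidth_phi)
    se = float(boots.std(ddof=1))
    p = 2 * stats.norm.sf(abs(point) / se)
    return MREstimate("weighted_mode", point, se, p, k)


HUBER_K = 1.345


def _huber_psi(t, k=HUBER_K):
    return np.clip(t, -k, k)


def _huber_rho(t, k=HUBER_K):
    a = np.abs(t)
    return np.where(a <= k, 0.5 * t**2, k * a - 0.5 * k**2)


def raps(ivs: pd.DataFrame, k_tuning: float = HUBER_K,
         overdispersion: bool = True) -> MREstimate:
    """Robust adjusted profile score estimator.

    Minimizes the Huber loss of the standardized profile residuals
    t_j(theta) = (by_j - theta bx_j)/sqrt(by_se^2 + theta^2 bx_se^2 + tau^2),
    with the overdispersion tau^2 profiled so that the average of
    psi(t) t matches its standard-normal expectation
    delta = 2 Phi(k) - 1.  SE from the M-estimation sandwich of the profile
    score.
    """
    if len(ivs) < 3:
        raise MRError("RAPS needs >= 3 instruments")
    bx, bx_se, by, by_se = _cols(ivs)
    delta = 2 * stats.norm.cdf(k_tuning) - 1.0

    def tresid(theta, tau2):
        s = np.sqrt(by_se**2 + theta**2 * bx_se**2 + tau2)
        return (by - theta * bx) / s, s

    def loss(theta, tau2):
        t, _ = tresid(theta, tau2)
        return float(np.sum(_huber_rho(t, k_tuning)))

    def solve_theta(tau2, bracket):
        res = optimize.minimize_scalar(lambda th: loss(th, tau2),
                                       bracket=bracket, method="brent",
                                       options={"xtol": 1e-12})
        return float(res.x)

    # initial from IVW
    theta = ivw(ivs, weighting="first", model="fixed").beta
    tau2 = 0.0
    for _ in range(50):
        theta_new = solve_theta(tau2, (theta - 1.0, theta, theta + 1.0))
        if overdispersion:
            def od(tau2_):
                t, _ = tresid(theta_new, tau2_)
                return float(np.mean(_huber_psi(t, k_tuning) * t)) - delta
            if od(0.0) <= 0:
                tau2_new = 0.0
            else:
                hi = 1.0
                while od(hi) > 0 and hi < 1e6:
                    hi *= 10
                tau2_new = optimize.brentq(od, 0.0, hi, xtol=1e-14)
        else:
            tau2_new = 0.0
        if abs(theta_new - theta) < 1e-10 and abs(tau2_new - tau2) < 1e-12:
            theta, tau2 = theta_new, tau2_new
            break
        theta, tau2 = theta_new, tau2_new

    # sandwich with expected psi-moments under t ~ N(0,1):
    # E[psi'] = 2 Phi(k) - 1, E[psi^2] = E[psi'] - 2k phi(k) + 2k^2 (1-Phi(k))
    t, s = tresid(theta, tau2)
    dt = bx / s + t * theta * bx_se**2 / s**2
    e_psi_prime = delta
    e_psi_sq = delta - 2 * k_tuning * stats.norm.pdf(k_tuning) \
        + 2 * k_tuning**2 * stats.norm.sf(k_tuning)
    A = e_psi_prime * np.sum(dt**2)
    B = e_psi_sq * np.sum(dt**2)
    se = float(np.sqrt(B) / A) if A != 0 else np.nan
    p = 2 * stats.norm.sf(abs(theta) / se)
    return MREstimate("raps", theta, se, p, len(bx),
                      extra={"tau2": tau2, "k_tuning": k_tuning,
                             "overdispersion": overdispersion})


def _loo_ivw_matrix(bx, by, w):
    """Leave-one-out first-order IVW estimates, vectorized.

    Accepts 1-d or (n_sim, k) arrays for ``by``; returns matching shape.
    """
    sxy = (w * bx * by).sum(axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx)
    num = sxy - w * bx * by
    den = sxx - w * bx * bx
    return num / den


def mr_presso(ivs: pd.DataFrame, n_sim: int = 1000, seed: int = 0,
              significance: float = 0.05) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier test.

    Observed RSS uses leave-one-out IVW predictions; the null distribution
    comes from ``n_sim`` parametric simulations of the outcome effects
    around those predictions.  Per-variant outlier p-values are
    Bonferroni-adjusted across instruments; the distortion test compares
    the outlier-corrected estimate with the raw one against a bootstrap of
    random same-size exclusion sets.
    """
    if len(ivs) < 4:
        raise MRError("MR-PRESSO needs >= 4 instruments")
    if n_sim < 100:
        raise MRError("n_sim < 100 gives an unusably coarse p-value floor")
    bx, bx_se, by, by_se = _cols(ivs)
    k = len(bx)
    w = 1.0 / by_se**2
    snps = (ivs["snp"] if "snp" in ivs else pd.Series(range(k))).to_numpy()

    theta_loo = _loo_ivw_matrix(bx, by, w)
    resid_obs = (by - theta_loo * bx) ** 2 * w
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(theta_loo * bx, by_se, size=(n_sim, k))
    theta_loo_sim = _loo_ivw_matrix(bx, by_sim, w)
    resid_sim = (by_sim - theta_loo_sim * bx) ** 2 * w
    rss_sim = resid_sim.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    outlier_p = (1 + (resid_sim >= resid_obs[None, :]).sum(axis=0)) / (n_sim + 1)
    outlier_p = pd.Series(np.minimum(outlier_p * k, 1.0), index=snps)
    outliers = set(outlier_p.index[outlier_p < significance]) \
        if global_p < significance else set()

    raw = ivw(ivs, weighting="first", model="random")
    if outliers:
        mask = ~pd.Series(snps).isin(outliers).to_numpy()
        if mask.sum() < 2:
            corrected = raw
            distortion_p = np.nan
        else:
            corrected = ivw(ivs[mask], weighting="first", model="random")
            d_obs = corrected.beta - raw.beta
            n_out = int((~mask).sum())
            d_boot = np.empty(n_boot_d := 1000)
            for i in range(n_boot_d):
                drop = rng.choice(k, size=n_out, replace=False)
                keep = np.setdiff1d(np.arange(k), drop)
                th = float(np.sum(w[keep] * bx[keep] * by[keep]) /
                           np.sum(w[keep] * bx[keep] ** 2))
                d_boot[i] = th - raw.beta
            distortion_p = float((1 + np.sum(np.abs(d_boot) >= abs(d_obs))) /
                                 (n_boot_d + 1))
    else:
        corrected = raw
        distortion_p = np.nan
    return PressoResult(global_rss=rss_obs, global_p=global_p,
                        outlier_p=outlier_p, outliers=outliers, raw=raw,
                        corrected=corrected, distortion_p=distortion_p,
                        n_simulations=n_sim, seed=seed)


def steiger_test(ivs: pd.DataFrame, n_x: float | None = None,
                 n_y: float | None = None) -> SteigerResult:
    """Directionality check: variance explained in exposure vs outcome.

    Per-instrument r^2 = z^2/(z^2 + n - 2) summed per trait;
    direction_correct iff the instruments explain more exposure than
    outcome variance.  p from the z-test on the Fisher-transformed
    explained correlations.
    """
    nx = n_x if n_x is not None else (float(ivs["nx"].median()) if "nx" in ivs else None)
    ny = n_y if n_y is not None else (float(ivs["ny"].median()) if "ny" in ivs else None)
    if nx is None or ny is None or not np.isfinite(nx) or not np.isfinite(ny):
        raise MRError("Steiger test needs sample sizes for both traits")
    bx, bx_se, by, by_se = _cols(ivs)
    zx2 = (bx / bx_se) ** 2
    zy2 = (by / by_se) ** 2
    r2x = float(np.sum(zx2 / (zx2 + nx - 2)))
    r2y = float(np.sum(zy2 / (zy2 + ny - 2)))
    r2x, r2y = min(r2x, 1.0), min(r2y, 1.0)
    zf = (np.arctanh(np.sqrt(r2x)) - np.arctanh(np.sqrt(r2y))) / \
        np.sqrt(1.0 / (nx - 3) + 1.0 / (ny - 3))
    p = float(2 * stats.norm.sf(abs(zf)))
    return SteigerResult(r2_exposure=r2x, r2_outcome=r2y,
                         direction_correct=r2x > r2y, steiger_p=p)


def leave_one_out(ivs: pd.DataFrame, alpha: float = 0.05,
                  weighting: str = "modified_second") -> pd.DataFrame:
    """IVW excluding each instrument in turn.

    Flags rows whose estimate changes sign or significance (at ``alpha``)
    relative to the full-set estimate.
    """
    if len(ivs) < 3:
        raise MRError("leave-one-out needs >= 3 instruments")
    full = ivw(ivs, weighting=weighting)
    snps = (ivs["snp"] if "snp" in ivs else pd.Series(range(len(ivs)))).to_numpy()
    rows = []
    for i in range(len(ivs)):
        sub = ivs.drop(ivs.index[i])
        est = ivw(sub, weighting=weighting)
        flag = (np.sign(est.beta) != np.sign(full.beta)) or \
            ((est.p_value < alpha) != (full.p_value < alpha))
        rows.append((snps[i], est.beta, est.se, est.p_value, flag))
    return pd.DataFrame(rows, columns=["excluded_snp", "beta", "se", "p", "flagged"])


def funnel_data(ivs: pd.DataFrame, estimate: MREstimate | None = None):
    """Per-variant (ratio, precision) pairs for a funnel plot, with the
    Egger intercept p as the asymmetry statistic."""
    bx, bx_se, by, by_se = _cols(ivs)
    ratios = by / bx
    prec = np.abs(bx) / by_se
    snps = (ivs["snp"] if "snp" in ivs else pd.Series(range(len(ivs)))).to_numpy()
    df = pd.DataFrame({"snp": snps, "ratio": ratios, "precision": prec})
    asym_p = np.nan
    if len(ivs) >= 3:
        _, _, _, asym_p = egger(ivs)
    return df, asym_p


@dataclass
class MRResults:
    """Combined univariable-MR output for one instrument set."""

    estimates: dict
    radial: RadialResult | None = None
    presso: PressoResult | None = None
    steiger: SteigerResult | None = None
    loo: pd.DataFrame | None = None
    egger_intercept: tuple | None = None

    def table(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            row = {"METHOD": name, "NSNP": est.n_snp, "BETA": est.beta,
                   "SE": est.se, "P": est.p_value,
                   "Q": est.extra.get("q", np.nan),
                   "Q_P": est.extra.get("q_p", np.nan),
                   "EGGER_INT": np.nan, "EGGER_INT_P": np.nan}
            if name == "egger" and self.egger_intercept is not None:
                row["EGGER_INT"] = self.egger_intercept[0]
                row["EGGER_INT_P"] = self.egger_intercept[2]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Univariable MR results"]
        for name, est in self.estimates.items():
            lines.append(f"  {name:18s} beta {est.beta:+.4f}  se {est.se:.4f}  "
                         f"p {est.p_value:.2e}  nSNP {est.n_snp}")
        if self.steiger is not None:
            lines.append(f"  steiger: correct direction = "
                         f"{self.steiger.direction_correct} "
                         f"(p {self.steiger.steiger_p:.2e})")
        return "\n".join(lines)


class UnivariableMR:
    """Model object bundling the estimator suite over one instrument frame."""

    def __init__(self, ivs: pd.DataFrame):
        if len(ivs) == 0:
            raise MRError("empty instrument set")
        self.ivs = ivs.reset_index(drop=True)

    def fit(self, seed: int = 0, n_boot: int = 1000, presso_sim: int = 1000,
            methods=("ivw", "radial", "egger", "wmedian", "wmode", "raps",
                     "presso")) -> MRResults:
        ivs = self.ivs
        estimates: dict = {}
        radial = presso = steig = loo = None
        egger_int = None
        k = len(ivs)
        if "ivw" in methods:
            estimates["ivw"] = ivw(ivs)
        if "radial" in methods and k >= 2:
            radial = ivw_radial(ivs)
            estimates["ivw_radial"] = radial.estimate
        if "egger" in methods and k >= 3:
            slope, b0, b0_se, b0_p = egger(ivs)
            estimates["egger"] = slope
            egger_int = (b0, b0_se, b0_p)
        elif "egger" in methods:
            logger.info("Egger skipped: fewer than 3 instruments")
        if "wmedian" in methods and k >= 3:
            estimates["weighted_median"] = weighted_median(ivs, n_boot, seed)
        if "wmode" in methods and k >= 3:
            estimates["weighted_mode"] = weighted_mode(ivs, n_boot=n_boot,
                                                       seed=seed + 1)
        if "raps" in methods and k >= 3:
            estimates["raps"] = raps(ivs)
        if "presso" in methods and k >= 4:
            presso = mr_presso(ivs, n_sim=presso_sim, seed=seed + 2)
            estimates["presso_raw"] = presso.raw
            if presso.outliers:
                estimates["presso_corrected"] = presso.corrected
        try:
            steig = steiger_test(ivs)
        except MRError:
            logger.info("Steiger test skipped: sample sizes unavailable")
        if k >= 3:
            loo = leave_one_out(ivs)
        return MRResults(estimates=estimates, radial=radial, presso=presso,
                         steiger=steig, loo=loo, egger_intercept=egger_int)
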