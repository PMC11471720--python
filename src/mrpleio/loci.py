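"""Locus-level Bayesian pleiotropy: four-model posteriors from Wakefield
approximate Bayes factors.

For each LD-independent locus the evidence for five configurations is
compared: (0) no association, (1) association with the exposure only,
(2) outcome only, (3) both traits through one shared variant, (4) both
traits through two distinct variants.  Per-SNP evidence is the Wakefield
approximate Bayes factor averaged over a grid of prior effect scales;
regional evidence assumes a uniform prior over which member SNP is causal.
A locus with PPA3 >= 0.9 is called pleiotropic, and the summed-PPA ratio
ppa3 / (ppa1 + ppa3 + ppa4) across loci measures how much of the exposure
signal is shared with the outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

#: prior standard deviations of the (standardized) effect, averaged equally
DEFAULT_PRIOR_SD_GRID = (0.01, 0.1, 0.5)
#: prior probabilities of models 0..4
DEFAULT_MODEL_PRIORS = (0.80, 0.05, 0.05, 0.05, 0.05)
DEFAULT_PPA3_THRESHOLD = 0.9
#: a SNP is exported as the shared variant when its joint ABF carries at
#: least this fraction of the locus model-3 evidence
SHARED_SNP_CONTRIB = 0.5


class LocusError(ValueError):
    pass


@dataclass
class LocusDefinition:
    locus_id: str
    chrom: str
    start: int
    end: int
    snp_ids: list = field(default_factory=list)


@dataclass
class LocusPPA:
    locus_id: str
    n_snps: int
    ppa0: float
    ppa1: float
    ppa2: float
    ppa3: float
    ppa4: float
    shared_snp_ids: list = field(default_factory=list)

    @property
    def pleiotropic(self) -> bool:
        return self.ppa3 >= DEFAULT_PPA3_THRESHOLD


def wakefield_lnabf(beta, se, prior_sd) -> np.ndarray:
    """Log approximate Bayes factor for one association.

    With V = se^2, W = prior_sd^2 and z = beta/se:
    ``lnABF = 0.5 ln(V/(V+W)) + 0.5 z^2 W/(V+W)``.
    ``prior_sd`` may be a scalar or a grid; a grid is averaged on the
    natural scale (log-mean-exp).
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise LocusError("se must be > 0")
    W = np.atleast_1d(np.asarray(prior_sd, float)) ** 2
    if np.any(W <= 0):
        raise LocusError("prior_sd must be > 0")
    V = se**2
    z2 = (beta / se) ** 2
    # shape (grid, snps)
    lab = 0.5 * np.log(V / (V + W[:, None])) + 0.5 * z2 * W[:, None] / (V + W[:, None])
    m = lab.max(axis=0)
    return m + np.log(np.mean(np.exp(lab - m), axis=0))


def _logmeanexp(x: np.ndarray) -> float:
    m = x.max()
    return float(m + np.log(np.mean(np.exp(x - m))))


def locus_model_ppas(locus_id, bx, bx_se, by, by_se, snp_ids=None,
                     priors=DEFAULT_MODEL_PRIORS,
                     prior_sd_grid=DEFAULT_PRIOR_SD_GRID) -> LocusPPA:
    """Posterior probabilities of the five locus models.

    Regional Bayes factors average per-SNP evidence uniformly over member
    SNPs: BF1 = mean_i ABF1_i, BF2 = mean_i ABF2_i, BF3 = mean_i
    ABF1_i ABF2_i, and BF4 = mean over ordered pairs i != j of
    ABF1_i ABF2_j (two distinct causal variants).  PPAs are the
    prior-weighted normalized BFs with BF0 = 1.
    """
    bx = np.asarray(bx, float)
    k = len(bx)
    if k == 0:
        raise LocusError(f"{locus_id}: no SNPs")
    la1 = wakefield_lnabf(bx, bx_se, prior_sd_grid)
    la2 = wakefield_lnabf(by, by_se, prior_sd_grid)

    lbf1 = _logmeanexp(la1)
    lbf2 = _logmeanexp(la2)
    lbf3 = _logmeanexp(la1 + la2)
    if k > 1:
        # sum over i != j of ABF1_i ABF2_j = sum_i sum_j - sum_i (same i)
        m = max(la1.max(), la2.max())
        s1 = np.exp(la1 - m).sum()
        s2 = np.exp(la2 - m).sum()
        s12 = np.exp(la1 + la2 - 2 * m).sum()
        cross = s1 * s2 - s12
        if cross <= 0:
            lbf4 = -np.inf
        else:
            lbf4 = 2 * m + np.log(cross) - np.log(k * (k - 1))
    else:
        lbf4 = -np.inf
        logger.debug("locus %s has a single SNP: ppa4 forced to 0", locus_id)

    lpost = np.array([0.0, lbf1, lbf2, lbf3, lbf4]) + np.log(np.asarray(priors, float))
    m = lpost[np.isfinite(lpost)].max()
    post = np.where(np.isfinite(lpost), np.exp(lpost - m), 0.0)
    post = post / post.sum()

    # SNPs dominating the model-3 evidence
    shared = []
    if snp_ids is not None:
        contrib = np.exp(la1 + la2 - (la1 + la2).max())
        contrib = contrib / contrib.sum()
        shared = [s for s, c in zip(snp_ids, contrib) if c >= SHARED_SNP_CONTRIB]
    return LocusPPA(locus_id=str(locus_id), n_snps=k,
                    ppa0=float(post[0]), ppa1=float(post[1]), ppa2=float(post[2]),
                    ppa3=float(post[3]), ppa4=float(post[4]),
                    shared_snp_ids=shared)


def assign_loci(sumstats: SummaryStats, locus_table: pd.DataFrame) -> list:
    """Build LocusDefinitions from a CHR/START/END partition table
    (1-based inclusive, non-overlapping)."""
    defs = []
    by_chrom = {c: g.sort_values("pos") for c, g in sumstats.df.groupby("chrom")}
    for i, row in enumerate(locus_table.itertuples(index=False)):
        chrom = str(row.CHR)
        snps: list = []
        g = by_chrom.get(chrom)
        if g is not None:
            pos = g["pos"].to_numpy()
            lo = np.searchsorted(pos, int(row.START), side="left")
            hi = np.searchsorted(pos, int(row.END), side="right")
            snps = list(g["snp"].to_numpy()[lo:hi])
        defs.append(LocusDefinition(locus_id=f"locus{i + 1:04d}", chrom=chrom,
                                    start=int(row.START), end=int(row.END),
                                    snp_ids=snps))
    return defs


def locus_scan(exposure: SummaryStats, outcome: SummaryStats,
               locus_table: pd.DataFrame,
               priors=DEFAULT_MODEL_PRIORS,
               prior_sd_grid=DEFAULT_PRIOR_SD_GRID) -> list:
    """Per-locus PPAs over the SNPs present in both traits."""
    ex = exposure.df.set_index("snp")
    ou = outcome.df.set_index("snp")
    common = ex.index.intersection(ou.index)
    ex, ou = ex.loc[common], ou.loc[common]
    out = []
    for ld in assign_loci(exposure, locus_table):
        snps = [s for s in ld.snp_ids if s in ex.index]
        if not snps:
            continue
        out.append(locus_model_ppas(
            ld.locus_id, ex.loc[snps, "beta"].to_numpy(), ex.loc[snps, "se"].to_numpy(),
            ou.loc[snps, "beta"].to_numpy(), ou.loc[snps, "se"].to_numpy(),
            snp_ids=snps, priors=priors, prior_sd_grid=prior_sd_grid))
    return out


def call_pleiotropic_loci(ppas: list, threshold: float = DEFAULT_PPA3_THRESHOLD) -> set:
    """Loci with ppa3 >= threshold (inclusive)."""
    return {p.locus_id for p in ppas if p.ppa3 >= threshold}


def pleiotropy_proportion(ppas: list, count_ratio: bool = False,
                          threshold: float = DEFAULT_PPA3_THRESHOLD) -> float:
    """Fraction of exposure-influencing locus signal shared with the outcome.

    Default: ratio of PPA sums, sum(ppa3) / sum(ppa1 + ppa3 + ppa4) across
    loci.  With ``count_ratio=True``: thresholded locus counts instead
    (|ppa3 >= t| / |max-model in {1,3,4}|).
    """
    if not ppas:
        raise LocusError("no locus PPAs")
    if count_ratio:
        num = sum(1 for p in ppas if p.ppa3 >= threshold)
        den = sum(1 for p in ppas
                  if max(p.ppa1, p.ppa3, p.ppa4) >= threshold)
        if den == 0:
            logger.warning("no exposure-associated loci at threshold: proportion undefined")
            return np.nan
        return num / den
    num = sum(p.ppa3 for p in ppas)
    den = sum(p.ppa1 + p.ppa3 + p.ppa4 for p in ppas)
    if den == 0:
        logger.warning("zero denominator: pleiotropy proportion undefined")
        return np.nan
    return num / den


def ppa_table(ppas: list) -> pd.DataFrame:
    rows = [(p.locus_id, p.n_snps, p.ppa1, p.ppa2, p.ppa3, p.ppa4,
             p.pleiotropic) for p in ppas]
    return pd.DataFrame(rows, columns=["LOCUS", "NSNPS", "PPA1", "PPA2",
                                       "PPA3", "PPA4", "FLAG"])


def pleiotropic_snps_from_loci(ppas: list,
                               threshold: float = DEFAULT_PPA3_THRESHOLD) -> set:
    """SNPs driving model 3 in called loci (for instrument exclusion)."""
    out: set = set()
    for p in ppas:
        if p.ppa3 >= threshold:
            out.update(p.shared_snp_ids)
    return out
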