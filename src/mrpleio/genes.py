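"""Gene-level association and the shared-gene pleiotropy proportion.

SNPs are assigned to genes by a +/- 500 kb window around the gene body; each
gene is tested with the SNP-wise mean chi-square statistic, whose null is a
weighted sum of 1-df chi-squares with weights the eigenvalues of the LD
correlation matrix of the member SNPs.  The tail probability is computed by
Imhof numerical integration, falling back to a two-moment (Satterthwaite /
Brown) chi-square approximation when the integral fails to converge.

A gene is trait-associated when p < 0.05/G (G = number of annotated genes);
if fewer than five genes pass, the threshold relaxes to 5/G.  Horizontal
pleiotropy between an exposure and an outcome is then summarized as the
proportion of exposure-associated genes that are also outcome-associated,
and the SNPs inside those shared genes are exported for instrument
exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .ld import LDReference
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_KB = 500.0
#: eigenvalue floor, as a fraction of the leading eigenvalue
EIGEN_FLOOR_FRAC = 1e-4


class GeneTestError(ValueError):
    pass


@dataclass
class GeneAnnotation:
    """A gene with its assignment window and member SNPs."""

    gene_id: str
    chrom: str
    start: int
    end: int
    window_start: int
    window_end: int
    snp_ids: list = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class GenePleiotropySummary:
    exposure_sig_genes: set
    outcome_sig_genes: set
    shared_genes: set
    shared_proportion: float
    pleiotropic_snp_ids: set
    defined: bool = True


def annotate_snps_to_genes(sumstats: SummaryStats, gene_table: pd.DataFrame,
                           window_kb: float = DEFAULT_WINDOW_KB) -> list:
    """Assign SNPs to genes by position (1-based inclusive windows).

    ``gene_table`` columns: GENE, CHR, START, END.  A SNP belongs to a gene
    iff ``start - w <= pos <= end + w`` on the same chromosome; one SNP may
    fall in several overlapping windows.  Genes with zero SNPs are returned
    too (callers drop them from testing but count them in reports).
    """
    if len(gene_table) == 0:
        raise GeneTestError("empty gene table")
    w = int(round(window_kb * 1000))
    out = []
    df = sumstats.df
    by_chrom = {c: g.sort_values("pos") for c, g in df.groupby("chrom")}
    for row in gene_table.itertuples(index=False):
        chrom = str(row.CHR)
        ws, we = int(row.START) - w, int(row.END) + w
        snps: list = []
        g = by_chrom.get(chrom)
        if g is not None:
            pos = g["pos"].to_numpy()
            lo = np.searchsorted(pos, ws, side="left")
            hi = np.searchsorted(pos, we, side="right")
            snps = list(g["snp"].to_numpy()[lo:hi])
        out.append(GeneAnnotation(gene_id=str(row.GENE), chrom=chrom,
                                  start=int(row.START), end=int(row.END),
                                  window_start=ws, window_end=we, snp_ids=snps))
    return out


def _imhof_tail(q: float, lam: np.ndarray):
    """P(sum lam_i chi2_1 > q) by Imhof's integral; None when the quadrature
    does not converge cleanly."""

    def theta(u):
        return 0.5 * np.sum(np.arctan(lam[:, None] * u), axis=0) - 0.5 * q * u

    def rho(u):
        return np.prod((1.0 + (lam[:, None] * u) ** 2) ** 0.25, axis=0)

    def integrand(u):
        u = np.atleast_1d(u)
        return (np.sin(theta(u)) / (u * rho(u)))[0]

    import warnings as _warnings
    try:
        with np.errstate(over="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    except Exception:
        return None
    if not np.isfinite(val) or err > 1e-4:
        return None
    p = 0.5 + val / np.pi
    return float(min(max(p, 0.0), 1.0))


def _two_moment_tail(q: float, lam: np.ndarray) -> float:
    """Satterthwaite/Brown approximation: match mean and variance to c chi2_df."""
    mu = lam.sum()
    var = 2.0 * (lam**2).sum()
    c = var / (2.0 * mu)
    dof = 2.0 * mu**2 / var
    return float(stats.chi2.sf(q / c, dof))


def weighted_chi2_tail(q: float, lam: np.ndarray) -> float:
    """Upper tail of a weighted sum of independent 1-df chi-squares."""
    lam = np.asarray(lam, float)
    lam = lam[lam > 0]
    if len(lam) == 0:
        return 1.0
    if len(lam) == 1:
        return float(stats.chi2.sf(q / lam[0], 1))
    if lam.max() - lam.min() <= 1e-12 * lam.max():
        # equal eigenvalues (e.g. identity LD): exact chi2_k reduction
        return float(stats.chi2.sf(q / lam.mean(), len(lam)))
    p = _imhof_tail(q, lam)
    if p is None or p <= 1e-12:
        # the oscillatory integral loses accuracy in the far tail
        logger.debug("Imhof integration inaccurate at q=%.3g; using two-moment "
                     "approximation", q)
        p = _two_moment_tail(q, lam)
    return min(max(p, np.nextafter(0, 1)), 1.0)


@dataclass
class GeneTestResult:
    gene_id: str
    n_snps: int
    statistic: float
    p_value: float


def gene_pvalue(snp_z_scores, ld_submatrix, gene_id: str = "gene") -> GeneTestResult:
    """SNP-wise mean chi-square test for one gene.

    ``statistic`` is the mean of the member SNPs' chi-squares; under the null
    the sum of chi-squares is distributed as a weighted sum of 1-df
    chi-squares with weights the eigenvalues of the (regularized) LD
    correlation matrix.
    """
    z = np.asarray(snp_z_scores, float)
    R = np.asarray(ld_submatrix, float)
    k = len(z)
    if R.shape != (k, k):
        raise GeneTestError(f"{gene_id}: LD matrix shape {R.shape} does not "
                            f"match {k} z-scores")
    if k == 0:
        raise GeneTestError(f"{gene_id}: no SNPs")
    q = float(np.sum(z**2))
    lam = np.linalg.eigvalsh((R + R.T) / 2.0)
    floor = EIGEN_FLOOR_FRAC * lam.max()
    if lam.max() <= 0:
        raise GeneTestError(f"{gene_id}: LD matrix not positive semidefinite")
    lam = np.maximum(lam, floor)
    p = weighted_chi2_tail(q, lam)
    return GeneTestResult(gene_id=gene_id, n_snps=k, statistic=q / k, p_value=p)


def gene_test_table(sumstats: SummaryStats, annotations: list,
                    ldref: LDReference) -> pd.DataFrame:
    """Run the mean-chi2 test for every annotated gene with >= 1 SNP.

    Returns a frame GENE, NSNPS, STAT, P sorted by gene id.
    """
    zmap = dict(zip(sumstats.df["snp"], sumstats.z))
    rows = []
    for ann in annotations:
        snps = [s for s in ann.snp_ids if s in zmap]
        if not snps:
            continue
        z = np.array([zmap[s] for s in snps])
        R = ldref.submatrix(snps)
        res = gene_pvalue(z, R, gene_id=ann.gene_id)
        rows.append((ann.gene_id, res.n_snps, res.statistic, res.p_value))
    return pd.DataFrame(rows, columns=["GENE", "NSNPS", "STAT", "P"]) \
        .sort_values("GENE").reset_index(drop=True)


def significant_genes(results: pd.DataFrame, n_annotated_genes: int):
    """Apply the 0.05/G rule with the 5/G fallback.

    Primary threshold 0.05/G; if fewer than five genes pass, re-threshold at
    5/G.  Returns ``(set of gene ids, threshold actually used)``.
    """
    if n_annotated_genes <= 0:
        raise GeneTestError("no annotated genes")
    primary = 0.05 / n_annotated_genes
    sig = set(results.loc[results["P"] < primary, "GENE"])
    threshold = primary
    if len(sig) < 5:
        threshold = 5.0 / n_annotated_genes
        sig = set(results.loc[results["P"] < threshold, "GENE"])
    return sig, threshold


def shared_gene_proportion(exposure_results: pd.DataFrame,
                           outcome_results: pd.DataFrame,
                           annotations: list,
                           n_annotated_genes: int | None = None) -> GenePleiotropySummary:
    """Shared-gene pleiotropy summary for one exposure-outcome pair.

    ``shared_proportion`` = |exposure-and-outcome significant| / |exposure
    significant|; the pleiotropic SNP list is the union of SNPs annotated to
    the shared genes.  Undefined (flagged) when no gene is exposure-
    significant.
    """
    G = n_annotated_genes if n_annotated_genes is not None else len(annotations)
    exp_sig, _ = significant_genes(exposure_results, G)
    out_sig, _ = significant_genes(outcome_results, G)
    shared = exp_sig & out_sig
    snps: set = set()
    for ann in annotations:
        if ann.gene_id in shared:
            snps.update(ann.snp_ids)
    if len(exp_sig) == 0:
        logger.warning("no exposure-significant genes: shared proportion undefined")
        return GenePleiotropySummary(exp_sig, out_sig, shared, np.nan, snps,
                                     defined=False)
    return GenePleiotropySummary(exp_sig, out_sig, shared,
                                 len(shared) / len(exp_sig), snps)
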