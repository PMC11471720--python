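"""Instrument construction: association threshold, LD clumping, harmonization
filters, and the staged removal ledger.

The selection proceeds through four reported steps: (1) association
threshold and LD clumping, (2) harmonization and palindromic-SNP exclusion,
(3) exclusion of instruments more strongly associated with the outcome than
the exposure (p_outcome < p_exposure), together with the confounder
blocklist and the weak-instrument rule F = beta^2/se^2 < 10, giving the
*initial* set, and (4) removal of pleiotropic SNPs, radial-IVW outliers and
(under the genome-wide threshold only) instruments nominally associated
with the outcome, giving the *final* set.  Every removed SNP carries exactly
one removal reason and the per-step counts are monotone non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import LDReference
from .sumstats import SummaryStats, harmonize, kept_pairs

logger = logging.getLogger(__name__)


class IVSelectionError(ValueError):
    pass


@dataclass
class IVSelectionConfig:
    p_threshold_primary: float = 5e-8
    p_threshold_relaxed: float = 5e-6
    #: relaxed threshold triggers when > this fraction of genome-wide
    #: candidates are absent from the outcome GWAS (strict >)
    missingness_trigger: float = 0.65
    #: ...or when fewer than this many genome-wide candidates exist
    min_candidates: int = 10
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    outcome_assoc_p: float = 0.05
    palindrome_eaf_window: tuple = (0.42, 0.58)


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome pairs with selection provenance.

    ``df`` columns: snp, chrom, pos, bx, bx_se, px, by, by_se, py, f_stat...
    ``trace`` is an ordered list of (step_name, n_remaining); ``removals``
    maps each removed snp to its single reason.
    """

    df: pd.DataFrame
    trace: list
    removals: dict
    threshold_used: float
    stage: str

    @property
    def n_snp(self) -> int:
        return len(self.df)

    def four_step_ledger(self) -> list:
        """The four nSNP counts reported per analysis: after (1) threshold +
        clumping, (2) harmonization + palindrome removal, (3) outcome-p /
        confounder / weak-instrument filters (= initial set), (4) pleiotropy
        -driven removals (= final set; equals step 3 for stage='initial')."""
        wanted = ["step1_clump", "step2_harmonize", "step3_filters", "step4_pleiotropy"]
        counts = dict(self.trace)
        ledger = []
        last = None
        for w in wanted:
            last = counts.get(w, last)
            ledger.append(last)
        return ledger


def choose_threshold(exposure: SummaryStats, outcome: SummaryStats,
                     config: IVSelectionConfig = IVSelectionConfig()):
    """Pick the candidate-instrument p threshold.

    The relaxed threshold applies iff the genome-wide-significant candidate
    count is below ``min_candidates`` or the fraction of those candidates
    missing from the outcome table exceeds ``missingness_trigger``
    (strictly).  Returns (threshold, decision record).
    """
    ex = exposure.df
    cand = ex.loc[ex["p"] < config.p_threshold_primary, "snp"]
    n_cand = len(cand)
    out_snps = set(outcome.df["snp"])
    n_missing = sum(1 for s in cand if s not in out_snps)
    frac_missing = n_missing / n_cand if n_cand else 1.0
    relaxed = (n_cand < config.min_candidates) or (frac_missing > config.missingness_trigger)
    threshold = config.p_threshold_relaxed if relaxed else config.p_threshold_primary
    n_relaxed = int((ex["p"] < config.p_threshold_relaxed).sum())
    if (relaxed and n_relaxed == 0) or (not relaxed and n_cand == 0):
        raise IVSelectionError("no candidate instruments at either threshold")
    record = {"n_candidates_primary": n_cand, "n_missing_from_outcome": n_missing,
              "frac_missing": frac_missing, "relaxed": relaxed,
              "threshold": threshold,
              "min_candidates_drove_decision": n_cand < config.min_candidates}
    logger.info("threshold decision: %s", record)
    return threshold, record


def ld_clump(candidates: pd.DataFrame, ld_reference: LDReference,
             r2_max: float = 0.001, window_kb: float = 10_000.0) -> list:
    """Greedy LD clumping: most significant first.

    Candidates need snp, chrom, pos, p columns.  A SNP is accepted iff its
    r² with every already-accepted SNP within ``window_kb`` (center-to-
    center, inclusive) on the same chromosome is below ``r2_max``.  Ties on
    p break by ascending (chrom, pos).  SNPs absent from the reference are
    treated as independent (warned).
    """
    df = candidates.sort_values(["p", "chrom", "pos"], kind="mergesort")
    accepted: list = []
    acc_pos: list = []
    window_bp = window_kb * 1000.0
    warned = False
    known = set(ld_reference.snp)
    for row in df.itertuples(index=False):
        ok = True
        if row.snp not in known:
            if not warned:
                logger.warning("snp %s absent from LD reference: treated as "
                               "independent", row.snp)
                warned = True
        else:
            for s, (c, p) in zip(accepted, acc_pos):
                if c == row.chrom and abs(p - row.pos) <= window_bp:
                    if ld_reference.r2(row.snp, s) >= r2_max:
                        ok = False
                        break
        if ok:
            accepted.append(row.snp)
            acc_pos.append((row.chrom, row.pos))
    return accepted


def _with_f(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["f_stat"] = df["bx"] ** 2 / df["bx_se"] ** 2
    return df


def select_instruments(exposure: SummaryStats, outcome: SummaryStats,
                       ld_reference: LDReference,
                       config: IVSelectionConfig = IVSelectionConfig(),
                       blocklist: set | None = None) -> InstrumentSet:
    """Build the initially selected instrument set (steps 1-3)."""
    blocklist = blocklist or set()
    threshold, decision = choose_threshold(exposure, outcome, config)
    ex = exposure.df
    cand = ex[ex["p"] < threshold][["snp", "chrom", "pos", "p"]]
    clumped = ld_clump(cand, ld_reference, config.clump_r2, config.clump_window_kb)
    trace = [("candidates", len(cand)), ("step1_clump", len(clumped))]
    removals: dict = {}

    sub = SummaryStats(trait_name=exposure.trait_name,
                       df=ex[ex["snp"].isin(clumped)].reset_index(drop=True),
                       genome_build=exposure.genome_build)
    pairs = harmonize(sub, outcome, palindrome_eaf_window=config.palindrome_eaf_window)
    for row in pairs.itertuples(index=False):
        if row.action.startswith("dropped"):
            removals[row.snp] = row.action
    kept = kept_pairs(pairs)
    # clumped SNPs absent from the outcome table count as harmonization losses
    for s in clumped:
        if s not in set(pairs["snp"]):
            removals[s] = "missing_in_outcome"
    trace.append(("step2_harmonize", len(kept)))

    mask_block = kept["snp"].isin(blocklist)
    for s in kept.loc[mask_block, "snp"]:
        removals[s] = "confounder_blocklist"
    kept = kept[~mask_block]

    mask_outcome = kept["py"] < kept["px"]
    for s in kept.loc[mask_outcome, "snp"]:
        removals[s] = "outcome_p_below_exposure_p"
    kept = kept[~mask_outcome]

    kept = _with_f(kept)
    mask_weak = kept["f_stat"] < config.f_min
    for s in kept.loc[mask_weak, "snp"]:
        removals[s] = "weak_instrument"
    kept = kept[~mask_weak].reset_index(drop=True)
    trace.append(("step3_filters", len(kept)))

    if len(kept) == 0:
        raise IVSelectionError("instrument set emptied at step 3 "
                               "(filters on outcome p / blocklist / F)")
    logger.info("initial instrument selection: %s", trace)
    return InstrumentSet(df=kept, trace=trace, removals=removals,
                         threshold_used=threshold, stage="initial")


def finalize_ivs(initial: InstrumentSet, pleiotropic_snps: set,
                 radial_outliers: set,
                 config: IVSelectionConfig = IVSelectionConfig()) -> InstrumentSet:
    """Apply the step-4 removals to an initial set.

    Excluded: pleiotropic SNPs from the gene/locus scans, radial-IVW
    outliers, and — only when the genome-wide threshold was used —
    instruments with outcome p below ``outcome_assoc_p``.  The overlap
    between outliers and outcome-associated instruments is recorded.
    """
    df = initial.df.copy()
    removals = dict(initial.removals)
    outcome_assoc: set = set()
    if initial.threshold_used <= config.p_threshold_primary:
        outcome_assoc = set(df.loc[df["py"] < config.outcome_assoc_p, "snp"])
    present = set(df["snp"])
    union = (pleiotropic_snps | radial_outliers | outcome_assoc) & present
    for s in sorted(union):
        if s in pleiotropic_snps:
            removals[s] = "pleiotropic"
        elif s in radial_outliers:
            removals[s] = "radial_outlier"
        else:
            removals[s] = "outcome_associated"
    df = df[~df["snp"].isin(union)].reset_index(drop=True)
    trace = initial.trace + [("step4_pleiotropy", len(df))]
    n_out = len(radial_outliers & present)
    overlap = (len(radial_outliers & outcome_assoc & present) / n_out
               if n_out else np.nan)
    logger.info("final instrument selection: %s (outlier/outcome-assoc "
                "overlap %.3f)", trace, overlap)
    if len(df) < 3:
        logger.warning("final set has %d instruments: Egger/median unreliable",
                       len(df))
    fs = InstrumentSet(df=df, trace=trace, removals=removals,
                       threshold_used=initial.threshold_used, stage="final")
    fs.outlier_outcome_overlap = overlap
    return fs
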