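"""End-to-end orchestration: heritability gate -> genetic correlation ->
pleiotropy scans -> instrument selection -> univariable MR (initial and
final sets) -> multivariable MR, with study-wide Bonferroni reporting.

The pipeline consumes validated in-memory objects (or file paths via
:class:`StudyConfig`) and emits a :class:`StudyReport` whose blocks mirror
the study outputs: a heritability table with gate decisions, a genetic-
correlation table, per-pair pleiotropy proportions, MR panels with the
four-number instrument ledgers, and per-test Bonferroni verdicts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genes as genemod
from . import loci as locimod
from .instruments import IVSelectionConfig, InstrumentSet, finalize_ivs, select_instruments
from .ld import LDReference
from .ldsc import estimate_h2, estimate_rg, heritability_gate
from .mr import UnivariableMR, ivw_radial
from .mvmr import MVMRError, MultivariableMR, build_mv_instruments
from .sumstats import SummaryStats, read_sumstats

logger = logging.getLogger(__name__)


def bonferroni_threshold(n_exposures: int, n_outcomes: int,
                         alpha: float = 0.05) -> float:
    """Study-wide significance threshold alpha / (n_exposures * n_outcomes)."""
    if n_exposures <= 0 or n_outcomes <= 0:
        raise ValueError("exposure and outcome counts must be positive")
    return alpha / (n_exposures * n_outcomes)


@dataclass
class StudyConfig:
    """File-based configuration for a full study run."""

    exposure_paths: dict
    outcome_paths: dict
    ldscore_path: str
    r2_path: str
    gene_path: str
    locus_path: str
    blocklist_path: str | None = None
    m_total: int | None = None
    ldsc_blocks: int = 200
    z_threshold: float = 4.0
    alpha: float = 0.05
    gene_window_kb: float = 500.0
    iv: IVSelectionConfig = field(default_factory=IVSelectionConfig)
    #: exposure pairs enter MVMR when their rg p-value is below this times
    #: the study alpha structure: "bonferroni" | "nominal"
    mvmr_trigger: str = "bonferroni"
    seed: int = 0


@dataclass
class StudyReport:
    heritability: pd.DataFrame
    gate_kept: list
    gate_excluded: list
    genetic_correlation: pd.DataFrame
    pleiotropy: pd.DataFrame
    mr_panels: pd.DataFrame
    ledgers: dict
    mvmr_panels: pd.DataFrame
    bonferroni: float
    seed: int

    def to_dict(self) -> dict:
        def df2rec(df):
            return json.loads(df.to_json(orient="records")) if df is not None else []
        return {
            "heritability": df2rec(self.heritability),
            "gate_kept": self.gate_kept,
            "gate_excluded": self.gate_excluded,
            "genetic_correlation": df2rec(self.genetic_correlation),
            "pleiotropy": df2rec(self.pleiotropy),
            "mr_panels": df2rec(self.mr_panels),
            "ledgers": self.ledgers,
            "mvmr_panels": df2rec(self.mvmr_panels),
            "bonferroni": self.bonferroni,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _load_tables(config: StudyConfig):
    exposures = {n: read_sumstats(p, trait_name=n)
                 for n, p in config.exposure_paths.items()}
    outcomes = {n: read_sumstats(p, trait_name=n)
                for n, p in config.outcome_paths.items()}
    ldref = LDReference.from_files(config.ldscore_path, config.r2_path)
    gene_table = pd.read_csv(config.gene_path, sep="\t", comment="#")
    locus_table = pd.read_csv(config.locus_path, sep="\t", comment="#")
    blocklist: set = set()
    if config.blocklist_path:
        for line in Path(config.blocklist_path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                blocklist.add(line)
    return exposures, outcomes, ldref, gene_table, locus_table, blocklist


def run_pipeline(config: StudyConfig) -> StudyReport:
    """Execute the full study flow from files; deterministic under seed."""
    exposures, outcomes, ldref, gene_table, locus_table, blocklist = _load_tables(config)
    return run_study(exposures, outcomes, ldref, gene_table, locus_table,
                     blocklist=blocklist, m_total=config.m_total,
                     ldsc_blocks=config.ldsc_blocks,
                     z_threshold=config.z_threshold, alpha=config.alpha,
                     gene_window_kb=config.gene_window_kb, iv=config.iv,
                     mvmr_trigger=config.mvmr_trigger, seed=config.seed)


def mvmr_pairs(rg_table: pd.DataFrame, threshold: float) -> list:
    """Exposure pairs whose genetic-correlation p falls below the trigger
    threshold (the rule that decides which exposures enter MVMR jointly)."""
    pairs = []
    sub = rg_table[rg_table["kind"] == "exposure-exposure"]
    for row in sub.itertuples(index=False):
        if np.isfinite(row.p) and row.p < threshold:
            pairs.append(tuple(sorted((row.trait1, row.trait2))))
    return sorted(set(pairs))


def run_study(exposures: dict, outcomes: dict, ldref: LDReference,
              gene_table: pd.DataFrame, locus_table: pd.DataFrame,
              blocklist: set | None = None, m_total: int | None = None,
              ldsc_blocks: int = 200, z_threshold: float = 4.0,
              alpha: float = 0.05, gene_window_kb: float = 500.0,
              iv: IVSelectionConfig = IVSelectionConfig(),
              mvmr_trigger: str = "bonferroni", seed: int = 0) -> StudyReport:
    """In-memory variant of :func:`run_pipeline`."""
    blocklist = blocklist or set()
    ld_scores = ldref.ld_scores()
    M = m_total if m_total is not None else len(ldref)
    bonf = bonferroni_threshold(len(exposures), len(outcomes), alpha)

    # 1. heritability + gate
    h2_rows = []
    h2_results = {}
    for name, ss in {**exposures, **outcomes}.items():
        res = estimate_h2(ss, ld_scores, M, ldsc_blocks)
        res.trait_name = name    # report under the study's label
        h2_results[name] = res
        h2_rows.append({"trait": name, "h2": res.h2, "h2_se": res.h2_se,
                        "z": res.z_score, "intercept": res.intercept,
                        "intercept_se": res.intercept_se,
                        "mean_chi2": res.mean_chi2, "m_snps": res.m_snps_used})
    kept, excluded = heritability_gate(h2_results.values(), z_threshold)
    kept_names = [r.trait_name for r in kept]
    gate_excluded = [r.trait_name for r in excluded]
    exp_kept = {n: s for n, s in exposures.items() if n in kept_names}
    out_kept = {n: s for n, s in outcomes.items() if n in kept_names}

    # 2. genetic correlations: exposure-outcome and exposure-exposure
    rg_rows = []
    pairs = [(e, o, "exposure-outcome") for e in exp_kept for o in out_kept]
    exp_names = list(exp_kept)
    pairs += [(exp_names[i], exp_names[j], "exposure-exposure")
              for i in range(len(exp_names)) for j in range(i + 1, len(exp_names))]
    for t1, t2, kind in pairs:
        ss1 = exp_kept.get(t1) or out_kept.get(t1)
        ss2 = exp_kept.get(t2) or out_kept.get(t2)
        res = estimate_rg(ss1, ss2, ld_scores, M, ldsc_blocks)
        rg_rows.append({"trait1": t1, "trait2": t2, "kind": kind,
                        "rg": res.rg, "rg_se": res.rg_se, "p": res.p_value,
                        "intercept": res.gencov_intercept,
                        "intercept_se": res.gencov_intercept_se,
                        "defined": res.defined})
    rg_table = pd.DataFrame(rg_rows) if rg_rows else pd.DataFrame(
        columns=["trait1", "trait2", "kind", "rg", "rg_se", "p",
                 "intercept", "intercept_se", "defined"])

    # 3-5. per exposure-outcome pair: pleiotropy scans, IVs, univariable MR
    pleio_rows = []
    mr_rows = []
    ledgers = {}
    pleio_sets = {}
    for e_name, ex in exp_kept.items():
        for o_name, ou in out_kept.items():
            ann = genemod.annotate_snps_to_genes(ex, gene_table, gene_window_kb)
            tested = [a for a in ann if a.n_snps > 0]
            gx = genemod.gene_test_table(ex, tested, ldref)
            gy = genemod.gene_test_table(ou, tested, ldref)
            gsum = genemod.shared_gene_proportion(gx, gy, tested,
                                                 n_annotated_genes=len(tested))
            ppas = locimod.locus_scan(ex, ou, locus_table)
            locus_prop = locimod.pleiotropy_proportion(ppas)
            locus_snps = locimod.pleiotropic_snps_from_loci(ppas)
            pleio_snps = set(gsum.pleiotropic_snp_ids) | locus_snps
            pleio_sets[(e_name, o_name)] = pleio_snps
            pleio_rows.append({
                "exposure": e_name, "outcome": o_name,
                "shared_gene_proportion": gsum.shared_proportion,
                "n_shared_genes": len(gsum.shared_genes),
                "n_exposure_genes": len(gsum.exposure_sig_genes),
                "locus_ppa_proportion": locus_prop,
                "n_pleiotropic_loci": len(locimod.call_pleiotropic_loci(ppas)),
                "n_pleiotropic_snps": len(pleio_snps)})

            initial = select_instruments(ex, ou, ldref, iv, blocklist)
            for stage, ivset in _stage_sets(initial, pleio_snps, iv):
                mr = UnivariableMR(ivset.df).fit(seed=seed)
                for mname, est in mr.estimates.items():
                    mr_rows.append({
                        "exposure": e_name, "outcome": o_name, "stage": stage,
                        "method": mname, "nsnp": est.n_snp, "beta": est.beta,
                        "se": est.se, "p": est.p_value,
                        "q": est.extra.get("q", np.nan),
                        "q_p": est.extra.get("q_p", np.nan),
                        "significant_bonferroni": bool(est.p_value < bonf)})
                ledgers[f"{e_name}|{o_name}|{stage}"] = ivset.four_step_ledger()

    mr_panels = pd.DataFrame(mr_rows) if mr_rows else pd.DataFrame()
    pleio_table = pd.DataFrame(pleio_rows) if pleio_rows else pd.DataFrame()

    # 6. multivariable MR for genetically correlated exposure pairs
    trigger = bonf if mvmr_trigger == "bonferroni" else alpha
    mv_rows = []
    for pair in mvmr_pairs(rg_table, trigger):
        for o_name, ou in out_kept.items():
            pleio = pleio_sets.get((pair[0], o_name), set()) | \
                pleio_sets.get((pair[1], o_name), set())
            for stage in ("initial", "final"):
                try:
                    mvset = build_mv_instruments(
                        [exp_kept[pair[0]], exp_kept[pair[1]]], ou, ldref, iv,
                        pleiotropic_snps=pleio if stage == "final" else None,
                        stage=stage)
                except MVMRError as exc:
                    logger.warning("MVMR %s->%s (%s) skipped: %s", pair,
                                   o_name, stage, exc)
                    continue
                table = MultivariableMR(mvset).fit(seed=seed)
                table.insert(0, "outcome", o_name)
                table.insert(0, "stage", stage)
                mv_rows.append(table)
    mvmr_panels = pd.concat(mv_rows, ignore_index=True) if mv_rows else pd.DataFrame()

    return StudyReport(
        heritability=pd.DataFrame(h2_rows), gate_kept=kept_names,
        gate_excluded=gate_excluded, genetic_correlation=rg_table,
        pleiotropy=pleio_table, mr_panels=mr_panels, ledgers=ledgers,
        mvmr_panels=mvmr_panels, bonferroni=bonf, seed=seed)


def _stage_sets(initial: InstrumentSet, pleio_snps: set,
                iv: IVSelectionConfig):
    """Yield (stage, instrument set) for the initial and final analyses.

    Radial outliers for the final stage come from the radial fit on the
    initial set, matching the staged design.
    """
    yield "initial", initial
    radial = ivw_radial(initial.df)
    final = finalize_ivs(initial, pleio_snps, radial.outliers, iv)
    if len(final.df) >= 2:
        yield "final", final
    else:
        logger.warning("final instrument set too small for MR; skipped")
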