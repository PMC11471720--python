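"""Synthetic two-trait GWAS summary statistics with known truth.

Generates the full test surface for the workflow without individual-level
genotypes: block-diagonal AR(1) LD, spike-and-slab exposure effects, a causal
effect of exposure on outcome, optional correlated and horizontal pleiotropy,
sample-overlap noise correlation, palindromic alleles, plus matching gene and
locus tables and a ground-truth record.

Effect-size bookkeeping is on the standardized-genotype scale: a variant with
standardized effect b contributes b^2 to trait variance, and the per-allele
effect written to the summary files is ``b / sqrt(2 p (1-p))``.  Estimated
marginal effects are the LD-convolved true effects plus estimation noise with
``se = 1/sqrt(2 n p (1-p))`` (unit-variance phenotype).

Genetic correlation and the causal effect are entangled by construction: the
causal pathway theta alone induces a total-effect correlation of
``theta * sqrt(h2_x / h2_y)``.  With ``rg=None`` the outcome-specific
polygenic component is independent of the exposure effects and that causal
value is the realized correlation.  With an explicit ``rg`` the generator
calibrates the total-effect correlation to it, which realizes the excess over
the causal contribution as correlated pleiotropy (a genuine exclusion-
restriction violation, useful for stress tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ld import LDReference
from .sumstats import SummaryStats

_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                         ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

#: base-pair spacing between adjacent simulated variants; chosen so a
#: +/- 500 kb gene window covers roughly one 50-SNP LD block
SNP_SPACING = 25_000


@dataclass
class SimulationConfig:
    """Parameters of the two-trait generator.

    Defaults are a desk-scale profile mirroring the statistical regime of
    large-biobank mineral-metabolism GWAS: SNP heritability ~0.1, sample
    sizes 10^5, a causal effect of 0.1 outcome units per exposure unit, a
    small set of horizontally pleiotropic variants, and modest sample
    overlap.
    """

    m_snps: int = 2000
    n_blocks: int = 40
    block_rho: float = 0.6
    maf_range: tuple = (0.05, 0.5)
    h2_x: float = 0.1
    h2_y: float = 0.1
    #: total-effect genetic correlation; None = causal pathway only
    rg: float | None = None
    theta: float = 0.1
    prop_causal_x: float = 0.1
    #: fraction of SNPs carrying outcome-specific effects (None = prop_causal_x)
    prop_causal_y: float | None = None
    #: causal variants cluster into this fraction of LD blocks per trait
    #: (independent block subsets for the two traits), emulating the sparse
    #: locus structure of real GWAS; 1.0 = uniform placement
    frac_active_blocks: float = 0.5
    n_horizontal_pleio: int = 10
    pleio_var: float = 5e-4
    n_x: int = 100_000
    n_y: int = 100_000
    overlap_frac: float = 0.0
    pheno_corr: float = 0.0
    palindromic_frac: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.m_snps % self.n_blocks != 0:
            raise ValueError("m_snps must be divisible by n_blocks")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if not (0 <= self.h2_x <= 1 and 0 <= self.h2_y <= 1):
            raise ValueError("heritabilities must be in [0, 1]")
        if self.rg is not None and not -1 <= self.rg <= 1:
            raise ValueError("rg must be in [-1, 1]")
        if self.rg not in (None, 0.0) and self.h2_x == 0:
            raise ValueError("rg != 0 requires h2_x > 0")
        if not 0 <= self.overlap_frac <= 1:
            raise ValueError("overlap_frac must be in [0, 1]")

    @property
    def block_size(self) -> int:
        return self.m_snps // self.n_blocks

    @property
    def causal_rg(self) -> float:
        """Total-effect correlation induced by the causal pathway alone."""
        if self.h2_y == 0:
            return 0.0
        val = self.theta * np.sqrt(self.h2_x / self.h2_y)
        return float(np.clip(val, -1.0, 1.0))

    @property
    def target_rg(self) -> float:
        return self.causal_rg if self.rg is None else self.rg


@dataclass
class TruthRecord:
    """Ground truth of one simulation, for parameter-recovery assertions.

    Standardized-scale per-SNP effects (``b_x``, ``b_y``), configured and
    realized heritabilities/correlation, and the identities of the
    horizontally pleiotropic and palindromic variants.
    """

    theta: float
    h2_x: float
    h2_y: float
    rg: float
    h2_x_realized: float
    h2_y_realized: float
    rg_realized: float
    b_x: np.ndarray
    b_y: np.ndarray
    snp: np.ndarray
    causal_x_snps: list
    pleiotropic_snps: list
    palindromic_snps: list

    def to_json(self, path) -> None:
        payload = {
            "theta": self.theta, "h2_x": self.h2_x, "h2_y": self.h2_y,
            "rg": self.rg, "h2_x_realized": self.h2_x_realized,
            "h2_y_realized": self.h2_y_realized, "rg_realized": self.rg_realized,
            "snp": list(map(str, self.snp)),
            "b_x": [float(f"{v:.10g}") for v in self.b_x],
            "b_y": [float(f"{v:.10g}") for v in self.b_y],
            "causal_x_snps": list(map(str, self.causal_x_snps)),
            "pleiotropic_snps": list(map(str, self.pleiotropic_snps)),
            "palindromic_snps": list(map(str, self.palindromic_snps)),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def simulate_ld_reference(config: SimulationConfig) -> LDReference:
    """Block-diagonal AR(1) LD: within a block r(i,j) = rho^|i-j|."""
    config.validate()
    B = config.block_size
    i = np.arange(B)
    R = config.block_rho ** np.abs(i[:, None] - i[None, :])
    snp = np.array([f"rs{i + 1}" for i in range(config.m_snps)])
    chrom = np.repeat("1", config.m_snps)
    pos = 1 + np.arange(config.m_snps) * SNP_SPACING
    block_index = np.repeat(np.arange(config.n_blocks), B)
    blocks = [R.copy() for _ in range(config.n_blocks)]
    return LDReference(snp=snp, chrom=chrom, pos=pos,
                       block_index=block_index, blocks=blocks)


def _active_snps(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Indices of SNPs inside a random subset of 'active' LD blocks."""
    nb, B = config.n_blocks, config.block_size
    n_active = max(1, round(config.frac_active_blocks * nb))
    blocks = rng.choice(nb, size=n_active, replace=False)
    return np.sort(np.concatenate([np.arange(b * B, (b + 1) * B) for b in blocks]))


def _draw_true_effects(config: SimulationConfig, rng: np.random.Generator):
    m = config.m_snps
    b_x = np.zeros(m)
    pool_x = _active_snps(config, rng)
    n_causal = (min(len(pool_x), max(1, round(config.prop_causal_x * m)))
                if config.h2_x > 0 else 0)
    causal_idx = (np.sort(rng.choice(pool_x, size=n_causal, replace=False))
                  if n_causal else np.array([], int))
    if n_causal:
        b_x[causal_idx] = rng.normal(0.0, np.sqrt(config.h2_x / n_causal), n_causal)

    # outcome total effects: c * b_x + outcome-specific spike-slab w (+ d later)
    rg = config.target_rg
    if config.h2_x > 0:
        c = rg * np.sqrt(config.h2_y / config.h2_x)
    else:
        c = 0.0
    var_w = config.h2_y * (1.0 - rg**2)
    w = np.zeros(m)
    if var_w > 0:
        prop_y = config.prop_causal_y if config.prop_causal_y is not None \
            else config.prop_causal_x
        pool_y = _active_snps(config, rng)
        n_causal_y = min(len(pool_y), max(1, round(prop_y * m)))
        idx_y = np.sort(rng.choice(pool_y, size=n_causal_y, replace=False))
        w[idx_y] = rng.normal(0.0, np.sqrt(var_w / n_causal_y), n_causal_y)
    b_y = c * b_x + w

    # horizontal pleiotropy: direct outcome effects on exposure-associated
    # SNPs (so the violating variants are selectable as instruments)
    pleio_idx = np.array([], int)
    if config.n_horizontal_pleio > 0:
        pool = causal_idx if len(causal_idx) >= config.n_horizontal_pleio else np.arange(m)
        pleio_idx = np.sort(rng.choice(pool, size=config.n_horizontal_pleio, replace=False))
        b_y[pleio_idx] += rng.normal(0.0, np.sqrt(config.pleio_var), len(pleio_idx))
    return b_x, b_y, causal_idx, pleio_idx


def _draw_alleles(config: SimulationConfig, rng: np.random.Generator):
    m = config.m_snps
    pal = rng.random(m) < config.palindromic_frac
    ea = np.empty(m, dtype="U1")
    oa = np.empty(m, dtype="U1")
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), m)
    non_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), m)
    for i in range(m):
        pair = _PALINDROMIC_PAIRS[pal_choice[i]] if pal[i] else _NONPALINDROMIC_PAIRS[non_choice[i]]
        ea[i], oa[i] = pair
    return ea, oa, pal


def simulate_joint_sumstats(config: SimulationConfig):
    """Generate exposure and outcome summary statistics plus truth and LD.

    Returns ``(exposure, outcome, truth, ld_reference)``.  Deterministic for
    a fixed config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ldref = simulate_ld_reference(config)
    m, B = config.m_snps, config.block_size
    nb = config.n_blocks

    eaf = rng.uniform(*config.maf_range, m)
    ea, oa, pal = _draw_alleles(config, rng)
    b_x, b_y, causal_idx, pleio_idx = _draw_true_effects(config, rng)

    R = ldref.blocks[0]          # identical AR(1) matrix in every block
    L = np.linalg.cholesky(R + 1e-12 * np.eye(B))

    # LD-convolved (marginal) standardized effects, blockwise
    mu_x = (b_x.reshape(nb, B) @ R).ravel()
    mu_y = (b_y.reshape(nb, B) @ R).ravel()

    n_shared = config.overlap_frac * min(config.n_x, config.n_y)
    rho_noise = n_shared * config.pheno_corr / np.sqrt(config.n_x * config.n_y)

    a = rng.standard_normal((nb, B))
    b = rng.standard_normal((nb, B))
    eta_x = (a @ L.T).ravel()
    eta_y = ((rho_noise * a + np.sqrt(1.0 - rho_noise**2) * b) @ L.T).ravel()

    z_x = np.sqrt(config.n_x) * mu_x + eta_x
    z_y = np.sqrt(config.n_y) * mu_y + eta_y

    scale = np.sqrt(2.0 * eaf * (1.0 - eaf))
    se_x = 1.0 / (scale * np.sqrt(config.n_x))
    se_y = 1.0 / (scale * np.sqrt(config.n_y))

    def _table(z, se, n, name):
        df = pd.DataFrame({
            "snp": ldref.snp, "chrom": ldref.chrom, "pos": ldref.pos,
            "ea": ea, "oa": oa, "eaf": eaf,
            "beta": z * se, "se": se, "p": np.nan,
            "n": float(n),
        })
        return SummaryStats.from_dataframe(df, trait_name=name)

    exposure = _table(z_x, se_x, config.n_x, "exposure")
    outcome = _table(z_y, se_y, config.n_y, "outcome")

    gx = float(np.sum(b_x**2))
    gy = float(np.sum(b_y**2))
    if gx > 0 and gy > 0:
        rg_real = float(np.sum(b_x * b_y) / np.sqrt(gx * gy))
    else:
        rg_real = 0.0
    truth = TruthRecord(
        theta=config.theta, h2_x=config.h2_x, h2_y=config.h2_y,
        rg=config.target_rg, h2_x_realized=gx, h2_y_realized=gy,
        rg_realized=rg_real, b_x=b_x, b_y=b_y, snp=ldref.snp,
        causal_x_snps=list(ldref.snp[causal_idx]),
        pleiotropic_snps=list(ldref.snp[pleio_idx]),
        palindromic_snps=list(ldref.snp[pal]),
    )
    return exposure, outcome, truth, ldref


def gene_table(config: SimulationConfig) -> pd.DataFrame:
    """One gene per LD block, its body spanning the central fifth of the
    block (GENE, CHR, START, END; 1-based inclusive)."""
    B = config.block_size
    rows = []
    for b in range(config.n_blocks):
        first = 1 + b * B * SNP_SPACING
        span = (B - 1) * SNP_SPACING
        start = first + 2 * span // 5
        end = first + 3 * span // 5
        rows.append((f"GENE{b + 1:04d}", "1", start, end))
    return pd.DataFrame(rows, columns=["GENE", "CHR", "START", "END"])


def locus_table(config: SimulationConfig) -> pd.DataFrame:
    """Non-overlapping loci tiling the chromosome, one per LD block
    (CHR, START, END; 1-based inclusive)."""
    B = config.block_size
    rows = []
    for b in range(config.n_blocks):
        start = 1 + b * B * SNP_SPACING if b == 0 else b * B * SNP_SPACING - SNP_SPACING // 2 + 1
        end = (b + 1) * B * SNP_SPACING - SNP_SPACING // 2 if b < config.n_blocks - 1 \
            else 1 + config.m_snps * SNP_SPACING
        rows.append(("1", start, end))
    return pd.DataFrame(rows, columns=["CHR", "START", "END"])


def write_fixture_bundle(config: SimulationConfig, out_dir) -> dict:
    """Write the complete text fixture set; byte-identical under one seed.

    Emits exposure/outcome summary statistics, LD-score and r² pair files,
    gene and locus tables, an (empty) confounder blocklist, the truth record
    and the YAML config that regenerates everything.
    Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exposure, outcome, truth, ldref = simulate_joint_sumstats(config)
    paths = {
        "exposure": out / "exposure.sumstats.tsv",
        "outcome": out / "outcome.sumstats.tsv",
        "ldscores": out / "ld.l2.ldscore.tsv",
        "r2_pairs": out / "ld.r2_pairs.tsv",
        "genes": out / "genes.tsv",
        "loci": out / "loci.tsv",
        "blocklist": out / "blocklist.txt",
        "truth": out / "truth.json",
        "config": out / "config.yaml",
    }

    def _write_ss(ss: SummaryStats, path):
        df = ss.df.rename(columns={"snp": "SNP", "chrom": "CHR", "pos": "POS",
                                   "ea": "A1", "oa": "A2", "eaf": "FREQ",
                                   "beta": "BETA", "se": "SE", "p": "P", "n": "N"})
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    _write_ss(exposure, paths["exposure"])
    _write_ss(outcome, paths["outcome"])
    ldref.write_ldscore_file(paths["ldscores"])
    ldref.write_r2_file(paths["r2_pairs"])
    gene_table(config).to_csv(paths["genes"], sep="\t", index=False)
    with open(paths["loci"], "w") as fh:
        fh.write("# 1-based inclusive coordinates\n")
        locus_table(config).to_csv(fh, sep="\t", index=False)
    paths["blocklist"].write_text("# one snp id per line: instruments to "
                                  "exclude as confounder-associated\n")
    truth.to_json(paths["truth"])
    cfg = asdict(config)
    cfg["maf_range"] = list(cfg["maf_range"])
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths


def simulate_instruments(k: int = 30, theta: float = 0.0, seed: int = 0,
                         bx_mean: float = 0.1, bx_spread: float = 0.04,
                         bx_se: float = 0.01, by_se: float = 0.02,
                         n_pleio: int = 0, pleio_sd: float = 0.0,
                         directional_offset: float = 0.0) -> pd.DataFrame:
    """Instrument-level two-sample draw for estimator calibration work.

    Bypasses the genome-scale generator: draws k true exposure effects
    (random sign, magnitude uniform in ``bx_mean ± bx_spread``), observes
    them with error ``bx_se``, and sets outcome effects
    ``theta * bx_true + alpha + noise(by_se)`` where alpha is a directional
    pleiotropy offset (applied in the exposure-raising-allele orientation,
    i.e. multiplied by sign(bx_true)) plus a random pleiotropy term on
    ``n_pleio`` instruments.  Returns a harmonized-pair-shaped frame ready
    for the MR estimators.
    """
    rng = np.random.default_rng(seed)
    sign = rng.choice([-1.0, 1.0], k)
    bx_true = sign * rng.uniform(bx_mean - bx_spread, bx_mean + bx_spread, k)
    alpha = directional_offset * sign
    if n_pleio > 0:
        idx = rng.choice(k, size=n_pleio, replace=False)
        alpha[idx] += rng.normal(0.0, pleio_sd, n_pleio)
    bx_hat = bx_true + rng.normal(0.0, bx_se, k)
    by_hat = theta * bx_true + alpha + rng.normal(0.0, by_se, k)
    from scipy import stats as _st
    df = pd.DataFrame({
        "snp": [f"iv{i + 1}" for i in range(k)],
        "bx": bx_hat, "bx_se": bx_se, "by": by_hat, "by_se": by_se,
    })
    df["px"] = 2 * _st.norm.sf(np.abs(df.bx / df.bx_se))
    df["py"] = 2 * _st.norm.sf(np.abs(df.by / df.by_se))
    df["nx"] = 100_000.0
    df["ny"] = 100_000.0
    return df
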