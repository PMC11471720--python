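"""Reading, validation and harmonization of GWAS summary statistics.

All downstream stages consume :class:`SummaryStats` tables and the harmonized
exposure/outcome pair frame produced by :func:`harmonize`.  Coordinates are
1-based inclusive throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical internal column names
COLUMNS = ["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]

#: default header names accepted in summary-statistics files
DEFAULT_COLUMN_MAP = {
    "SNP": "snp",
    "CHR": "chrom",
    "POS": "pos",
    "A1": "ea",
    "A2": "oa",
    "FREQ": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "p",
    "N": "n",
}

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: palindrome-drop window on min(eaf, 1-eaf); variants whose effect-allele
#: frequency falls in [0.42, 0.58] on either trait are ambiguous
DEFAULT_PALINDROME_EAF_WINDOW = (0.42, 0.58)


class SumstatsError(ValueError):
    """Fatal problem with a summary-statistics input."""


@dataclass
class SummaryStats:
    """A validated per-variant GWAS summary-statistics table for one trait.

    ``df`` carries the canonical columns (snp, chrom, pos, ea, oa, eaf, beta,
    se, p, n), unique snp ids, sorted by (chrom, pos).  p-values are stored
    but ``z = beta/se`` is the canonical statistic: p is regenerated from z
    when absent or underflowed to zero.
    """

    trait_name: str
    df: pd.DataFrame
    genome_build: str = "GRCh37"
    n_dropped: int = 0
    drop_log: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def z(self) -> pd.Series:
        return self.df["beta"] / self.df["se"]

    @property
    def chi2(self) -> pd.Series:
        return self.z**2

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, trait_name: str = "trait",
                       genome_build: str = "GRCh37") -> "SummaryStats":
        """Validate a raw dataframe (canonical column names) into a table.

        Rows violating the record invariants are dropped and logged:
        non-ACGT or identical alleles (indels / multi-allelics rejected),
        se <= 0, eaf outside [0,1], n <= 0, missing beta.
        """
        df = df.copy()
        missing = [c for c in COLUMNS if c not in df.columns and c not in ("p", "eaf", "n")]
        if missing:
            raise SumstatsError(f"missing required columns: {missing}")
        if "p" not in df.columns:
            df["p"] = np.nan
        if "eaf" not in df.columns:
            df["eaf"] = np.nan
        if "n" not in df.columns:
            df["n"] = np.nan

        df["ea"] = df["ea"].astype(str).str.upper()
        df["oa"] = df["oa"].astype(str).str.upper()
        df["chrom"] = df["chrom"].astype(str)
        for col in ("pos", "eaf", "beta", "se", "p", "n"):
            df[col] = pd.to_numeric(df[col], errors="coerce")

        drop_log: list[tuple[str, str]] = []

        def _flag(mask: pd.Series, reason: str) -> None:
            for snp in df.loc[mask, "snp"]:
                drop_log.append((str(snp), reason))

        bad_allele = (~df["ea"].isin(_VALID_ALLELES)) | (~df["oa"].isin(_VALID_ALLELES))
        _flag(bad_allele, "non_snv_allele")
        same_allele = (df["ea"] == df["oa"]) & ~bad_allele
        _flag(same_allele, "identical_alleles")
        bad_se = ~(df["se"] > 0)
        _flag(bad_se & ~bad_allele & ~same_allele, "nonpositive_se")
        bad_beta = df["beta"].isna()
        _flag(bad_beta & ~bad_se & ~bad_allele & ~same_allele, "missing_beta")
        bad_eaf = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
        _flag(bad_eaf & ~bad_beta & ~bad_se & ~bad_allele & ~same_allele, "eaf_out_of_range")
        bad_n = df["n"].notna() & ~(df["n"] > 0)
        _flag(bad_n & ~bad_eaf & ~bad_beta & ~bad_se & ~bad_allele & ~same_allele,
              "nonpositive_n")

        bad = bad_allele | same_allele | bad_se | bad_beta | bad_eaf | bad_n
        n_dropped = int(bad.sum())
        df = df.loc[~bad].copy()
        if n_dropped:
            logger.info("dropped %d invalid rows for trait %s", n_dropped, trait_name)
            for snp, reason in drop_log:
                logger.debug("drop step=read snp=%s reason=%s", snp, reason)

        # regenerate p from z when absent or zero-underflowed
        z = np.abs(df["beta"] / df["se"])
        need_p = df["p"].isna() | (df["p"] <= 0) | (df["p"] > 1)
        df.loc[need_p, "p"] = 2.0 * stats.norm.sf(z[need_p])
        # keep a strictly positive floor so log-scale work never sees 0
        df.loc[df["p"] == 0, "p"] = np.nextafter(0, 1)

        df = df.drop_duplicates(subset="snp", keep="first")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if len(df) == 0:
            raise SumstatsError(f"no valid rows survive validation for {trait_name}")
        return cls(trait_name=trait_name, df=df[COLUMNS], genome_build=genome_build,
                   n_dropped=n_dropped, drop_log=drop_log)


def read_sumstats(path, column_map: dict | None = None, trait_name: str | None = None,
                  sep: str | None = None) -> SummaryStats:
    """Read a whitespace- or tab-delimited summary-statistics file.

    Parameters
    ----------
    path : str or Path
        Delimited text file with a header row.  Positions are 1-based.
    column_map : dict, optional
        Mapping from file header names to the canonical fields
        (snp, chrom, pos, ea, oa, eaf, beta, se, p, n); merged over the
        defaults (SNP, CHR, POS, A1, A2, FREQ, BETA, SE, P, N).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep or r"\s+", comment="#")
    raw = raw.rename(columns={k: v for k, v in cmap.items() if k in raw.columns})
    required = ["snp", "chrom", "pos", "ea", "oa", "beta", "se"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SumstatsError(f"{path}: missing required columns {missing} "
                            f"(after applying column map)")
    name = trait_name or str(path)
    return SummaryStats.from_dataframe(raw, trait_name=name)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the pair is A/T or C/G in either order (strand-ambiguous)."""
    pair = {effect_allele.upper(), other_allele.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def harmonize(exposure: SummaryStats, outcome: SummaryStats,
              palindrome_eaf_window: tuple[float, float] = DEFAULT_PALINDROME_EAF_WINDOW,
              drop_palindromic_if_no_eaf: bool = True) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele on the snp
    intersection.

    For mismatched alleles an allele swap is tried first (negate the outcome
    beta, eaf -> 1-eaf), then a strand complement, then a complement+swap.
    Palindromic variants whose min(eaf, 1-eaf) lies inside the intermediate
    window on either trait are dropped (always dropped when eaf is missing,
    conservatively).  Every intersection snp appears exactly once in the
    output with an ``action`` in {kept, allele_flipped, strand_flipped,
    dropped_palindromic, dropped_incompatible}; dropped rows never reach
    estimators (filter on ``action.str.startswith('dropped')``).
    """
    lo, hi = palindrome_eaf_window
    ex = exposure.df.set_index("snp")
    ou = outcome.df.set_index("snp")
    common = ex.index.intersection(ou.index)
    if len(common) == 0:
        raise SumstatsError("no snp overlap between exposure and outcome tables")

    ex = ex.loc[common]
    ou = ou.loc[common]

    rows = []
    for snp in common:
        e = ex.loc[snp]
        o = ou.loc[snp]
        by, by_se, eaf_y = o["beta"], o["se"], o["eaf"]
        action = None
        palindromic = is_palindromic(e["ea"], e["oa"])

        if (o["ea"], o["oa"]) == (e["ea"], e["oa"]):
            action = "kept"
        elif (o["ea"], o["oa"]) == (e["oa"], e["ea"]):
            by = -by
            eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else eaf_y
            action = "allele_flipped"
        elif not palindromic:
            cea, coa = _complement(o["ea"]), _complement(o["oa"])
            if (cea, coa) == (e["ea"], e["oa"]):
                action = "strand_flipped"
            elif (coa, cea) == (e["ea"], e["oa"]):
                by = -by
                eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else eaf_y
                action = "strand_flipped"
            else:
                action = "dropped_incompatible"
        else:
            # palindromic pair whose outcome alleles do not literally match:
            # complementing maps the pair onto itself, so orientation is
            # ambiguous regardless of frequency
            action = "dropped_incompatible"

        if palindromic and not action.startswith("dropped"):
            eafs = [e["eaf"], eaf_y]
            if any(pd.isna(f) for f in eafs):
                if drop_palindromic_if_no_eaf:
                    action = "dropped_palindromic"
            elif any(lo <= f <= hi for f in eafs):
                # eaf in [0.42, 0.58] <=> min(eaf, 1-eaf) >= 0.42: the
                # frequency cannot disambiguate strand
                action = "dropped_palindromic"
            elif (e["eaf"] - 0.5) * (eaf_y - 0.5) < 0:
                # frequencies disagree on which allele is minor: the outcome
                # record is on the opposite strand, so undo the literal-match
                # interpretation
                by = -by
                eaf_y = 1.0 - eaf_y
                action = "strand_flipped"

        rows.append({
            "snp": snp, "chrom": e["chrom"], "pos": e["pos"],
            "ea": e["ea"], "oa": e["oa"],
            "bx": e["beta"], "bx_se": e["se"], "px": e["p"],
            "by": by, "by_se": by_se, "py": o["p"],
            "eaf_x": e["eaf"], "eaf_y": eaf_y,
            "nx": e["n"], "ny": o["n"],
            "palindromic": palindromic, "action": action,
        })
        if action.startswith("dropped"):
            logger.debug("drop step=harmonize snp=%s reason=%s", snp, action)

    out = pd.DataFrame(rows)
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def kept_pairs(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonized frame that survived (not dropped)."""
    return harmonized[~harmonized["action"].str.startswith("dropped")].reset_index(drop=True)
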