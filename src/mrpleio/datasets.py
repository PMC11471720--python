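"""Published LD-score regression estimates used in the worked example.

These are the reported heritability and genetic-correlation estimates from a
mineral-metabolism / kidney-function study of European-ancestry GWAS
(UK Biobank serum calcium, phosphate, 25-hydroxyvitamin D and INTERVAL
parathyroid hormone as exposures; CKDGen-consortium kidney traits as
outcomes).  They serve as worked-example inputs: the z-score semantics, the
heritability gate and the two-sided p-values can be recomputed from the
printed (estimate, SE) pairs and compared with the printed calls.

``flagged_low_z`` marks traits the source flagged as underpowered; note the
CKDi25 row carries the flag despite a z-score of 4.5, which conflicts with
the stated z > 4 rule — :func:`gate_published_estimates` surfaces this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ldsc import heritability_gate

EXPOSURES = ["Calcium", "Phosphate", "25OHD", "PTH"]
OUTCOMES = ["CKD", "CKD_Rapid3", "CKDi25", "eGFRcrea", "eGFRcys", "BUN",
            "UACR", "MA"]

_H2_ROWS = [
    # trait, design, n, h2, h2_se, printed z (1 dp), flagged_low_z
    ("Calcium", "population", 315_153, 0.115, 0.010, 11.5, False),
    ("Phosphate", "population", 315_153, 0.108, 0.010, 10.8, False),
    ("25OHD", "population", 417_580, 0.096, 0.014, 6.9, False),
    ("PTH", "population", 3_310, 0.137, 0.122, 1.1, True),
    ("CKD", "meta-analysis", 480_698, 0.010, 0.001, 10.0, False),
    ("CKD_Rapid3", "meta-analysis", 141_964, 0.009, 0.003, 3.0, True),
    ("CKDi25", "meta-analysis", 195_145, 0.010, 0.0022, 4.5, True),
    ("eGFRcrea", "meta-analysis", 567_460, 0.071, 0.004, 17.8, False),
    ("eGFRcys", "meta-analysis", 24_061, 0.134, 0.055, 2.4, True),
    ("BUN", "meta-analysis", 243_029, 0.064, 0.005, 12.8, False),
    ("UACR", "meta-analysis", 54_450, 0.046, 0.008, 5.8, False),
    ("MA", "meta-analysis", 54_116, 0.014, 0.007, 2.0, True),
]

_RG_ROWS = [
    # exposure, outcome, rg, rg_se, gencov intercept, intercept se,
    # printed p, flagged significant (at 0.05/12)
    ("Calcium", "Phosphate", -0.080, 0.049, 0.186, 0.013, 0.10, False),
    ("Calcium", "25OHD", 0.032, 0.024, 0.058, 0.010, 0.18, False),
    ("Calcium", "CKD", 0.010, 0.052, 0.016, 0.007, 0.85, False),
    ("Calcium", "eGFRcrea", 0.002, 0.029, -0.013, 0.009, 0.95, False),
    ("Calcium", "BUN", -0.034, 0.036, 0.023, 0.008, 0.34, False),
    ("Calcium", "UACR", 0.202, 0.058, -0.002, 0.006, 5.0e-04, True),
    ("25OHD", "Calcium", 0.032, 0.024, 0.058, 0.010, 0.18, False),
    ("25OHD", "Phosphate", 0.076, 0.025, 0.039, 0.008, 0.002, True),
    ("25OHD", "CKD", 0.071, 0.042, 0.009, 0.007, 0.10, False),
    ("25OHD", "eGFRcrea", -0.094, 0.022, -0.019, 0.009, 1.4e-05, True),
    ("25OHD", "BUN", 0.127, 0.027, 0.009, 0.007, 1.7e-06, True),
    ("25OHD", "UACR", 0.006, 0.052, -0.004, 0.007, 0.91, False),
    ("Phosphate", "Calcium", -0.080, 0.049, 0.186, 0.013, 0.10, False),
    ("Phosphate", "25OHD", 0.076, 0.025, 0.039, 0.008, 0.002, False),
    ("Phosphate", "CKD", -0.118, 0.055, 0.009, 0.007, 0.03, False),
    ("Phosphate", "eGFRcrea", 0.057, 0.035, -0.006, 0.009, 0.10, False),
    ("Phosphate", "BUN", 0.041, 0.037, 0.003, 0.008, 0.27, False),
    ("Phosphate", "UACR", -0.037, 0.060, 0.002, 0.006, 0.54, False),
]


def published_heritability() -> pd.DataFrame:
    """Published per-trait SNP-heritability estimates (h2, SE, printed z)."""
    return pd.DataFrame(_H2_ROWS, columns=[
        "trait", "study_design", "n", "h2", "h2_se", "z_printed",
        "flagged_low_z"])


def published_genetic_correlations() -> pd.DataFrame:
    """Published cross-trait estimates (rg, SE, intercept, printed p).

    ``significant_printed`` marks the pairs the source called significant at
    its study-wide threshold of 0.05/12.  The 25OHD-Phosphate pair appears
    once flagged and once unflagged in the source; both rows are kept as
    printed.
    """
    return pd.DataFrame(_RG_ROWS, columns=[
        "exposure", "outcome", "rg", "rg_se", "intercept", "intercept_se",
        "p_printed", "significant_printed"])


@dataclass
class _GateRecord:
    trait_name: str
    z_score: float


def gate_published_estimates(z_threshold: float = 4.0):
    """Apply the heritability gate to the published table.

    Uses recomputed z = h2/h2_se.  Returns (kept trait names, excluded
    trait names).  Warns when a trait the source flagged as underpowered
    passes the stated z > threshold rule (the CKDi25 inconsistency).
    """
    df = published_heritability()
    records = [_GateRecord(t, h2 / se)
               for t, h2, se in zip(df["trait"], df["h2"], df["h2_se"])]
    kept, excluded = heritability_gate(records, z_threshold)
    kept_names = [r.trait_name for r in kept]
    flagged = set(df.loc[df["flagged_low_z"], "trait"])
    for name in kept_names:
        if name in flagged:
            warnings.warn(
                f"trait {name} passes the z > {z_threshold} gate "
                f"(z = {df.set_index('trait').loc[name, 'h2'] / df.set_index('trait').loc[name, 'h2_se']:.1f}) "
                f"but was flagged as underpowered in the source table",
                stacklevel=2)
    return kept_names, [r.trait_name for r in excluded]
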