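import numpy as np
import pandas as pd
import pytest

import mrpleio as m


@pytest.fixture(scope="session")
def demo_sim():
    """One desk-scale two-trait simulation shared across tests."""
    cfg = m.SimulationConfig(seed=11)
    exposure, outcome, truth, ldref = m.simulate_joint_sumstats(cfg)
    return cfg, exposure, outcome, truth, ldref


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """Fixture-bundle files for the demo configuration."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = m.SimulationConfig(seed=11)
    paths = m.write_fixture_bundle(cfg, out)
    return cfg, paths


@pytest.fixture
def clean_instruments():
    return m.simulate_instruments(k=40, theta=0.1, seed=3, by_se=0.01)


def make_sumstats(snp, beta, se, p=None, chrom="1", pos=None, ea="A", oa="G",
                  eaf=0.3, n=100_000, trait="trait"):
    """Small helper to build a validated table from plain vectors."""
    k = len(snp)
    df = pd.DataFrame({
        "snp": snp,
        "chrom": np.broadcast_to(np.asarray(chrom, object), k).copy(),
        "pos": pos if pos is not None else np.arange(1, k + 1) * 1000,
        "ea": np.broadcast_to(np.asarray(ea, object), k).copy(),
        "oa": np.broadcast_to(np.asarray(oa, object), k).copy(),
        "eaf": np.broadcast_to(np.asarray(eaf, float), k).copy(),
        "beta": beta, "se": se,
        "p": p if p is not None else np.nan,
        "n": float(n),
    })
    return m.SummaryStats.from_dataframe(df, trait_name=trait)
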