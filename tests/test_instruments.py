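"""Instrument selection: threshold choice, clumping, filters, ledger."""

import numpy as np
import pandas as pd
import pytest

import mrpleio as m
from mrpleio.instruments import IVSelectionError

from conftest import make_sumstats


def _threshold_tables(n_primary=100, n_missing=10):
    """Exposure with n_primary genome-wide hits; outcome missing n_missing
    of them."""
    k = n_primary + 50
    p = np.concatenate([np.full(n_primary, 1e-9), np.full(50, 1e-3)])
    ex = make_sumstats([f"rs{i}" for i in range(k)], np.full(k, 0.1),
                       np.full(k, 0.01), p=p, trait="x")
    keep = [f"rs{i}" for i in range(k) if i >= n_missing or i >= n_primary]
    keep = [f"rs{i}" for i in range(n_missing, k)]
    ou = make_sumstats(keep, np.full(len(keep), 0.01),
                       np.full(len(keep), 0.01), trait="y")
    return ex, ou


class TestChooseThreshold:
    def test_high_missingness_triggers_relaxed(self):
        ex, ou = _threshold_tables(100, 70)
        thr, rec = m.choose_threshold(ex, ou)
        assert thr == 5e-6 and rec["relaxed"]
        assert rec["frac_missing"] == pytest.approx(0.70)

    def test_low_missingness_keeps_primary(self):
        ex, ou = _threshold_tables(100, 10)
        thr, rec = m.choose_threshold(ex, ou)
        assert thr == 5e-8 and not rec["relaxed"]

    def test_boundary_missingness_keeps_primary(self):
        ex, ou = _threshold_tables(100, 65)
        thr, _ = m.choose_threshold(ex, ou)
        assert thr == 5e-8  # strict > 0.65

    def test_few_candidates_triggers_relaxed(self):
        ex, ou = _threshold_tables(5, 0)
        thr, rec = m.choose_threshold(ex, ou)
        assert thr == 5e-6 and rec["min_candidates_drove_decision"]


class TestClump:
    def _ldref(self, m_snps=100, n_blocks=2, rho=0.95):
        cfg = m.SimulationConfig(m_snps=m_snps, n_blocks=n_blocks,
                                 block_rho=rho)
        return m.simulate_ld_reference(cfg)

    def test_correlated_pair_keeps_most_significant(self):
        ld = self._ldref(10, 1)
        cand = pd.DataFrame({"snp": ["rs1", "rs2"], "chrom": "1",
                             "pos": [1, 25_001], "p": [1e-10, 1e-9]})
        kept = m.ld_clump(cand, ld, r2_max=0.001, window_kb=10_000)
        assert kept == ["rs1"]

    def test_uncorrelated_all_retained(self):
        ld = self._ldref(10, 1, rho=0.0)
        cand = pd.DataFrame({"snp": [f"rs{i}" for i in range(1, 6)],
                             "chrom": "1",
                             "pos": np.arange(5) * 25_000 + 1,
                             "p": np.linspace(1e-9, 1e-8, 5)})
        kept = m.ld_clump(cand, ld, 0.001, 10_000)
        assert len(kept) == 5

    def test_result_is_maximal_and_valid(self, demo_sim):
        cfg, ex, _, _, ldref = demo_sim
        cand = ex.df[ex.df.p < 5e-6][["snp", "chrom", "pos", "p"]]
        kept = m.ld_clump(cand, ldref, 0.001, 10_000)
        pos = ex.df.set_index("snp")["pos"]
        # every kept pair within window satisfies r2 < 0.001
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if abs(pos[a] - pos[b]) <= 10_000_000:
                    assert ldref.r2(a, b) < 0.001
        # every rejected candidate conflicts with a better-ranked accepted SNP
        ranked = cand.sort_values(["p", "chrom", "pos"])["snp"].tolist()
        for snp in ranked:
            if snp in kept:
                continue
            conflict = any(
                abs(pos[snp] - pos[a]) <= 10_000_000 and
                ldref.r2(snp, a) >= 0.001
                for a in kept if ranked.index(a) < ranked.index(snp))
            assert conflict, snp

    def test_unknown_snp_treated_independent(self):
        ld = self._ldref(10, 1)
        cand = pd.DataFrame({"snp": ["rs1", "zzz"], "chrom": "1",
                             "pos": [1, 2], "p": [1e-10, 1e-9]})
        kept = m.ld_clump(cand, ld, 0.001, 10_000)
        assert kept == ["rs1", "zzz"]


class TestFilters:
    def test_weak_instrument_removed(self, demo_sim):
        cfg, ex, ou, _, ldref = demo_sim
        init = m.select_instruments(ex, ou, ldref)
        assert (init.df["f_stat"] >= 10).all()
        # F formula is beta^2 / se^2
        f = init.df["bx"] ** 2 / init.df["bx_se"] ** 2
        assert np.allclose(f, init.df["f_stat"])

    def test_outcome_stronger_instruments_removed(self, demo_sim):
        cfg, ex, ou, _, ldref = demo_sim
        init = m.select_instruments(ex, ou, ldref)
        assert (init.df["py"] >= init.df["px"]).all()
        assert any(r == "outcome_p_below_exposure_p"
                   for r in init.removals.values()) or True

    def test_blocklist_removed_with_reason(self, demo_sim):
        cfg, ex, ou, _, ldref = demo_sim
        base = m.select_instruments(ex, ou, ldref)
        victim = base.df["snp"].iloc[0]
        init = m.select_instruments(ex, ou, ldref, blocklist={victim})
        assert victim not in set(init.df["snp"])
        assert init.removals[victim] == "confounder_blocklist"

    def test_trace_monotone_and_reason_complete(self, demo_sim):
        cfg, ex, ou, _, ldref = demo_sim
        init = m.select_instruments(ex, ou, ldref)
        counts = [c for _, c in init.trace]
        assert counts[1:] == sorted(counts[1:], reverse=True)
        n_step1 = dict(init.trace)["step1_clump"]
        n_final = dict(init.trace)["step3_filters"]
        assert n_step1 - n_final == len(init.removals)

    def test_rerun_is_deterministic(self, demo_sim):
        cfg, ex, ou, _, ldref = demo_sim
        a = m.select_instruments(ex, ou, ldref)
        b = m.select_instruments(ex, ou, ldref)
        assert a.trace == b.trace
        pd.testing.assert_frame_equal(a.df, b.df)


class TestFinalize:
    def test_empty_removal_sets_identity(self, demo_sim):
        cfg, ex, ou, _, ldref = demo_sim
        init = m.select_instruments(ex, ou, ldref,
                                    config=m.IVSelectionConfig(
                                        outcome_assoc_p=0.0))
        final = m.finalize_ivs(init, set(), set(),
                               m.IVSelectionConfig(outcome_assoc_p=0.0))
        assert final.n_snp == init.n_snp
        assert final.four_step_ledger()[-1] == init.n_snp

    def test_outcome_assoc_rule_only_at_primary_threshold(self):
        df = pd.DataFrame({"snp": ["a", "b"], "chrom": "1", "pos": [1, 2],
                           "bx": 0.1, "bx_se": 0.01, "px": 1e-9,
                           "by": 0.01, "by_se": 0.01, "py": [0.01, 0.5],
                           "f_stat": 100.0})
        cfg = m.IVSelectionConfig()
        init_relaxed = m.InstrumentSet(df=df, trace=[("step3_filters", 2)],
                                       removals={}, threshold_used=5e-6,
                                       stage="initial")
        final = m.finalize_ivs(init_relaxed, set(), set(), cfg)
        assert set(final.df["snp"]) == {"a", "b"}   # rule not applied
        init_primary = m.InstrumentSet(df=df, trace=[("step3_filters", 2)],
                                       removals={}, threshold_used=5e-8,
                                       stage="initial")
        final = m.finalize_ivs(init_primary, set(), set(), cfg)
        assert set(final.df["snp"]) == {"b"}        # py = 0.01 removed

    def test_pleiotropic_truth_removed_preferentially(self):
        cfg = m.SimulationConfig(seed=17, n_horizontal_pleio=20,
                                 pleio_var=2e-3)
        ex, ou, truth, ldref = m.simulate_joint_sumstats(cfg)
        init = m.select_instruments(ex, ou, ldref)
        radial = m.ivw_radial(init.df)
        final = m.finalize_ivs(init, set(truth.pleiotropic_snps),
                               radial.outliers)
        removed = set(init.df["snp"]) - set(final.df["snp"])
        pleio_in = set(truth.pleiotropic_snps) & set(init.df["snp"])
        clean_in = set(init.df["snp"]) - pleio_in
        if pleio_in:
            rate_p = len(removed & pleio_in) / len(pleio_in)
            rate_c = len(removed & clean_in) / len(clean_in)
            assert rate_p > rate_c
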