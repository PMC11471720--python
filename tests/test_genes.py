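"""Gene annotation, the LD-aware mean-chi2 test, and the shared-gene summary."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mrpleio as m
from mrpleio.genes import GeneTestError, gene_pvalue, weighted_chi2_tail

from conftest import make_sumstats


class TestAnnotation:
    def test_window_boundary_inclusive(self):
        ss = make_sumstats(["rs1", "rs2"], [0.1, 0.1], [0.01, 0.01],
                           pos=[502_000, 502_001])
        genes = pd.DataFrame([("G1", "1", 1000, 2000)],
                             columns=["GENE", "CHR", "START", "END"])
        ann = m.annotate_snps_to_genes(ss, genes, window_kb=500)
        assert ann[0].snp_ids == ["rs1"]

    def test_snp_in_overlapping_windows(self):
        ss = make_sumstats(["rs1"], [0.1], [0.01], pos=[1500])
        genes = pd.DataFrame([("G1", "1", 1000, 2000), ("G2", "1", 1400, 3000)],
                             columns=["GENE", "CHR", "START", "END"])
        ann = m.annotate_snps_to_genes(ss, genes, window_kb=0.0)
        assert ann[0].snp_ids == ["rs1"] and ann[1].snp_ids == ["rs1"]

    def test_matches_brute_force_scan(self, demo_sim):
        cfg, ex, _, _, _ = demo_sim
        genes = m.gene_table(cfg)
        ann = m.annotate_snps_to_genes(ex, genes, window_kb=500)
        w = 500_000
        df = ex.df
        for a, grow in zip(ann, genes.itertuples(index=False)):
            expect = [
                s for s, c, p in zip(df.snp, df.chrom, df.pos)
                if c == str(grow.CHR) and grow.START - w <= p <= grow.END + w]
            assert a.snp_ids == expect

    def test_empty_gene_table_fatal(self, demo_sim):
        _, ex, _, _, _ = demo_sim
        with pytest.raises(GeneTestError, match="empty"):
            m.annotate_snps_to_genes(ex, pd.DataFrame(
                columns=["GENE", "CHR", "START", "END"]))


class TestGenePvalue:
    def test_single_snp_closed_form(self):
        res = gene_pvalue([2.0], [[1.0]])
        assert res.p_value == pytest.approx(0.0455, abs=5e-5)

    def test_identity_ld_reduces_to_chi2_k(self):
        z = np.array([1.0, -2.0, 0.5, 1.5, 0.3])
        res = gene_pvalue(z, np.eye(5))
        assert res.p_value == pytest.approx(stats.chi2.sf((z**2).sum(), 5),
                                            abs=1e-10)

    def test_invariant_to_snp_reordering(self):
        rng = np.random.default_rng(1)
        k = 6
        A = rng.normal(size=(k, k))
        R = np.corrcoef(A @ A.T + 5 * np.eye(k))
        z = rng.normal(size=k)
        perm = rng.permutation(k)
        p1 = gene_pvalue(z, R).p_value
        p2 = gene_pvalue(z[perm], R[np.ix_(perm, perm)]).p_value
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_tail_matches_monte_carlo(self):
        # 5-SNP AR(1) LD: compare the Imhof tail with the empirical tail of
        # sum z^2 under the multivariate-normal null
        rho = 0.6
        R = rho ** np.abs(np.subtract.outer(np.arange(5), np.arange(5)))
        L = np.linalg.cholesky(R)
        rng = np.random.default_rng(7)
        draws = (rng.standard_normal((500_000, 5)) @ L.T)
        q_obs = (draws**2).sum(axis=1)
        lam = np.linalg.eigvalsh(R)
        for q in (5.0, 12.0, 20.0):
            p_num = weighted_chi2_tail(q, lam)
            p_mc = (q_obs > q).mean()
            mc_se = np.sqrt(p_mc * (1 - p_mc) / len(q_obs))
            assert abs(p_num - p_mc) < 4 * mc_se + 1e-6

    def test_mismatched_dimensions_fatal(self):
        with pytest.raises(GeneTestError, match="shape"):
            gene_pvalue([1.0, 2.0], np.eye(3))


class TestSignificance:
    def _results(self, pvals):
        return pd.DataFrame({"GENE": [f"g{i}" for i in range(len(pvals))],
                             "NSNPS": 1, "STAT": 1.0, "P": pvals})

    def test_primary_rule(self):
        pv = [1e-6] * 6 + [0.01] * 994
        sig, thr = m.significant_genes(self._results(pv), 1000)
        assert thr == pytest.approx(5e-5)
        assert len(sig) == 6

    def test_fallback_rule(self):
        pv = [1e-6] * 2 + [1e-3] * 4 + [0.5] * 994
        sig, thr = m.significant_genes(self._results(pv), 1000)
        assert thr == pytest.approx(5e-3)
        assert len(sig) == 6  # the two strong plus the four moderate

    def test_null_false_positive_rate(self):
        # under the primary rule the expected number of false positives per
        # scan is <= 0.05; check the average over independent null scans
        rng = np.random.default_rng(3)
        G = 500
        fps = []
        for _ in range(200):
            pv = rng.uniform(size=G)
            sig = set(np.flatnonzero(pv < 0.05 / G))
            fps.append(len(sig))
        assert np.mean(fps) <= 0.05 + 3 * np.std(fps) / np.sqrt(len(fps))

    def test_zero_genes_fatal(self):
        with pytest.raises(GeneTestError):
            m.significant_genes(self._results([]), 0)


class TestSharedProportion:
    def _ann(self, gene_snps):
        from mrpleio.genes import GeneAnnotation
        return [GeneAnnotation(g, "1", 0, 1, 0, 1, snp_ids=s)
                for g, s in gene_snps.items()]

    def _res(self, pvals):
        return pd.DataFrame({"GENE": list(pvals), "NSNPS": 1, "STAT": 1.0,
                             "P": list(pvals.values())})

    def test_disjoint_sets_give_zero(self):
        ex = self._res({"g1": 1e-9, "g2": 0.9, "g3": 0.9})
        ou = self._res({"g1": 0.9, "g2": 1e-9, "g3": 0.9})
        ann = self._ann({"g1": ["a"], "g2": ["b"], "g3": ["c"]})
        s = m.shared_gene_proportion(ex, ou, ann, 1000)
        assert s.shared_proportion == 0.0
        assert s.pleiotropic_snp_ids == set()

    def test_identical_sets_give_one(self):
        ex = self._res({"g1": 1e-9, "g2": 1e-9, "g3": 0.9})
        ann = self._ann({"g1": ["a", "b"], "g2": ["c"], "g3": ["d"]})
        s = m.shared_gene_proportion(ex, ex.copy(), ann, 1000)
        assert s.shared_proportion == 1.0
        assert s.pleiotropic_snp_ids == {"a", "b", "c"}

    def test_undefined_when_no_exposure_genes(self):
        ex = self._res({"g1": 0.9, "g2": 0.9, "g3": 0.9, "g4": 0.9,
                        "g5": 0.9, "g6": 0.9})
        ou = self._res({f"g{i}": 1e-9 for i in range(1, 7)})
        ann = self._ann({f"g{i}": [] for i in range(1, 7)})
        s = m.shared_gene_proportion(ex, ou, ann, 6)
        assert not s.defined and np.isnan(s.shared_proportion)

    def test_proportion_grows_with_truly_shared_architecture(self):
        # sweep: more shared causal blocks -> higher shared-gene proportion
        props = []
        for frac, seed in [(0.0, 41), (1.0, 43)]:
            cfg = m.SimulationConfig(seed=seed, theta=0.0,
                                     rg=None if frac == 0 else 0.9,
                                     n_horizontal_pleio=0)
            ex, ou, _, ldref = m.simulate_joint_sumstats(cfg)
            genes = m.gene_table(cfg)
            ann = [a for a in m.annotate_snps_to_genes(ex, genes)
                   if a.n_snps > 0]
            gx = m.gene_test_table(ex, ann, ldref)
            gy = m.gene_test_table(ou, ann, ldref)
            s = m.shared_gene_proportion(gx, gy, ann, len(ann))
            props.append(s.shared_proportion)
        assert props[1] > props[0]
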