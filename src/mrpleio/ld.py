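"""Block-structured LD reference: pairwise correlations and LD scores.

The reference stores signed correlations ``r`` in memory (eigen-structure and
multivariate-normal nulls need the sign); the on-disk pair file stores r².
LD score of variant j is ``l_j = sum_k r(j,k)^2`` over its block, the
regressor of LD-score regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LDReference:
    """Per-SNP block membership plus one correlation matrix per block.

    ``snp``, ``chrom``, ``pos`` are parallel arrays in genome order;
    ``block_index[i]`` gives the block of snp i and ``blocks[b]`` the signed
    correlation matrix of block b.  Correlation between variants in different
    blocks is exactly zero.
    """

    snp: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    block_index: np.ndarray
    blocks: list

    def __post_init__(self):
        self._snp_to_idx = {s: i for i, s in enumerate(self.snp)}
        self._block_offsets = {}
        for b in range(len(self.blocks)):
            members = np.flatnonzero(self.block_index == b)
            self._block_offsets[b] = members

    def __len__(self) -> int:
        return len(self.snp)

    def ld_scores(self) -> pd.Series:
        """Exact per-SNP LD scores (sum of squared within-block r)."""
        out = np.empty(len(self.snp))
        for b, R in enumerate(self.blocks):
            members = self._block_offsets[b]
            out[members] = (np.asarray(R) ** 2).sum(axis=1)
        return pd.Series(out, index=self.snp, name="l2")

    def r(self, snp_a: str, snp_b: str) -> float:
        """Signed correlation between two variants (0.0 across blocks or for
        variants absent from the reference)."""
        ia = self._snp_to_idx.get(snp_a)
        ib = self._snp_to_idx.get(snp_b)
        if ia is None or ib is None:
            return np.nan
        ba, bb = self.block_index[ia], self.block_index[ib]
        if ba != bb:
            return 0.0
        members = self._block_offsets[ba]
        ja = int(np.searchsorted(members, ia))
        jb = int(np.searchsorted(members, ib))
        return float(self.blocks[ba][ja, jb])

    def r2(self, snp_a: str, snp_b: str) -> float:
        v = self.r(snp_a, snp_b)
        return v * v

    def submatrix(self, snps) -> np.ndarray:
        """Signed correlation matrix for an ordered list of snp ids.

        Cross-block entries are zero; unknown snps raise KeyError.
        """
        idx = np.array([self._snp_to_idx[s] for s in snps])
        k = len(idx)
        R = np.zeros((k, k))
        blk = self.block_index[idx]
        for b in np.unique(blk):
            sel = np.flatnonzero(blk == b)
            members = self._block_offsets[b]
            within = np.searchsorted(members, idx[sel])
            R[np.ix_(sel, sel)] = np.asarray(self.blocks[b])[np.ix_(within, within)]
        np.fill_diagonal(R, 1.0)
        return R

    # ---- text interfaces -------------------------------------------------

    def write_ldscore_file(self, path) -> None:
        df = pd.DataFrame({"SNP": self.snp, "CHR": self.chrom,
                           "POS": self.pos, "L2": self.ld_scores().values})
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def write_r2_file(self, path, r2_min: float = 1e-4) -> None:
        """Within-block pairs with r² >= r2_min as SNP_A, SNP_B, R2."""
        rows = []
        for b, R in enumerate(self.blocks):
            members = self._block_offsets[b]
            R = np.asarray(R)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    r2 = R[i, j] ** 2
                    if r2 >= r2_min:
                        rows.append((self.snp[members[i]], self.snp[members[j]], r2))
        pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_files(cls, ldscore_path, r2_path) -> "LDReference":
        """Rebuild a reference from the text interfaces.

        Pair r² values are mapped back to r assuming positive correlation
        (true for the AR(1) references this package generates); blocks are
        the connected components of the pair graph.
        """
        snps = pd.read_csv(ldscore_path, sep="\t")
        pairs = pd.read_csv(r2_path, sep="\t")
        idx = {s: i for i, s in enumerate(snps["SNP"])}
        m = len(snps)
        parent = list(range(m))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in zip(pairs["SNP_A"], pairs["SNP_B"]):
            ra, rb = find(idx[a]), find(idx[b])
            if ra != rb:
                parent[ra] = rb
        roots = np.array([find(i) for i in range(m)])
        _, block_index = np.unique(roots, return_inverse=True)
        # order blocks by first occurrence for determinism
        order = {}
        for i, b in enumerate(block_index):
            order.setdefault(b, len(order))
        block_index = np.array([order[b] for b in block_index])
        n_blocks = block_index.max() + 1
        members = [np.flatnonzero(block_index == b) for b in range(n_blocks)]
        mats = [np.eye(len(mb)) for mb in members]
        within = [{i: j for j, i in enumerate(mb)} for mb in members]
        for a, b, r2 in zip(pairs["SNP_A"], pairs["SNP_B"], pairs["R2"]):
            ia, ib = idx[a], idx[b]
            blk = block_index[ia]
            ja, jb = within[blk][ia], within[blk][ib]
            r = np.sqrt(r2)
            mats[blk][ja, jb] = mats[blk][jb, ja] = r
        return cls(snp=snps["SNP"].to_numpy(), chrom=snps["CHR"].astype(str).to_numpy(),
                   pos=snps["POS"].to_numpy(), block_index=block_index, blocks=mats)
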