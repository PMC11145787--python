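"""Hi-C contact-map processing at 10 kb resolution.

Per-chromosome sparse symmetric matrices go through: ICE balancing
(iterative row-sum correction until the coefficient of variation of
nonzero-row sums drops below tolerance), distance normalisation
(subtracting the per-diagonal median, clamping at zero), and top-k
neighbour graph construction. Valid-pair lists support seeded
down-sampling and multi-sample aggregation for averaged contact maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class ContactMap:
    """Sparse symmetric nonnegative intra-chromosomal contact matrix."""

    chrom: str
    matrix: sp.csr_matrix
    bin_size: int = 10_000
    balanced: bool = False
    distance_normalized: bool = False

    def __post_init__(self) -> None:
        m = sp.csr_matrix(self.matrix, dtype=np.float64)
        if m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if m.nnz and m.data.min() < 0:
            raise ValueError("contact values must be >= 0")
        asym = abs(m - m.T)
        if asym.nnz and asym.data.max() > 1e-8:
            raise ValueError("contact matrix must be symmetric (tol 1e-8)")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def value(self, i: int, j: int) -> float:
        return float(self.matrix[i, j])

    # -- COO text interchange ("bin_i\tbin_j\tvalue") -----------------------

    def to_coo_text(self, path) -> None:
        coo = sp.triu(self.matrix).tocoo()
        with open(path, "w") as fh:
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i}\t{j}\t{v:g}\n")

    @classmethod
    def from_coo_text(cls, path, chrom: str, n_bins: int, bin_size: int = 10_000):
        rows, cols, vals = [], [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                i, j, v = line.split()
                rows.append(int(i))
                cols.append(int(j))
                vals.append(float(v))
        m = sp.coo_matrix((vals, (rows, cols)), shape=(n_bins, n_bins))
        m = m + sp.triu(m, k=1).T  # stored upper triangle; mirror it
        return cls(chrom=chrom, matrix=m.tocsr(), bin_size=bin_size)


def ice_normalize(
    cmap: ContactMap, tol: float = 1e-5, max_iter: int = 200
) -> tuple[ContactMap, np.ndarray]:
    """Iterative correction: equalise nonzero row sums; returns biases.

    Zero rows (unmappable bins) are left untouched with bias 1. Stops when
    the coefficient of variation of nonzero-row sums falls below ``tol``.
    """
    W = cmap.matrix.astype(np.float64).copy()
    if W.nnz == 0:
        raise ValueError("cannot balance an all-zero contact matrix")
    n = W.shape[0]
    bias = np.ones(n)
    nz = np.asarray(W.sum(axis=1)).ravel() > 0
    for _ in range(max_iter):
        s = np.asarray(W.sum(axis=1)).ravel()
        s_nz = s[nz]
        cv = s_nz.std() / s_nz.mean()
        if cv < tol:
            break
        d = np.ones(n)
        d[nz] = s_nz / s_nz.mean()
        bias *= d
        D = sp.diags(1.0 / d)
        W = D @ W @ D
        W = sp.csr_matrix(W)
    return (
        ContactMap(chrom=cmap.chrom, matrix=W, bin_size=cmap.bin_size, balanced=True),
        bias,
    )


def ice_oracle(dense: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    """Slow elementwise fixed-point balancing oracle on a dense matrix."""
    W = np.asarray(dense, dtype=float).copy()
    n = W.shape[0]
    nz = W.sum(axis=1) > 0
    for _ in range(max_iter):
        s = W.sum(axis=1)
        s_nz = s[nz]
        if s_nz.std() / s_nz.mean() < tol:
            break
        d = np.ones(n)
        d[nz] = s_nz / s_nz.mean()
        for i in range(n):
            for j in range(n):
                W[i, j] = W[i, j] / (d[i] * d[j])
    return W


def distance_normalize(cmap: ContactMap) -> ContactMap:
    """Subtract the per-diagonal median (all pairs, zeros included); clamp at 0.

    The median at each offset is taken over every bin pair at that genomic
    distance, structural zeros included, so sparse storage cannot bias it
    upward. Symmetry is preserved.
    """
    D = cmap.dense()
    n = D.shape[0]
    out = np.zeros_like(D)
    for d in range(n):
        diag = np.diagonal(D, offset=d)
        med = np.median(diag)
        vals = np.clip(diag - med, 0.0, None)
        idx = np.arange(n - d)
        out[idx, idx + d] = vals
        out[idx + d, idx] = vals
    return ContactMap(
        chrom=cmap.chrom,
        matrix=sp.csr_matrix(out),
        bin_size=cmap.bin_size,
        balanced=cmap.balanced,
        distance_normalized=True,
    )


def topk_graph(cmap: ContactMap, k: int = 10) -> np.ndarray:
    """Undirected union of each bin's k strongest nonzero contacts.

    Selection is per-node (directed) before the undirected union, so hub
    bins may end with degree above ``k``. Ties break toward the smaller
    bin index. Self-contacts (the diagonal) are never selected. Returns an
    ``(n_edges, 2)`` array with ``edge[0] < edge[1]``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    csr = cmap.matrix.tocsr()
    edges: set[tuple[int, int]] = set()
    for i in range(csr.shape[0]):
        lo, hi = csr.indptr[i], csr.indptr[i + 1]
        cols = csr.indices[lo:hi]
        vals = csr.data[lo:hi]
        keep = (cols != i) & (vals > 0)
        cols, vals = cols[keep], vals[keep]
        if len(cols) == 0:
            continue
        order = np.lexsort((cols, -vals))[:k]
        for j in cols[order]:
            edges.add((min(i, int(j)), max(i, int(j))))
    if not edges:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(sorted(edges), dtype=np.int64)


@dataclass
class PairList:
    """Intra-chromosomal valid interaction pairs with multiplicity."""

    frame: pd.DataFrame  # columns: chrom, bin_i, bin_j, count

    COLUMNS = ("chrom", "bin_i", "bin_j", "count")

    def __post_init__(self) -> None:
        for c in self.COLUMNS:
            if c not in self.frame.columns:
                raise ValueError(f"PairList missing column {c!r}")
        if (self.frame["count"] < 0).any():
            raise ValueError("pair counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.frame["count"].sum())

    def to_bedpe(self, path, bin_size: int = 10_000) -> None:
        with open(path, "w") as fh:
            for r in self.frame.itertuples():
                fh.write(
                    f"{r.chrom}\t{r.bin_i * bin_size}\t{(r.bin_i + 1) * bin_size}\t"
                    f"{r.chrom}\t{r.bin_j * bin_size}\t{(r.bin_j + 1) * bin_size}\t"
                    f".\t{int(r.count)}\n"
                )


def downsample_pairs(pairs: PairList, n: int, seed: int) -> PairList:
    """Uniform without-replacement sample of exactly ``n`` interactions."""
    total = pairs.total
    if n > total:
        raise ValueError(f"cannot draw {n} pairs from {total}")
    rng = np.random.default_rng(seed)
    counts = pairs.frame["count"].to_numpy(dtype=np.int64)
    drawn = rng.multivariate_hypergeometric(counts, n)
    out = pairs.frame.copy()
    out["count"] = drawn
    return PairList(out[out["count"] > 0].reset_index(drop=True))


def pairs_to_maps(
    pairs: PairList, n_bins: dict[str, int], bin_size: int = 10_000
) -> dict[str, ContactMap]:
    """Bin a pair list into per-chromosome symmetric contact maps."""
    maps = {}
    for chrom, sub in pairs.frame.groupby("chrom"):
        nb = n_bins[chrom]
        m = sp.coo_matrix(
            (sub["count"], (sub["bin_i"], sub["bin_j"])), shape=(nb, nb)
        ).tocsr()
        upper = sp.triu(m) + sp.tril(m, k=-1).T
        full = upper + sp.triu(upper, k=1).T
        maps[chrom] = ContactMap(chrom=chrom, matrix=full, bin_size=bin_size)
    return maps


def aggregate_maps(
    pair_lists: dict[str, PairList],
    n_each: int,
    n_bins: dict[str, int],
    seed: int = 0,
    bin_size: int = 10_000,
    leave_out: str | None = None,
    ice_tol: float = 1e-5,
) -> dict[str, ContactMap]:
    """Down-sample each dataset to ``n_each`` pairs, merge, bin, and balance.

    ``pair_lists`` maps dataset name -> PairList; ``leave_out`` excludes a
    named dataset before aggregation.
    """
    names = [n for n in pair_lists if n != leave_out]
    if len(names) < 2:
        raise ValueError("aggregation needs >= 2 datasets")
    merged: list[pd.DataFrame] = []
    for k, name in enumerate(names):
        ds = downsample_pairs(pair_lists[name], n_each, seed=seed + k)
        merged.append(ds.frame)
    allpairs = PairList(
        pd.concat(merged)
        .groupby(["chrom", "bin_i", "bin_j"], as_index=False)["count"]
        .sum()
    )
    maps = pairs_to_maps(allpairs, n_bins, bin_size=bin_size)
    return {c: ice_normalize(m, tol=ice_tol)[0] for c, m in maps.items()}


def map_to_pairs(cmap: ContactMap) -> PairList:
    """Integer contact counts of a raw map as a valid-pair list."""
    coo = sp.triu(cmap.matrix).tocoo()
    frame = pd.DataFrame(
        {
            "chrom": cmap.chrom,
            "bin_i": coo.row,
            "bin_j": coo.col,
            "count": coo.data.astype(np.int64),
        }
    )
    return PairList(frame[frame["count"] > 0].reset_index(drop=True))
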