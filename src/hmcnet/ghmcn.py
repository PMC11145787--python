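"""Graph convolutional classifier over the 10 kb genome graph (GhmCN).

Nodes are 10 kb genomic windows carrying two features: log10(1 + RPKM) of
the 5hmC IP signal and of its matched input. Edges connect each window to
its top-k strongest distance-normalised Hi-C contacts (per chromosome).
Windows containing at least one gene TSS carry a High/Low label (mean TPM
over their genes, dichotomised at the sample's gene-level median) and are
the only nodes seen by the loss; they are split 70/15/15 into
train/validation/test folds.

The network follows the GraphSAGE mean-aggregator formulation: each
convolution concatenates (in effect, sums after separate affine maps) the
node's own representation with the mean of its neighbours', followed by a
rectifier; a three-layer perceptron head with 50% dropout produces the
logit. The aggregation accepts per-edge weights so a trained model can be
interrogated by the edge-mask explainer; training uses unit weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .evaluate import EvalReport, evaluate
from .genome_io import CoverageTrack, GeneSet
from .hic import ContactMap, topk_graph
from .nn import Adam, bce_loss_and_grad, sigmoid


@dataclass
class GhmcnConfig:
    conv_layers: int = 2
    hidden: int = 128
    head_hidden: tuple[int, ...] = (64, 32)
    dropout: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_layers < 1:
            raise ValueError("need >= 1 convolution layer")


@dataclass
class GenomeGraph:
    """Node table + undirected edge list over 10 kb windows."""

    nodes: pd.DataFrame  # chrom, bin, ip, input, label, mask, fold
    edges: np.ndarray  # (n_edges, 2) global node indices, i < j
    bin_size: int = 10_000

    def __post_init__(self) -> None:
        if self.edges.ndim != 2 or (len(self.edges) and self.edges.shape[1] != 2):
            raise ValueError("edges must be an (n, 2) array")
        labeled = self.nodes["label"].notna()
        if (labeled & ~self.nodes["mask"]).any():
            raise ValueError("only masked (TSS-bearing) nodes may carry labels")
        if ((self.nodes["fold"] != "") & ~self.nodes["mask"]).any():
            raise ValueError("only masked nodes may carry fold assignments")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def features(self) -> np.ndarray:
        return self.nodes[["ip", "input"]].to_numpy(dtype=np.float64)

    @property
    def mask(self) -> np.ndarray:
        return self.nodes["mask"].to_numpy(dtype=bool)

    @property
    def labels(self) -> np.ndarray:
        return self.nodes["label"].to_numpy(dtype=np.float64)

    def fold_mask(self, fold: str) -> np.ndarray:
        return (self.nodes["fold"] == fold).to_numpy()

    def with_edges(self, edges: np.ndarray) -> "GenomeGraph":
        return GenomeGraph(nodes=self.nodes, edges=np.asarray(edges), bin_size=self.bin_size)

    def node_interval(self, idx: int) -> tuple[str, int, int]:
        row = self.nodes.iloc[idx]
        start = int(row["bin"]) * self.bin_size
        return str(row["chrom"]), start, start + self.bin_size

    def neighbors(self, idx: int) -> np.ndarray:
        e = self.edges
        out = np.concatenate([e[e[:, 0] == idx, 1], e[e[:, 1] == idx, 0]])
        return np.unique(out)

    # -- serialization ------------------------------------------------------

    def to_tsv(self, node_path, edge_path) -> None:
        self.nodes.to_csv(node_path, sep="\t", index=False)
        pd.DataFrame(self.edges, columns=["node_i", "node_j"]).to_csv(
            edge_path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, node_path, edge_path, bin_size: int = 10_000) -> "GenomeGraph":
        nodes = pd.read_csv(node_path, sep="\t")
        nodes["fold"] = nodes["fold"].fillna("")
        edges = pd.read_csv(edge_path, sep="\t").to_numpy(dtype=np.int64)
        return cls(nodes=nodes, edges=edges, bin_size=bin_size)


def _chrom_offsets(n_bins: dict[str, int]) -> dict[str, int]:
    off, cum = {}, 0
    for chrom, nb in n_bins.items():
        off[chrom] = cum
        cum += nb
    return off


def build_genome_graph(
    maps: dict[str, ContactMap],
    ip: CoverageTrack,
    input_track: CoverageTrack,
    genes: GeneSet,
    tpm: pd.Series,
    k: int = 10,
    seed: int = 0,
    fold_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> GenomeGraph:
    """Assemble the genome graph from distance-normalised maps and tracks.

    ``tpm`` is the per-gene expression (indexed by gene_id) of the sample
    being modelled; the High/Low threshold is its median over the genes.
    """
    bin_size = next(iter(maps.values())).bin_size
    n_bins = {c: m.n_bins for c, m in maps.items()}
    offsets = _chrom_offsets(n_bins)

    rows = []
    for chrom, nb in n_bins.items():
        starts = np.arange(nb, dtype=np.int64) * bin_size
        ends = starts + bin_size
        ip_sig = ip.region_signal_many(chrom, starts, ends)
        in_sig = input_track.region_signal_many(chrom, starts, ends)
        ip_rpkm = ip_sig / ((bin_size / 1000.0) * (ip.total_mapped / 1e6))
        in_rpkm = in_sig / ((bin_size / 1000.0) * (input_track.total_mapped / 1e6))
        for b in range(nb):
            rows.append((chrom, b, np.log10(1 + ip_rpkm[b]), np.log10(1 + in_rpkm[b])))
    nodes = pd.DataFrame(rows, columns=["chrom", "bin", "ip", "input"])

    # gene TSS -> node assignment; multi-TSS nodes get the mean TPM
    node_tpms: dict[int, list[float]] = {}
    median_tpm = tpm.reindex(genes.gene_ids).median()
    for g in genes:
        if g.chrom not in offsets:
            continue
        b = g.tss // bin_size
        if b >= n_bins[g.chrom]:
            continue
        node_tpms.setdefault(offsets[g.chrom] + b, []).append(float(tpm[g.gene_id]))

    labels = np.full(len(nodes), np.nan)
    mask = np.zeros(len(nodes), dtype=bool)
    for idx, vals in node_tpms.items():
        mask[idx] = True
        labels[idx] = 1.0 if float(np.mean(vals)) > median_tpm else 0.0
    if not mask.any():
        raise ValueError("no node contains a gene TSS")

    folds = np.array([""] * len(nodes), dtype=object)
    midx = np.flatnonzero(mask)
    rng = np.random.default_rng(seed)
    midx = rng.permutation(midx)
    n_train = int(round(fold_fractions[0] * len(midx)))
    n_val = int(round(fold_fractions[1] * len(midx)))
    folds[midx[:n_train]] = "train"
    folds[midx[n_train : n_train + n_val]] = "val"
    folds[midx[n_train + n_val :]] = "test"

    nodes["label"] = labels
    nodes["mask"] = mask
    nodes["fold"] = folds

    edges = []
    for chrom, cmap in maps.items():
        e = topk_graph(cmap, k=k)
        if len(e):
            edges.append(e + offsets[chrom])
    all_edges = np.vstack(edges) if edges else np.empty((0, 2), dtype=np.int64)
    return GenomeGraph(nodes=nodes, edges=all_edges, bin_size=bin_size)


def nearest1d_graph(n_bins: dict[str, int], k: int = 10) -> np.ndarray:
    """Each bin connected to its k/2 upstream and k/2 downstream neighbours.

    A 1D-distance control for the Hi-C-derived graph; edges are truncated
    at chromosome ends (no padding). Global node indices follow the
    chromosome order of ``n_bins``.
    """
    half = k // 2
    offsets = _chrom_offsets(n_bins)
    edges = []
    for chrom, nb in n_bins.items():
        off = offsets[chrom]
        for i in range(nb):
            for d in range(1, half + 1):
                if i + d < nb:
                    edges.append((off + i, off + i + d))
    return np.unique(np.array(edges, dtype=np.int64), axis=0)


# ---------------------------------------------------------------------------
# GraphSAGE network (numpy, weighted mean aggregator)
# ---------------------------------------------------------------------------


class GraphSageNet:
    """Mean-aggregator graph convolutions + MLP head, manual backprop.

    Inputs are z-scored with statistics frozen on the training graph
    (``feat_mean``/``feat_sd``): window RPKMs sit on a large common offset
    with small informative variation, and without centring a fraction of
    inits collapses to a constant predictor.
    """

    def __init__(self, n_features: int, config: GhmcnConfig, rng: np.random.Generator):
        self.config = config
        self.feat_mean = np.zeros(n_features)
        self.feat_sd = np.ones(n_features)
        h = config.hidden
        dims = [n_features] + [h] * config.conv_layers
        self.Wself, self.Wneigh, self.bconv = [], [], []
        for fi, fo in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / (2 * fi))
            self.Wself.append(rng.normal(0, scale, (fi, fo)))
            self.Wneigh.append(rng.normal(0, scale, (fi, fo)))
            self.bconv.append(np.zeros(fo))
        head_dims = [h, *config.head_hidden, 1]
        self.Whead, self.bhead = [], []
        for fi, fo in zip(head_dims[:-1], head_dims[1:]):
            self.Whead.append(rng.normal(0, np.sqrt(2.0 / fi), (fi, fo)))
            self.bhead.append(np.zeros(fo))

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.Wself, *self.Wneigh, *self.bconv, *self.Whead, *self.bhead]

    def _pack_grads(self, gWs, gWn, gbc, gWh, gbh) -> list[np.ndarray]:
        return [*gWs, *gWn, *gbc, *gWh, *gbh]

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        H0: np.ndarray,
        src: np.ndarray,
        dst: np.ndarray,
        w: np.ndarray | None = None,
        dropout_rng: np.random.Generator | None = None,
    ):
        """Logits for all nodes given directed edges (src -> dst).

        ``w`` are per-directed-edge message weights (default 1). Messages
        are scaled by their weight and normalised by the neighbour COUNT,
        so with unit weights this is the plain mean aggregator and masking
        an edge genuinely removes its contribution (no renormalisation —
        the semantics the edge-mask explainer relies on). Neighbourless
        nodes aggregate a zero vector.
        """
        n = H0.shape[0]
        if w is None:
            w = np.ones(len(src))
        A = sp.csr_matrix((w, (dst, src)), shape=(n, n))
        deg = np.bincount(dst, minlength=n).astype(np.float64)
        Sinv = np.where(deg > 0, 1.0 / np.maximum(deg, 1.0), 0.0)
        conv_caches = []
        H = (np.asarray(H0, dtype=np.float64) - self.feat_mean) / self.feat_sd
        for Ws, Wn, b in zip(self.Wself, self.Wneigh, self.bconv):
            N = (A @ H) * Sinv[:, None]
            Z = H @ Ws + N @ Wn + b
            Hn = np.maximum(Z, 0.0)
            conv_caches.append((H, N, Z))
            H = Hn
        head_caches = []
        dcfg = self.config.dropout
        for li, (Wh, bh) in enumerate(zip(self.Whead, self.bhead)):
            Z = H @ Wh + bh
            if li < len(self.Whead) - 1:
                Hh = np.maximum(Z, 0.0)
                mask = None
                if dropout_rng is not None and dcfg > 0:
                    mask = (dropout_rng.random(Hh.shape) >= dcfg) / (1.0 - dcfg)
                    Hh = Hh * mask
                head_caches.append((H, Z, mask))
                H = Hh
            else:
                head_caches.append((H, Z, None))
        logits = Z[:, 0]
        cache = {
            "conv": conv_caches,
            "head": head_caches,
            "A": A,
            "Sinv": Sinv,
            "src": src,
            "dst": dst,
        }
        return logits, cache

    def predict_proba(self, H0, src, dst, w=None) -> np.ndarray:
        return sigmoid(self.forward(H0, src, dst, w)[0])

    # -- backward -----------------------------------------------------------

    def backward(self, cache, dlogits: np.ndarray, need_edge_grads: bool = False):
        """Parameter gradients (and optionally per-directed-edge weight grads)."""
        A, Sinv = cache["A"], cache["Sinv"]
        src, dst = cache["src"], cache["dst"]
        gWh = [np.zeros_like(W) for W in self.Whead]
        gbh = [np.zeros_like(b) for b in self.bhead]
        dZ = dlogits[:, None]
        for li in range(len(self.Whead) - 1, -1, -1):
            H_in, Z, mask = cache["head"][li]
            gWh[li] = H_in.T @ dZ
            gbh[li] = dZ.sum(axis=0)
            dH = dZ @ self.Whead[li].T
            if li > 0:
                _, Z_prev, mask_prev = cache["head"][li - 1]
                if mask_prev is not None:
                    dH = dH * mask_prev
                dZ = dH * (Z_prev > 0)
        # dH now w.r.t. the last conv output
        gWs = [np.zeros_like(W) for W in self.Wself]
        gWn = [np.zeros_like(W) for W in self.Wneigh]
        gbc = [np.zeros_like(b) for b in self.bconv]
        edge_grads = np.zeros(len(src)) if need_edge_grads else None
        for li in range(len(self.Wself) - 1, -1, -1):
            H_in, N, Z = cache["conv"][li]
            dZc = dH * (Z > 0)
            gWs[li] = H_in.T @ dZc
            gWn[li] = N.T @ dZc
            gbc[li] = dZc.sum(axis=0)
            dN = dZc @ self.Wneigh[li].T
            G = dN * Sinv[:, None]  # count-normalised upstream gradient
            if need_edge_grads:
                # N_i = sum_e w_e H_src / deg_i, so dN_i/dw_e = H_src/deg_i
                edge_grads += np.einsum("ef,ef->e", G[dst], H_in[src])
            dH = dZc @ self.Wself[li].T + A.T @ G
        grads = self._pack_grads(gWs, gWn, gbc, gWh, gbh)
        return (grads, edge_grads) if need_edge_grads else grads


def _directed_edges(edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Both directions of an undirected edge list."""
    if len(edges) == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    return src, dst


@dataclass
class GhmcnResults:
    """A trained GhmCN with its graph, history and per-fold metrics."""

    net: GraphSageNet
    graph: GenomeGraph
    config: GhmcnConfig
    history: list[float]
    report: EvalReport | None
    val_report: EvalReport | None

    def predict(self, graph: GenomeGraph | None = None) -> pd.Series:
        """P(High) for the masked nodes of ``graph`` (default: training graph).

        Cross-cell-type application is exactly this call on a new graph
        built from another sample's features/contacts; no retraining.
        """
        g = graph if graph is not None else self.graph
        if g.features.shape[1] != self.graph.features.shape[1]:
            raise ValueError("node feature arity differs from the training graph")
        src, dst = _directed_edges(g.edges)
        probs = self.net.predict_proba(g.features, src, dst)
        midx = np.flatnonzero(g.mask)
        return pd.Series(probs[midx], index=midx)

    def evaluate_fold(self, fold: str = "test", graph: GenomeGraph | None = None) -> EvalReport:
        g = graph if graph is not None else self.graph
        src, dst = _directed_edges(g.edges)
        probs = self.net.predict_proba(g.features, src, dst)
        sel = g.fold_mask(fold)
        return evaluate(probs[sel], g.labels[sel])

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "GhmCN graph convolutional classifier",
            "=" * 46,
            f"conv layers      : {cfg.conv_layers} (mean aggregator, width {cfg.hidden})",
            f"head             : {' -> '.join(map(str, (*cfg.head_hidden, 1)))} "
            f"(dropout {cfg.dropout:g})",
            f"lr / epochs      : {cfg.learning_rate:g} / {cfg.epochs}",
            f"seed             : {cfg.seed}",
            f"nodes / edges    : {self.graph.n_nodes} / {len(self.graph.edges)}",
            f"masked nodes     : {int(self.graph.mask.sum())}",
            f"final train loss : {self.history[-1]:.4f}",
        ]
        if self.val_report is not None:
            lines.append(f"validation       : {self.val_report}")
        if self.report is not None:
            lines.append(f"test             : {self.report}")
        return "\n".join(lines)


class GhmcnClassifier:
    """Graph model over a labeled GenomeGraph; ``fit`` returns results."""

    def __init__(self, graph: GenomeGraph, config: GhmcnConfig | None = None):
        self.graph = graph
        self.config = config or GhmcnConfig()

    def fit(self) -> GhmcnResults:
        g = self.graph
        cfg = self.config
        train_sel = g.fold_mask("train")
        if train_sel.sum() == 0:
            raise ValueError("empty training fold")
        y = g.labels
        if len(np.unique(y[train_sel])) < 2:
            raise ValueError("training fold contains a single class")
        rng = np.random.default_rng(cfg.seed)
        net = GraphSageNet(g.features.shape[1], cfg, rng)
        H0 = g.features
        net.feat_mean = H0.mean(axis=0)
        sd = H0.std(axis=0)
        net.feat_sd = np.where(sd < 1e-12, 1.0, sd)
        src, dst = _directed_edges(g.edges)
        opt = Adam(net.params, lr=cfg.learning_rate)
        history = []
        t_idx = np.flatnonzero(train_sel)
        for _ in range(cfg.epochs):
            logits, cache = net.forward(H0, src, dst, dropout_rng=rng)
            loss, dl_sel = bce_loss_and_grad(logits[t_idx], y[t_idx])
            if not np.isfinite(loss):
                raise RuntimeError("training aborted: non-finite loss")
            dlogits = np.zeros_like(logits)
            dlogits[t_idx] = dl_sel
            grads = net.backward(cache, dlogits)
            opt.step(net.params, grads)
            history.append(float(loss))
        probs = net.predict_proba(H0, src, dst)
        report = val_report = None
        test_sel = g.fold_mask("test")
        if test_sel.sum() and len(np.unique(y[test_sel])) == 2:
            report = evaluate(probs[test_sel], y[test_sel])
        val_sel = g.fold_mask("val")
        if val_sel.sum() and len(np.unique(y[val_sel])) == 2:
            val_report = evaluate(probs[val_sel], y[val_sel])
        return GhmcnResults(
            net=net,
            graph=g,
            config=cfg,
            history=history,
            report=report,
            val_report=val_report,
        )
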