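"""Per-gene 5hmC feature vectors and High/Low expression labels.

Each gene longer than 1 kb is summarised by 230 bins laid out 5'->3' in
transcription orientation:

* 15 fixed 100-bp bins tiling the 1.5 kb upstream of the TSS,
* 100 fixed 100-bp bins tiling the 10 kb promoter window (TSS +/- 5 kb),
* 100 variable-width bins tiling the gene body [TSS, TTS),
* 15 fixed 100-bp bins tiling the 1.5 kb downstream of the TTS.

The upstream flank overlaps the promoter window; the redundancy is kept so
the layout totals 230 features. Per-bin signal is the log2 ratio of
RPKM-normalised IP over input coverage (pseudocount 0.5), then per-bin
z-scored with statistics frozen on the training genes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, ExpressionTable, GeneModel, GeneSet

HIGH, LOW = "High", "Low"


@dataclass(frozen=True)
class BinScheme:
    """Bin layout parameters; defaults give the canonical 230-bin scheme."""

    promoter_flank: int = 5000
    promoter_bins: int = 100
    flank: int = 1500
    flank_bins: int = 15
    genebody_bins: int = 100

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.promoter_bins + self.genebody_bins

    @property
    def roles(self) -> np.ndarray:
        return np.array(
            ["tss_flank"] * self.flank_bins
            + ["promoter"] * self.promoter_bins
            + ["body"] * self.genebody_bins
            + ["tts_flank"] * self.flank_bins
        )

    @property
    def fixed_bin_indices(self) -> np.ndarray:
        """Indices of the fixed-width bins surrounding the promoter/TSS."""
        return np.flatnonzero(self.roles != "body")


def make_feature_bins(gene: GeneModel, scheme: BinScheme = BinScheme()) -> np.ndarray:
    """Genomic intervals of the gene's feature bins, ordered 5'->3'.

    Returns an ``(n_bins, 2)`` int array of half-open genomic intervals.
    Bin index always increases in transcription direction; for minus-strand
    genes the intervals therefore decrease in genomic coordinate.
    """
    L = gene.length
    if L < 1000:
        raise ValueError(f"gene {gene.gene_id}: length {L} < 1 kb")
    # transcription-space edges relative to the TSS base (offset 0 = TSS)
    edges: list[tuple[int, int]] = []
    f, fb = scheme.flank, scheme.flank_bins
    fw = f // fb
    for i in range(fb):  # upstream TSS flank
        edges.append((-f + i * fw, -f + (i + 1) * fw))
    p, pb = scheme.promoter_flank, scheme.promoter_bins
    pw = 2 * p // pb
    for i in range(pb):  # promoter window TSS +/- promoter_flank
        edges.append((-p + i * pw, -p + (i + 1) * pw))
    gb = scheme.genebody_bins
    body_edges = [(i * L) // gb for i in range(gb + 1)]
    for i in range(gb):
        edges.append((body_edges[i], body_edges[i + 1]))
    for i in range(fb):  # downstream TTS flank
        edges.append((L + i * fw, L + (i + 1) * fw))

    out = np.empty((len(edges), 2), dtype=np.int64)
    tss = gene.tss
    for k, (a, b) in enumerate(edges):
        if gene.strand == "+":
            out[k] = (tss + a, tss + b)
        else:
            # offset o maps to genomic base tss - o
            out[k] = (tss - b + 1, tss - a + 1)
    return out


def rpkm(count: float, width: int, depth: float) -> float:
    """Reads per kilobase per million mapped reads."""
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    return count / ((width / 1000.0) * (depth / 1e6))


@dataclass
class FeatureMatrix:
    """Genes x bins feature matrix with optional High/Low labels.

    ``X`` holds the raw (pre-standardisation) log2 enrichment features;
    :meth:`standardize` freezes per-bin z-score statistics on a training
    subset and returns a standardised copy.
    """

    X: np.ndarray
    gene_ids: np.ndarray
    chroms: np.ndarray
    roles: np.ndarray
    labels: np.ndarray | None = None  # values in {"High", "Low"}
    tpms: np.ndarray | None = None
    standardization: dict | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")
        if self.X.shape[0] != len(self.gene_ids):
            raise ValueError("X rows must match gene_ids")
        if self.X.shape[1] != len(self.roles):
            raise ValueError("X columns must match bin roles")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def y(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("feature matrix is unlabeled")
        return (np.asarray(self.labels) == HIGH).astype(np.float64)

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return FeatureMatrix(
            X=self.X[mask],
            gene_ids=np.asarray(self.gene_ids)[mask],
            chroms=np.asarray(self.chroms)[mask],
            roles=self.roles,
            labels=None if self.labels is None else np.asarray(self.labels)[mask],
            tpms=None if self.tpms is None else np.asarray(self.tpms)[mask],
            standardization=self.standardization,
        )

    def with_labels(self, labels: pd.Series, tpms: pd.Series | None = None) -> "FeatureMatrix":
        lab = labels.reindex(self.gene_ids)
        if lab.isna().any():
            raise ValueError("labels missing for some genes")
        t = None if tpms is None else tpms.reindex(self.gene_ids).to_numpy()
        return FeatureMatrix(
            X=self.X,
            gene_ids=self.gene_ids,
            chroms=self.chroms,
            roles=self.roles,
            labels=lab.to_numpy(),
            tpms=t,
            standardization=self.standardization,
        )

    def standardize(self, train_mask: np.ndarray) -> "FeatureMatrix":
        """Per-bin z-score using statistics from ``train_mask`` genes only."""
        train_mask = np.asarray(train_mask)
        if train_mask.sum() < 2:
            raise ValueError("need >= 2 training genes to standardize")
        mu = self.X[train_mask].mean(axis=0)
        sd = self.X[train_mask].std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        out = FeatureMatrix(
            X=(self.X - mu) / sd,
            gene_ids=self.gene_ids,
            chroms=self.chroms,
            roles=self.roles,
            labels=self.labels,
            tpms=self.tpms,
            standardization={"mean": mu, "sd": sd},
        )
        return out

    def apply_standardization(self, stats: dict) -> "FeatureMatrix":
        mu, sd = np.asarray(stats["mean"]), np.asarray(stats["sd"])
        return FeatureMatrix(
            X=(self.X - mu) / sd,
            gene_ids=self.gene_ids,
            chroms=self.chroms,
            roles=self.roles,
            labels=self.labels,
            tpms=self.tpms,
            standardization={"mean": mu, "sd": sd},
        )

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path, sidecar_json=None) -> None:
        df = pd.DataFrame(self.X, columns=[f"bin_{i}" for i in range(self.n_features)])
        df.insert(0, "gene_id", self.gene_ids)
        df.insert(1, "chrom", self.chroms)
        if self.labels is not None:
            df["label"] = self.labels
        if self.tpms is not None:
            df["tpm"] = self.tpms
        df.to_csv(path, sep="\t", index=False)
        if sidecar_json is not None:
            meta = {"roles": self.roles.tolist()}
            if self.standardization is not None:
                meta["standardization"] = {
                    k: np.asarray(v).tolist() for k, v in self.standardization.items()
                }
            with open(sidecar_json, "w") as fh:
                json.dump(meta, fh)

    @classmethod
    def from_tsv(cls, path, sidecar_json=None) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        bins = [c for c in df.columns if c.startswith("bin_")]
        roles = None
        stats = None
        if sidecar_json is not None:
            with open(sidecar_json) as fh:
                meta = json.load(fh)
            roles = np.asarray(meta["roles"])
            if "standardization" in meta:
                stats = {k: np.asarray(v) for k, v in meta["standardization"].items()}
        if roles is None:
            roles = np.asarray(["?"] * len(bins))
        return cls(
            X=df[bins].to_numpy(),
            gene_ids=df["gene_id"].to_numpy(),
            chroms=df["chrom"].to_numpy(),
            roles=roles,
            labels=df["label"].to_numpy() if "label" in df else None,
            tpms=df["tpm"].to_numpy() if "tpm" in df else None,
            standardization=stats,
        )


def featurize_sample(
    genes: GeneSet,
    ip: CoverageTrack,
    input_track: CoverageTrack,
    scheme: BinScheme = BinScheme(),
    pseudocount: float = 0.5,
) -> FeatureMatrix:
    """Raw (unstandardised) log2 IP/input enrichment features per gene bin.

    Per bin: ``log2((RPKM_ip + c) / (RPKM_input + c))`` with pseudocount
    ``c``. If the input track is empty, features fall back to
    ``log2(RPKM_ip + c)`` with a warning.
    """
    input_empty = input_track.total_mapped <= 0
    if input_empty:
        warnings.warn(
            "input track carries no signal; features fall back to log2(RPKM_ip + c)"
        )
    n = len(genes)
    X = np.empty((n, scheme.n_bins), dtype=np.float64)
    for gi, gene in enumerate(genes):
        bins = make_feature_bins(gene, scheme)
        starts, ends = bins[:, 0], bins[:, 1]
        widths = (ends - starts).astype(float)
        ip_counts = ip.region_signal_many(gene.chrom, starts, ends)
        ip_rpkm = ip_counts / ((widths / 1000.0) * (ip.total_mapped / 1e6))
        if input_empty:
            X[gi] = np.log2(ip_rpkm + pseudocount)
        else:
            in_counts = input_track.region_signal_many(gene.chrom, starts, ends)
            in_rpkm = in_counts / ((widths / 1000.0) * (input_track.total_mapped / 1e6))
            X[gi] = np.log2((ip_rpkm + pseudocount) / (in_rpkm + pseudocount))
    return FeatureMatrix(
        X=X,
        gene_ids=np.asarray(genes.gene_ids),
        chroms=np.asarray([g.chrom for g in genes]),
        roles=scheme.roles,
    )


def label_genes(expr: ExpressionTable, sample: str, gene_ids=None) -> pd.Series:
    """High/Low labels from the per-sample median TPM (strictly above -> High)."""
    tpm = expr.tpm(sample)
    if gene_ids is not None:
        tpm = tpm.reindex(gene_ids)
        if tpm.isna().any():
            raise ValueError("some genes missing from expression table")
    if len(tpm) < 2:
        raise ValueError("need >= 2 genes to dichotomize at the median")
    med = tpm.median()
    return pd.Series(np.where(tpm.to_numpy() > med, HIGH, LOW), index=tpm.index)


def mask_promoter_bins(
    matrix: FeatureMatrix, bin_indices: np.ndarray | None = None
) -> FeatureMatrix:
    """Remove the given bins (default: all 130 fixed-size bins around the TSS)."""
    if bin_indices is None:
        scheme_roles = matrix.roles
        bin_indices = np.flatnonzero(scheme_roles != "body")
    bin_indices = np.asarray(bin_indices, dtype=int)
    n = matrix.n_features
    if len(bin_indices) and (bin_indices.min() < 0 or bin_indices.max() >= n):
        raise IndexError("bin index out of range")
    keep = np.setdiff1d(np.arange(n), bin_indices)
    if len(keep) == 0:
        raise ValueError("masking all bins leaves no features")
    return FeatureMatrix(
        X=matrix.X[:, keep],
        gene_ids=matrix.gene_ids,
        chroms=matrix.chroms,
        roles=matrix.roles[keep],
        labels=matrix.labels,
        tpms=matrix.tpms,
        standardization=None,
    )
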