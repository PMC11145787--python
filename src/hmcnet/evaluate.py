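"""Baseline classifiers and evaluation utilities.

The baselines (logistic regression, random forest, SVM) are deliberately
off-the-shelf scikit-learn estimators run with default parameters; the
point of comparison is the feature set, not the learner. The
majority-vote baseline memorises each gene's label across training
samples. Metrics follow the usual definitions: AUROC by rank statistic,
AUPR by step interpolation (average precision), F1/accuracy at a score
threshold with High as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)
from sklearn.svm import SVC

from .featurize import HIGH, LOW, FeatureMatrix

BASELINE_KINDS = ("logistic", "random_forest", "svm")


@dataclass
class EvalReport:
    """Scalar classification metrics plus the per-quartile breakdown."""

    auc: float
    aupr: float
    f1: float
    accuracy: float
    n_test: int
    quartile_accuracy: tuple | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def __str__(self) -> str:  # compact one-line report
        s = (
            f"AUC={self.auc:.3f}  AUPR={self.aupr:.3f}  F1={self.f1:.3f}  "
            f"acc={self.accuracy:.3f}  n={self.n_test}"
        )
        if self.quartile_accuracy is not None:
            qs = "/".join(f"{q:.2f}" for q in self.quartile_accuracy)
            s += f"  Q1-Q4 acc={qs}"
        return s


def evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    tpms: np.ndarray | None = None,
) -> EvalReport:
    """Compute AUROC/AUPR/F1/accuracy for scores against binary labels.

    ``labels`` may be 0/1 or "High"/"Low" strings. Raises if only one
    class is present (AUC undefined).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "UOS":
        y = (y == HIGH).astype(int)
    else:
        y = y.astype(int)
    if len(scores) != len(y):
        raise ValueError("scores and labels must be aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    pred = (scores >= threshold).astype(int)
    quart = None
    if tpms is not None:
        quart = tuple(quartile_accuracy(y, pred, np.asarray(tpms)))
    return EvalReport(
        auc=float(roc_auc_score(y, scores)),
        aupr=float(average_precision_score(y, scores)),
        f1=float(f1_score(y, pred)),
        accuracy=float(accuracy_score(y, pred)),
        n_test=len(y),
        quartile_accuracy=quart,
    )


def auc_bruteforce(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise-concordance AUC oracle: P(score_pos > score_neg) + 0.5 ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "UOS":
        y = (y == HIGH).astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined: single class")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class BaselineClassifier:
    """Thin wrapper giving every baseline a common score interface."""

    def __init__(self, kind: str, estimator):
        self.kind = kind
        self.estimator = estimator

    def score_genes(self, X: np.ndarray) -> np.ndarray:
        if hasattr(self.estimator, "predict_proba") and self.kind != "svm":
            return self.estimator.predict_proba(X)[:, 1]
        return self.estimator.decision_function(X)


def fit_baseline(kind: str, train: FeatureMatrix, seed: int = 0) -> BaselineClassifier:
    """Fit an off-the-shelf baseline on a labeled feature matrix."""
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline kind {kind!r}; choose from {BASELINE_KINDS}")
    y = train.y
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if kind == "logistic":
        est = LogisticRegression(max_iter=1000, random_state=seed)
    elif kind == "random_forest":
        est = RandomForestClassifier(random_state=seed)
    else:
        est = SVC(random_state=seed)  # scores via decision_function
    est.fit(train.X, y)
    return BaselineClassifier(kind, est)


def majority_vote_predict(
    labels_by_sample: pd.DataFrame, held_out_sample: str
) -> pd.Series:
    """Per-gene majority label across all samples except the held-out one.

    Ties are resolved to High (documented convention; the strict-majority
    rule leaves an even split undefined).
    """
    if held_out_sample not in labels_by_sample.columns:
        raise KeyError(f"sample {held_out_sample!r} not in table")
    train = labels_by_sample.drop(columns=[held_out_sample])
    if train.shape[1] < 1:
        raise ValueError("need >= 2 samples for a majority vote")
    if train.isna().any().any():
        raise ValueError("label table has missing genes")
    n_high = (train == HIGH).sum(axis=1)
    n_low = (train == LOW).sum(axis=1)
    return pd.Series(
        np.where(n_high >= n_low, HIGH, LOW), index=labels_by_sample.index
    )


def quartile_accuracy(
    y_true: np.ndarray, y_pred: np.ndarray, tpms: np.ndarray
) -> list[float]:
    """Accuracy within four expression quartiles (Q4 = top 25% by TPM).

    Genes are ranked by TPM ascending and cut into four groups; with a
    remainder, lower quartiles receive the extra genes.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tpms = np.asarray(tpms, dtype=float)
    n = len(tpms)
    if n < 4:
        raise ValueError("need >= 4 genes for quartiles")
    order = np.argsort(tpms, kind="stable")
    base, rem = divmod(n, 4)
    sizes = [base + (1 if q < rem else 0) for q in range(4)]
    out = []
    pos = 0
    for size in sizes:
        idx = order[pos : pos + size]
        out.append(float(np.mean(y_true[idx] == y_pred[idx])))
        pos += size
    return out


def variable_gene_subset(
    labels_by_sample: pd.DataFrame, min_minor_fraction: float | None = 1 / 3
) -> pd.Index:
    """Genes whose minority label covers >= ``min_minor_fraction`` of samples.

    Passing ``None`` (or 0) selects every gene with any label variation.
    """
    if labels_by_sample.isna().any().any():
        raise ValueError("label table has missing genes")
    n = labels_by_sample.shape[1]
    n_high = (labels_by_sample == HIGH).sum(axis=1)
    minor = np.minimum(n_high, n - n_high) / n
    if not min_minor_fraction:
        keep = minor > 0
    else:
        keep = minor >= min_minor_fraction
    return labels_by_sample.index[keep]


def promoter_cpg_content(
    genome_sequence, gene, flank: int = 1000
) -> float:
    """CpG dinucleotide density in the TSS +/- ``flank`` window.

    ``genome_sequence`` is any mapping chrom -> sequence string (a dict or
    a pyfaidx Fasta). The window is clipped at sequence ends; density is
    CpG count over the clipped window length. CG is its own reverse
    complement, so the density is strand-invariant.
    """
    try:
        seq = genome_sequence[gene.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {gene.chrom!r} not in genome") from exc
    seq = str(seq)
    lo = max(0, gene.tss - flank)
    hi = min(len(seq), gene.tss + flank)
    window = seq[lo:hi].upper()
    if len(window) == 0:
        raise ValueError("empty promoter window")
    return window.count("CG") / len(window)
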