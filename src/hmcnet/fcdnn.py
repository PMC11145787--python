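"""Fully connected deep neural network (FCDNN) for expression-state prediction.

The classifier maps a gene's 230-bin 5hmC enrichment vector to P(High
expression) through three rectifier hidden layers (200, 100, 50 units) and
a sigmoid output, trained with binary cross-entropy and Adam at learning
rate 1e-4, hidden dropout 0.15 and minibatch size 128. Chromosome-held-out
evaluation is built in: one chromosome is withheld for validation and one
for testing, for every sample in a combined fit, so test genes are truly
unseen. A 19-entry split schedule rotates every autosome once through the
test role and once through the validation role.

Usage follows the Model/Results convention::

    model = FcdnnClassifier(features, config)
    res = model.fit(test_chrom="chr4", val_chrom="chr5")
    res.summary()
    scores = res.predict(other_features)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .evaluate import EvalReport, evaluate
from .featurize import FeatureMatrix
from .nn import DenseNet, train_dense


@dataclass
class FcdnnConfig:
    """Hyperparameters; defaults are the tuned per-sample setting."""

    hidden: tuple[int, ...] = (200, 100, 50)
    learning_rate: float = 1e-4
    dropout: float = 0.15
    epochs: int = 40  # combined fits conventionally use 60
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")


def make_split_schedule(chromosomes, seed: int = 0) -> list[tuple[str, str]]:
    """Pair every chromosome once as test with a distinct validation partner.

    Returns ``len(chromosomes)`` (test, val) pairs in which each chromosome
    appears exactly once in each role and never with itself — a seeded
    derangement of the chromosome list.
    """
    chroms = list(chromosomes)
    n = len(chroms)
    if n < 2:
        raise ValueError("need >= 2 chromosomes for a split schedule")
    rng = np.random.default_rng(seed)
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return [(chroms[i], chroms[perm[i]]) for i in range(n)]


@dataclass
class FcdnnResults:
    """A fitted FCDNN with its split, training history and test metrics."""

    net: DenseNet
    config: FcdnnConfig
    test_chrom: str
    val_chrom: str
    standardization: dict
    roles: np.ndarray
    history: list[float]
    epochs_used: int
    report: EvalReport | None
    val_report: EvalReport | None
    test_scores: pd.Series | None

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        """Per-gene P(High) for a raw (unstandardised) feature matrix."""
        if features.n_features != self.net.n_input:
            raise ValueError(
                f"feature width {features.n_features} != model input {self.net.n_input}"
            )
        X = features.apply_standardization(self.standardization).X
        return self.net.predict_proba(X)

    def predict_standardized(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.net.n_input:
            raise ValueError("feature width mismatch")
        return self.net.predict_proba(X)

    def summary(self) -> str:
        lines = [
            "FCDNN expression-state classifier",
            "=" * 46,
            f"layers           : {' -> '.join(map(str, self.net.widths))}",
            f"learning rate    : {self.config.learning_rate:g}",
            f"dropout (hidden) : {self.config.dropout:g}",
            f"epochs x batch   : {self.epochs_used} x {self.config.batch_size}",
            f"seed             : {self.config.seed}",
            f"held-out test    : {self.test_chrom}",
            f"held-out val     : {self.val_chrom}",
            f"final train loss : {self.history[-1]:.4f}",
        ]
        if self.val_report is not None:
            lines.append(f"validation       : {self.val_report}")
        if self.report is not None:
            lines.append(f"test             : {self.report}")
        return "\n".join(lines)

    def save(self, path_npz, path_json) -> None:
        arrays = {}
        for i, W in enumerate(self.net.W):
            arrays[f"W{i}"] = W
        for i, b in enumerate(self.net.b):
            arrays[f"b{i}"] = b
        arrays["std_mean"] = np.asarray(self.standardization["mean"])
        arrays["std_sd"] = np.asarray(self.standardization["sd"])
        np.savez(path_npz, **arrays)
        with open(path_json, "w") as fh:
            json.dump(
                {
                    "config": asdict(self.config),
                    "test_chrom": self.test_chrom,
                    "val_chrom": self.val_chrom,
                    "roles": self.roles.tolist(),
                },
                fh,
            )


class FcdnnClassifier:
    """FCDNN model built from one or many concatenated labeled samples.

    ``features`` holds raw (unstandardised) per-gene bins with labels; for
    a combined fit, rows from several samples are concatenated and every
    sample's genes on the held-out chromosomes are withheld together.
    """

    def __init__(self, features: FeatureMatrix, config: FcdnnConfig | None = None):
        if features.labels is None:
            raise ValueError("FcdnnClassifier needs labeled features")
        self.features = features
        self.config = config or FcdnnConfig()

    def fit(
        self,
        test_chrom: str = "chr4",
        val_chrom: str = "chr5",
        epochs: int | None = None,
    ) -> FcdnnResults:
        if test_chrom == val_chrom:
            raise ValueError("test and validation chromosomes must differ")
        cfg = self.config
        feats = self.features
        chroms = np.asarray(feats.chroms)
        test_mask = chroms == test_chrom
        val_mask = chroms == val_chrom
        train_mask = ~(test_mask | val_mask)
        if train_mask.sum() == 0:
            raise ValueError("empty training fold")
        std = feats.standardize(train_mask)  # stats frozen on training genes
        X, y = std.X, std.y
        rng = np.random.default_rng(cfg.seed)
        net = DenseNet(feats.n_features, cfg.hidden, rng)
        history = train_dense(
            net,
            X[train_mask],
            y[train_mask],
            epochs=epochs if epochs is not None else cfg.epochs,
            batch_size=cfg.batch_size,
            lr=cfg.learning_rate,
            dropout=cfg.dropout,
            rng=rng,
        )
        report = val_report = None
        test_scores = None
        if test_mask.sum() > 0:
            s = net.predict_proba(X[test_mask])
            test_scores = pd.Series(s, index=np.asarray(feats.gene_ids)[test_mask])
            if len(np.unique(y[test_mask])) == 2:
                tp = None if feats.tpms is None else np.asarray(feats.tpms)[test_mask]
                report = evaluate(s, y[test_mask], tpms=tp)
        if val_mask.sum() > 0 and len(np.unique(y[val_mask])) == 2:
            val_report = evaluate(net.predict_proba(X[val_mask]), y[val_mask])
        return FcdnnResults(
            net=net,
            config=cfg,
            test_chrom=test_chrom,
            val_chrom=val_chrom,
            standardization=std.standardization,
            roles=feats.roles,
            history=history,
            epochs_used=epochs if epochs is not None else cfg.epochs,
            report=report,
            val_report=val_report,
            test_scores=test_scores,
        )

    def fit_schedule(self, seed: int | None = None, epochs: int | None = None):
        """Fit one model per (test, val) entry of the 19-style schedule."""
        chroms = list(dict.fromkeys(np.asarray(self.features.chroms).tolist()))
        schedule = make_split_schedule(
            chroms, seed if seed is not None else self.config.seed
        )
        return [
            self.fit(test_chrom=t, val_chrom=v, epochs=epochs) for t, v in schedule
        ]


def concat_samples(matrices: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack per-sample feature matrices for a combined fit.

    Gene ids are suffixed per sample to keep rows distinct while chromosome
    assignment (and hence held-out folds) stays shared across samples.
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    roles = matrices[0].roles
    for m in matrices[1:]:
        if not np.array_equal(m.roles, roles):
            raise ValueError("bin layouts differ across samples")
    return FeatureMatrix(
        X=np.vstack([m.X for m in matrices]),
        gene_ids=np.concatenate(
            [
                np.char.add(np.asarray(m.gene_ids, dtype=str), f"@s{i}")
                for i, m in enumerate(matrices)
            ]
        ),
        chroms=np.concatenate([np.asarray(m.chroms) for m in matrices]),
        roles=roles,
        labels=(
            None
            if any(m.labels is None for m in matrices)
            else np.concatenate([np.asarray(m.labels) for m in matrices])
        ),
        tpms=(
            None
            if any(m.tpms is None for m in matrices)
            else np.concatenate([np.asarray(m.tpms) for m in matrices])
        ),
    )
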