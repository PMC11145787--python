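"""DeepLift (Rescale) decoding of a trained FCDNN.

Contributions are computed with respect to the pre-sigmoid logit, relative
to a neutral reference input: a single constant broadcast across all bins,
chosen so the network output is as close as possible to 0.5 (neither
class). The Rescale rule assigns each unit the multiplier
``(f(z) - f(z0)) / (z - z0)`` (its derivative where the difference
vanishes); chained multipliers give per-bin scores that satisfy
summation-to-delta exactly: the scores of a gene sum to
``logit(x) - logit(reference)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .featurize import HIGH, LOW
from .nn import DenseNet, sigmoid


def find_neutral_reference(
    net: DenseNet,
    feature_range: tuple[float, float],
    target: float = 0.5,
    n_grid: int = 401,
    tol: float = 1e-3,
    band: tuple[float, float] = (0.05, 0.95),
) -> tuple[float, float]:
    """Search constant inputs for the one whose output is nearest ``target``.

    Grid-scans constants over ``feature_range`` and refines by bisection
    when the output crosses the target between grid points. Returns
    ``(constant, achieved_probability)``. Raises if no constant keeps the
    output inside the non-saturated ``band`` (a per-bin mean reference is
    the recommended fallback).
    """
    lo, hi = feature_range
    grid = np.linspace(lo, hi, n_grid)
    probs = sigmoid(net.logits(np.tile(grid[:, None], (1, net.n_input))))
    k = int(np.argmin(np.abs(probs - target)))
    c, p = float(grid[k]), float(probs[k])

    def p_of(c_):
        return float(sigmoid(net.logits(np.full((1, net.n_input), c_)))[0])

    # refine by bisection on a bracketing neighbour if the sign changes
    for j in (k - 1, k + 1):
        if 0 <= j < n_grid and (probs[j] - target) * (p - target) < 0:
            a, b = sorted((grid[k], grid[j]))
            fa = p_of(a) - target
            for _ in range(100):
                m = 0.5 * (a + b)
                fm = p_of(m) - target
                if abs(fm) < tol / 10:
                    break
                if fa * fm < 0:
                    b = m
                else:
                    a, fa = m, fm
            c, p = m, fm + target
            break
    if not (band[0] < p < band[1]):
        raise ValueError(
            f"no constant input yields a non-saturated output (closest p={p:.4f}); "
            "consider a per-bin mean reference instead"
        )
    return c, p


def deeplift_scores(
    net: DenseNet, inputs: np.ndarray, reference: np.ndarray | float
) -> np.ndarray:
    """Per-gene per-bin Rescale contributions to the logit.

    ``reference`` is either a full input vector or a constant to broadcast.
    Returns an array shaped like ``inputs``; each row sums to
    ``logit(x) - logit(reference)``.
    """
    X = np.asarray(inputs, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != net.n_input:
        raise ValueError("input width does not match model")
    ref = np.asarray(reference, dtype=np.float64)
    if ref.ndim == 0:
        ref = np.full(net.n_input, float(ref))
    ref_row = ref[None, :]

    # forward both x and reference, caching pre-activations
    _, caches_x = net.forward(X)
    _, caches_r = net.forward(np.repeat(ref_row, len(X), axis=0))

    n_layers = len(net.W)
    # multipliers flow backward from the logit (multiplier 1 on the logit)
    M = np.ones((len(X), 1))
    for li in range(n_layers - 1, -1, -1):
        # through the linear map of layer li: multipliers left-multiply W^T
        M = M @ net.W[li].T
        if li > 0:
            Zx = caches_x[li - 1][1]
            Zr = caches_r[li - 1][1]
            dz = Zx - Zr
            da = np.maximum(Zx, 0.0) - np.maximum(Zr, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(np.abs(dz) > 1e-12, da / dz, (Zx > 0).astype(float))
            M = M * t
    return M * (X - ref_row)


@dataclass
class AttributionProfile:
    """Per-bin mean +/- sd of contribution scores per observed label group."""

    frame: pd.DataFrame  # columns: group, bin, role, mean, sd

    def group(self, label: str) -> pd.DataFrame:
        return self.frame[self.frame["group"] == label].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        for label, sub in self.frame.groupby("group"):
            ax.plot(sub["bin"], sub["mean"], label=str(label))
            ax.fill_between(
                sub["bin"],
                sub["mean"] - sub["sd"],
                sub["mean"] + sub["sd"],
                alpha=0.2,
            )
        ax.set_xlabel("bin index (5' -> 3')")
        ax.set_ylabel("contribution to logit")
        ax.legend(title="observed label")
        return ax


def summarize_contributions(
    scores: np.ndarray, labels: np.ndarray, roles: np.ndarray | None = None
) -> AttributionProfile:
    """Mean +/- sd of per-bin scores, separately for High and Low genes."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores contain non-finite values")
    n_bins = scores.shape[1]
    if roles is None:
        roles = np.asarray(["?"] * n_bins)
    rows = []
    for label in (HIGH, LOW):
        grp = scores[labels == label]
        if len(grp) == 0:
            raise ValueError(f"no genes observed with label {label!r}")
        mean = grp.mean(axis=0)
        sd = grp.std(axis=0)
        for b in range(n_bins):
            rows.append((label, b, roles[b], mean[b], sd[b]))
    return AttributionProfile(
        pd.DataFrame(rows, columns=["group", "bin", "role", "mean", "sd"])
    )
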