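"""Generalised Activity-by-Contact (ABC) enhancer scoring.

Candidate elements are the strongest accessibility peaks, trimmed to
summit +/- 250 bp and merged. Element activity is the geometric mean of
RPKM-normalised accessibility and activity-track signal — the activity
track is pluggable (5hmC enrichment or H3K27ac). Contact between an
element and a gene promoter is the balanced Hi-C entry at 10 kb
resolution, regularised by a power-law fit of contact versus distance.
The ABC score of element e for gene g is

    S(e, g) = A_e * C_eg / sum_{e' within 5 Mb of g} A_e' * C_e'g

so scores for a gene sum to one before thresholding (default 0.02).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, GeneSet, PeakSet, exclude_blacklist, merge_intervals
from .hic import ContactMap


@dataclass
class PowerlawFit:
    """Contact ~ kappa * distance^(-gamma), fitted on log-log means."""

    gamma: float
    kappa: float
    d_range: tuple[float, float]

    def expected(self, d: float) -> float:
        d = max(float(d), 1.0)
        return self.kappa * d ** (-self.gamma)


def fit_powerlaw(
    cmap: ContactMap, d_range: tuple[float, float] = (20_000, 2_000_000)
) -> PowerlawFit:
    """Least-squares line on (log distance, log mean contact per offset)."""
    D = cmap.dense()
    n = D.shape[0]
    lo = max(1, int(np.ceil(d_range[0] / cmap.bin_size)))
    hi = min(n - 1, int(d_range[1] // cmap.bin_size))
    ds, means = [], []
    for off in range(lo, hi + 1):
        m = float(np.diagonal(D, offset=off).mean())
        if m > 0:
            ds.append(off * cmap.bin_size)
            means.append(m)
    if len(ds) < 3:
        raise ValueError("fewer than 3 usable distances for the power-law fit")
    slope, intercept = np.polyfit(np.log(ds), np.log(means), deg=1)
    return PowerlawFit(gamma=-float(slope), kappa=float(np.exp(intercept)), d_range=d_range)


@dataclass
class AbcCandidate:
    chrom: str
    start: int
    end: int
    score: float
    activity: float | None = None

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def candidate_regions(
    peaks: PeakSet,
    extend: int = 250,
    n_strongest: int = 150_000,
    blacklist: pd.DataFrame | None = None,
) -> list[AbcCandidate]:
    """Summit +/- ``extend`` windows of the strongest peaks, merged.

    Keeps the ``n_strongest`` peaks by score, expands each summit into a
    ``2*extend`` window, merges overlapping windows (summing peak scores),
    and removes any merged region overlapping the blacklist.
    """
    f = peaks.frame
    if len(f) == 0:
        return []
    top = f.nlargest(min(n_strongest, len(f)), "score", keep="all").head(n_strongest)
    out: list[AbcCandidate] = []
    for chrom, sub in top.groupby("chrom"):
        starts = (sub["summit"] - extend).clip(lower=0).to_numpy()
        ends = (sub["summit"] + extend).to_numpy()
        ms, me = merge_intervals(starts, ends)
        # attach the summed score of constituent peaks to each merged region
        for s, e in zip(ms, me):
            inside = (sub["summit"] >= s) & (sub["summit"] < e)
            out.append(AbcCandidate(chrom, int(s), int(e), float(sub.loc[inside, "score"].sum())))
    if blacklist is not None and len(blacklist):
        frame = pd.DataFrame(
            {"chrom": [c.chrom for c in out], "start": [c.start for c in out],
             "end": [c.end for c in out], "idx": np.arange(len(out))}
        )
        kept = exclude_blacklist(frame, blacklist)
        out = [out[i] for i in kept["idx"]]
    return sorted(out, key=lambda c: (c.chrom, c.start))


def element_activity(
    candidate: AbcCandidate,
    accessibility: CoverageTrack,
    activity: CoverageTrack,
    pseudocount: float = 0.1,
) -> float:
    """Geometric mean of accessibility and activity RPKM over the element."""
    width = candidate.end - candidate.start
    acc = accessibility.region_signal(candidate.chrom, candidate.start, candidate.end)
    act = activity.region_signal(candidate.chrom, candidate.start, candidate.end)
    acc_rpkm = acc / ((width / 1000.0) * (accessibility.total_mapped / 1e6))
    act_rpkm = act / ((width / 1000.0) * (activity.total_mapped / 1e6))
    return float(np.sqrt((acc_rpkm + pseudocount) * (act_rpkm + pseudocount)))


def gene_element_contact(
    cmap: ContactMap,
    fit: PowerlawFit,
    element: AbcCandidate,
    tss: int,
    max_dist: float = 5e6,
) -> float | None:
    """Regularised contact between an element and a gene TSS.

    Returns ``None`` when the element lies beyond ``max_dist`` (simply not
    a candidate for that gene). The observed balanced contact is imputed
    by the power law when zero/missing, and a floor pseudocount of
    ``kappa * max(d, 1 Mb)^(-gamma)`` is always added. Same-bin elements
    use the maximum observed contact at offsets 1-2 of that bin (the
    post-balancing diagonal is ill-defined).
    """
    d_bp = abs(element.midpoint - tss)
    if d_bp > max_dist:
        return None
    bi = element.midpoint // cmap.bin_size
    bj = tss // cmap.bin_size
    n = cmap.n_bins
    bi, bj = min(bi, n - 1), min(bj, n - 1)
    d = abs(bi - bj) * cmap.bin_size
    if bi == bj:
        neigh = []
        for off in (1, 2):
            if bj + off < n:
                neigh.append(cmap.value(bj, bj + off))
            if bj - off >= 0:
                neigh.append(cmap.value(bj, bj - off))
        obs = max(neigh) if neigh else 0.0
    else:
        obs = cmap.value(bi, bj)
    if obs <= 0:
        obs = fit.expected(max(d, cmap.bin_size))
    return obs + fit.kappa * max(d, 1e6) ** (-fit.gamma)


@dataclass
class AbcPrediction:
    chrom: str
    start: int
    end: int
    gene_id: str
    activity: float
    contact: float
    score: float


def abc_scores(
    candidates: list[AbcCandidate],
    genes: GeneSet,
    maps: dict[str, ContactMap],
    fits: dict[str, PowerlawFit],
    accessibility: CoverageTrack,
    activity: CoverageTrack,
    threshold: float = 0.02,
    max_dist: float = 5e6,
    all_putative: bool = False,
) -> pd.DataFrame:
    """ABC scores for every (element, gene) pair within ``max_dist``.

    Returns a frame with per-gene normalised scores; with
    ``all_putative`` the threshold is not applied. Genes with no
    in-range candidate are skipped.
    """
    by_chrom: dict[str, list[AbcCandidate]] = {}
    for c in candidates:
        if c.activity is None:
            c.activity = element_activity(c, accessibility, activity)
        by_chrom.setdefault(c.chrom, []).append(c)
    rows = []
    for gene in genes:
        cands = by_chrom.get(gene.chrom, [])
        if gene.chrom not in maps or not cands:
            continue
        cmap, fit = maps[gene.chrom], fits[gene.chrom]
        recs = []
        for c in cands:
            contact = gene_element_contact(cmap, fit, c, gene.tss, max_dist=max_dist)
            if contact is None:
                continue
            recs.append((c, contact, c.activity * contact))
        total = sum(r[2] for r in recs)
        if not recs or total <= 0:
            continue
        for c, contact, ac in recs:
            s = ac / total
            if all_putative or s >= threshold:
                rows.append(
                    (c.chrom, c.start, c.end, gene.gene_id, c.activity, contact, s)
                )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "activity", "contact", "score"]
    )


def compare_region_sets(
    set_a: pd.DataFrame, set_b: pd.DataFrame, mode: str = "any_overlap"
) -> tuple[int, int, int]:
    """(a_only, shared, b_only) counts between two interval sets.

    ``any_overlap``: >= 1 bp overlap marks an a-region shared (and
    likewise for b against a). ``contained_in_bins``: an a-region is
    shared only if fully inside a b interval.
    """
    if mode not in ("any_overlap", "contained_in_bins"):
        raise ValueError(f"unknown mode {mode!r}")
    from .genome_io import _overlaps_any

    def _count_overlap(q: pd.DataFrame, t: pd.DataFrame) -> int:
        hits = 0
        for chrom, sub in q.groupby("chrom"):
            tt = t[t["chrom"] == chrom]
            if len(tt) == 0:
                continue
            ms, me = merge_intervals(tt["start"].to_numpy(), tt["end"].to_numpy())
            hits += int(
                _overlaps_any(sub["start"].to_numpy(), sub["end"].to_numpy(), ms, me).sum()
            )
        return hits

    def _count_contained(q: pd.DataFrame, t: pd.DataFrame) -> int:
        # contained within a single t interval (no merging across bins)
        hits = 0
        for chrom, sub in q.groupby("chrom"):
            tt = t[t["chrom"] == chrom]
            if len(tt) == 0:
                continue
            ts = tt["start"].to_numpy()
            te = tt["end"].to_numpy()
            order = np.argsort(ts, kind="stable")
            ts, te = ts[order], te[order]
            te_prefix_max = np.maximum.accumulate(te)
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            i = np.searchsorted(ts, s, side="right") - 1
            ok = i >= 0
            hits += int((ok & (te_prefix_max[np.maximum(i, 0)] >= e)).sum())
        return hits

    if mode == "contained_in_bins":
        shared = _count_contained(set_a, set_b)
    else:
        shared = _count_overlap(set_a, set_b)
    b_hits = _count_overlap(set_b, set_a)
    return len(set_a) - shared, shared, len(set_b) - b_hits


def distance_distributions(predictions: pd.DataFrame, genes: GeneSet) -> pd.DataFrame:
    """Distances from each predicted element to its target and nearest TSS."""
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}
    rows = []
    for r in predictions.itertuples():
        mid = (r.start + r.end) // 2
        target = abs(mid - genes[r.gene_id].tss)
        all_tss = tss_by_chrom[r.chrom]
        i = np.searchsorted(all_tss, mid)
        cands = []
        if i < len(all_tss):
            cands.append(abs(int(all_tss[i]) - mid))
        if i > 0:
            cands.append(abs(int(all_tss[i - 1]) - mid))
        rows.append((r.gene_id, target, min(cands)))
    return pd.DataFrame(rows, columns=["gene_id", "dist_target_tss", "dist_closest_tss"])


@dataclass
class AbcResults:
    """Scored (element, gene) pairs with the fitted power laws."""

    predictions: pd.DataFrame
    candidates: list[AbcCandidate]
    fits: dict[str, PowerlawFit]
    threshold: float

    def regions(self) -> pd.DataFrame:
        """Unique prioritised regions (deduplicated over genes)."""
        return (
            self.predictions[["chrom", "start", "end"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def summary(self) -> str:
        p = self.predictions
        lines = [
            "Activity-by-Contact enhancer predictions",
            "=" * 46,
            f"candidate elements : {len(self.candidates)}",
            f"threshold          : {self.threshold:g}",
            f"(element, gene) pairs kept : {len(p)}",
            f"unique regions     : {len(self.regions())}",
            f"genes with >= 1 prediction : {p['gene_id'].nunique() if len(p) else 0}",
        ]
        for chrom, fit in self.fits.items():
            lines.append(
                f"power law {chrom}   : gamma={fit.gamma:.3f} kappa={fit.kappa:.3g}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.predictions.to_csv(path, sep="\t", index=False)


class AbcModel:
    """ABC scoring pipeline as a fit-once model object."""

    def __init__(
        self,
        genes: GeneSet,
        peaks: PeakSet,
        maps: dict[str, ContactMap],
        accessibility: CoverageTrack,
        activity: CoverageTrack,
        blacklist: pd.DataFrame | None = None,
        extend: int = 250,
        n_strongest: int = 150_000,
        threshold: float = 0.02,
        max_dist: float = 5e6,
    ):
        self.genes = genes
        self.peaks = peaks
        self.maps = maps
        self.accessibility = accessibility
        self.activity = activity
        self.blacklist = blacklist
        self.extend = extend
        self.n_strongest = n_strongest
        self.threshold = threshold
        self.max_dist = max_dist

    def fit(self, all_putative: bool = False) -> AbcResults:
        for cmap in self.maps.values():
            if not cmap.balanced:
                raise ValueError("ABC expects balanced (ICE-normalised) contact maps")
        cands = candidate_regions(
            self.peaks, extend=self.extend, n_strongest=self.n_strongest,
            blacklist=self.blacklist,
        )
        fits = {c: fit_powerlaw(m) for c, m in self.maps.items()}
        preds = abc_scores(
            cands,
            self.genes,
            self.maps,
            fits,
            self.accessibility,
            self.activity,
            threshold=self.threshold,
            max_dist=self.max_dist,
            all_putative=all_putative,
        )
        return AbcResults(
            predictions=preds, candidates=cands, fits=fits, threshold=self.threshold
        )
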