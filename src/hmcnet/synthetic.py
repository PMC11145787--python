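"""Seeded miniature-genome generators.

A synthetic genome carries every statistical structure the pipeline
assumes about real data, so each module can be exercised end-to-end
without downloads:

* non-overlapping genes (>= 1.5 kb, log-uniform lengths) with a planted
  High/Low expression state; TPMs from two well-separated log-normal
  components so the median split recovers the planted labels exactly;
* IP/input read tracks where High genes gain gene-body 5hmC enrichment
  with a dip at the TSS and a maximum just downstream of it (the first few
  percent of the body), a plateau along the body and a shoulder decaying
  past the TTS;
* planted intergenic enhancers 50-500 kb from (a subset of) High-gene
  TSSs, visible as IP bumps, accessibility peaks and boosted Hi-C contact
  with their promoter;
* distance-decaying symmetric contact maps (expected contact
  proportional to |i-j|^-decay) with Poisson counts and the planted
  enhancer-promoter loops.

Defaults: 4 chromosomes x 10 Mb, 400 genes, enrichment effect d = 2
(log2 IP/input at the body maximum), contact decay exponent 1, loop
boost 8x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .featurize import HIGH, LOW
from .genome_io import CoverageTrack, ExpressionTable, GeneModel, GeneSet, PeakSet
from .hic import ContactMap, PairList, map_to_pairs


@dataclass
class SynthConfig:
    n_chroms: int = 4
    chrom_length: int = 10_000_000
    n_genes: int = 400
    gene_length_range: tuple[int, int] = (1_500, 100_000)  # log-uniform
    high_fraction: float = 0.5
    effect: float = 2.0  # log2 IP/input at the body enrichment maximum
    background_rate: float = 5.0  # mean reads per track step
    track_step: int = 50  # bp
    enhancer_fraction: float = 1.0  # fraction of High genes with a planted enhancer
    enhancers_for_all: bool = False  # plant loops for Low genes too (loop-label studies)
    enhancer_distance: tuple[int, int] = (50_000, 500_000)
    loop_boost: float = 8.0
    decay: float = 1.0  # contact distance-decay exponent
    hic_bin_size: int = 10_000
    hic_scale: float = 60.0  # expected counts at one-bin separation
    seed: int = 0

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def n_bins(self) -> dict[str, int]:
        nb = self.chrom_length // self.hic_bin_size
        return {c: nb for c in self.chrom_names}


@dataclass
class SyntheticGenome:
    genes: GeneSet
    expression: ExpressionTable  # single sample named "synth"
    planted_labels: pd.Series  # gene_id -> High/Low
    enhancers: pd.DataFrame  # gene_id, chrom, pos (enhancer midpoint)
    config: SynthConfig


def synth_genome(config: SynthConfig | None = None, seed: int | None = None) -> SyntheticGenome:
    """Place genes, draw TPMs and plant enhancers; deterministic per seed."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    per_chrom = cfg.n_genes // cfg.n_chroms
    extras = cfg.n_genes - per_chrom * cfg.n_chroms
    lo, hi = cfg.gene_length_range

    genes: list[GeneModel] = []
    gene_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chrom_names}
    gid = 0
    margin = 8_000  # keep promoter windows and flanks inside the chromosome
    for ci, chrom in enumerate(cfg.chrom_names):
        n_here = per_chrom + (1 if ci < extras else 0)
        lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_here)).astype(int)
        slack = cfg.chrom_length - 2 * margin - int(lengths.sum()) - n_here * 2 * margin
        if slack < 0:
            raise ValueError(
                "genes cannot be placed without overlap; use fewer or shorter genes"
            )
        gaps = rng.dirichlet(np.ones(n_here + 1)) * slack
        cursor = margin
        for i, L in enumerate(lengths):
            cursor += int(gaps[i]) + margin
            start = cursor
            end = start + int(L)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(gene_id=f"g{gid:04d}", chrom=chrom, start=start, end=end, strand=strand)
            )
            gid += 1
            gene_spans[chrom].append((start, end))
            cursor = end + margin
        if cursor > cfg.chrom_length - margin:
            raise ValueError("gene placement overflowed the chromosome")

    gene_set = GeneSet(genes)
    n = len(genes)
    n_high = int(round(cfg.high_fraction * n))
    labels = np.array([LOW] * n, dtype=object)
    labels[rng.permutation(n)[:n_high]] = HIGH
    planted = pd.Series(labels, index=gene_set.gene_ids)

    # two-component log-normal TPMs: separation makes the median split exact
    tpm = np.where(
        labels == HIGH,
        np.exp(rng.normal(np.log(50.0), 0.5, n)),
        np.exp(rng.normal(np.log(0.5), 0.5, n)),
    )
    expr = ExpressionTable(pd.DataFrame({"synth": tpm}, index=gene_set.gene_ids))

    # plant intergenic enhancers for a fraction of High genes
    enh_rows = []
    half_w = 1_000  # keep-clear half-width around the enhancer
    for g in gene_set:
        eligible = cfg.enhancers_for_all or planted[g.gene_id] == HIGH
        if not eligible or rng.random() > cfg.enhancer_fraction:
            continue
        spans = gene_spans[g.chrom]
        for _ in range(50):  # rejection-sample an intergenic position
            dist = int(rng.uniform(*cfg.enhancer_distance))
            side = 1 if rng.random() < 0.5 else -1
            pos = g.tss + side * dist
            if not (margin < pos < cfg.chrom_length - margin):
                continue
            if any(s - half_w <= pos < e + half_w for s, e in spans):
                continue
            enh_rows.append((g.gene_id, g.chrom, pos))
            break
    enhancers = pd.DataFrame(enh_rows, columns=["gene_id", "chrom", "pos"])
    return SyntheticGenome(
        genes=gene_set,
        expression=expr,
        planted_labels=planted,
        enhancers=enhancers,
        config=cfg,
    )


def _body_profile(u: np.ndarray) -> np.ndarray:
    """Enrichment weight along the gene body (u in [0, 1], 0 = TSS).

    Zero at the TSS (the dip), maximal over the first 1-5% of the body,
    decaying to a plateau of half strength along the rest.
    """
    w = np.zeros_like(u)
    ramp = (u > 0) & (u < 0.01)
    w[ramp] = u[ramp] / 0.01
    peak = (u >= 0.01) & (u <= 0.05)
    w[peak] = 1.0
    tail = u > 0.05
    w[tail] = 0.5 + 0.5 * np.exp(-(u[tail] - 0.05) / 0.05)
    return w


@dataclass
class SynthTracks:
    ip: CoverageTrack
    input: CoverageTrack
    peaks: PeakSet
    accessibility: CoverageTrack


def synth_tracks(
    genome: SyntheticGenome, seed: int | None = None
) -> SynthTracks:
    """Poisson IP/input read tracks plus accessibility peaks.

    The input track is pure Poisson background. The IP track multiplies the
    background rate by ``2**(effect * profile)`` over High-gene bodies
    (dip at TSS, maximum just downstream), adds bumps at planted
    enhancers, and is Poisson-sampled per step. ATAC-like peaks (with
    summits) sit at every promoter and every planted enhancer, plus weak
    background peaks.
    """
    cfg = genome.config
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    step = cfg.track_step
    n_steps = cfg.chrom_length // step

    ip_vals: dict[str, np.ndarray] = {}
    in_vals: dict[str, np.ndarray] = {}
    acc_vals: dict[str, np.ndarray] = {}
    mult: dict[str, np.ndarray] = {
        c: np.ones(n_steps) for c in cfg.chrom_names
    }
    acc_rate: dict[str, np.ndarray] = {c: np.ones(n_steps) for c in cfg.chrom_names}

    pos_axis = (np.arange(n_steps) + 0.5) * step
    for g in genome.genes:
        if genome.planted_labels[g.gene_id] != HIGH:
            continue
        m = mult[g.chrom]
        b0, b1 = g.start // step, g.end // step
        idx = np.arange(b0, min(b1 + 1, n_steps))
        centers = pos_axis[idx]
        if g.strand == "+":
            u = (centers - g.tss) / g.length
        else:
            u = (g.tss - centers) / g.length
        u = np.clip(u, 0.0, 1.0)
        boost = 2.0 ** (cfg.effect * _body_profile(u))
        m[idx] = np.maximum(m[idx], boost)

    # promoter accessibility bumps
    for g in genome.genes:
        a = acc_rate[g.chrom]
        b = g.tss // step
        w = 500 // step
        sl = slice(max(0, b - w), min(n_steps, b + w + 1))
        a[sl] += 20.0

    # planted enhancers: IP bump + accessibility bump
    for r in genome.enhancers.itertuples():
        m = mult[r.chrom]
        a = acc_rate[r.chrom]
        b = r.pos // step
        w = 300 // step
        sl = slice(max(0, b - w), min(n_steps, b + w + 1))
        m[sl] = np.maximum(m[sl], 2.0 ** cfg.effect)
        a[sl] += 10.0

    for chrom in cfg.chrom_names:
        in_vals[chrom] = rng.poisson(cfg.background_rate, n_steps).astype(float)
        ip_vals[chrom] = rng.poisson(cfg.background_rate * mult[chrom]).astype(float)
        acc_vals[chrom] = rng.poisson(cfg.background_rate * acc_rate[chrom]).astype(float)

    def _as_track(vals: dict[str, np.ndarray]) -> CoverageTrack:
        total = float(sum(v.sum() for v in vals.values()))
        # store read counts per step as depth; signal over a step == reads
        return CoverageTrack.from_steps(
            {c: v / step for c, v in vals.items()}, step=step, total_mapped=total
        )

    # ATAC-like peaks: promoters (strong), enhancers (medium), background (weak)
    peak_rows = []
    for g in genome.genes:
        peak_rows.append((g.chrom, g.tss - 500, g.tss + 500, g.tss, 100.0))
    for r in genome.enhancers.itertuples():
        peak_rows.append((r.chrom, r.pos - 500, r.pos + 500, r.pos, 50.0))
    n_bg = len(genome.genes) // 4
    for _ in range(n_bg):
        chrom = cfg.chrom_names[rng.integers(cfg.n_chroms)]
        pos = int(rng.uniform(10_000, cfg.chrom_length - 10_000))
        peak_rows.append((chrom, pos - 500, pos + 500, pos, 5.0))
    peaks = PeakSet(
        pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "summit", "score"])
    )
    return SynthTracks(
        ip=_as_track(ip_vals),
        input=_as_track(in_vals),
        peaks=peaks,
        accessibility=_as_track(acc_vals),
    )


def synth_hic(
    genome: SyntheticGenome, seed: int | None = None
) -> tuple[dict[str, ContactMap], dict[str, PairList]]:
    """Distance-decaying Poisson contact maps with planted loops.

    Expected contact at offset d bins is ``hic_scale * d^-decay``; the
    (promoter bin, enhancer bin) entry of every planted loop is multiplied
    by ``loop_boost`` before sampling. Counts are sampled once for the
    upper triangle and mirrored, so maps are exactly symmetric.
    """
    cfg = genome.config
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 2)
    bs = cfg.hic_bin_size
    nb = cfg.chrom_length // bs

    loops: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chrom_names}
    for r in genome.enhancers.itertuples():
        g = genome.genes[r.gene_id]
        loops[r.chrom].append((g.tss // bs, r.pos // bs))

    maps: dict[str, ContactMap] = {}
    pair_lists: dict[str, PairList] = {}
    for chrom in cfg.chrom_names:
        rows, cols, vals = [], [], []
        for off in range(1, nb):
            mu = cfg.hic_scale * off ** (-cfg.decay)
            if mu < 1e-4:
                break
            i = np.arange(nb - off)
            mus = np.full(nb - off, mu)
            for (a, b) in loops[chrom]:
                lo, hi = min(a, b), max(a, b)
                if hi - lo == off:
                    mus[lo] *= cfg.loop_boost
            counts = rng.poisson(mus)
            nz = counts > 0
            rows.append(i[nz])
            cols.append(i[nz] + off)
            vals.append(counts[nz])
        r_ = np.concatenate(rows)
        c_ = np.concatenate(cols)
        v_ = np.concatenate(vals).astype(float)
        upper = sp.coo_matrix((v_, (r_, c_)), shape=(nb, nb))
        full = (upper + upper.T).tocsr()
        maps[chrom] = ContactMap(chrom=chrom, matrix=full, bin_size=bs)
        pair_lists[chrom] = map_to_pairs(maps[chrom])
    return maps, pair_lists


def synth_loop_tracks(
    genome: SyntheticGenome, seed: int | None = None
) -> tuple[CoverageTrack, CoverageTrack]:
    """IP/input tracks for loop-dependence studies.

    Gene bodies carry NO enrichment; the only non-background IP signal is a
    bump at the planted enhancer of every High gene (strength
    ``2**effect``). A promoter node's own features are therefore
    uninformative about its label — only the loop-linked enhancer node's
    IP feature carries it. Use with a genome built with
    ``enhancers_for_all=True`` so both classes have loops.
    """
    cfg = genome.config
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 3)
    step = cfg.track_step
    n_steps = cfg.chrom_length // step
    mult: dict[str, np.ndarray] = {c: np.ones(n_steps) for c in cfg.chrom_names}
    for r in genome.enhancers.itertuples():
        if genome.planted_labels[r.gene_id] != HIGH:
            continue
        m = mult[r.chrom]
        b = r.pos // step
        w = 2000 // step  # bump wide enough to dominate the 10 kb window mean
        sl = slice(max(0, b - w), min(n_steps, b + w + 1))
        m[sl] = 2.0 ** cfg.effect
    ip_vals, in_vals = {}, {}
    for chrom in cfg.chrom_names:
        in_vals[chrom] = rng.poisson(cfg.background_rate, n_steps).astype(float)
        ip_vals[chrom] = rng.poisson(cfg.background_rate * mult[chrom]).astype(float)

    def _as_track(vals):
        total = float(sum(v.sum() for v in vals.values()))
        return CoverageTrack.from_steps(
            {c: v / step for c, v in vals.items()}, step=step, total_mapped=total
        )

    return _as_track(ip_vals), _as_track(in_vals)


def synth_loop_label_graph(
    genome: SyntheticGenome,
    ip: CoverageTrack,
    input_track: CoverageTrack,
    maps_normalized: dict[str, ContactMap],
    k: int = 10,
    seed: int = 0,
):
    """A genome graph whose masked-node labels depend only on the planted
    distal enhancer (loop-linked), never on the node's own features.

    Masked nodes are the promoter windows of genes with a planted loop;
    their label is the gene's planted High/Low state, which (with
    :func:`synth_loop_tracks`) is encoded solely in the enhancer window's
    IP feature 50-500 kb away. Supports the paired experiment contrasting
    the Hi-C-derived graph with the 1D-nearest control: only a wiring that
    includes the enhancer-promoter loop lets the model see the
    label-generating feature. Returns ``(graph, enhancer_nodes)`` where
    ``enhancer_nodes`` maps promoter node -> enhancer node; swap edge sets
    with :meth:`GenomeGraph.with_edges`.
    """
    from .ghmcn import GenomeGraph, _chrom_offsets, build_genome_graph

    g0 = build_genome_graph(
        maps_normalized,
        ip,
        input_track,
        genome.genes,
        genome.expression.tpm("synth"),
        k=k,
        seed=seed,
    )
    nodes = g0.nodes.copy()
    cfg = genome.config
    offsets = _chrom_offsets({c: m.n_bins for c, m in maps_normalized.items()})
    bs = cfg.hic_bin_size

    enhancer_nodes: dict[int, int] = {}
    labels = np.full(len(nodes), np.nan)
    mask = np.zeros(len(nodes), dtype=bool)
    for r in genome.enhancers.itertuples():
        gene = genome.genes[r.gene_id]
        pnode = offsets[r.chrom] + gene.tss // bs
        enode = offsets[r.chrom] + r.pos // bs
        enhancer_nodes[pnode] = enode
        mask[pnode] = True
        labels[pnode] = 1.0 if genome.planted_labels[r.gene_id] == HIGH else 0.0

    rng = np.random.default_rng(seed)
    folds = np.array([""] * len(nodes), dtype=object)
    midx = rng.permutation(np.flatnonzero(mask))
    n_train = int(round(0.70 * len(midx)))
    n_val = int(round(0.15 * len(midx)))
    folds[midx[:n_train]] = "train"
    folds[midx[n_train : n_train + n_val]] = "val"
    folds[midx[n_train + n_val :]] = "test"
    nodes["label"] = labels
    nodes["mask"] = mask
    nodes["fold"] = folds
    return GenomeGraph(nodes=nodes, edges=g0.edges, bin_size=g0.bin_size), enhancer_nodes
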