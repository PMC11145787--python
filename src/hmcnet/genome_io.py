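"""Genomic data model and parsers.

Everything downstream of this module works on a single coordinate
convention: 0-based, half-open intervals (BED-native). GTF input (1-based,
closed) is converted on load. Gene orientation is carried as ``+``/``-``
strand; the transcription start site (TSS) of a minus-strand gene is the
last base of its span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A record in an input file could not be parsed."""


class ValidationError(ValueError):
    """Input parsed but violates an invariant of the data model."""


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene as a stranded genomic span.

    Coordinates are 0-based half-open. ``tss``/``tts`` are derived from
    strand: on ``+`` the TSS is ``start``; on ``-`` it is ``end - 1``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.end - self.start < 1:
            raise ValidationError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


class GeneSet:
    """An ordered collection of :class:`GeneModel` with unique ids."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        self._by_id: dict[str, GeneModel] = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.chrom, None)
        return list(seen)

    def filter_length(self, min_length: int) -> "GeneSet":
        """Keep genes strictly longer than ``min_length`` base pairs."""
        return GeneSet(g for g in self.genes if g.length > min_length)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "tts": [g.tts for g in self.genes],
            }
        )

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def _parse_bed_gene(line: str, lineno: int) -> GeneModel:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 6:
        raise ParseError(f"line {lineno}: BED gene records need 6 columns, got {len(fields)}")
    chrom, start, end, name, _score, strand = fields[:6]
    try:
        s, e = int(start), int(end)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinates") from exc
    return GeneModel(gene_id=name, chrom=chrom, start=s, end=e, strand=strand)


def _parse_gtf_genes(path) -> list[GeneModel]:
    spans: dict[str, list] = {}  # gene_id -> [chrom, start0, end, strand]
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"line {lineno}: GTF records need 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("gene", "transcript", "exon"):
                continue
            try:
                s1, e1 = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinates") from exc
            if e1 < s1:
                raise ParseError(f"line {lineno}: end < start")
            gid = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gid = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if gid is None:
                raise ParseError(f"line {lineno}: missing gene_id attribute")
            s0 = s1 - 1  # GTF is 1-based closed
            rec = spans.get(gid)
            if rec is None:
                spans[gid] = [chrom, s0, e1, strand]
            else:
                if rec[0] != chrom or rec[3] != strand:
                    raise ValidationError(
                        f"gene {gid}: features on multiple chromosomes/strands"
                    )
                # gene-level span across transcripts: min start, max end
                rec[1] = min(rec[1], s0)
                rec[2] = max(rec[2], e1)
    return [
        GeneModel(gene_id=gid, chrom=c, start=s, end=e, strand=st)
        for gid, (c, s, e, st) in spans.items()
    ]


def load_gene_models(path, min_length: int = 1000) -> GeneSet:
    """Load genes from BED6 or GTF and keep those longer than ``min_length``.

    Format is sniffed from the extension (``.gtf``) or the column count.
    """
    path = str(path)
    if path.endswith((".gtf", ".gtf.txt")):
        genes = _parse_gtf_genes(path)
    else:
        genes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                genes.append(_parse_bed_gene(line.rstrip("\n"), lineno))
    return GeneSet(genes).filter_length(min_length)


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------


class CoverageTrack:
    """Per-chromosome stepwise read coverage.

    Stored per chromosome as sorted, non-overlapping intervals with a
    float depth value (read-depth units, per-base). ``total_mapped`` is the
    library depth in reads used for RPKM normalisation; if not given it
    defaults to the integral of coverage (coverage-bases).
    """

    def __init__(
        self,
        intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        total_mapped: float | None = None,
    ):
        self._chroms: dict[str, dict[str, np.ndarray]] = {}
        integral = 0.0
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if np.any(values < 0):
                raise ValidationError(f"{chrom}: coverage values must be >= 0")
            if np.any(ends <= starts):
                raise ValidationError(f"{chrom}: empty or inverted coverage interval")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"{chrom}: overlapping coverage intervals")
            widths = (ends - starts).astype(np.float64)
            cum = np.concatenate([[0.0], np.cumsum(values * widths)])
            self._chroms[chrom] = {
                "starts": starts,
                "ends": ends,
                "values": values,
                "cum": cum,
            }
            integral += cum[-1]
        self.total_mapped = float(total_mapped) if total_mapped is not None else integral

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def _integral_to(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of coverage over (-inf, x) for each x (vectorised)."""
        d = self._chroms[chrom]
        starts, ends, values, cum = d["starts"], d["ends"], d["values"], d["cum"]
        i = np.searchsorted(starts, x, side="right") - 1
        out = np.where(i >= 0, cum[np.maximum(i, 0)], 0.0)
        valid = i >= 0
        iv = np.maximum(i, 0)
        partial = values[iv] * np.clip(np.minimum(x, ends[iv]) - starts[iv], 0, None)
        return out + np.where(valid, partial, 0.0)

    def region_signal(self, chrom: str, start: int, end: int) -> float:
        """Summed read signal (coverage x overlapping bases) over [start, end).

        Intervals reaching outside covered territory contribute zero there
        (implicit clipping). Unknown chromosomes raise ``KeyError``.
        """
        return float(self.region_signal_many(chrom, np.array([start]), np.array([end]))[0])

    def region_signal_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        if chrom not in self._chroms:
            raise KeyError(f"chromosome {chrom!r} not in track")
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        return self._integral_to(chrom, ends) - self._integral_to(chrom, starts)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_bedgraph(cls, path, total_mapped: float | None = None) -> "CoverageTrack":
        per: dict[str, list[list]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise ParseError(f"line {lineno}: bedGraph needs 4 columns")
                chrom, s, e, v = fields[:4]
                per.setdefault(chrom, []).append([int(s), int(e), float(v)])
        intervals = {}
        for chrom, rows in per.items():
            arr = np.array(rows, dtype=np.float64)
            intervals[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(intervals, total_mapped=total_mapped)

    @classmethod
    def from_bigwig(cls, path, total_mapped: float | None = None) -> "CoverageTrack":
        import pyBigWig  # optional dependency

        bw = pyBigWig.open(str(path))
        intervals = {}
        try:
            for chrom in bw.chroms():
                ivs = bw.intervals(chrom)
                if not ivs:
                    continue
                arr = np.array(ivs, dtype=np.float64)
                intervals[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        finally:
            bw.close()
        return cls(intervals, total_mapped=total_mapped)

    @classmethod
    def from_steps(
        cls,
        values_by_chrom: Mapping[str, np.ndarray],
        step: int,
        total_mapped: float | None = None,
    ) -> "CoverageTrack":
        """Build from fixed-step per-bin depth arrays starting at 0."""
        intervals = {}
        for chrom, vals in values_by_chrom.items():
            vals = np.asarray(vals, dtype=np.float64)
            starts = np.arange(len(vals), dtype=np.int64) * step
            intervals[chrom] = (starts, starts + step, vals)
        return cls(intervals, total_mapped=total_mapped)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, d in self._chroms.items():
                for s, e, v in zip(d["starts"], d["ends"], d["values"]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def load_coverage(path, total_mapped: float | None = None) -> CoverageTrack:
    path = str(path)
    if path.endswith((".bw", ".bigwig", ".bigWig")):
        return CoverageTrack.from_bigwig(path, total_mapped=total_mapped)
    return CoverageTrack.from_bedgraph(path, total_mapped=total_mapped)


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


@dataclass
class PeakSet:
    """Peak intervals with absolute summit positions and a score per peak."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("chrom", "start", "end", "summit", "score")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValidationError(f"PeakSet missing column {col!r}")
        f = self.frame
        bad = (f["summit"] < f["start"]) | (f["summit"] >= f["end"])
        if bad.any():
            raise ValidationError("peak summit outside its interval")
        if (f["score"] < 0).any():
            raise ValidationError("peak scores must be >= 0")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_narrowpeak(cls, path) -> "PeakSet":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                fields = line.split()
                if len(fields) < 10:
                    raise ParseError(f"line {lineno}: narrowPeak needs 10 columns")
                chrom, s, e = fields[0], int(fields[1]), int(fields[2])
                score = float(fields[6])  # signalValue
                offset = int(fields[9])
                if offset < 0:
                    raise ValidationError(f"line {lineno}: peak without summit offset")
                rows.append((chrom, s, e, s + offset, score))
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))

    def to_narrowpeak(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in self.frame.iterrows():
                fh.write(
                    f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\tpeak_{i}\t0\t.\t"
                    f"{r.score:g}\t-1\t-1\t{int(r.summit - r.start)}\n"
                )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


class ExpressionTable:
    """gene_id -> TPM, one column per sample."""

    def __init__(self, frame: pd.DataFrame):
        if (frame.values < 0).any():
            raise ValidationError("TPM values must be >= 0")
        self.frame = frame.astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)

    def tpm(self, sample: str) -> pd.Series:
        return self.frame[sample]

    def restrict(self, gene_ids: Sequence[str]) -> "ExpressionTable":
        missing = [g for g in gene_ids if g not in self.frame.index]
        if missing:
            raise ValidationError(f"genes absent from expression table: {missing[:5]}")
        return ExpressionTable(self.frame.loc[list(gene_ids)])

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Interval utilities (half-open semantics throughout)
# ---------------------------------------------------------------------------


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals; touching intervals are merged."""
    if len(starts) == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    starts, ends = np.asarray(starts)[order], np.asarray(ends)[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def _overlaps_any(
    starts: np.ndarray, ends: np.ndarray, m_starts: np.ndarray, m_ends: np.ndarray
) -> np.ndarray:
    """For each query [s,e), does it overlap (>=1 bp) any merged interval?"""
    if len(m_starts) == 0 or len(starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    # merged interval whose start is the last <= query end-1
    idx = np.searchsorted(m_starts, np.asarray(ends) - 1, side="right") - 1
    hit = idx >= 0
    idx = np.maximum(idx, 0)
    return hit & (m_ends[idx] > np.asarray(starts))


def exclude_blacklist(
    intervals: pd.DataFrame, blacklist: pd.DataFrame
) -> pd.DataFrame:
    """Drop intervals overlapping (>= 1 bp) any blacklist region.

    Both frames need ``chrom``/``start``/``end`` columns. Half-open
    coordinates: touching intervals do not overlap.
    """
    if len(blacklist) == 0 or len(intervals) == 0:
        return intervals.copy()
    keep = np.ones(len(intervals), dtype=bool)
    for chrom, bl in blacklist.groupby("chrom"):
        sel = intervals["chrom"] == chrom
        if not sel.any():
            continue
        ms, me = merge_intervals(bl["start"].to_numpy(), bl["end"].to_numpy())
        sub = intervals.loc[sel]
        keep[np.flatnonzero(sel.to_numpy())] = ~_overlaps_any(
            sub["start"].to_numpy(), sub["end"].to_numpy(), ms, me
        )
    return intervals.loc[keep].reset_index(drop=True)


def load_bed_intervals(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: BED needs >= 3 columns")
            rows.append((fields[0], int(fields[1]), int(fields[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
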