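"""Coordinate-anchored data model, interval arithmetic, and text-format I/O.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Transcripts keep their genomic orientation: on the minus strand the TSS is the
larger coordinate.  Everything downstream (peak calling, metagenes, annotation)
is built on the small set of primitives here: interval overlap, disjoining into
atomic units, and window-averaged coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with their lengths in bases."""

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]

    def __post_init__(self):
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        for name in self.chrom_names:
            if self.chrom_lengths.get(name, 0) <= 0:
                raise ValueError(f"chromosome {name!r} must have positive length")

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, optionally stranded/named/scored."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        # even length -> start + len/2; odd -> start + floor(len/2)
        return self.start + len(self) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Transcript:
    """Annotated transcript with genomic TSS/TES and exon structure.

    ``tss``/``tes`` are genomic base positions; on the minus strand
    ``tss > tes``.  ``exons`` are (start, end) pairs in genomic order.
    """

    id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be +/- not {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"{self.id}: - strand requires tss > tes")
        lo, hi = self.start, self.end
        for s, e in self.exons:
            if not (lo <= s < e <= hi):
                raise ValueError(f"{self.id}: exon [{s},{e}) outside gene body")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    @property
    def length(self) -> int:
        return self.end - self.start

    def body_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.id)


class CoverageTrack:
    """Per-base read-depth of 3'-extended sequencing fragments.

    Holds one depth vector per chromosome plus the total number of mapped
    fragments (for per-million scaling).  When built from fragment intervals
    the sorted fragment starts are retained so bins can also be scored by
    *fragment counts* (RPKM-style), not only by per-base depth.
    """

    def __init__(
        self,
        layout: GenomeLayout,
        depth: dict[str, np.ndarray],
        total_mapped: int,
        fragment_extension: int = 300,
        fragment_starts: dict[str, np.ndarray] | None = None,
    ):
        if total_mapped < 1:
            raise ValueError("total_mapped must be >= 1")
        self.layout = layout
        self.depth = depth
        self.total_mapped = int(total_mapped)
        self.fragment_extension = int(fragment_extension)
        self.fragment_starts = fragment_starts

    @classmethod
    def from_fragments(
        cls,
        layout: GenomeLayout,
        fragments: dict[str, np.ndarray],
        fragment_length: int = 300,
    ) -> "CoverageTrack":
        """Build from per-chromosome arrays of fragment start positions.

        Each fragment covers ``[start, start + fragment_length)`` clipped to
        the chromosome.
        """
        depth = {}
        starts = {}
        total = 0
        for chrom in layout.chrom_names:
            L = layout.length(chrom)
            s = np.sort(np.asarray(fragments.get(chrom, np.empty(0, int)), dtype=np.int64))
            s = s[(s > -fragment_length) & (s < L)]
            starts[chrom] = s
            total += s.size
            d = np.zeros(L + 1, dtype=np.float64)
            lo = np.clip(s, 0, L)
            hi = np.clip(s + fragment_length, 0, L)
            np.add.at(d, lo, 1.0)
            np.add.at(d, hi, -1.0)
            depth[chrom] = np.cumsum(d)[:L]
        return cls(layout, depth, max(total, 1), fragment_length, starts)

    @classmethod
    def from_depth(
        cls, layout: GenomeLayout, depth: dict[str, np.ndarray], total_mapped: int = 1
    ) -> "CoverageTrack":
        return cls(layout, {c: np.asarray(v, float) for c, v in depth.items()}, total_mapped)

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        depth = {
            c: self.depth[c] + other.depth[c] for c in self.layout.chrom_names
        }
        return CoverageTrack(
            self.layout, depth, self.total_mapped + other.total_mapped,
            self.fragment_extension,
        )

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        d = self.depth[chrom]
        return float(d[max(start, 0): min(end, d.size)].sum())

    def count_fragments_overlapping(self, chrom: str, start: int, end: int) -> int:
        """Number of (extended) fragments sharing >= 1 bp with [start, end)."""
        if self.fragment_starts is None:
            raise ValueError("track was not built from fragments")
        s = self.fragment_starts[chrom]
        lo = np.searchsorted(s, start - self.fragment_extension, side="right")
        hi = np.searchsorted(s, end, side="left")
        return int(hi - lo)


# ---------------------------------------------------------------------------
# interval operations
# ---------------------------------------------------------------------------


def dedup_transcripts(transcripts: Sequence[Transcript]) -> list[Transcript]:
    """Drop transcripts covering duplicated loci.

    Among transcripts sharing an identical (chrom, TSS, TES) triple exactly one
    is retained — the first in id order.
    """
    by_key: dict[tuple, Transcript] = {}
    for t in sorted(transcripts, key=lambda t: t.id):
        key = (t.chrom, t.tss, t.tes)
        by_key.setdefault(key, t)
    kept = set(t.id for t in by_key.values())
    return [t for t in transcripts if t.id in kept]


def overlap_any(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> np.ndarray:
    """Boolean flag per ``a`` interval: does some ``b`` interval share >= min_bp bases?"""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    arr = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        starts = np.array([p[0] for p in pairs])
        ends = np.array([p[1] for p in pairs])
        # cummax of ends is nondecreasing, so both scan bounds binary-search
        arr[chrom] = (starts, ends, np.maximum.accumulate(ends))
    out = np.zeros(len(a), dtype=bool)
    for i, iv in enumerate(a):
        if iv.chrom not in arr:
            continue
        starts, ends, cummax_ends = arr[iv.chrom]
        # candidates: start small enough AND some end large enough
        hi = np.searchsorted(starts, iv.end - min_bp, side="right")
        lo = np.searchsorted(cummax_ends, iv.start + min_bp, side="left")
        for j in range(lo, hi):
            if min(iv.end, ends[j]) - max(iv.start, starts[j]) >= min_bp:
                out[i] = True
                break
    return out


def disjoin(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Fragment intervals at every breakpoint into pairwise-disjoint atomic units.

    The union of units equals the union of inputs and every input is an exact
    union of units (the GenomicRanges ``disjoin`` restricted to covered bases).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        pairs = by_chrom[chrom]
        cuts = np.unique(np.concatenate([[s for s, _ in pairs], [e for _, e in pairs]]))
        starts = np.array(sorted(s for s, _ in pairs))
        ends_sorted = np.array(sorted(e for _, e in pairs))
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            # unit [lo,hi) is covered iff #starts<=lo > #ends<=lo
            n_open = np.searchsorted(starts, lo, side="right") - np.searchsorted(
                ends_sorted, lo, side="right"
            )
            if n_open > 0:
                out.append(GenomicInterval(chrom, int(lo), int(hi)))
    return out


def window_counts(
    track: CoverageTrack,
    windows: Sequence[GenomicInterval],
    rpm: bool = False,
) -> np.ndarray:
    """Per-window mean per-base depth, optionally scaled per million fragments.

    Windows extending past a chromosome end are clipped (with a warning); the
    divisor remains the *requested* window length so truncated flanks do not
    inflate the mean.
    """
    out = np.zeros(len(windows))
    clipped = 0
    for i, w in enumerate(windows):
        L = track.layout.length(w.chrom)
        lo, hi = max(0, w.start), min(L, w.end)
        if (lo, hi) != (w.start, w.end):
            clipped += 1
        if hi > lo:
            out[i] = track.window_sum(w.chrom, lo, hi) / len(w)
    if clipped:
        warnings.warn(f"{clipped} window(s) clipped at chromosome bounds")
    if rpm:
        out = out * 1e6 / track.total_mapped
    return out


# ---------------------------------------------------------------------------
# text formats
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals; malformed lines raise with line numbers."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else None
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, name, score))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                score = "0" if iv.score is None else f"{iv.score:g}"
                fields += [iv.name or ".", score, iv.strand]
            fh.write("\t".join(fields) + "\n")


def write_bedgraph(track: CoverageTrack, path, header: bool = False) -> None:
    """Run-length-encoded bedGraph of a depth track (zero runs omitted)."""
    with open(path, "w") as fh:
        if header:
            fh.write("track type=bedGraph\n")
        for chrom in track.layout.chrom_names:
            d = track.depth[chrom]
            if d.size == 0:
                continue
            change = np.flatnonzero(np.diff(d)) + 1
            bounds = np.concatenate([[0], change, [d.size]])
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                v = d[lo]
                if v != 0:
                    fh.write(f"{chrom}\t{lo}\t{hi}\t{v:g}\n")


TRANSCRIPT_COLUMNS = ("id", "chrom", "strand", "txStart", "txEnd", "exonStarts", "exonEnds")


def read_transcripts(path) -> list[Transcript]:
    """Read a refFlat-like TSV (txStart < txEnd genomic; strand decides TSS)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"exonStarts": str, "exonEnds": str})
    out = []
    for row in df.itertuples(index=False):
        s, e = int(row.txStart), int(row.txEnd)
        tss, tes = (s, e) if row.strand == "+" else (e, s)
        ex_s = [int(x) for x in str(row.exonStarts).split(",") if x not in ("", "nan")]
        ex_e = [int(x) for x in str(row.exonEnds).split(",") if x not in ("", "nan")]
        out.append(
            Transcript(str(row.id), str(row.chrom), str(row.strand), tss, tes,
                       tuple(zip(ex_s, ex_e)))
        )
    return out


def write_transcripts(transcripts: Iterable[Transcript], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRANSCRIPT_COLUMNS) + "\n")
        for t in transcripts:
            ex_s = ",".join(str(s) for s, _ in t.exons)
            ex_e = ",".join(str(e) for _, e in t.exons)
            fh.write(
                f"{t.id}\t{t.chrom}\t{t.strand}\t{t.start}\t{t.end}\t{ex_s}\t{ex_e}\n"
            )


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out
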