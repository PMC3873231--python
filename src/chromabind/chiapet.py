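"""ChIA-PET anchor filtering and MBD3 end scoring.

Pol II ChIA-PET pairs link two genomic loci in three-dimensional proximity.
Pairs are retained when at least one end overlaps a TSS +/- 3 kb window; the
TSS-proximal end is designated end 1.  Both ends are then scored by the MBD3
fragment count in a 1 kb window around the end center, per million mapped
fragments, and pairs are rank-ordered by the end-1 score into equal groups
(descending), emitting the end-2 scores in the same order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CoverageTrack, GenomicInterval, Transcript


@dataclass(frozen=True)
class PETPair:
    end1: GenomicInterval
    end2: GenomicInterval
    ipet_count: int | None = None


def _tss_index(transcripts: list[Transcript], flank: int):
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append((t.tss, t.id))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out[chrom] = (np.array([p[0] for p in pairs]), [p[1] for p in pairs])
    return out


def _nearest_tss(end: GenomicInterval, index, flank: int) -> tuple[str | None, int | None]:
    """(gene id, distance) for the nearest TSS whose +/- flank window the end
    overlaps, or (None, None).  Ties by distance break lexicographically."""
    if end.chrom not in index:
        return None, None
    tss, ids = index[end.chrom]
    lo = np.searchsorted(tss, end.start - flank + 1, side="left")
    hi = np.searchsorted(tss, end.end + flank - 1, side="right")
    best: tuple[int, str] | None = None
    for j in range(lo, hi):
        # distance from interval to TSS point
        d = max(tss[j] - (end.end - 1), end.start - tss[j], 0)
        if d >= flank + 1:
            continue
        if best is None or (d, ids[j]) < best:
            best = (int(d), ids[j])
    if best is None:
        return None, None
    return best[1], best[0]


def filter_anchor_pets(
    pets: list[PETPair],
    transcripts: list[Transcript],
    flank: int = 3000,
) -> list[PETPair]:
    """Retain pairs with >= 1 end overlapping some TSS +/- flank window.

    The overlapping end becomes end 1; when both ends overlap, the one closer
    to its nearest TSS is end 1 (ties keep the given order).
    """
    index = _tss_index(transcripts, flank)
    out = []
    for pair in pets:
        _, d1 = _nearest_tss(pair.end1, index, flank)
        _, d2 = _nearest_tss(pair.end2, index, flank)
        if d1 is None and d2 is None:
            continue
        if d1 is None or (d2 is not None and d2 < d1):
            pair = PETPair(pair.end2, pair.end1, pair.ipet_count)
        out.append(pair)
    return out


def pet_end_scores(
    pairs: list[PETPair],
    mbd3_track: CoverageTrack,
    transcripts: list[Transcript],
    half_width: int = 500,
    flank: int = 3000,
) -> pd.DataFrame:
    """Per-end MBD3 fragment count in [center - 500, center + 500), per million.

    A gene id is attached to an end only when it overlaps a TSS +/- flank
    window (nearest TSS, ties lexicographic).
    """
    index = _tss_index(transcripts, flank)
    scale = 1e6 / mbd3_track.total_mapped
    rows = []
    for i, pair in enumerate(pairs):
        row = {"pair": i}
        for which, end in (("end1", pair.end1), ("end2", pair.end2)):
            c = end.center
            L = mbd3_track.layout.length(end.chrom)
            n = mbd3_track.count_fragments_overlapping(
                end.chrom, max(0, c - half_width), min(L, c + half_width)
            )
            gene, _ = _nearest_tss(end, index, flank)
            row[f"{which}_score"] = n * scale
            row[f"{which}_gene"] = gene or ""
        rows.append(row)
    return pd.DataFrame(rows)


def rank_group_ends(scored: pd.DataFrame, n_groups: int = 10) -> pd.DataFrame:
    """Sort pairs by descending end-1 score (stable) and assign rank groups.

    Group g of a pair at 1-based rank ``i`` among ``n`` pairs is
    ``ceil(i * n_groups / n)``; group sizes differ by at most 1.
    """
    n = len(scored)
    if n == 0:
        return scored.assign(group=[])
    if n < n_groups:
        warnings.warn("fewer pairs than groups; groups of size >= 1 formed")
    out = scored.sort_values("end1_score", ascending=False, kind="stable").reset_index(
        drop=True
    )
    ranks = np.arange(1, n + 1)
    out["group"] = np.ceil(ranks * min(n_groups, n) / n).astype(int)
    return out
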