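"""MNase-seq nucleosome occupancy: size selection, midpoints, downsampling,
and TSS-aligned quartile metagenes.

Paired-end MNase fragments are filtered to mononucleosome size (120-180 bp
inclusive) and collapsed to their midpoints, which estimate nucleosome dyads.
Conditions are downsampled to a common midpoint count, aligned on TSSs
(strand-flipped), split into quartiles by MBD3 signal at the promoter,
normalized per quartile by the mean occupancy over +/- 5 kb, and smoothed with
a centered moving average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CoverageTrack, Transcript


@dataclass
class MnaseParams:
    min_len: int = 120
    max_len: int = 180
    smoothing_period: int = 50
    norm_flank: int = 5000
    quartile_flank: int = 3000

    def __post_init__(self):
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")
        if self.smoothing_period < 1:
            raise ValueError("smoothing period must be >= 1")


def size_filter_midpoints(
    fragments: dict[str, np.ndarray], params: MnaseParams | None = None
) -> tuple[dict[str, np.ndarray], float]:
    """Filter fragments to [min_len, max_len] and convert to midpoints.

    ``fragments`` maps chromosome -> (n, 2) array of (start, end) pairs.
    Midpoint = start + floor(len / 2).  Returns per-chromosome sorted midpoint
    arrays and the retained fraction.
    """
    params = params or MnaseParams()
    out: dict[str, np.ndarray] = {}
    kept = 0
    total = 0
    for chrom, arr in fragments.items():
        arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
        lens = arr[:, 1] - arr[:, 0]
        if np.any(lens <= 0):
            raise ValueError("fragments must have start < end")
        mask = (lens >= params.min_len) & (lens <= params.max_len)
        total += arr.shape[0]
        kept += int(mask.sum())
        mids = arr[mask, 0] + lens[mask] // 2
        out[chrom] = np.sort(mids)
    frac = kept / total if total else 0.0
    return out, frac


def downsample(
    midpoints_by_condition: dict[str, dict[str, np.ndarray]],
    target_n: int | None = None,
    seed: int = 0,
) -> dict[str, dict[str, np.ndarray]]:
    """Uniform without-replacement downsampling to a common count per condition."""
    counts = {
        cond: sum(v.size for v in chroms.values())
        for cond, chroms in midpoints_by_condition.items()
    }
    n = min(counts.values()) if target_n is None else target_n
    if any(c < n for c in counts.values()):
        warnings.warn("target exceeds smallest condition; using the minimum count")
        n = min(counts.values())
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, np.ndarray]] = {}
    for cond, chroms in midpoints_by_condition.items():
        names = sorted(chroms)
        sizes = np.array([chroms[c].size for c in names])
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        pick = rng.choice(offsets[-1], size=n, replace=False)
        out[cond] = {}
        for i, c in enumerate(names):
            local = pick[(pick >= offsets[i]) & (pick < offsets[i + 1])] - offsets[i]
            out[cond][c] = np.sort(chroms[c][local])
    return out


def moving_average(x: np.ndarray, period: int) -> np.ndarray:
    """Centered moving average with symmetric truncation at the edges."""
    n = x.size
    half_lo = (period - 1) // 2
    half_hi = period // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.maximum(np.arange(n) - half_lo, 0)
    hi = np.minimum(np.arange(n) + half_hi + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def mbd3_promoter_counts(
    transcripts: list[Transcript], mbd3_track: CoverageTrack, flank: int = 3000
) -> np.ndarray:
    """MBD3 fragment count in TSS +/- flank per transcript (quartile ranking key)."""
    out = np.empty(len(transcripts), dtype=np.int64)
    for i, t in enumerate(transcripts):
        L = mbd3_track.layout.length(t.chrom)
        out[i] = mbd3_track.count_fragments_overlapping(
            t.chrom, max(0, t.tss - flank), min(L, t.tss + flank)
        )
    return out


def quartile_assign(scores: np.ndarray, ids: list[str]) -> np.ndarray:
    """Equal-size rank quartiles (0 = lowest, 3 = highest); ties break by id."""
    n = len(ids)
    order = sorted(range(n), key=lambda i: (scores[i], ids[i]))
    q = np.empty(n, dtype=int)
    for rank, i in enumerate(order):
        q[i] = min(3, rank * 4 // n)
    return q


def tss_aligned_occupancy(
    midpoints: dict[str, np.ndarray],
    transcripts: list[Transcript],
    flank: int,
) -> np.ndarray:
    """(n_transcripts, 2*flank+1) midpoint counts aligned to TSS, strand-flipped."""
    out = np.zeros((len(transcripts), 2 * flank + 1))
    for i, t in enumerate(transcripts):
        mids = midpoints.get(t.chrom)
        if mids is None or mids.size == 0:
            continue
        lo = np.searchsorted(mids, t.tss - flank, side="left")
        hi = np.searchsorted(mids, t.tss + flank, side="right")
        rel = mids[lo:hi] - (t.tss - flank)
        counts = np.bincount(rel, minlength=2 * flank + 1)[: 2 * flank + 1]
        out[i] = counts[::-1] if t.strand == "-" else counts
    return out


def quartile_metagene(
    midpoints_by_condition: dict[str, dict[str, np.ndarray]],
    transcripts: list[Transcript],
    mbd3_track: CoverageTrack,
    params: MnaseParams | None = None,
) -> pd.DataFrame:
    """Per-quartile normalized, smoothed nucleosome-occupancy metagenes.

    Transcripts are split into four equal-size groups by MBD3 fragment count in
    TSS +/- 3 kb.  Per condition and quartile, TSS-aligned midpoint counts over
    +/- 5 kb are averaged, divided by their own mean (so the +/- 5 kb mean is
    exactly 1 before smoothing), then smoothed with a centered moving average.
    Returns long-format (position, quartile, condition, value, raw).
    """
    params = params or MnaseParams()
    if len(transcripts) < 4:
        raise ValueError("need at least 4 transcripts for quartiles")
    scores = mbd3_promoter_counts(transcripts, mbd3_track, params.quartile_flank)
    quart = quartile_assign(scores, [t.id for t in transcripts])
    flank = params.norm_flank
    positions = np.arange(-flank, flank + 1)
    frames = []
    for cond, mids in midpoints_by_condition.items():
        aligned = tss_aligned_occupancy(mids, transcripts, flank)
        for q in range(4):
            rows = aligned[quart == q]
            profile = rows.mean(axis=0)
            m = profile.mean()
            norm = profile / m if m > 0 else profile
            smooth = moving_average(norm, params.smoothing_period)
            frames.append(
                pd.DataFrame(
                    {
                        "position": positions,
                        "quartile": q + 1,
                        "condition": cond,
                        "value": smooth,
                        "raw": norm,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
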