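"""Composite (metagene) profiles and promoter heatmap matrices.

All anchored profiles are strand-aware: windows are tiled across the anchored
span in genomic coordinates and the per-transcript window vector is reversed
for minus-strand transcripts, so "downstream" always means 5'->3'.  Composite
profiles are unweighted means across transcripts (or peaks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CoverageTrack, GenomicInterval, Transcript, overlap_any


@dataclass
class ProfileSpec:
    anchor: str = "TSS"  # TSS | TES | peak_center | gene_body
    flank: int = 5000
    window: int = 70
    body_bins: int = 100
    rpm: bool = False


def _windows_for_anchor(
    chrom: str, anchor_pos: int, strand: str, flank: int, window: int
) -> tuple[list[tuple[int, int]], bool]:
    """Tile ``[anchor - flank, anchor + flank)`` into fixed windows.

    Returns genomic (start, end) pairs in left-to-right genomic order plus a
    flag whether the per-window vector must be flipped (minus strand).
    """
    n_win = (2 * flank) // window
    span = n_win * window
    left = anchor_pos - span // 2
    wins = [(left + i * window, left + (i + 1) * window) for i in range(n_win)]
    return wins, strand == "-"


def tss_profile(
    track: CoverageTrack,
    transcripts: list[Transcript],
    spec: ProfileSpec | None = None,
) -> pd.DataFrame:
    """Average signal in fixed windows across [TSS - flank, TSS + flank).

    Transcripts whose span exits the chromosome contribute only their in-bounds
    windows.  Returns a frame with the window-center offset from the TSS
    (5'->3'), the composite mean and the across-transcript standard error.
    """
    spec = spec or ProfileSpec()
    n_win = (2 * spec.flank) // spec.window
    acc = np.zeros(n_win)
    acc2 = np.zeros(n_win)
    cnt = np.zeros(n_win)
    for t in transcripts:
        wins, flip = _windows_for_anchor(t.chrom, t.tss, t.strand, spec.flank, spec.window)
        L = track.layout.length(t.chrom)
        vals = np.full(n_win, np.nan)
        for i, (s, e) in enumerate(wins):
            if s < 0 or e > L:
                continue  # truncated windows dropped for this transcript
            vals[i] = track.window_sum(t.chrom, s, e) / (e - s)
        if flip:
            vals = vals[::-1]
        ok = ~np.isnan(vals)
        acc[ok] += vals[ok]
        acc2[ok] += vals[ok] ** 2
        cnt[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = acc / cnt
        var = np.maximum(acc2 / cnt - mean**2, 0.0)
        se = np.sqrt(var / np.maximum(cnt, 1))
    if spec.rpm:
        scale = 1e6 / track.total_mapped
        mean, se = mean * scale, se * scale
    offsets = (np.arange(n_win) - n_win / 2 + 0.5) * spec.window
    return pd.DataFrame({"offset": offsets, "mean": mean, "se": se, "n": cnt.astype(int)})


def genebody_profile(
    track: CoverageTrack,
    transcripts: list[Transcript],
    spec: ProfileSpec | None = None,
    min_length: int = 2000,
) -> pd.DataFrame:
    """Scaled gene-body model: 100 equal bins per gene (plus fixed flanks).

    Only full-length gene bodies strictly longer than ``min_length`` qualify.
    Returns per-bin composite means over flank5', body (percent bins), flank3'.
    """
    spec = spec or ProfileSpec(anchor="gene_body")
    genes = [t for t in transcripts if t.length > min_length]
    if not genes:
        raise ValueError("no transcripts longer than the minimum length")
    n_flank = spec.flank // spec.window
    nb = spec.body_bins
    total = 2 * n_flank + nb
    acc = np.zeros(total)
    cnt = np.zeros(total)
    for t in genes:
        L = track.layout.length(t.chrom)
        vals = np.full(total, np.nan)
        # 5' flank: windows upstream of TSS (genomically left on + strand)
        edges = np.linspace(t.start, t.end, nb + 1)
        body = np.empty(nb)
        for i in range(nb):
            s, e = int(edges[i]), int(edges[i + 1])
            body[i] = track.window_sum(t.chrom, s, e) / max(e - s, 1)
        up = np.full(n_flank, np.nan)
        down = np.full(n_flank, np.nan)
        for i in range(n_flank):
            s = t.start - (n_flank - i) * spec.window
            e = s + spec.window
            if s >= 0:
                up[i] = track.window_sum(t.chrom, s, e) / spec.window
            s = t.end + i * spec.window
            e = s + spec.window
            if e <= L:
                down[i] = track.window_sum(t.chrom, s, e) / spec.window
        if t.strand == "-":
            vals = np.concatenate([down[::-1], body[::-1], up[::-1]])
        else:
            vals = np.concatenate([up, body, down])
        ok = ~np.isnan(vals)
        acc[ok] += vals[ok]
        cnt[ok] += 1
    mean = acc / np.maximum(cnt, 1)
    labels = (
        [f"up{n_flank - i}" for i in range(n_flank)]
        + [f"body{i + 1}" for i in range(nb)]
        + [f"down{i + 1}" for i in range(n_flank)]
    )
    return pd.DataFrame({"bin": labels, "mean": mean, "n": cnt.astype(int)})


def promoter_matrix(
    ranking_track: CoverageTrack,
    passenger_tracks: dict[str, CoverageTrack],
    transcripts: list[Transcript],
    upstream: int = 7000,
    downstream: int = 3000,
    n_bins: int = 20,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Binned promoter matrices ranked by total signal of the ranking track.

    Rows are transcripts, columns equal-width bins across [TSS - upstream,
    TSS + downstream) oriented 5'->3'.  Rows are sorted by descending total
    ranking-track signal; every passenger matrix is emitted in the same order.
    """
    span = upstream + downstream
    bin_w = span // n_bins

    def one_matrix(track: CoverageTrack) -> np.ndarray:
        M = np.zeros((len(transcripts), n_bins))
        for r, t in enumerate(transcripts):
            if t.strand == "+":
                left = t.tss - upstream
            else:
                left = t.tss - downstream
            L = track.layout.length(t.chrom)
            for i in range(n_bins):
                s = left + i * bin_w
                e = s + bin_w
                if s < 0 or e > L:
                    continue
                M[r, i] = track.window_sum(t.chrom, s, e) / bin_w
            if t.strand == "-":
                M[r] = M[r, ::-1]
        return M

    ranking = one_matrix(ranking_track)
    totals = ranking.sum(axis=1)
    order = np.argsort(-totals, kind="stable")
    ids = [transcripts[i].id for i in order]
    cols = [f"bin{i + 1}" for i in range(n_bins)]
    rank_df = pd.DataFrame(ranking[order], index=ids, columns=cols)
    passengers = {
        name: pd.DataFrame(one_matrix(tr)[order], index=ids, columns=cols)
        for name, tr in passenger_tracks.items()
    }
    return rank_df, passengers


def damid_heatmap_gene_filter(
    transcripts: list[Transcript],
    expression: dict[str, float | None],
    probe_intervals: list[GenomicInterval],
    allowed_chroms: set[str] | None = None,
    upstream: int = 7000,
    downstream: int = 3000,
    n_bins: int = 20,
) -> tuple[list[Transcript], list[tuple[str, int]]]:
    """The iterative promoter-heatmap gene filter, with per-step counts.

    Steps: (1) restrict to the allowed chromosome set (autosomes + X + Y by
    default, i.e. everything here unless told otherwise); (2) non-missing
    expression; (3) at least one array probe in every TSS bin; (4) unique TSS;
    (5) no other TSS within ``upstream`` bp upstream or ``downstream`` bp
    downstream.  Returns survivors plus (step name, count-after) pairs.
    """
    counts: list[tuple[str, int]] = []
    kept = list(transcripts)
    if allowed_chroms is not None:
        kept = [t for t in kept if t.chrom in allowed_chroms]
    counts.append(("chromosome_restriction", len(kept)))

    kept = [t for t in kept if expression.get(t.id) is not None]
    counts.append(("non_missing_expression", len(kept)))

    bin_w = (upstream + downstream) // n_bins
    tmp: dict[str, list[tuple[int, int]]] = {}
    for iv in probe_intervals:
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
    probe_sorted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c, v in tmp.items():
        v.sort()
        starts = np.array([p[0] for p in v])
        ends = np.array([p[1] for p in v])
        probe_sorted[c] = (starts, np.maximum.accumulate(ends))

    def covered(t: Transcript) -> bool:
        if t.chrom not in probe_sorted:
            return False
        starts, cummax_ends = probe_sorted[t.chrom]
        left = t.tss - upstream if t.strand == "+" else t.tss - downstream
        for i in range(n_bins):
            s, e = left + i * bin_w, left + (i + 1) * bin_w
            # overlap exists iff some probe has start < e and end > s;
            # probes never nest here (tiled), so the cummax prefix test is exact
            hi = np.searchsorted(starts, e, side="left")
            if hi == 0 or cummax_ends[hi - 1] <= s:
                return False
        return True

    kept = [t for t in kept if covered(t)]
    counts.append(("probe_in_every_bin", len(kept)))

    seen: dict[tuple, int] = {}
    for t in kept:
        seen[(t.chrom, t.tss)] = seen.get((t.chrom, t.tss), 0) + 1
    kept = [t for t in kept if seen[(t.chrom, t.tss)] == 1]
    counts.append(("unique_tss", len(kept)))

    all_tss: dict[str, np.ndarray] = {}
    for t in transcripts:
        all_tss.setdefault(t.chrom, []).append(t.tss)
    all_tss = {c: np.sort(np.array(v)) for c, v in all_tss.items()}

    def isolated(t: Transcript) -> bool:
        tss = all_tss[t.chrom]
        if t.strand == "+":
            lo, hi = t.tss - upstream, t.tss + downstream
        else:
            lo, hi = t.tss - downstream, t.tss + upstream
        i0 = np.searchsorted(tss, lo, side="left")
        i1 = np.searchsorted(tss, hi, side="right")
        n_in = i1 - i0  # includes self
        return n_in <= 1

    kept = [t for t in kept if isolated(t)]
    counts.append(("no_neighbors", len(kept)))
    return kept, counts


def mad_row_filter(matrix: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Rows whose mean absolute deviation about the row mean exceeds the threshold.

    Returns a boolean retention mask (strict > comparison).
    """
    X = np.asarray(matrix, float)
    mad = np.abs(X - X.mean(axis=1, keepdims=True)).mean(axis=1)
    return mad > threshold


def peak_center_profile(
    tracks: dict[str, CoverageTrack],
    peaks: list[GenomicInterval],
    transcripts: list[Transcript],
    tss_radius: int = 3000,
    flank: int = 3000,
    window: int = 60,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-track composite profiles around peak centers, split by TSS overlap.

    Peaks are stratified by >= 1 bp overlap with any TSS +/- ``tss_radius``
    window; per stratum and track, signal is averaged in fixed windows across
    [center - flank, center + flank) and scaled per million mapped fragments.
    """
    tss_windows = [
        GenomicInterval(t.chrom, max(0, t.tss - tss_radius), t.tss + tss_radius)
        for t in transcripts
    ]
    at_tss = overlap_any(peaks, tss_windows)
    strata = {
        "tss": [p for p, f in zip(peaks, at_tss) if f],
        "non_tss": [p for p, f in zip(peaks, at_tss) if not f],
    }
    n_win = (2 * flank) // window
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for name, track in tracks.items():
        out[name] = {}
        for stratum, pks in strata.items():
            if not pks:
                warnings.warn(f"empty {stratum} stratum; profile omitted")
                continue
            acc = np.zeros(n_win)
            cnt = np.zeros(n_win)
            for pk in pks:
                wins, _ = _windows_for_anchor(pk.chrom, pk.center, ".", flank, window)
                L = track.layout.length(pk.chrom)
                for i, (s, e) in enumerate(wins):
                    if s < 0 or e > L:
                        continue
                    acc[i] += track.window_sum(pk.chrom, s, e) / (e - s)
                    cnt[i] += 1
            mean = acc / np.maximum(cnt, 1) * 1e6 / track.total_mapped
            offsets = (np.arange(n_win) - n_win / 2 + 0.5) * window
            out[name][stratum] = pd.DataFrame({"offset": offsets, "mean": mean})
    return out
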