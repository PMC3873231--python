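"""Peak feature annotation, mark-presence thresholds, 1 kb pattern classes,
and the CpG-island methylation decile table.

Mark presence follows the super-enhancer-style rank/elbow procedure: all
non-overlapping 1 kb genomic bins are scored in RPKM, sorted ascending, rank
and value are rescaled to [0, 1], and the threshold is the value at the first
point where the discrete slope exceeds 1 (the geometric tangent criterion).
A TSS carries a mark when any sliding 1 kb bin (step 100) within +/- 3 kb has
RPKM above the mark's threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .core import CoverageTrack, GenomicInterval, Transcript, overlap_any

PATTERN_LABELS = {
    1: "H3K4me3 + TSS",
    2: "H3K27me3 + TSS",
    3: "H3K9me3",
    4: "H3K27ac non-TSS",
    5: "none",
    0: "other",
}


def annotate_peak_features(
    peaks: list[GenomicInterval],
    transcripts: list[Transcript],
    promoter_radius: int = 3000,
) -> pd.DataFrame:
    """Per-peak boolean flags for each genomic feature (>= 1 bp intersection).

    Features: promoter (TSS +/- radius), TSS, TES, exon, intron, gene body,
    intergenic (= not overlapping any gene body).  A peak may carry several
    flags.
    """
    promoters, tss_pts, tes_pts, exons, introns, bodies = [], [], [], [], [], []
    for t in transcripts:
        promoters.append(
            GenomicInterval(t.chrom, max(0, t.tss - promoter_radius), t.tss + promoter_radius)
        )
        tss_pts.append(GenomicInterval(t.chrom, t.tss, t.tss + 1))
        tes_pts.append(GenomicInterval(t.chrom, t.tes, t.tes + 1))
        bodies.append(GenomicInterval(t.chrom, t.start, t.end))
        for s, e in t.exons:
            exons.append(GenomicInterval(t.chrom, s, e))
        ex_sorted = sorted(t.exons)
        prev = t.start
        for s, e in ex_sorted:
            if s > prev:
                introns.append(GenomicInterval(t.chrom, prev, s))
            prev = max(prev, e)
        if t.exons and prev < t.end:
            introns.append(GenomicInterval(t.chrom, prev, t.end))

    flags = {
        "promoter": overlap_any(peaks, promoters),
        "tss": overlap_any(peaks, tss_pts),
        "tes": overlap_any(peaks, tes_pts),
        "exon": overlap_any(peaks, exons) if exons else np.zeros(len(peaks), bool),
        "intron": overlap_any(peaks, introns) if introns else np.zeros(len(peaks), bool),
        "gene_body": overlap_any(peaks, bodies),
    }
    flags["intergenic"] = ~flags["gene_body"]
    df = pd.DataFrame(flags)
    df.insert(0, "chrom", [p.chrom for p in peaks])
    df.insert(1, "start", [p.start for p in peaks])
    df.insert(2, "end", [p.end for p in peaks])
    return df


def rank_elbow_threshold(bin_values: np.ndarray) -> float:
    """Elbow threshold on sorted bin signal (super-enhancer tangent criterion).

    Values are sorted ascending and both axes rescaled to [0, 1]; the
    threshold is the value where a line of slope 1 is tangent to the curve —
    the point maximizing (rank - value), i.e. the last point before the
    rescaled curve rises faster than the diagonal.  Ties take the highest
    qualifying index, so a perfectly linear ramp returns the final value and
    nothing clears the strict-> presence comparison.
    """
    v = np.sort(np.asarray(bin_values, float))
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if v[0] == v[-1]:
        raise ValueError("all values equal: no elbow")
    x = np.arange(n) / (n - 1)
    y = (v - v[0]) / (v[-1] - v[0])
    gap = x - y
    idx = np.flatnonzero(gap >= gap.max() - 1e-12)[-1]  # ties -> highest index
    return float(v[idx])


def genome_bins(layout, bin_size: int = 1000) -> list[GenomicInterval]:
    """Non-overlapping fixed-size bins tiling the genome (remainders dropped)."""
    out = []
    for chrom in layout.chrom_names:
        L = layout.length(chrom)
        for s in range(0, L - bin_size + 1, bin_size):
            out.append(GenomicInterval(chrom, s, s + bin_size))
    return out


def bin_rpkm(track: CoverageTrack, bins: list[GenomicInterval]) -> np.ndarray:
    """RPKM per bin: overlapping extended-fragment count * 1e9 / (bin_len * total)."""
    out = np.empty(len(bins))
    scale = 1e9 / track.total_mapped
    for i, b in enumerate(bins):
        out[i] = track.count_fragments_overlapping(b.chrom, b.start, b.end) * scale / len(b)
    return out


def mark_presence_threshold(track: CoverageTrack, layout, bin_size: int = 1000) -> float:
    """Genome-wide 1 kb bin RPKM elbow threshold for one mark."""
    bins = genome_bins(layout, bin_size)
    return rank_elbow_threshold(bin_rpkm(track, bins))


def tss_mark_presence(
    transcripts: list[Transcript],
    track: CoverageTrack,
    threshold: float,
    flank: int = 3000,
    bin_size: int = 1000,
    step: int = 100,
) -> np.ndarray:
    """Presence flag per TSS: any sliding 1 kb bin in +/- flank with RPKM above
    the threshold (strict)."""
    out = np.zeros(len(transcripts), dtype=bool)
    scale = 1e9 / track.total_mapped / bin_size
    for i, t in enumerate(transcripts):
        L = track.layout.length(t.chrom)
        lo = max(0, t.tss - flank)
        hi = min(L, t.tss + flank)
        for s in range(lo, hi - bin_size + 1, step):
            rpkm = track.count_fragments_overlapping(t.chrom, s, s + bin_size) * scale
            if rpkm > threshold:
                out[i] = True
                break
    return out


def window_mark_presence(
    windows: list[GenomicInterval],
    track: CoverageTrack,
    threshold: float,
) -> np.ndarray:
    """Presence flag per fixed window: its own RPKM above the threshold."""
    return bin_rpkm(track, windows) > threshold


def pattern_classify(
    mbd3_windows: list[GenomicInterval],
    mark_presence: dict[str, np.ndarray],
    tss_overlap: np.ndarray,
) -> np.ndarray:
    """Histone-mark/location pattern per MBD3-bound 1 kb window.

    Precedence order: 1 = H3K4me3 & TSS (active promoter); 2 = H3K27me3 & TSS
    (inactive promoter); 3 = H3K9me3; 4 = H3K27ac & not TSS (enhancer);
    5 = no queried mark and no TSS; 0 = anything else ("other").
    """
    n = len(mbd3_windows)
    k4 = np.asarray(mark_presence.get("H3K4me3", np.zeros(n, bool)))
    k27me3 = np.asarray(mark_presence.get("H3K27me3", np.zeros(n, bool)))
    k9 = np.asarray(mark_presence.get("H3K9me3", np.zeros(n, bool)))
    k27ac = np.asarray(mark_presence.get("H3K27ac", np.zeros(n, bool)))
    tss = np.asarray(tss_overlap, bool)
    out = np.zeros(n, dtype=int)
    for i in range(n):
        if k4[i] and tss[i]:
            out[i] = 1
        elif k27me3[i] and tss[i]:
            out[i] = 2
        elif k9[i]:
            out[i] = 3
        elif k27ac[i] and not tss[i]:
            out[i] = 4
        elif not (k4[i] or k27me3[i] or k9[i] or k27ac[i] or tss[i]):
            out[i] = 5
        else:
            out[i] = 0
    return out


def pattern_percentages(patterns: np.ndarray) -> pd.Series:
    """Percentage of MBD3 windows per pattern label (sums to 100)."""
    n = patterns.size
    out = {}
    for code, label in PATTERN_LABELS.items():
        out[label] = 100.0 * np.sum(patterns == code) / n if n else 0.0
    return pd.Series(out)


# ---------------------------------------------------------------------------
# CpG-island methylation deciles
# ---------------------------------------------------------------------------


def methylation_fraction(meth_reads: int, total_reads: int) -> float:
    """Methylated reads over total sequenced reads (fraction in [0, 1])."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    f = meth_reads / total_reads
    if not 0 <= f <= 1:
        raise ValueError("methylated reads exceed total")
    return f


METH_BIN_LABELS = (
    "x=0%", "0<x<10%", "10<=x<20%", "20<=x<30%", "30<=x<40%", "40<=x<50%",
    "50<=x<60%", "60<=x<70%", "70<=x<80%", "80<=x<90%", "90<=x<=100%",
)


def methylation_bin_index(fraction: float) -> int:
    """Bin index for one methylation fraction: x=0 separate, then deciles.

    [0.9, 1.0] closes the final bin; boundaries such as exactly 0.10 fall in
    the right-open decile starting there.
    """
    pct = 100.0 * fraction
    if pct == 0:
        return 0
    if pct >= 90:
        return 10
    if pct < 10:
        return 1
    return 1 + int(pct // 10)


def methylation_decile_counts(fractions: np.ndarray) -> np.ndarray:
    idx = np.array([methylation_bin_index(f) for f in np.asarray(fractions, float)])
    return np.bincount(idx, minlength=11)


def decile_table_from_counts(
    assoc_counts: np.ndarray, total_counts: np.ndarray, test: str = "ztest"
) -> pd.DataFrame:
    """Format per-bin counts into the decile table with percentages and p-values.

    ``assoc_counts`` are islands overlapping an MBD3 peak, ``total_counts`` all
    islands (the associated ones included).  Per bin, a two-sided two-sample
    proportion comparison of bin share among associated vs among all islands.
    """
    assoc = np.asarray(assoc_counts, int)
    total = np.asarray(total_counts, int)
    if assoc.shape != (11,) or total.shape != (11,):
        raise ValueError("expected 11 bins")
    n_assoc, n_total = assoc.sum(), total.sum()
    rows = []
    for i, label in enumerate(METH_BIN_LABELS):
        if test == "ztest":
            if assoc[i] + total[i] == 0 or (assoc[i] == n_assoc and total[i] == n_total):
                p = 1.0
            else:
                _, p = proportions_ztest(
                    [assoc[i], total[i]], [n_assoc, n_total], alternative="two-sided"
                )
                if np.isnan(p):
                    p = 1.0
        elif test == "fisher":
            _, p = stats.fisher_exact(
                [[assoc[i], n_assoc - assoc[i]], [total[i], n_total - total[i]]]
            )
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            (
                label,
                int(assoc[i]),
                100.0 * assoc[i] / n_assoc,
                int(total[i]),
                100.0 * total[i] / n_total,
                float(p),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["bin", "mbd3_count", "mbd3_pct", "total_count", "total_pct", "pval"],
    )


def methylation_decile_table(
    islands: list[GenomicInterval],
    fractions: np.ndarray,
    peaks: list[GenomicInterval],
    test: str = "ztest",
) -> pd.DataFrame:
    """Decile table for a set of CpG islands given their methylation fractions.

    Islands are flagged MBD3-associated by >= 1 bp overlap with any peak; the
    comparison column is the *total* island set (associated included).
    """
    if not islands:
        raise ValueError("empty island set")
    assoc_mask = overlap_any(islands, peaks)
    fr = np.asarray(fractions, float)
    assoc_counts = methylation_decile_counts(fr[assoc_mask])
    total_counts = methylation_decile_counts(fr)
    return decile_table_from_counts(assoc_counts, total_counts, test=test)
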