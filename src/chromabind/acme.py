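"""Replicate-spooling ACME peak calling on normalized tiling-array signal.

For every probe, a genomic window of width ``w`` centered on the probe midpoint
collects the normalized values of all probes inside it across the ``r``
replicates (``k`` probes -> ``k*r`` values).  ``x`` of them exceed (strictly)
the pooled ``100*s``-th percentile threshold; enrichment is scored by the
upper-tail hypergeometric probability of drawing ``x`` or more of the ``M``
genome-wide exceedances in ``k*r`` draws from a population of ``N*r`` values.
Peaks are maximal runs of consecutive probes with p below the threshold,
discarded when they span fewer than ``min_probes`` probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GenomicInterval, Transcript
from .damid import ProbeChip


@dataclass
class AcmeParams:
    w: int = 2000
    s: float = 0.95
    p: float = 0.001
    min_probes: int = 6
    empirical_m: bool = True  # M = observed exceedances; else nominal ceil((1-s)N r)

    def __post_init__(self):
        if not 0 < self.s < 1:
            raise ValueError("s must be in (0,1)")
        if self.w <= 0:
            raise ValueError("w must be positive")
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0,1)")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


@dataclass
class WindowStats:
    """Per-probe window summary: probe order index, k probes, x exceedances, p."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    k: np.ndarray
    x: np.ndarray
    pval: np.ndarray


@dataclass
class PopulationSummary:
    N: int
    M: int
    threshold_value: float
    r: int


def percentile_threshold(signals: np.ndarray, s: float) -> float:
    """``100*s``-th percentile of the pooled replicate signal (linear interpolation)."""
    pooled = np.asarray(signals, float).ravel()
    if pooled.size == 0:
        raise ValueError("empty signal vector")
    return float(np.percentile(pooled, 100.0 * s, method="linear"))


def hypergeom_tail(x: int, draws: int, successes: int, population: int) -> float:
    """Upper-tail P(X >= x) for X ~ Hypergeometric(population, successes, draws).

    Inclusive upper tail, computed exactly via log-gamma arithmetic.
    """
    if not (0 <= successes <= population and 0 <= draws <= population and x >= 0):
        raise ValueError("inconsistent hypergeometric arguments")
    if x > min(draws, successes):
        return 0.0
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, population, successes, draws))


def probe_enrichment_pvalues(
    chips: list[ProbeChip], params: AcmeParams | None = None
) -> tuple[WindowStats, PopulationSummary]:
    """Window statistics and hypergeometric p-values for every probe.

    All chips must share the probe set (same ids in the same order) and be
    normalized.  Windows span ``[midpoint - w/2, midpoint + w/2]`` and truncate
    at chromosome ends (k shrinks accordingly).
    """
    params = params or AcmeParams()
    first = chips[0]
    for chip in chips[1:]:
        if not np.array_equal(chip.probe_ids, first.probe_ids):
            raise ValueError("replicate chips do not share a probe set")
    if any(chip.normalized is None for chip in chips):
        raise ValueError("chips must be normalized first")
    r = len(chips)
    signal = np.stack([chip.normalized for chip in chips], axis=1)  # (N, r)
    N = first.n_probes
    threshold = percentile_threshold(signal, params.s)
    exceed = signal > threshold  # strict
    M = int(exceed.sum()) if params.empirical_m else int(np.ceil((1 - params.s) * N * r))

    chrom_arr = np.array([iv.chrom for iv in first.intervals])
    mid = np.array([iv.center for iv in first.intervals])
    start_arr = np.array([iv.start for iv in first.intervals])
    end_arr = np.array([iv.end for iv in first.intervals])
    exceed_per_probe = exceed.sum(axis=1)

    k = np.zeros(N, dtype=int)
    x = np.zeros(N, dtype=int)
    half = params.w / 2.0
    # per chromosome, probes sorted by midpoint; windows via searchsorted
    for chrom in np.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        order = idx[np.argsort(mid[idx], kind="stable")]
        m_sorted = mid[order]
        ex_cum = np.concatenate([[0], np.cumsum(exceed_per_probe[order])])
        lo = np.searchsorted(m_sorted, m_sorted - half, side="left")
        hi = np.searchsorted(m_sorted, m_sorted + half, side="right")
        k[order] = hi - lo
        x[order] = ex_cum[hi] - ex_cum[lo]

    # unique (x, k) pairs -> hypergeometric tail
    pval = np.ones(N)
    pairs = np.stack([x, k], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    pu = np.array(
        [hypergeom_tail(int(xi), int(ki) * r, M, N * r) for xi, ki in uniq]
    )
    pval = pu[inverse]
    stats_out = WindowStats(chrom_arr, start_arr, end_arr, k, x, pval)
    return stats_out, PopulationSummary(N=N, M=M, threshold_value=threshold, r=r)


def call_peaks(
    window_stats: WindowStats, params: AcmeParams | None = None
) -> list[GenomicInterval]:
    """Maximal runs of consecutive significant probes, >= min_probes long.

    A peak spans from the first probe's start to the last probe's end; its
    name carries the probe count and its score -log10 of the minimum p.
    """
    params = params or AcmeParams()
    peaks: list[GenomicInterval] = []
    ws = window_stats
    for chrom in np.unique(ws.chrom):
        idx = np.flatnonzero(ws.chrom == chrom)
        order = idx[np.argsort(ws.start[idx], kind="stable")]
        sig = ws.pval[order] < params.p
        if not sig.any():
            continue
        padded = np.concatenate([[False], sig, [False]])
        run_starts = np.flatnonzero(~padded[:-1] & padded[1:])
        run_ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for a, b in zip(run_starts, run_ends):
            if b - a < params.min_probes:
                continue
            probes = order[a:b]
            min_p = float(ws.pval[probes].min())
            score = 350.0 if min_p == 0 else -np.log10(min_p)
            peaks.append(
                GenomicInterval(
                    str(chrom),
                    int(ws.start[probes[0]]),
                    int(ws.end[probes[-1]]),
                    name=str(b - a),
                    score=round(float(score), 4),
                )
            )
    return peaks


def assign_target_genes(
    peaks: list[GenomicInterval],
    transcripts: list[Transcript],
    radius: int = 3000,
) -> set[str]:
    """Gene ids with a peak overlapping [TSS - radius, TSS + radius)."""
    out: set[str] = set()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for pk in peaks:
        by_chrom.setdefault(pk.chrom, []).append((pk.start, pk.end))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    for t in transcripts:
        pairs = by_chrom.get(t.chrom)
        if not pairs:
            continue
        lo, hi = t.tss - radius, t.tss + radius
        for s, e in pairs:
            if s >= hi:
                break
            if e > lo:
                out.add(t.id)
                break
    return out
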