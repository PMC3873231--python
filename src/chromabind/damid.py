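"""Two-step normalization of two-color DamID tiling/promoter arrays.

Step one (within chip) removes GC-dependent dye bias: probes are binned by GC
content using the zero-stage (normal-scale) bin-width rule, small bins are
merged until every bin holds at least ``min_bin_probes`` probes, and within
each bin a robust lowess fit predicts log(cy5) from log(cy3).  The residuals,
scaled by the bin's median absolute residual, are the normalized signal — the
log-ratio of the methyltransferase fusion channel to the Dam-only control with
dye/GC structure removed and a comparable scale across bins.

Step two (between chips) is ordinary quantile normalization across replicate
chips sharing a probe set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .core import GenomicInterval


@dataclass
class NormalizationParams:
    min_bin_probes: int = 500
    lowess_span: float = 2.0 / 3.0
    lowess_iterations: int = 3
    log_base: float = 2.0

    def __post_init__(self):
        if self.min_bin_probes < 2:
            raise ValueError("min_bin_probes must be >= 2")
        if not 0 < self.lowess_span <= 1:
            raise ValueError("lowess_span must be in (0, 1]")


@dataclass
class ProbeChip:
    """One two-color chip: tiled probes with GC and per-channel log intensities.

    ``log_cy5`` is the fusion (MBD3-Dam) channel, ``log_cy3`` the Dam-only
    control.  ``normalized`` is populated by :func:`lowess_residual_normalize`.
    """

    probe_ids: np.ndarray
    intervals: list[GenomicInterval]
    gc: np.ndarray
    log_cy3: np.ndarray
    log_cy5: np.ndarray
    normalized: np.ndarray | None = field(default=None)

    def __post_init__(self):
        n = len(self.probe_ids)
        for name in ("gc", "log_cy3", "log_cy5"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("gc must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "gc": self.gc,
                "log_cy3": self.log_cy3,
                "log_cy5": self.log_cy5,
            }
        )
        if self.normalized is not None:
            df["normalized"] = self.normalized
        return df


def gc_bin_assign(gc_values: np.ndarray, min_bin_probes: int = 500) -> np.ndarray:
    """Assign a GC bin label to every probe.

    Initial width follows the zero-stage rule ``h = 3.49 sigma n^(-1/3)`` with
    the robust scale ``sigma = min(sd, IQR/1.349)``; contiguous-in-GC bins with
    fewer than ``min_bin_probes`` probes are then merged left-to-right
    (smallest GC first) until every bin satisfies the floor.  Probes with equal
    GC always share a bin.
    """
    gc = np.asarray(gc_values, float)
    n = gc.size
    if n == 0:
        raise ValueError("no probes")
    if n < min_bin_probes:
        warnings.warn("fewer probes than min_bin_probes; using a single bin")
        return np.zeros(n, dtype=int)
    sd = float(np.std(gc, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(gc, [75, 25])
    sigma = min(sd, (q75 - q25) / 1.349) if (q75 > q25) else sd
    if sigma <= 0:
        return np.zeros(n, dtype=int)
    h = 3.49 * sigma * n ** (-1.0 / 3.0)
    lo, hi = gc.min(), gc.max()
    n_bins = max(1, int(np.ceil((hi - lo) / h)))
    edges = lo + h * np.arange(1, n_bins)  # interior edges
    raw = np.digitize(gc, edges)
    # merge left-to-right until every occupied bin holds >= min_bin_probes
    order = np.argsort(gc, kind="stable")
    raw_sorted = raw[order]
    labels_sorted = np.empty(n, dtype=int)
    label = 0
    count = 0
    boundaries = np.flatnonzero(np.diff(raw_sorted)) + 1
    blocks = np.split(np.arange(n), boundaries)
    pos = 0
    for block in blocks:
        labels_sorted[block] = label
        count += block.size
        if count >= min_bin_probes:
            label += 1
            count = 0
        pos += block.size
    if count:  # trailing underfull bin merges into its left neighbor
        labels_sorted[labels_sorted == label] = max(label - 1, 0)
    out = np.empty(n, dtype=int)
    out[order] = labels_sorted
    return out


def zero_stage_width(gc_values: np.ndarray) -> float:
    """The initial (pre-merge) zero-stage bin width for a GC sample."""
    gc = np.asarray(gc_values, float)
    sd = float(np.std(gc, ddof=1))
    q75, q25 = np.percentile(gc, [75, 25])
    sigma = min(sd, (q75 - q25) / 1.349) if q75 > q25 else sd
    return 3.49 * sigma * gc.size ** (-1.0 / 3.0)


def lowess_residual_normalize(
    chip: ProbeChip,
    bins: np.ndarray | None = None,
    params: NormalizationParams | None = None,
) -> np.ndarray:
    """Within-chip normalization: scaled lowess residuals of log(cy5) on log(cy3).

    Within each GC bin the fit is robust lowess; each probe's normalized value
    is its residual divided by the bin's median absolute residual.  A bin whose
    median absolute residual is zero is left unscaled (with a warning).
    Mutates ``chip.normalized`` and returns it.
    """
    params = params or NormalizationParams()
    if bins is None:
        bins = gc_bin_assign(chip.gc, params.min_bin_probes)
    x, y = chip.log_cy3, chip.log_cy5
    normalized = np.empty(chip.n_probes)
    for label in np.unique(bins):
        idx = np.flatnonzero(bins == label)
        xb, yb = x[idx], y[idx]
        if idx.size < 3 or np.ptp(xb) == 0:
            fit = np.full(idx.size, yb.mean())
        else:
            fit = sm_lowess(
                yb, xb,
                frac=params.lowess_span,
                it=params.lowess_iterations,
                return_sorted=False,
            )
        resid = yb - fit
        scale = float(np.median(np.abs(resid)))
        # a numerically perfect fit must not amplify float noise into signal
        if scale <= 1e-9 * max(1.0, float(np.abs(yb).max())):
            scale = 0.0
        if scale == 0:
            warnings.warn(f"GC bin {label}: zero median absolute residual; unscaled")
            normalized[idx] = resid
        else:
            normalized[idx] = resid / scale
    chip.normalized = normalized
    return normalized


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Between-chip quantile normalization of a (probes x chips) matrix.

    After the transform every column's sorted vector equals the rank-wise mean
    of the sorted input columns; ties within a column receive the mean of
    their tied ranks' reference values.
    """
    X = np.asarray(matrix, float)
    if np.isnan(X).any():
        raise ValueError("missing values not supported")
    n, m = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(X, order, axis=0), axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        # average reference values over tied ranks
        sorted_idx = order[:, j]
        sorted_vals = col[sorted_idx]
        ranks_ref = ref.copy()
        # group ties
        uniq, inverse = np.unique(sorted_vals, return_inverse=True)
        tie_means = np.zeros(uniq.size)
        np.add.at(tie_means, inverse, ranks_ref)
        counts = np.bincount(inverse)
        tie_means /= counts
        out[sorted_idx, j] = tie_means[inverse]
    return out
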