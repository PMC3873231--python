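"""Promoter CpG classification (HCP / ICP / LCP).

A promoter is summarized over a 1,001 bp window centered on the TSS.  Within
it, 500 bp subwindows slide at a small step; per subwindow the GC content and
the CpG observed/expected ratio (observed CG dinucleotides over #C*#G/L) are
computed.  High-CpG promoters (HCP) contain some subwindow with ratio > 0.75
and GC > 0.55; low-CpG promoters (LCP) have no subwindow with ratio > 0.48;
everything else is intermediate (ICP).  N bases are excluded from all counts
and a subwindow that is mostly N is skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PromoterClassParams:
    window: int = 1001
    subwindow: int = 500
    # step 1 keeps the subwindow grid mirror-symmetric, so classification is
    # exactly reverse-complement invariant; coarser steps (e.g. 5) are faster
    step: int = 1
    hcp_ratio: float = 0.75
    hcp_gc: float = 0.55
    lcp_ratio: float = 0.48
    max_n_fraction: float = 0.5  # subwindows with more N than this are skipped

    def __post_init__(self):
        if self.subwindow > self.window:
            raise ValueError("subwindow must not exceed window")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass
class CpGStats:
    gc_content: float
    cpg_observed: int
    cpg_expected: float
    ratio: float
    n_called: int


def cpg_stats(sequence: str) -> CpGStats:
    """GC content and observed/expected CpG ratio of a sequence.

    ``expected = (#C * #G) / L`` with L the number of called (non-N) bases;
    the ratio is defined as 0 when the expected count is 0.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    called = sum(seq.count(b) for b in "ACGT")
    observed = seq.count("CG")
    if called == 0:
        return CpGStats(0.0, 0, 0.0, 0.0, 0)
    expected = n_c * n_g / called
    ratio = observed / expected if expected > 0 else 0.0
    return CpGStats((n_c + n_g) / called, observed, expected, ratio, called)


def classify_promoter(sequence: str, params: PromoterClassParams | None = None) -> str:
    """Classify a TSS-centered promoter sequence as 'HCP', 'ICP' or 'LCP'."""
    params = params or PromoterClassParams()
    seq = sequence.upper()
    if len(seq) < params.window:
        # chromosome-edge promoters arrive padded; pad here for robustness
        seq = seq + "N" * (params.window - len(seq))
    if all(b == "N" for b in seq):
        raise ValueError("all-N sequence: classification undefined")
    w, sw, step = params.window, params.subwindow, params.step
    any_hcp = False
    any_above_lcp = False
    evaluated = 0
    for off in range(0, w - sw + 1, step):
        sub = seq[off: off + sw]
        n_frac = sub.count("N") / sw
        if n_frac > params.max_n_fraction:
            continue
        st = cpg_stats(sub)
        evaluated += 1
        if st.ratio > params.hcp_ratio and st.gc_content > params.hcp_gc:
            any_hcp = True
        if st.ratio > params.lcp_ratio:
            any_above_lcp = True
    if evaluated == 0:
        raise ValueError("no evaluable subwindow (too many N bases)")
    if any_hcp:
        return "HCP"
    if not any_above_lcp:
        return "LCP"
    return "ICP"


def classify_promoters(
    sequences: dict[str, str], params: PromoterClassParams | None = None
) -> "pd.DataFrame":
    """Classify a set of promoter sequences; returns per-id class and subwindow maxima."""
    import pandas as pd

    params = params or PromoterClassParams()
    rows = []
    for name, seq in sequences.items():
        cls = classify_promoter(seq, params)
        # summary stats over subwindows for reporting
        best_ratio, best_gc = 0.0, 0.0
        s = seq.upper()
        if len(s) < params.window:
            s = s + "N" * (params.window - len(s))
        for off in range(0, params.window - params.subwindow + 1, params.step):
            sub = s[off: off + params.subwindow]
            if sub.count("N") / params.subwindow > params.max_n_fraction:
                continue
            st = cpg_stats(sub)
            best_ratio = max(best_ratio, st.ratio)
            best_gc = max(best_gc, st.gc_content)
        rows.append((name, cls, best_ratio, best_gc))
    return pd.DataFrame(rows, columns=["id", "class", "max_ratio", "max_gc"])
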