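#!/usr/bin/env python
"""Two-step DamID array normalization and what it removes.

Simulates the two-color replicate chips (GC-dependent dye bias on the fusion
channel, planted enrichment, noise), runs the within-chip GC-binned lowess
residual normalization and between-chip quantile normalization, and reports
the Spearman correlation of signal with probe GC before and after — the
whole point of step one is to drive that correlation to zero.
"""

import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
import numpy as np
import pandas as pd
from _common import cohort, damid_pipeline, results_dir
from scipy import stats

from chromabind.damid import gc_bin_assign


def main(seed: int = 1) -> None:
    params, ann, truth = cohort(seed)
    chips, _, _, _ = damid_pipeline(params, ann, truth)
    chip = chips[0]
    raw = chip.log_cy5 - chip.log_cy3
    rho_raw = stats.spearmanr(raw, chip.gc).statistic
    rho_norm = stats.spearmanr(chip.normalized, chip.gc).statistic

    bins = gc_bin_assign(chip.gc)
    rows = []
    for b in np.unique(bins):
        m = bins == b
        rows.append(
            (int(b), int(m.sum()), float(chip.gc[m].min()), float(chip.gc[m].max()),
             float(raw[m].mean()), float(chip.normalized[m].mean()))
        )
    df = pd.DataFrame(
        rows, columns=["bin", "n_probes", "gc_min", "gc_max", "raw_ratio_mean",
                       "normalized_mean"]
    )
    out = results_dir()
    df.to_csv(out / "damid_gc_bins.tsv", sep="\t", index=False)

    # between-chip step: sorted columns now coincide
    sorted_gap = float(
        np.max(np.abs(np.sort(chips[0].normalized) - np.sort(chips[1].normalized)))
    )
    print(f"probes: {chip.n_probes}, GC bins: {len(df)} (>=500 probes each)")
    print(f"Spearman(signal, GC): raw {rho_raw:+.3f} -> normalized {rho_norm:+.3f}")
    print(f"max gap between sorted replicate columns after quantile step: {sorted_gap:.2e}")
    print(f"per-bin summary -> {out / 'damid_gc_bins.tsv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
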