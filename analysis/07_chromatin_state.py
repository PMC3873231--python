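#!/usr/bin/env python
"""Chromatin context of MBD3-bound regions: mark co-occurrence at TSSs,
1 kb pattern classes, and the CpG-island methylation decile table.

Per mark, a presence threshold comes from the rank/elbow (tangent) procedure
over genome-wide 1 kb bin RPKM; a TSS carries a mark when any sliding 1 kb
bin within +/- 3 kb clears it.  MBD3-present 1 kb bins are then classified
into the five modification/location patterns, and CpG islands are binned by
methylation fraction split by MBD3-peak overlap.
"""

import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
import pandas as pd
from _common import cohort, damid_pipeline, deduped, results_dir

from chromabind.chromstate import (
    PATTERN_LABELS,
    genome_bins,
    mark_presence_threshold,
    methylation_decile_table,
    pattern_classify,
    pattern_percentages,
    tss_mark_presence,
    window_mark_presence,
)
from chromabind.core import GenomicInterval, overlap_any
from chromabind.synth import simulate_chip_tracks, simulate_methylation


def main(seed: int = 1) -> None:
    params, ann, truth = cohort(seed)
    _, _, _, peaks = damid_pipeline(params, ann, truth)
    transcripts = deduped(ann)
    tracks = simulate_chip_tracks(ann, truth, params)
    out = results_dir()

    marks = ["MBD3", "H3K4me3", "H3K27me3", "H3K9me3", "H3K27ac"]
    thr = {m: mark_presence_threshold(tracks[m], ann.layout) for m in marks}
    print("elbow RPKM thresholds:", {m: round(v, 2) for m, v in thr.items()})

    pres = {
        m: tss_mark_presence(transcripts, tracks[m], thr[m]) for m in marks
    }
    tss_df = pd.DataFrame({"id": [t.id for t in transcripts], **pres})
    tss_df.to_csv(out / "tss_mark_presence.tsv", sep="\t", index=False)
    mbd3 = tss_df["MBD3"]
    if mbd3.any():
        for m in marks[1:]:
            co = (tss_df[m] & mbd3).sum() / mbd3.sum()
            print(f"  {m} at MBD3-positive TSSs: {co:.1%}")

    bins = genome_bins(ann.layout, 1000)
    mbd3_bins = [
        b for b, f in zip(bins, window_mark_presence(bins, tracks["MBD3"], thr["MBD3"]))
        if f
    ]
    presence = {
        m: window_mark_presence(mbd3_bins, tracks[m], thr[m]) for m in marks[1:]
    }
    tssw = [GenomicInterval(t.chrom, t.tss - 3000, t.tss + 3000) for t in transcripts]
    pats = pattern_classify(mbd3_bins, presence, overlap_any(mbd3_bins, tssw))
    pct = pattern_percentages(pats)
    print(f"\npattern classes over {len(mbd3_bins)} MBD3-present 1 kb bins:")
    print(pct.round(1).to_string())
    pct.rename(PATTERN_LABELS).to_csv(out / "pattern_percentages.tsv", sep="\t")

    bound = overlap_any(ann.cpg_islands, peaks)
    fr, _, _ = simulate_methylation(ann.cpg_islands, bound, params)
    table = methylation_decile_table(ann.cpg_islands, fr, peaks)
    table.to_csv(out / "methylation_decile_table.tsv", sep="\t", index=False)
    print("\nCpG-island methylation deciles (MBD3-associated vs all):")
    print(table.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
    print(f"\ntables -> {out}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
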