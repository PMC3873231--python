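#!/usr/bin/env python
"""Chromosome-bound circular-permutation overlap test and gene-set enrichment.

Maps called peaks and planted domains onto disjoined probe units, rotates one
membership vector within each chromosome 20,000 times, and reports the odds
ratio of observed to expected overlap with an empirical p and percentile CI.
Then tests the called target genes for enrichment of the planted luminal-like
signature (Fisher exact + Benjamini-Hochberg).
"""

import json
import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
import numpy as np
from _common import cohort, damid_pipeline, deduped, results_dir

from chromabind import acme
from chromabind.core import disjoin, overlap_any
from chromabind.overlap import (
    OverlapTestParams,
    gene_set_enrichment,
    permutation_overlap_test,
)


def main(seed: int = 1) -> None:
    params, ann, truth = cohort(seed)
    chips, _, _, peaks = damid_pipeline(params, ann, truth)
    transcripts = deduped(ann)

    units = disjoin(chips[0].intervals)
    by_chrom = {}
    for u in units:
        by_chrom.setdefault(u.chrom, []).append(u)
    mem_a, mem_b = {}, {}
    for chrom, us in by_chrom.items():
        us.sort(key=lambda u: u.start)
        mem_a[chrom] = np.asarray(overlap_any(us, peaks), bool)
        mem_b[chrom] = np.asarray(overlap_any(us, truth.enriched_regions), bool)
    res = permutation_overlap_test(
        mem_a, mem_b, OverlapTestParams(n_perm=20_000, seed=seed)
    )
    print(f"disjoined units: {sum(v.size for v in mem_a.values())}")
    print(f"overlap observed {res.observed} vs expected {res.expected:.1f} "
          f"-> odds ratio {res.odds_ratio:.2f}, p = {res.pval:.2e}, "
          f"95% CI ({res.ci[0]:.2f}, {res.ci[1]:.2f})")

    targets = acme.assign_target_genes(peaks, transcripts)
    universe = {t.id for t in transcripts}
    gene_sets = {
        "luminal_like": set(truth.luminal_like_geneset),
        "first40_alphabetical": set(sorted(universe)[:40]),
    }
    enr = gene_set_enrichment(targets, universe, gene_sets)
    print(enr.to_string(index=False))

    out = results_dir()
    enr.to_csv(out / "geneset_enrichment.tsv", sep="\t", index=False)
    (out / "overlap_test.json").write_text(
        json.dumps(
            {
                "observed": res.observed,
                "expected": res.expected,
                "odds_ratio": res.odds_ratio,
                "pval": res.pval,
                "ci": list(res.ci),
                "n_perm": 20_000,
            },
            indent=2,
        )
        + "\n"
    )
    print(f"tables -> {out / 'overlap_test.json'}, {out / 'geneset_enrichment.tsv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
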