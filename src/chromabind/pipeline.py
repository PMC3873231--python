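"""End-to-end demonstration pipeline on synthetic data.

Wires every stage together: simulate -> normalize -> call peaks -> assign
targets -> permutation overlap vs the planted regions -> gene-set enrichment
-> promoter classes -> TSS/gene-body profiles -> chromatin-state patterns and
the methylation decile table -> ChIA-PET ranking -> MNase quartile metagenes.
Emits a JSON-serializable report of every statistic plus truth-recovery
metrics.  Every stage is also individually invokable with identical results —
the pipeline holds no hidden state beyond the seeded generators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from . import acme, chiapet, chromstate, mnase, overlap, profiles, promoters, synth
from .core import GenomicInterval, dedup_transcripts, disjoin, overlap_any
from .damid import NormalizationParams, lowess_residual_normalize, quantile_normalize
from .synth import SimParams


@dataclass
class PipelineConfig:
    sim: SimParams = field(default_factory=SimParams)
    norm: NormalizationParams = field(default_factory=NormalizationParams)
    acme: acme.AcmeParams = field(default_factory=acme.AcmeParams)
    overlap: overlap.OverlapTestParams = field(
        default_factory=lambda: overlap.OverlapTestParams(n_perm=2000)
    )
    mnase: mnase.MnaseParams = field(default_factory=mnase.MnaseParams)
    run_chip_stages: bool = True
    run_mnase: bool = True


def region_recovery(
    peaks: list[GenomicInterval],
    truth_regions: list[GenomicInterval],
    w: int,
) -> dict:
    """Planted-region recovery: per-region best Jaccard, and stray peaks.

    A peak is *stray* when it lies entirely outside every truth region's
    +/- w neighborhood.
    """
    jaccards = []
    for region in truth_regions:
        best = 0.0
        for pk in peaks:
            inter = region.overlap_bp(pk)
            if inter == 0:
                continue
            union = len(region) + len(pk) - inter
            best = max(best, inter / union)
        jaccards.append(best)
    halo = [
        GenomicInterval(r.chrom, max(0, r.start - w), r.end + w) for r in truth_regions
    ]
    stray = int((~overlap_any(peaks, halo)).sum()) if peaks else 0
    jaccards = np.array(jaccards) if jaccards else np.zeros(0)
    return {
        "n_truth_regions": len(truth_regions),
        "n_peaks": len(peaks),
        "frac_recovered_j50": float((jaccards >= 0.5).mean()) if jaccards.size else 0.0,
        "median_jaccard": float(np.median(jaccards)) if jaccards.size else 0.0,
        "stray_peaks": stray,
    }


def run_damid_stage(config: PipelineConfig, ann=None, truth=None) -> dict:
    """Simulate DamID chips, normalize, call peaks, score truth recovery."""
    if ann is None:
        ann, truth = synth.make_genome_annotation(config.sim)
    chips = synth.simulate_damid_arrays(ann, truth, config.sim)
    gc = chips[0].gc
    raw_ratio = chips[0].log_cy5 - chips[0].log_cy3
    rho_raw = float(sp_stats.spearmanr(raw_ratio, gc).statistic)
    for chip in chips:
        lowess_residual_normalize(chip, params=config.norm)
    # between-chip quantile normalization across the replicate chips
    mat = np.stack([c.normalized for c in chips], axis=1)
    mat = quantile_normalize(mat)
    for j, chip in enumerate(chips):
        chip.normalized = mat[:, j]
    rho_norm = float(sp_stats.spearmanr(chips[0].normalized, gc).statistic)

    window_stats, pop = acme.probe_enrichment_pvalues(chips, config.acme)
    peaks = acme.call_peaks(window_stats, config.acme)
    transcripts = dedup_transcripts(ann.transcripts)
    targets = acme.assign_target_genes(peaks, transcripts)
    recovery = region_recovery(peaks, truth.enriched_regions, config.acme.w)
    sig_frac = float((window_stats.pval < config.acme.p).mean())
    return {
        "ann": ann,
        "truth": truth,
        "chips": chips,
        "window_stats": window_stats,
        "population": pop,
        "peaks": peaks,
        "targets": targets,
        "report": {
            "n_probes": pop.N,
            "n_exceedances_M": pop.M,
            "threshold_value": pop.threshold_value,
            "significant_probe_fraction": sig_frac,
            "spearman_gc_raw": rho_raw,
            "spearman_gc_normalized": rho_norm,
            "n_peaks": len(peaks),
            "n_target_genes": len(targets),
            **recovery,
        },
    }


def run_demo(config: PipelineConfig | None = None) -> dict:
    """Full pipeline on one synthetic dataset; returns the JSON-able report."""
    config = config or PipelineConfig()
    report: dict = {"seed": config.sim.seed}

    damid = run_damid_stage(config)
    ann, truth = damid["ann"], damid["truth"]
    peaks = damid["peaks"]
    transcripts = dedup_transcripts(ann.transcripts)
    report["damid"] = damid["report"]

    # permutation overlap of called peaks vs planted truth regions over
    # disjoined probe units
    units = disjoin(damid["chips"][0].intervals)
    units_by_chrom: dict[str, list[GenomicInterval]] = {}
    for u in units:
        units_by_chrom.setdefault(u.chrom, []).append(u)
    mem_a, mem_b = {}, {}
    for chrom, us in units_by_chrom.items():
        us.sort(key=lambda u: u.start)
        mem_a[chrom] = np.asarray(overlap_any(us, peaks), bool)
        mem_b[chrom] = np.asarray(overlap_any(us, truth.enriched_regions), bool)
    res = overlap.permutation_overlap_test(mem_a, mem_b, config.overlap)
    report["overlap_vs_truth"] = {
        "observed": res.observed,
        "expected": res.expected,
        "odds_ratio": res.odds_ratio,
        "pval": res.pval,
        "ci": list(res.ci),
    }

    # gene-set enrichment of the planted luminal-like signature
    universe = {t.id for t in transcripts}
    gene_sets = {
        "luminal_like": set(truth.luminal_like_geneset),
        "random_set": set(sorted(universe)[:40]),
    }
    enr = overlap.gene_set_enrichment(damid["targets"], universe, gene_sets)
    row = enr.set_index("set").loc["luminal_like"]
    report["gene_set_enrichment"] = {
        "luminal_like_odds_ratio": float(row["odds_ratio"]),
        "luminal_like_qval": float(row["qval"]),
    }

    # promoter classes
    cls = promoters.classify_promoters(ann.promoter_sequences)
    report["promoter_classes"] = cls["class"].value_counts().to_dict()

    if config.run_chip_stages:
        tracks = synth.simulate_chip_tracks(ann, truth, config.sim)
        prof = profiles.tss_profile(
            tracks["MBD3"], transcripts, profiles.ProfileSpec(flank=3000, window=70)
        )
        mid = len(prof) // 2
        report["tss_profile"] = {
            "tss_bin_value": float(prof["mean"].iloc[mid]),
            "max_bin_offset": float(prof["offset"].iloc[int(prof["mean"].idxmax())]),
        }

        # chromatin-state patterns over MBD3-present 1 kb bins
        layout = ann.layout
        bins = chromstate.genome_bins(layout, 1000)
        marks = ["H3K4me3", "H3K27me3", "H3K9me3", "H3K27ac"]
        thresholds = {
            m: chromstate.mark_presence_threshold(tracks[m], layout) for m in marks
        }
        thresholds["MBD3"] = chromstate.mark_presence_threshold(tracks["MBD3"], layout)
        mbd3_present = chromstate.window_mark_presence(
            bins, tracks["MBD3"], thresholds["MBD3"]
        )
        mbd3_bins = [b for b, f in zip(bins, mbd3_present) if f]
        presence = {
            m: chromstate.window_mark_presence(mbd3_bins, tracks[m], thresholds[m])
            for m in marks
        }
        tss_windows = [
            GenomicInterval(t.chrom, max(0, t.tss - 3000), t.tss + 3000)
            for t in transcripts
        ]
        tss_flag = overlap_any(mbd3_bins, tss_windows)
        patterns = chromstate.pattern_classify(mbd3_bins, presence, tss_flag)
        report["patterns_pct"] = chromstate.pattern_percentages(patterns).to_dict()

        # methylation decile table on CpG islands vs called peaks
        bound = overlap_any(ann.cpg_islands, peaks)
        fr, _, _ = synth.simulate_methylation(ann.cpg_islands, bound, config.sim)
        table = chromstate.methylation_decile_table(ann.cpg_islands, fr, peaks)
        report["methylation_table"] = {
            "pct_assoc_low_bin": float(table["mbd3_pct"].iloc[1]),
            "pct_assoc_high_bin": float(table["mbd3_pct"].iloc[10]),
            "low_bin_pval": float(table["pval"].iloc[1]),
        }

        # ChIA-PET ranking
        pets = synth.simulate_pets(ann, truth, config.sim)
        pairs = [
            chiapet.PETPair(
                GenomicInterval(p.chrom1, p.start1, p.end1),
                GenomicInterval(p.chrom2, p.start2, p.end2),
            )
            for p in pets
        ]
        kept = chiapet.filter_anchor_pets(pairs, transcripts)
        scored = chiapet.pet_end_scores(kept, tracks["MBD3"], transcripts)
        ranked = chiapet.rank_group_ends(scored)
        if len(ranked) >= 3:
            rho = sp_stats.spearmanr(ranked["end1_score"], ranked["end2_score"]).statistic
        else:
            rho = float("nan")
        report["chiapet"] = {
            "n_pairs": len(pairs),
            "n_retained": len(kept),
            "end_score_spearman": float(rho),
        }

        if config.run_mnase:
            control = synth.simulate_mnase(ann, truth, config.sim, depleted=False)
            depleted = synth.simulate_mnase(ann, truth, config.sim, depleted=True)
            mids_c, frac_c = mnase.size_filter_midpoints(control, config.mnase)
            mids_d, frac_d = mnase.size_filter_midpoints(depleted, config.mnase)
            down = mnase.downsample(
                {"control": mids_c, "depleted": mids_d}, seed=config.sim.seed
            )
            meta = mnase.quartile_metagene(
                down, transcripts, tracks["MBD3"], config.mnase
            )
            report["mnase"] = {
                "retained_fraction_control": frac_c,
                "retained_fraction_depleted": frac_d,
                "n_profiles": int(meta.groupby(["condition", "quartile"]).ngroups),
            }
            report["_mnase_meta"] = meta

    return report


def report_to_json(report: dict) -> str:
    """Serialize the demo report (dropping non-JSON intermediate objects)."""
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(clean, indent=2, sort_keys=True, default=str)
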