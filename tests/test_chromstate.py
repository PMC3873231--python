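"""Feature annotation, presence thresholds, pattern classes, methylation table."""

import numpy as np
import pytest

from chromabind.chromstate import (
    METH_BIN_LABELS,
    decile_table_from_counts,
    annotate_peak_features,
    mark_presence_threshold,
    methylation_bin_index,
    methylation_decile_counts,
    methylation_decile_table,
    methylation_fraction,
    pattern_classify,
    pattern_percentages,
    rank_elbow_threshold,
    tss_mark_presence,
    window_mark_presence,
)
from chromabind.core import CoverageTrack, GenomeLayout, GenomicInterval, Transcript

LAYOUT = GenomeLayout(("chr1",), {"chr1": 100_000})


class TestAnnotateFeatures:
    T = [Transcript("a", "chr1", "+", 20_000, 40_000, ((20_000, 22_000), (30_000, 40_000)))]

    def test_tss_spanning_peak_multi_flag(self):
        df = annotate_peak_features([GenomicInterval("chr1", 19_900, 20_100)], self.T)
        row = df.iloc[0]
        assert row.promoter and row.tss and row.gene_body and row.exon
        assert not row.intergenic

    def test_intergenic_only(self):
        df = annotate_peak_features([GenomicInterval("chr1", 60_000, 61_000)], self.T)
        row = df.iloc[0]
        assert row.intergenic
        assert not (row.promoter or row.tss or row.tes or row.exon or row.gene_body)

    def test_exon_intron_straddle(self):
        df = annotate_peak_features([GenomicInterval("chr1", 21_900, 22_100)], self.T)
        row = df.iloc[0]
        assert row.exon and row.intron


class TestElbowThreshold:
    def test_step_fixture(self):
        thr = rank_elbow_threshold(np.array([1.0, 1, 1, 1, 10]))
        assert thr == 1.0  # only the 10-bin clears the strict comparison

    def test_linear_ramp_final_point(self):
        v = np.linspace(0, 1, 50)
        assert rank_elbow_threshold(v) == pytest.approx(v[-1])

    def test_two_clusters_separated(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0.1, 0.02, 970), rng.normal(100, 5, 30)])
        thr = rank_elbow_threshold(v)
        # threshold sits at the top of the low cluster: separates exactly
        assert 0.1 < thr < 1.0
        assert (v > thr).sum() == 30

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            rank_elbow_threshold(np.full(10, 2.0))
        with pytest.raises(ValueError):
            rank_elbow_threshold(np.array([1.0, 2.0]))


def frag_track(starts):
    return CoverageTrack.from_fragments(LAYOUT, {"chr1": np.asarray(starts)}, 300)


class TestTssPresence:
    T = [Transcript("a", "chr1", "+", 50_000, 60_000)]

    def test_zero_coverage_absent(self):
        track = frag_track([10])
        assert not tss_mark_presence(self.T, track, threshold=1.0)[0]

    def test_any_bin_semantics(self):
        # a clump of fragments at TSS+2900: a sliding bin still catches it
        track = frag_track([52_900] * 50)
        pres = tss_mark_presence(self.T, track, threshold=1.0)
        assert pres[0]

    def test_outside_flank_absent(self):
        track = frag_track([58_000] * 50)  # 8 kb downstream
        assert not tss_mark_presence(self.T, track, threshold=1.0)[0]

    def test_monotone_in_coverage(self):
        thr = 100.0
        sparse = frag_track([50_100] * 3)
        dense = frag_track([50_100] * 30)
        p_sparse = tss_mark_presence(self.T, sparse, thr)[0]
        p_dense = tss_mark_presence(self.T, dense, thr)[0]
        assert (not p_sparse) or p_dense


class TestPatternClassify:
    def run(self, k4=False, k27me3=False, k9=False, k27ac=False, tss=False):
        wins = [GenomicInterval("chr1", 0, 1000)]
        pres = {
            "H3K4me3": np.array([k4]),
            "H3K27me3": np.array([k27me3]),
            "H3K9me3": np.array([k9]),
            "H3K27ac": np.array([k27ac]),
        }
        return pattern_classify(wins, pres, np.array([tss]))[0]

    def test_precedence_truth_table(self):
        assert self.run(k4=True, tss=True) == 1
        assert self.run(k27me3=True, tss=True) == 2
        assert self.run(k9=True) == 3
        assert self.run(k27ac=True) == 4
        assert self.run() == 5
        # K27ac + TSS without K4me3 falls through to "other"
        assert self.run(k27ac=True, tss=True) == 0
        # precedence: K4me3+TSS wins over K9me3
        assert self.run(k4=True, tss=True, k9=True) == 1

    def test_percentages_sum_to_100(self):
        pats = np.array([1, 1, 4, 5, 0, 3, 2, 4])
        ps = pattern_percentages(pats)
        assert ps.sum() == pytest.approx(100.0)


class TestMethylation:
    def test_fraction(self):
        assert methylation_fraction(0, 10) == 0.0
        assert methylation_fraction(10, 10) == 1.0
        assert methylation_fraction(57, 100) == 0.57
        with pytest.raises(ValueError):
            methylation_fraction(1, 0)

    def test_bin_edges(self):
        assert methylation_bin_index(0.0) == 0
        assert methylation_bin_index(0.05) == 1
        assert methylation_bin_index(0.10) == 2  # boundary: right-open deciles
        assert methylation_bin_index(0.50) == 6
        assert methylation_bin_index(0.95) == 10
        assert methylation_bin_index(1.0) == 10

    def test_decile_counts(self):
        counts = methylation_decile_counts(np.array([0.0, 0.05, 0.5, 0.95]))
        assert counts[[0, 1, 6, 10]].tolist() == [1, 1, 1, 1]
        assert counts.sum() == 4

    def test_table_counts_consistency(self, annotation, called_peaks):
        from chromabind.core import overlap_any
        from chromabind.synth import SimParams, simulate_methylation

        ann, _ = annotation
        _, _, peaks = called_peaks
        bound = overlap_any(ann.cpg_islands, peaks)
        fr, _, _ = simulate_methylation(ann.cpg_islands, bound, SimParams(seed=1))
        table = methylation_decile_table(ann.cpg_islands, fr, peaks)
        assert table["total_count"].sum() == len(ann.cpg_islands)
        assert (table["mbd3_count"] <= table["total_count"]).all()
        assert table["mbd3_pct"].sum() == pytest.approx(100.0)
        assert list(table["bin"]) == list(METH_BIN_LABELS)

    def test_empty_islands_rejected(self):
        with pytest.raises(ValueError):
            methylation_decile_table([], np.array([]), [])


class TestPlantedPatternRecovery:
    def test_enhancers_pattern4_promoters_pattern1(self, annotation, chip_tracks, transcripts):
        from chromabind.core import overlap_any

        ann, truth = annotation
        marks = ["H3K4me3", "H3K27me3", "H3K9me3", "H3K27ac"]
        thr = {m: mark_presence_threshold(chip_tracks[m], ann.layout) for m in marks}
        tssw = [
            GenomicInterval(t.chrom, t.tss - 3000, t.tss + 3000) for t in transcripts
        ]
        by_id = {t.id: t for t in ann.transcripts}
        enh_wins = [
            GenomicInterval(e.chrom, e.center - 500, e.center + 500)
            for e, _ in truth.enhancer_links
        ]
        prom_wins = [
            GenomicInterval(by_id[g].chrom, by_id[g].tss - 500, by_id[g].tss + 500)
            for g in sorted(truth.mbd3_target_genes)
        ]
        for wins, want in [(enh_wins, 4), (prom_wins, 1)]:
            pres = {
                m: window_mark_presence(wins, chip_tracks[m], thr[m]) for m in marks
            }
            pats = pattern_classify(wins, pres, overlap_any(wins, tssw))
            assert (pats == want).mean() >= 0.9
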