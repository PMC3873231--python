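"""Metagene profiles, promoter heatmap matrices and gene filter chains."""

import numpy as np
import pytest

from chromabind.core import CoverageTrack, GenomeLayout, GenomicInterval, Transcript
from chromabind.profiles import (
    ProfileSpec,
    damid_heatmap_gene_filter,
    genebody_profile,
    mad_row_filter,
    peak_center_profile,
    promoter_matrix,
    tss_profile,
)

LAYOUT = GenomeLayout(("chr1",), {"chr1": 100_000})


def uniform_track(value=1.0, total=100):
    return CoverageTrack.from_depth(
        LAYOUT, {"chr1": np.full(100_000, float(value))}, total
    )


def point_track(pos, width=70, value=1.0):
    d = np.zeros(100_000)
    d[pos: pos + width] = value
    return CoverageTrack.from_depth(LAYOUT, {"chr1": d}, 100)


class TestTssProfile:
    def test_uniform_coverage_flat(self):
        t = Transcript("a", "chr1", "+", 50_000, 60_000)
        prof = tss_profile(uniform_track(3.0), [t], ProfileSpec(flank=3000, window=70))
        np.testing.assert_allclose(prof["mean"], 3.0)

    def test_single_window_index(self):
        # coverage only at TSS+100 of a + strand gene
        t = Transcript("a", "chr1", "+", 50_000, 60_000)
        spec = ProfileSpec(flank=3000, window=70)
        prof = tss_profile(point_track(50_100, width=70), [t], spec)
        n_win = (2 * 3000) // 70
        expect = int((n_win * 70 // 2 + 100) / 70)
        nz = np.flatnonzero(prof["mean"].to_numpy() > 0)
        assert expect in nz and len(nz) <= 2

    def test_minus_strand_mirrors(self):
        plus = Transcript("a", "chr1", "+", 50_000, 60_000)
        minus = Transcript("b", "chr1", "-", 50_000, 40_000)
        spec = ProfileSpec(flank=3000, window=70)
        track = point_track(50_100, width=70)
        p_plus = tss_profile(track, [plus], spec)["mean"].to_numpy()
        p_minus = tss_profile(track, [minus], spec)["mean"].to_numpy()
        np.testing.assert_allclose(p_minus, p_plus[::-1])

    def test_profile_linear_in_track(self):
        t = Transcript("a", "chr1", "+", 50_000, 60_000)
        spec = ProfileSpec(flank=2100, window=70)
        t1, t2 = point_track(49_000, 300), point_track(51_000, 150, 2.0)
        p1 = tss_profile(t1, [t], spec)["mean"]
        p2 = tss_profile(t2, [t], spec)["mean"]
        p12 = tss_profile(t1 + t2, [t], spec)["mean"]
        np.testing.assert_allclose(p12, p1 + p2)


class TestGenebodyProfile:
    def test_short_genes_excluded(self):
        t = Transcript("a", "chr1", "+", 10_000, 12_000)  # length exactly 2000
        with pytest.raises(ValueError):
            genebody_profile(uniform_track(), [t])

    def test_uniform_flat_body(self):
        t = Transcript("a", "chr1", "+", 10_000, 20_000)
        prof = genebody_profile(uniform_track(2.0), [t], ProfileSpec(flank=700, window=70))
        body = prof[prof["bin"].str.startswith("body")]["mean"]
        np.testing.assert_allclose(body, 2.0)

    def test_decaying_coverage_monotone(self):
        d = np.zeros(100_000)
        d[10_000:20_000] = np.linspace(10, 0, 10_000)
        track = CoverageTrack.from_depth(LAYOUT, {"chr1": d}, 100)
        genes = [Transcript("a", "chr1", "+", 10_000, 20_000)]
        prof = genebody_profile(track, genes, ProfileSpec(flank=700, window=70))
        body = prof[prof["bin"].str.startswith("body")]["mean"].to_numpy()
        assert (np.diff(body) < 0).all()

    def test_minus_strand_decay_still_5prime_to_3prime(self):
        d = np.zeros(100_000)
        d[10_000:20_000] = np.linspace(0, 10, 10_000)  # rises left to right
        track = CoverageTrack.from_depth(LAYOUT, {"chr1": d}, 100)
        genes = [Transcript("a", "chr1", "-", 20_000, 10_000)]
        prof = genebody_profile(track, genes, ProfileSpec(flank=700, window=70))
        body = prof[prof["bin"].str.startswith("body")]["mean"].to_numpy()
        assert (np.diff(body) < 0).all()  # decays 5' -> 3'


class TestPromoterMatrix:
    def test_bins_and_ranking(self):
        g1 = Transcript("low", "chr1", "+", 30_000, 40_000)
        g2 = Transcript("high", "chr1", "+", 60_000, 70_000)
        d = np.zeros(100_000)
        d[59_000:61_000] = 5.0
        d[29_000:31_000] = 1.0
        rank_track = CoverageTrack.from_depth(LAYOUT, {"chr1": d}, 100)
        pass_track = uniform_track(7.0)
        M, passengers = promoter_matrix(rank_track, {"u": pass_track}, [g1, g2])
        assert M.shape == (2, 20)  # 10 kb / 20 bins = 500 bp bins
        assert list(M.index) == ["high", "low"]
        assert list(passengers["u"].index) == ["high", "low"]
        np.testing.assert_allclose(passengers["u"].to_numpy(), 7.0)


class TestHeatmapGeneFilter:
    def make_transcripts(self):
        return [
            Transcript("iso", "chr1", "+", 30_000, 40_000),
            Transcript("pair1", "chr1", "+", 60_000, 70_000),
            Transcript("pair2", "chr1", "+", 61_000, 71_000),  # 1 kb neighbor
            Transcript("noexpr", "chr1", "+", 90_000, 95_000),
        ]

    def probes_covering(self, transcripts):
        probes = []
        for t in transcripts:
            for s in range(t.tss - 7000, t.tss + 3000, 200):
                probes.append(GenomicInterval("chr1", s, s + 50))
        return probes

    def test_filter_chain(self):
        ts = self.make_transcripts()
        expr = {"iso": 5.0, "pair1": 1.0, "pair2": 2.0, "noexpr": None}
        kept, counts = damid_heatmap_gene_filter(ts, expr, self.probes_covering(ts))
        steps = dict(counts)
        assert steps["non_missing_expression"] == 3
        assert steps["no_neighbors"] == 1
        assert [t.id for t in kept] == ["iso"]

    def test_probe_coverage_step(self):
        ts = self.make_transcripts()[:1]
        expr = {"iso": 5.0}
        kept, counts = damid_heatmap_gene_filter(ts, expr, [])
        assert dict(counts)["probe_in_every_bin"] == 0
        assert kept == []

    def test_step_counts_match_brute_force(self, annotation):
        ann, _ = annotation
        from chromabind.synth import SimParams, promoter_probes

        probes = promoter_probes(ann, SimParams(seed=1))
        kept, counts = damid_heatmap_gene_filter(
            ann.transcripts, ann.expression, probes
        )
        # brute-force neighbor recount on the survivors of the previous steps
        def brute_isolated(t):
            for o in ann.transcripts:
                if o.id == t.id or o.chrom != t.chrom:
                    continue
                if (t.strand == "+" and t.tss - 7000 <= o.tss < t.tss + 3000) or (
                    t.strand == "-" and t.tss - 3000 < o.tss <= t.tss + 7000
                ):
                    return False
            return True

        ids = {t.id for t in kept}
        for t in kept:
            assert brute_isolated(t), t.id
        # some clustered genes must have been removed by the neighbor step
        steps = dict(counts)
        assert steps["no_neighbors"] < steps["unique_tss"]


class TestMadFilter:
    def test_rows(self):
        M = np.array([[1.0, 1.0], [0.0, 2.0], [0.0, 4.0]])
        mask = mad_row_filter(M, 1.0)
        # constant -> MAD 0; (0,2) -> MAD exactly 1 (strict >); (0,4) -> MAD 2
        assert mask.tolist() == [False, False, True]


class TestPeakCenterProfile:
    def test_strata_and_enhancer_signature(self, annotation, chip_tracks, called_peaks, transcripts):
        ann, truth = annotation
        _, _, peaks = called_peaks
        # add synthetic enhancer "peaks" so the non-TSS stratum is populated
        enh_peaks = [
            GenomicInterval(e.chrom, e.center - 500, e.center + 500)
            for e, _ in truth.enhancer_links
        ]
        profs = peak_center_profile(
            {"H3K27ac": chip_tracks["H3K27ac"], "H3K4me3": chip_tracks["H3K4me3"]},
            peaks + enh_peaks,
            transcripts,
        )
        for mark in ("H3K27ac", "H3K4me3"):
            assert {"tss", "non_tss"} <= set(profs[mark])
        # non-TSS (enhancer) stratum: K27ac center far above its own flanks,
        # K4me3 essentially flat
        k27 = profs["H3K27ac"]["non_tss"]["mean"].to_numpy()
        k4 = profs["H3K4me3"]["non_tss"]["mean"].to_numpy()
        center = slice(len(k27) // 2 - 5, len(k27) // 2 + 5)
        flank = np.r_[k27[:10], k27[-10:]].mean()
        assert k27[center].mean() > 5 * max(flank, 1e-12)
        assert k4[center].mean() < k27[center].mean() / 5

    def test_empty_stratum_warns(self):
        t = [Transcript("a", "chr1", "+", 50_000, 60_000)]
        pk = [GenomicInterval("chr1", 49_000, 51_000)]  # overlaps the TSS window
        with pytest.warns(UserWarning, match="non_tss"):
            profs = peak_center_profile({"u": uniform_track()}, pk, t)
        assert "non_tss" not in profs["u"]

    def test_odd_length_center_convention(self):
        assert GenomicInterval("chr1", 10, 15).center == 12
        assert GenomicInterval("chr1", 10, 16).center == 13
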