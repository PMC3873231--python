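"""Synthetic-data generators: determinism, planted structure, null behavior."""

import numpy as np
import pytest
from scipy import stats

from chromabind.core import GenomicInterval
from chromabind.synth import (
    SimParams,
    make_genome_annotation,
    simulate_damid_arrays,
    simulate_methylation,
    simulate_mnase,
    simulate_pets,
)


class TestAnnotation:
    def test_seed_determinism(self):
        p = SimParams(seed=11, n_transcripts=60, chrom_length=1_500_000)
        a1, t1 = make_genome_annotation(p)
        a2, t2 = make_genome_annotation(p)
        assert [t.id for t in a1.transcripts] == [t.id for t in a2.transcripts]
        assert [t.tss for t in a1.transcripts] == [t.tss for t in a2.transcripts]
        assert a1.promoter_sequences == a2.promoter_sequences
        assert [r.start for r in t1.enriched_regions] == [
            r.start for r in t2.enriched_regions
        ]

    def test_zero_transcripts(self):
        p = SimParams(seed=1, n_transcripts=0)
        ann, truth = make_genome_annotation(p)
        assert ann.transcripts == []
        assert ann.layout.length("chr1") == p.chrom_length

    def test_too_dense_rejected(self):
        with pytest.raises(ValueError, match="denser"):
            make_genome_annotation(SimParams(seed=1, n_transcripts=500, chrom_length=400_000))

    def test_transcripts_not_duplicated(self, annotation):
        ann, _ = annotation
        keys = [(t.chrom, t.tss, t.tes) for t in ann.transcripts]
        assert len(keys) == len(set(keys))

    def test_neighbor_structure_exercises_heatmap_filter(self, annotation):
        # a meaningful share of genes is isolated (no TSS within 7 kb up /
        # 3 kb down) and a meaningful share is clustered
        ann, _ = annotation
        iso = 0
        for t in ann.transcripts:
            lo, hi = (
                (t.tss - 7000, t.tss + 3000)
                if t.strand == "+"
                else (t.tss - 3000, t.tss + 7000)
            )
            n_in = sum(
                1
                for o in ann.transcripts
                if o.chrom == t.chrom and lo < o.tss < hi and o.id != t.id
            )
            iso += n_in == 0
        frac = iso / len(ann.transcripts)
        assert 0.15 < frac < 0.75

    def test_enhancers_clear_of_tss_windows(self, annotation):
        ann, truth = annotation
        tss_windows = [
            GenomicInterval(t.chrom, t.tss - 3000, t.tss + 3000)
            for t in ann.transcripts
        ]
        from chromabind.core import overlap_any

        enh = [e for e, _ in truth.enhancer_links]
        assert not overlap_any(enh, tss_windows).any()


class TestDamID:
    def test_null_channels_exchangeable(self):
        # effect 0: log-ratios at island vs non-island probes share a location
        p = SimParams(seed=5, n_transcripts=40, chrom_length=1_200_000,
                      enrichment_effect=0.0, gc_bias_amplitude=0.0)
        ann, truth = make_genome_annotation(p)
        chips = simulate_damid_arrays(ann, truth, p)
        ratio = chips[0].log_cy5 - chips[0].log_cy3
        mids = np.array([iv.center for iv in chips[0].intervals])
        chroms = np.array([iv.chrom for iv in chips[0].intervals])
        inr = np.zeros(mids.size, bool)
        for r in truth.enriched_regions:
            inr |= (chroms == r.chrom) & (mids >= r.start) & (mids < r.end)
        t = stats.ttest_ind(ratio[inr], ratio[~inr])
        assert t.pvalue > 0.01

    def test_noiseless_limit_exact_effect(self):
        p = SimParams(seed=5, n_transcripts=30, chrom_length=1_000_000,
                      enrichment_effect=1.75, gc_bias_amplitude=0.0, noise_sd=0.0)
        ann, truth = make_genome_annotation(p)
        chips = simulate_damid_arrays(ann, truth, p)
        ratio = chips[0].log_cy5 - chips[0].log_cy3
        vals = np.unique(np.round(ratio, 9))
        assert set(vals) <= {0.0, 1.75}
        assert (ratio == 1.75).any()

    def test_gc_bias_visible_before_normalization(self, damid_chips):
        chip = damid_chips[0]
        rho = stats.spearmanr(chip.log_cy5 - chip.log_cy3, chip.gc).statistic
        assert abs(rho) > 0.2

    def test_replicates_share_probe_set(self, damid_chips):
        a, b = damid_chips[:2]
        assert (a.probe_ids == b.probe_ids).all()
        assert a.intervals == b.intervals


class TestMethylation:
    def islands(self, n=300):
        return [GenomicInterval("chr1", 1000 * i, 1000 * i + 500) for i in range(n)]

    def test_extreme_mixture_weights(self):
        p_low = SimParams(seed=3, meth_mixture=(0.04, 0.96, 1.0))
        fr, _, _ = simulate_methylation(self.islands(), np.zeros(300, bool), p_low)
        assert (fr < 0.5).all()
        p_high = SimParams(seed=3, meth_mixture=(0.04, 0.96, 0.0))
        fr, _, _ = simulate_methylation(self.islands(), np.zeros(300, bool), p_high)
        assert (fr > 0.5).all()

    def test_default_bimodal_deciles(self):
        from chromabind.chromstate import methylation_decile_counts

        p = SimParams(seed=3)
        fr, meth, total = simulate_methylation(self.islands(), np.zeros(300, bool), p)
        assert ((fr >= 0) & (fr <= 1)).all()
        counts = methylation_decile_counts(fr)
        # extreme bins (0<x<10 and 90<=x<=100) jointly dominate
        assert (counts[1] + counts[10]) / counts.sum() > 0.6

    def test_bound_islands_biased_low(self):
        p = SimParams(seed=3)
        bound = np.zeros(300, bool)
        bound[:150] = True
        fr, _, _ = simulate_methylation(self.islands(), bound, p)
        assert (fr[:150] < 0.5).mean() > (fr[150:] < 0.5).mean()


class TestPets:
    def test_empty_without_links(self):
        p = SimParams(seed=2, n_transcripts=0, n_enhancers=0)
        ann, truth = make_genome_annotation(p)
        assert simulate_pets(ann, truth, p) == []

    def test_no_decoys_all_anchor(self, annotation):
        ann, truth = annotation
        p = SimParams(seed=1, pet_decoy_rate=0.0)
        pets = simulate_pets(ann, truth, p)
        assert pets and all(not x.is_decoy for x in pets)

    def test_decoy_rate_half(self, annotation):
        ann, truth = annotation
        p = SimParams(seed=1, pet_decoy_rate=0.5)
        pets = simulate_pets(ann, truth, p)
        n_decoy = sum(x.is_decoy for x in pets)
        assert n_decoy == len(pets) - n_decoy  # half decoys at rate 0.5


class TestMnase:
    def test_flat_when_phasing_amplitude_zero(self, annotation, sim_params):
        from chromabind.mnase import size_filter_midpoints, tss_aligned_occupancy

        ann, truth = annotation
        frags = simulate_mnase(ann, truth, sim_params, phasing_amplitude=0.0)
        mids, _ = size_filter_midpoints(frags)
        occ = tss_aligned_occupancy(mids, ann.transcripts, 2000).sum(axis=0)
        # uniform background only: coefficient of variation of 100 bp bins small
        bins = occ[: 4000 // 100 * 100].reshape(-1, 100).sum(axis=1)
        assert bins.std() / bins.mean() < 0.3

    def test_fragment_lengths_truncated(self, annotation, sim_params):
        ann, truth = annotation
        frags = simulate_mnase(ann, truth, sim_params)
        lens = np.concatenate([(v[:, 1] - v[:, 0]) for v in frags.values()])
        assert lens.min() >= 100 and lens.max() <= 200
        # ~N(147, 15): the mononucleosome filter retains ~90-95%
        keep = ((lens >= 120) & (lens <= 180)).mean()
        assert 0.88 < keep < 0.97

    def test_determinism(self, annotation, sim_params):
        ann, truth = annotation
        f1 = simulate_mnase(ann, truth, sim_params)
        f2 = simulate_mnase(ann, truth, sim_params)
        for c in f1:
            assert (f1[c] == f2[c]).all()
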