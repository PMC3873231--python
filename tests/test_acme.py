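"""ACME peak calling: thresholds, hypergeometric tail, windows, runs, targets."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from chromabind.acme import (
    AcmeParams,
    WindowStats,
    assign_target_genes,
    call_peaks,
    hypergeom_tail,
    percentile_threshold,
    probe_enrichment_pvalues,
)
from chromabind.core import GenomicInterval, Transcript
from chromabind.damid import ProbeChip


def exact_tail(x, draws, successes, population):
    """Rational-arithmetic upper tail P(X >= x), by direct enumeration."""
    if x > min(draws, successes):
        return Fraction(0)
    total = comb(population, draws)
    acc = Fraction(0)
    for i in range(x, min(draws, successes) + 1):
        acc += Fraction(comb(successes, i) * comb(population - successes, draws - i), total)
    return acc


class TestPercentileThreshold:
    def test_constant_vector(self):
        assert percentile_threshold(np.full(50, 3.3), 0.95) == 3.3

    def test_linear_interpolation(self):
        # pooled 1..100 at s = 0.95 -> 95.05 under linear interpolation
        assert percentile_threshold(np.arange(1, 101, dtype=float), 0.95) == pytest.approx(95.05)

    def test_median(self):
        assert percentile_threshold(np.array([1.0, 2.0, 3.0]), 0.5) == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_threshold(np.array([]), 0.95)


class TestHypergeomTail:
    def test_zero_is_certain(self):
        assert hypergeom_tail(0, 4, 5, 20) == 1.0

    def test_enumeration_examples(self):
        # population 20, successes 5, draws 4: full enumeration over C(20,4)
        assert hypergeom_tail(4, 4, 5, 20) == pytest.approx(5 / 4845, rel=1e-12)
        assert hypergeom_tail(2, 4, 5, 20) == pytest.approx(1205 / 4845, rel=1e-12)

    def test_impossible_x(self):
        assert hypergeom_tail(6, 4, 5, 20) == 0.0

    def test_inconsistent_arguments(self):
        with pytest.raises(ValueError):
            hypergeom_tail(1, 4, 25, 20)

    def test_matches_rational_oracle_small_populations(self):
        # exhaustive sweep over populations <= 25 (coarse stride on the
        # larger populations keeps the sweep dense but quick)
        for population in range(1, 26):
            step = 1 if population <= 12 else 3
            for successes in range(0, population + 1, step):
                for draws in range(0, population + 1, step):
                    for x in range(0, min(draws, successes) + 2):
                        got = hypergeom_tail(x, draws, successes, population)
                        want = float(exact_tail(x, draws, successes, population))
                        assert got == pytest.approx(want, rel=1e-10, abs=1e-14)

    def test_monotone_in_x(self):
        ps = [hypergeom_tail(x, 30, 40, 200) for x in range(0, 31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def chip_from_signal(signal, spacing=100):
    n = len(signal)
    ivs = [GenomicInterval("chr1", spacing * i, spacing * i + 50) for i in range(n)]
    chip = ProbeChip(
        np.array([f"p{i}" for i in range(n)]),
        ivs,
        np.full(n, 0.5),
        np.zeros(n),
        np.zeros(n),
    )
    chip.normalized = np.asarray(signal, float)
    return chip


class TestWindowStats:
    def test_all_equal_gives_p_one(self):
        chips = [chip_from_signal(np.ones(50)), chip_from_signal(np.ones(50))]
        ws, pop = probe_enrichment_pvalues(chips, AcmeParams())
        assert (ws.pval == 1.0).all()
        assert pop.M == 0

    def test_toy_instance_matches_enumeration(self):
        # N = 10 probes spaced 5 kb apart (windows hold one probe), r = 2;
        # plant the exceedances on two adjacent probes moved close together
        s1 = np.zeros(10)
        s2 = np.zeros(10)
        s1[3] = s1[4] = 10.0  # exceedances
        s2[3] = s2[4] = 10.0
        chips = [chip_from_signal(s1, spacing=5000), chip_from_signal(s2, spacing=5000)]
        # move probes 3,4,5 within one 2 kb window
        for chip in chips:
            for i, start in [(3, 20_000), (4, 20_400), (5, 20_800)]:
                chip.intervals[i] = GenomicInterval("chr1", start, start + 50)
        params = AcmeParams(s=0.6)  # threshold below 10, above 0
        ws, pop = probe_enrichment_pvalues(chips, params)
        assert pop.M == 4
        # probe 4 sees k = 3 probes -> draws 6, x = 4
        i = 4
        assert ws.k[i] == 3 and ws.x[i] == 4
        want = float(exact_tail(4, 6, 4, 20))
        assert ws.pval[i] == pytest.approx(want, rel=1e-10)

    def test_probe_set_mismatch_rejected(self):
        a = chip_from_signal(np.ones(10))
        b = chip_from_signal(np.ones(10))
        b.probe_ids = np.array([f"q{i}" for i in range(10)])
        with pytest.raises(ValueError):
            probe_enrichment_pvalues([a, b])


def stats_from_pvals(pvals, spacing=100):
    n = len(pvals)
    return WindowStats(
        chrom=np.array(["chr1"] * n),
        start=np.arange(n) * spacing,
        end=np.arange(n) * spacing + 50,
        k=np.full(n, 5),
        x=np.zeros(n, int),
        pval=np.asarray(pvals, float),
    )


class TestCallPeaks:
    def test_min_probe_rule(self):
        sig = [1e-5] * 5 + [1.0] * 5
        assert call_peaks(stats_from_pvals(sig)) == []
        sig = [1e-5] * 6 + [1.0] * 4
        (peak,) = call_peaks(stats_from_pvals(sig))
        assert peak.name == "6"
        assert (peak.start, peak.end) == (0, 550)

    def test_runs_split_by_single_gap(self):
        sig = [1e-5] * 6 + [0.5] + [1e-6] * 7
        peaks = call_peaks(stats_from_pvals(sig))
        assert len(peaks) == 2
        assert [p.name for p in peaks] == ["6", "7"]


class TestAssignTargets:
    T = [
        Transcript("near", "chr1", "+", 12_000, 20_000),
        Transcript("far", "chr1", "+", 50_000, 60_000),
        Transcript("edge", "chr1", "+", 80_000, 90_000),
    ]

    def test_distance_rule(self):
        peaks = [GenomicInterval("chr1", 9_000, 9_500)]
        assert assign_target_genes(peaks, self.T) == {"near"}

    def test_halfopen_boundary(self):
        # peak ending exactly at TSS - 3000 does not reach the window
        peaks = [GenomicInterval("chr1", 76_000, 77_000)]
        assert assign_target_genes(peaks, self.T) == set()
        peaks = [GenomicInterval("chr1", 76_000, 77_001)]
        assert assign_target_genes(peaks, self.T) == {"edge"}

    def test_no_peaks(self):
        assert assign_target_genes([], self.T) == set()


def test_recovers_planted_regions(called_peaks, annotation):
    """At default SNR every planted domain is hit and no peak is stray."""
    from chromabind.pipeline import region_recovery

    _, truth = annotation
    _, _, peaks = called_peaks
    rec = region_recovery(peaks, truth.enriched_regions, 2000)
    assert rec["frac_recovered_j50"] >= 0.9
    assert rec["stray_peaks"] == 0
    # peaks are pairwise disjoint and >= 6 probes each
    by_chrom = {}
    for p in sorted(peaks, key=lambda p: (p.chrom, p.start)):
        assert int(p.name) >= 6
        if p.chrom in by_chrom:
            assert p.start >= by_chrom[p.chrom]
        by_chrom[p.chrom] = p.end
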