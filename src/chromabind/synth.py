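"""Seeded synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure of the real inputs — two-color
promoter-array DamID with GC-dependent dye bias and planted enriched regions,
extended-fragment ChIP coverage with the bimodal promoter shape (modes about
1.5 kb either side of the TSS, dip at the TSS), enhancer loci co-marked by
H3K27ac, bimodal CpG-island methylation, TSS-anchored ChIA-PET pairs, and
phased nucleosomes flanking an NDR — together with ground-truth records so
downstream callers can be scored against what was planted.

Every generator draws from an independent stream derived from (seed, stage
name), so adding a stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .core import CoverageTrack, GenomeLayout, GenomicInterval, Transcript
from .damid import ProbeChip


@dataclass
class SimParams:
    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 3_000_000
    n_transcripts: int = 150
    probe_spacing: int = 100
    probe_length: int = 50
    replicate_count: int = 2
    enrichment_effect: float = 3.0  # log2 units planted into the fusion channel
    gc_bias_amplitude: float = 0.6
    noise_sd: float = 0.35
    meth_mixture: tuple[float, float, float] = (0.04, 0.96, 0.55)
    ndr_depth_factor: float = 0.5
    phasing_period: int = 185
    pet_decoy_rate: float = 0.5
    n_enhancers: int = 20
    chip_fragments: int = 120_000
    mnase_fragments_per_position: int = 90

    def __post_init__(self):
        if self.replicate_count < 2:
            raise ValueError("replicate_count must be >= 2")
        if self.enrichment_effect < 0:
            raise ValueError("enrichment_effect must be >= 0")
        low, high, w = self.meth_mixture
        if not (0 <= w <= 1 and 0 <= low <= 1 and 0 <= high <= 1):
            raise ValueError("meth_mixture components must lie in [0, 1]")


@dataclass
class TruthSet:
    """Ground truth planted by the generators, for recovery scoring."""

    enriched_regions: list[GenomicInterval] = field(default_factory=list)
    enhancer_links: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    nucleosome_centers: dict[str, np.ndarray] = field(default_factory=dict)
    depleted_center_mask: dict[str, np.ndarray] = field(default_factory=dict)
    luminal_like_geneset: list[str] = field(default_factory=list)
    active_genes: set[str] = field(default_factory=set)
    mbd3_target_genes: set[str] = field(default_factory=set)
    k27me3_genes: set[str] = field(default_factory=set)
    k9me3_regions: list[GenomicInterval] = field(default_factory=list)


@dataclass
class Annotation:
    layout: GenomeLayout
    transcripts: list[Transcript]
    cpg_islands: list[GenomicInterval]  # name = owning gene id
    promoter_sequences: dict[str, str]
    expression: dict[str, float | None]


def stage_rng(params: SimParams, stage: str) -> np.random.Generator:
    """Independent stream per (seed, stage name)."""
    return np.random.default_rng([params.seed, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _markov_sequence(rng, length: int, gc: float, cpg_factor: float) -> str:
    """Sequence with tunable GC content and CpG observed/expected ratio.

    First-order Markov chain with base composition set by ``gc``; the C->G
    transition probability is multiplied by ``cpg_factor`` (then renormalized),
    so the resulting CpG observed/expected ratio is approximately
    ``cpg_factor`` (depleted below 1, enriched above 1).
    """
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    after_c = pi.copy()
    after_c[2] *= cpg_factor
    after_c /= after_c.sum()
    # vectorized: draw in blocks, honoring the previous-base dependence
    out = np.empty(length, dtype=np.int8)
    u = rng.random(length)
    cum_pi = np.cumsum(pi)
    cum_c = np.cumsum(after_c)
    prev = -1
    for i in range(length):
        cum = cum_c if prev == 1 else cum_pi
        b = int(np.searchsorted(cum, u[i]))
        out[i] = b
        prev = b
    return "".join(_BASES[out])


def make_genome_annotation(params: SimParams) -> tuple[Annotation, TruthSet]:
    """Generate the genome layout, transcripts, CpG islands and truth records.

    Genes are placed in clusters (singletons and groups of 2-3 with close
    TSSs) so the promoter-heatmap neighbor filter has structure to remove;
    a subset of genes is "active", a subset of those are MBD3 targets with a
    planted DamID-enriched region around the TSS, and intergenic enhancer
    loci are linked to active TSSs.
    """
    rng = stage_rng(params, "annotation")
    names = tuple(f"chr{i + 1}" for i in range(params.n_chrom))
    layout = GenomeLayout(names, {c: params.chrom_length for c in names})

    margin = 60_000
    per_chrom = [params.n_transcripts // params.n_chrom] * params.n_chrom
    per_chrom[0] += params.n_transcripts - sum(per_chrom)

    transcripts: list[Transcript] = []
    gid = 0
    for chrom, n_genes in zip(names, per_chrom):
        if n_genes == 0:
            continue
        usable = params.chrom_length - 2 * margin
        # cluster sizes 1/2/3 with weights 0.40/0.35/0.25
        sizes = []
        while sum(sizes) < n_genes:
            sizes.append(int(rng.choice([1, 2, 3], p=[0.40, 0.35, 0.25])))
        sizes[-1] -= sum(sizes) - n_genes
        if sizes[-1] == 0:
            sizes.pop()
        n_clusters = len(sizes)
        slot = usable // n_clusters
        if slot < 30_000:
            raise ValueError("requested transcripts denser than chromosome allows")
        for ci, size in enumerate(sizes):
            # one cluster per equal-width slot; jitter inside the slot keeps
            # clusters well separated while TSSs within a cluster stay close
            tss = margin + ci * slot + int(rng.integers(0, slot // 3))
            for _ in range(size):
                strand = "+" if rng.random() < 0.5 else "-"
                length = int(np.clip(rng.lognormal(np.log(9000), 0.55), 2500, 40_000))
                if strand == "+":
                    t = Transcript(f"g{gid:04d}", chrom, "+", tss, tss + length)
                else:
                    t = Transcript(f"g{gid:04d}", chrom, "-", tss, tss - length)
                # 1-3 exons inside the body
                n_ex = int(rng.integers(1, 4))
                edges = np.sort(rng.integers(t.start, t.end, size=2 * n_ex))
                exons = tuple(
                    (int(edges[2 * i]), int(edges[2 * i + 1]))
                    for i in range(n_ex)
                    if edges[2 * i] < edges[2 * i + 1]
                )
                transcripts.append(
                    Transcript(t.id, chrom, strand, t.tss, t.tes, exons)
                )
                gid += 1
                tss += int(rng.integers(2500, 8000))  # close neighbor inside cluster
    transcripts = transcripts[: params.n_transcripts]

    truth = TruthSet()
    ids = [t.id for t in transcripts]
    n = len(ids)

    def subset(pool, k):
        pool = sorted(pool)
        if not pool or k <= 0:
            return set()
        return set(rng.choice(pool, size=min(k, len(pool)), replace=False).tolist())

    active = subset(ids, int(0.6 * n))
    truth.active_genes = active
    targets = subset(active, int(0.35 * len(active)))
    inactive = [i for i in ids if i not in active]
    truth.k27me3_genes = subset(inactive, max(1, int(0.4 * len(inactive))))
    truth.mbd3_target_genes = targets

    by_id = {t.id: t for t in transcripts}
    # planted enrichment forms contiguous domains: target-promoter intervals
    # closer than 2 kb merge, since clustered promoters share one bound domain
    raw_regions = sorted(
        (by_id[tid].chrom, by_id[tid].tss - 1500, by_id[tid].tss + 1500, tid)
        for tid in targets
    )
    for chrom, s, e, tid in raw_regions:
        last = truth.enriched_regions[-1] if truth.enriched_regions else None
        if last is not None and last.chrom == chrom and s - last.end <= 2000:
            truth.enriched_regions[-1] = GenomicInterval(
                chrom, last.start, max(last.end, e), name=f"{last.name},{tid}"
            )
        else:
            truth.enriched_regions.append(GenomicInterval(chrom, s, e, name=tid))

    # CpG islands: most MBD3-target promoters, some other active promoters
    islands: list[GenomicInterval] = []
    sequences: dict[str, str] = {}
    for t in transcripts:
        if t.id in targets:
            has_island = rng.random() < 0.85
        elif t.id in active:
            has_island = rng.random() < 0.45
        else:
            has_island = rng.random() < 0.15
        if has_island:
            half = int(rng.integers(300, 700))
            islands.append(
                GenomicInterval(t.chrom, t.tss - half, t.tss + half, name=t.id)
            )
            sequences[t.id] = _markov_sequence(rng, 1001, gc=0.62, cpg_factor=1.8)
        elif rng.random() < 0.35:
            sequences[t.id] = _markov_sequence(rng, 1001, gc=0.52, cpg_factor=0.6)
        else:
            sequences[t.id] = _markov_sequence(rng, 1001, gc=0.40, cpg_factor=0.15)

    # expression: active genes high, inactive low; ~5% missing
    expression: dict[str, float | None] = {}
    for t in transcripts:
        if rng.random() < 0.05:
            expression[t.id] = None
        elif t.id in active:
            expression[t.id] = float(rng.lognormal(np.log(200), 0.6))
        else:
            expression[t.id] = float(rng.lognormal(np.log(3), 0.8))

    # intergenic enhancers linked to active TSSs on the same chromosome
    tss_by_chrom = {c: np.sort([t.tss for t in transcripts if t.chrom == c]) for c in names}
    active_by_chrom = {
        c: [t for t in transcripts if t.chrom == c and t.id in active] for c in names
    }
    attempts = 0
    while len(truth.enhancer_links) < params.n_enhancers and attempts < 5000:
        attempts += 1
        chrom = names[int(rng.integers(0, len(names)))]
        if not active_by_chrom[chrom]:
            continue
        pos = int(rng.integers(margin, params.chrom_length - margin))
        tss = tss_by_chrom[chrom]
        i = np.searchsorted(tss, pos)
        near = min(
            [abs(pos - tss[j]) for j in (i - 1, i) if 0 <= j < tss.size], default=10**9
        )
        if near < 4500:  # keep the enhancer clear of every TSS +/- 3 kb window
            continue
        target = active_by_chrom[chrom][int(rng.integers(0, len(active_by_chrom[chrom])))]
        enh = GenomicInterval(chrom, pos - 500, pos + 500, name=target.id)
        truth.enhancer_links.append((enh, target.id))

    # phased nucleosome centers flanking an NDR at every TSS
    period = params.phasing_period
    for t in transcripts:
        sign = 1 if t.strand == "+" else -1
        rel = np.array(
            [-(180 + period * k) for k in range(3)] + [120 + period * k for k in range(6)]
        )
        centers = t.tss + sign * rel
        # mask of positions whose occupancy drops on MBD3 depletion: -1,+2,+3,+4
        mask = np.zeros(rel.size, dtype=bool)
        mask[[0, 4, 5, 6]] = True
        truth.nucleosome_centers[t.id] = centers
        truth.depleted_center_mask[t.id] = mask

    # planted "luminal-like" gene set: drawn mostly from MBD3 targets
    lum = subset(targets, 20)
    lum |= subset([i for i in ids if i not in targets], 5)
    truth.luminal_like_geneset = sorted(lum)

    ann = Annotation(layout, transcripts, islands, sequences, expression)
    return ann, truth


# ---------------------------------------------------------------------------
# DamID arrays
# ---------------------------------------------------------------------------


def promoter_probes(ann: Annotation, params: SimParams) -> list[GenomicInterval]:
    """Array probes tiling TSS +/- 7.2 kb at the configured spacing (deduplicated)."""
    seen = set()
    probes = []
    for t in sorted(ann.transcripts, key=lambda t: (t.chrom, t.tss)):
        for s in range(t.tss - 7200, t.tss + 7200, params.probe_spacing):
            if s < 0 or s + params.probe_length > ann.layout.length(t.chrom):
                continue
            key = (t.chrom, s)
            if key in seen:
                continue
            seen.add(key)
            probes.append(GenomicInterval(t.chrom, s, s + params.probe_length))
    return probes


def simulate_damid_arrays(
    ann: Annotation, truth: TruthSet, params: SimParams
) -> list[ProbeChip]:
    """Two-color DamID chips: r replicates of (fusion cy5, Dam-only cy3).

    Per probe, both log2 channels share a hybridization baseline; the fusion
    channel additionally carries a smooth monotone GC dye-bias curve, the
    planted enrichment effect inside truth regions, and Gaussian noise.
    """
    rng = stage_rng(params, "damid")
    probes = promoter_probes(ann, params)
    n = len(probes)
    # GC per probe: smooth around islands, noisy elsewhere
    gc = np.clip(rng.normal(0.45, 0.08, size=n), 0.25, 0.75)
    island_mask = np.zeros(n, dtype=bool)
    island_sorted = {}
    for iv in ann.cpg_islands:
        island_sorted.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for i, p in enumerate(probes):
        for s, e in island_sorted.get(p.chrom, ()):  # islands are sparse
            if p.start < e and p.end > s:
                island_mask[i] = True
                break
    gc[island_mask] = np.clip(gc[island_mask] + 0.12, 0.25, 0.85)

    in_region = np.zeros(n, dtype=bool)
    region_sorted: dict[str, list[tuple[int, int]]] = {}
    for iv in truth.enriched_regions:
        region_sorted.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for c in region_sorted:
        region_sorted[c].sort()
    for i, p in enumerate(probes):
        mid = p.center
        for s, e in region_sorted.get(p.chrom, ()):
            if s <= mid < e:
                in_region[i] = True
                break

    bias = params.gc_bias_amplitude * np.tanh((gc - 0.5) / 0.15)
    probe_ids = np.array([f"p{i:06d}" for i in range(n)])
    chips = []
    for _rep in range(params.replicate_count):
        baseline = rng.normal(10.0, 0.7, size=n)
        eps3 = rng.normal(0.0, params.noise_sd, size=n)
        eps5 = rng.normal(0.0, params.noise_sd, size=n)
        log_cy3 = baseline + eps3
        log_cy5 = baseline + bias + params.enrichment_effect * in_region + eps5
        chips.append(ProbeChip(probe_ids.copy(), list(probes), gc.copy(), log_cy3, log_cy5))
    return chips


# ---------------------------------------------------------------------------
# ChIP tracks
# ---------------------------------------------------------------------------


def _fragments_from_centers(centers: np.ndarray, fragment_length: int = 300) -> np.ndarray:
    return np.asarray(np.rint(centers), dtype=np.int64) - fragment_length // 2


def simulate_chip_tracks(
    ann: Annotation, truth: TruthSet, params: SimParams
) -> dict[str, CoverageTrack]:
    """Extended-fragment coverage tracks for MBD3, four histone marks and input.

    MBD3 fragments mix a promoter-bimodal component at target genes (modes
    +/- 1.5 kb of the TSS), a 5'->3' decaying gene-body component, a TES
    component, an enhancer component (shared loci with H3K27ac), and uniform
    background.
    """
    rng = stage_rng(params, "chip")
    layout = ann.layout
    by_id = {t.id: t for t in ann.transcripts}
    targets = [by_id[i] for i in sorted(truth.mbd3_target_genes)]
    active = [by_id[i] for i in sorted(truth.active_genes)]
    k27_genes = [by_id[i] for i in sorted(truth.k27me3_genes)]
    enhancers = [iv for iv, _ in truth.enhancer_links]
    # enhancers of MBD3-target genes carry proportionally more MBD3, so pairs
    # with high TSS-end signal also show high distal-end signal
    enh_w = np.array(
        [3.0 if tid in truth.mbd3_target_genes else 1.0 for _, tid in truth.enhancer_links]
    )
    enh_p = enh_w / enh_w.sum() if enh_w.size else enh_w
    n_frag = params.chip_fragments

    def uniform_positions(m):
        chroms = rng.choice(layout.chrom_names, size=m)
        pos = rng.integers(0, params.chrom_length, size=m)
        return chroms, pos

    def pack(chroms, centers):
        frags: dict[str, np.ndarray] = {}
        for c in layout.chrom_names:
            frags[c] = _fragments_from_centers(centers[chroms == c])
        return frags

    def sample_gene(pool):
        return pool[int(rng.integers(0, len(pool)))]

    # --- MBD3 ---
    mix = rng.choice(5, size=n_frag, p=[0.45, 0.18, 0.07, 0.12, 0.18])
    chroms = np.empty(n_frag, dtype=object)
    centers = np.empty(n_frag)
    for i in range(n_frag):
        kind = mix[i]
        if kind == 0 and targets:  # promoter bimodal
            t = sample_gene(targets)
            sign = 1 if t.strand == "+" else -1
            side = 1 if rng.random() < 0.5 else -1
            centers[i] = t.tss + sign * side * rng.normal(1500, 400)
            chroms[i] = t.chrom
        elif kind == 1 and targets:  # gene body, 5'->3' decay
            t = sample_gene(targets)
            u = rng.beta(1.0, 2.5)  # mass near the 5' end
            pos = t.tss + (t.tes - t.tss) * u
            centers[i] = pos
            chroms[i] = t.chrom
        elif kind == 2 and targets:  # TES bump
            t = sample_gene(targets)
            centers[i] = t.tes + rng.normal(0, 400)
            chroms[i] = t.chrom
        elif kind == 3 and enhancers:  # enhancer component, target-weighted
            e = enhancers[int(rng.choice(len(enhancers), p=enh_p))]
            centers[i] = e.center + rng.normal(0, 300)
            chroms[i] = e.chrom
        else:  # background
            chroms[i] = layout.chrom_names[int(rng.integers(0, len(layout.chrom_names)))]
            centers[i] = rng.integers(0, params.chrom_length)
    tracks = {"MBD3": CoverageTrack.from_fragments(layout, pack(chroms, centers))}

    # --- H3K4me3: active promoters ---
    m = int(0.7 * n_frag)
    mix = rng.random(m)
    chroms = np.empty(m, dtype=object)
    centers = np.empty(m)
    for i in range(m):
        if mix[i] < 0.8 and active:
            t = sample_gene(active)
            sign = 1 if t.strand == "+" else -1
            centers[i] = t.tss + sign * rng.normal(500, 700)
            chroms[i] = t.chrom
        else:
            chroms[i] = layout.chrom_names[int(rng.integers(0, len(layout.chrom_names)))]
            centers[i] = rng.integers(0, params.chrom_length)
    tracks["H3K4me3"] = CoverageTrack.from_fragments(layout, pack(chroms, centers))

    # --- H3K27ac: enhancers + active promoters ---
    m = int(0.7 * n_frag)
    mix = rng.random(m)
    chroms = np.empty(m, dtype=object)
    centers = np.empty(m)
    for i in range(m):
        if mix[i] < 0.45 and enhancers:
            e = enhancers[int(rng.integers(0, len(enhancers)))]
            centers[i] = e.center + rng.normal(0, 300)
            chroms[i] = e.chrom
        elif mix[i] < 0.85 and active:
            t = sample_gene(active)
            sign = 1 if t.strand == "+" else -1
            centers[i] = t.tss + sign * rng.normal(800, 800)
            chroms[i] = t.chrom
        else:
            chroms[i] = layout.chrom_names[int(rng.integers(0, len(layout.chrom_names)))]
            centers[i] = rng.integers(0, params.chrom_length)
    tracks["H3K27ac"] = CoverageTrack.from_fragments(layout, pack(chroms, centers))

    # --- H3K27me3: broad domains over repressed promoters ---
    m = int(0.5 * n_frag)
    mix = rng.random(m)
    chroms = np.empty(m, dtype=object)
    centers = np.empty(m)
    for i in range(m):
        if mix[i] < 0.75 and k27_genes:
            t = sample_gene(k27_genes)
            centers[i] = t.tss + rng.uniform(-3000, 3000)
            chroms[i] = t.chrom
        else:
            chroms[i] = layout.chrom_names[int(rng.integers(0, len(layout.chrom_names)))]
            centers[i] = rng.integers(0, params.chrom_length)
    tracks["H3K27me3"] = CoverageTrack.from_fragments(layout, pack(chroms, centers))

    # --- H3K9me3: a few broad heterochromatic domains ---
    k9_regions = []
    avoid: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chrom_names}
    for t in ann.transcripts:
        avoid[t.chrom].append((t.tss - 5000, t.tss + 5000))
    for e in enhancers:
        avoid[e.chrom].append((e.start - 2000, e.end + 2000))
    guard = 0
    while len(k9_regions) < 6 and guard < 10_000:
        guard += 1
        chrom = layout.chrom_names[int(rng.integers(0, len(layout.chrom_names)))]
        s = int(rng.integers(50_000, params.chrom_length - 60_000))
        # heterochromatic domains sit away from active loci
        if any(s < e2 and s + 10_000 > s2 for s2, e2 in avoid[chrom]):
            continue
        k9_regions.append(GenomicInterval(chrom, s, s + 10_000))
    truth.k9me3_regions = k9_regions
    m = int(0.4 * n_frag)
    mix = rng.random(m)
    chroms = np.empty(m, dtype=object)
    centers = np.empty(m)
    for i in range(m):
        if mix[i] < 0.7:
            r = k9_regions[int(rng.integers(0, len(k9_regions)))]
            centers[i] = rng.uniform(r.start, r.end)
            chroms[i] = r.chrom
        else:
            chroms[i] = layout.chrom_names[int(rng.integers(0, len(layout.chrom_names)))]
            centers[i] = rng.integers(0, params.chrom_length)
    tracks["H3K9me3"] = CoverageTrack.from_fragments(layout, pack(chroms, centers))

    # --- input: uniform ---
    m = int(0.6 * n_frag)
    chroms, pos = uniform_positions(m)
    tracks["input"] = CoverageTrack.from_fragments(layout, pack(chroms, pos.astype(float)))
    return tracks


# ---------------------------------------------------------------------------
# methylation, ChIA-PET, MNase
# ---------------------------------------------------------------------------


def simulate_methylation(
    islands: list[GenomicInterval],
    bound_mask: np.ndarray,
    params: SimParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bisulfite methylation per CpG island: (fraction, meth_reads, total_reads).

    Fractions follow a two-mode mixture (hypo <0.1, hyper >0.9); islands
    flagged as MBD3-bound draw from the hypomethylated mode with high
    probability, unbound islands per the configured mixing weight.
    """
    rng = stage_rng(params, "methylation")
    low_mean, high_mean, weight_low = params.meth_mixture
    n = len(islands)
    bound = np.asarray(bound_mask, bool)
    p_low = np.where(bound, 0.92, weight_low)
    is_low = rng.random(n) < p_low
    a_low = 0.5
    b_low = a_low * (1 - low_mean) / max(low_mean, 1e-6)
    b_high = 0.5
    a_high = b_high * high_mean / max(1 - high_mean, 1e-6)
    p = np.where(is_low, rng.beta(a_low, b_low, size=n), rng.beta(a_high, b_high, size=n))
    total = rng.poisson(120, size=n) + 20
    meth = rng.binomial(total, np.clip(p, 0, 1))
    return meth / total, meth, total


@dataclass(frozen=True)
class SimPET:
    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    is_decoy: bool


def simulate_pets(
    ann: Annotation, truth: TruthSet, params: SimParams, pairs_per_link: int = 3
) -> list[SimPET]:
    """Pol II ChIA-PET pairs: one end at a linked TSS, the other at its enhancer,
    plus decoy pairs with neither end near any TSS."""
    rng = stage_rng(params, "pets")
    tss_by_chrom = {
        c: np.sort([t.tss for t in ann.transcripts if t.chrom == c])
        for c in ann.layout.chrom_names
    }
    by_id = {t.id: t for t in ann.transcripts}
    out: list[SimPET] = []
    for enh, tid in truth.enhancer_links:
        t = by_id[tid]
        for _ in range(max(1, int(rng.integers(1, pairs_per_link + 1)))):
            c1 = t.tss + int(rng.integers(-2500, 2500))
            c2 = enh.center + int(rng.normal(0, 200))
            out.append(
                SimPET(t.chrom, c1 - 250, c1 + 250, enh.chrom, c2 - 250, c2 + 250, False)
            )
    n_link = len(out)
    rate = params.pet_decoy_rate
    n_decoy = int(round(n_link * rate / max(1e-9, 1 - rate)))
    made = 0
    guard = 0
    while made < n_decoy and guard < 50_000:
        guard += 1
        chrom = ann.layout.chrom_names[int(rng.integers(0, params.n_chrom))]
        tss = tss_by_chrom[chrom]
        cs = rng.integers(10_000, params.chrom_length - 10_000, size=2)
        ok = True
        for c in cs:
            i = np.searchsorted(tss, c)
            near = min(
                [abs(int(c) - int(tss[j])) for j in (i - 1, i) if 0 <= j < tss.size],
                default=10**9,
            )
            if near < 4000:
                ok = False
        if not ok:
            continue
        out.append(
            SimPET(chrom, int(cs[0]) - 250, int(cs[0]) + 250,
                   chrom, int(cs[1]) - 250, int(cs[1]) + 250, True)
        )
        made += 1
    return out


def simulate_mnase(
    ann: Annotation,
    truth: TruthSet,
    params: SimParams,
    depleted: bool = False,
    phasing_amplitude: float = 1.0,
    background_fraction: float = 0.25,
) -> dict[str, np.ndarray]:
    """Paired-end MNase fragments as per-chromosome (start, end) arrays.

    Nucleosome dyads sit at the planted phased positions flanking the TSS NDR;
    fragment lengths are ~N(147, 15) truncated to [100, 200].  Under the
    ``depleted`` condition the occupancy at the -1, +2, +3 and +4 positions of
    MBD3-target promoters is reduced by ``ndr_depth_factor``.
    """
    rng = stage_rng(params, "mnase_depleted" if depleted else "mnase_control")
    per_pos = params.mnase_fragments_per_position
    frags: dict[str, list[np.ndarray]] = {c: [] for c in ann.layout.chrom_names}

    def emit(chrom: str, mids: np.ndarray):
        lens = rng.normal(147, 15, size=mids.size)
        bad = (lens < 100) | (lens > 200)
        while bad.any():  # truncated normal via resampling
            lens[bad] = rng.normal(147, 15, size=int(bad.sum()))
            bad = (lens < 100) | (lens > 200)
        lens = np.rint(lens).astype(np.int64)
        starts = np.rint(mids).astype(np.int64) - lens // 2
        frags[chrom].append(np.stack([starts, starts + lens], axis=1))

    for t in ann.transcripts:
        centers = truth.nucleosome_centers[t.id]
        dep_mask = truth.depleted_center_mask[t.id]
        for c, dep in zip(centers, dep_mask):
            lam = per_pos * phasing_amplitude
            if depleted and dep and t.id in truth.mbd3_target_genes:
                lam *= params.ndr_depth_factor
            k = rng.poisson(lam)
            if k:
                mids = c + rng.normal(0, 20, size=k)
                emit(t.chrom, mids)
    # uniform background (also fills the profile when phasing_amplitude = 0)
    n_pos = sum(v.size for v in truth.nucleosome_centers.values())
    n_bg = int(background_fraction * n_pos * per_pos)
    for chrom in ann.layout.chrom_names:
        k = n_bg // params.n_chrom
        mids = rng.uniform(5_000, params.chrom_length - 5_000, size=k)
        emit(chrom, mids)
    return {
        c: (np.concatenate(v) if v else np.empty((0, 2), dtype=np.int64))
        for c, v in frags.items()
    }
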