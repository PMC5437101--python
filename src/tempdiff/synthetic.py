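"""Generators for every input the pipeline consumes.

Everything is a pure function of a :class:`SimConfig` and its seed:
genotype VCFs whose site configurations are multinomial draws from a
model-determined joint SFS (unlinked sites, as the composite likelihood
assumes), piecewise-linear genetic maps, BED files of "selected"
regions, and fastIBD-style segment tables with exponential tract
lengths and localized hotspot enrichment. A separate block-copy
generator produces LD-bearing genotypes for linkage statistics, which
the unlinked SFS generator deliberately cannot.

Defaults emulate the maize study's conditions: the best-fit
double-bottleneck history, two panels of ~80 inbred lines, ten
chromosomes, about a quarter of SNPs synonymous, and IBD sharing of a
few exponentially distributed multi-cM tracts per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalescent import CoalescentConfig, expected_joint_sfs
from .demography import (PhysicalParams, ScaledParams, build_timeline,
                         maize_split5_bestfit, to_scaled)
from .ibd import GeneticMap, IBDSegment

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_map",
    "simulate_ibd",
    "simulate_ibd_runs",
    "simulate_ld_genotypes",
    "write_vcf",
    "write_bed",
    "write_map",
]


def _default_chroms() -> dict[str, int]:
    # ten chromosomes, desk-scale lengths with a maize-like size gradient
    return {str(c): int(30e6 - c * 1.5e6) for c in range(1, 11)}


@dataclass
class SimConfig:
    """Study conditions for the generators; ``seed`` is mandatory.

    ``cm_per_mb`` defaults to 0.7, the genome-wide maize average
    (~1,500 cM over ~2.1 Gbp). ``frac_synonymous`` defaults to 0.24
    (246,943 synonymous SNPs out of the panel's 1.03 M).
    """

    seed: int
    physical: PhysicalParams = field(default_factory=maize_split5_bestfit)
    n_snps: int = 20_000
    samples_per_pop: tuple[int, int] = (80, 80)
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    cm_per_mb: float = 0.7
    map_jitter: float = 0.3
    frac_synonymous: float = 0.24
    frac_selected_genome: float = 0.05
    missing_rate: float = 0.0
    ibd_rate_per_pair: float = 3.0
    ibd_mean_cm: float = 2.0
    hotspots: list[tuple[str, float, float]] = field(default_factory=list)
    hotspot_enrichment: float = 1.0
    sfs_replicates: int = 30_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_snps < 1 or any(n < 2 for n in self.samples_per_pop):
            raise ValueError("counts must be positive")
        if not (0 <= self.frac_synonymous <= 1 and 0 <= self.missing_rate < 1):
            raise ValueError("fractions must lie in [0, 1]")


#: Minimum spacing the genotype generator guarantees between sites (bp).
MIN_SPACING = 2_000
_SLOT = 3_000  # slot stride; jitter below _SLOT - MIN_SPACING keeps spacing


def _scaled(cfg: SimConfig) -> ScaledParams:
    return to_scaled(cfg.physical)


def simulate_genotypes(cfg: SimConfig):
    """Draw an inbred-line genotype panel from the model's joint SFS.

    Site configurations ``(i, j)`` are multinomial in the normalized
    expected joint SFS at the panel's haploid sample sizes; carriers
    are assigned uniformly within each population, so sites are
    unlinked and exchangeable. Positions keep at least 2 kb spacing. A
    ``frac_synonymous`` share of sites is annotated synonymous and a
    ``frac_selected_genome`` share of each chromosome is emitted as
    "selected" BED intervals, so the filtering stages have work to do.

    Returns ``(variants, samples, regions, truth)`` where ``variants``
    is a list of dicts ready for :func:`write_vcf` and ``truth`` records
    the generating parameters and per-site configurations.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    n1, n2 = cfg.samples_per_pop
    scaled = _scaled(cfg)
    sfs = expected_joint_sfs(
        build_timeline(scaled), n1, n2, 1.0,
        CoalescentConfig(replicates=cfg.sfs_replicates,
                         seed=int(rng.integers(2**31 - 1))),
    )
    weights = np.where(sfs.mask, 0.0, sfs.data).ravel()
    weights /= weights.sum()
    cells = rng.choice(weights.size, size=cfg.n_snps, p=weights)
    counts1, counts2 = np.divmod(cells, n2 + 1)

    # positions: per-chromosome slots of _SLOT bp plus sub-slot jitter
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    capacity = (lengths // _SLOT).astype(int)
    if capacity.sum() < cfg.n_snps:
        raise ValueError("n_snps incompatible with chromosome lengths and spacing")
    per_chrom = rng.multinomial(cfg.n_snps, lengths / lengths.sum())
    while np.any(per_chrom > capacity):
        over = per_chrom > capacity
        excess = int((per_chrom - capacity)[over].sum())
        per_chrom = np.minimum(per_chrom, capacity)
        room = capacity - per_chrom
        for _ in range(excess):
            j = rng.choice(np.flatnonzero(room > 0))
            per_chrom[j] += 1
            room[j] -= 1

    samples = [f"TS{i:03d}" for i in range(n1)] + [f"NS{j:03d}" for j in range(n2)]
    variants = []
    site = 0
    regions = []
    jitter_max = _SLOT - MIN_SPACING
    for ci, chrom in enumerate(chroms):
        slots = np.sort(rng.choice(capacity[ci], size=per_chrom[ci], replace=False))
        positions = slots * _SLOT + rng.integers(0, jitter_max, size=per_chrom[ci])
        sel_len = int(cfg.frac_selected_genome * cfg.chrom_lengths[chrom])
        if sel_len > 0:
            sel_start = int(rng.integers(0, cfg.chrom_lengths[chrom] - sel_len))
            regions.append((chrom, sel_start, sel_start + sel_len))
        for pos in positions:
            i, j = int(counts1[site]), int(counts2[site])
            gt = np.zeros(n1 + n2, dtype=np.int8)
            gt[rng.choice(n1, size=i, replace=False)] = 1
            gt[n1 + rng.choice(n2, size=j, replace=False)] = 1
            if cfg.missing_rate > 0:
                gt[rng.random(n1 + n2) < cfg.missing_rate] = -1
            ann = ("synonymous" if rng.random() < cfg.frac_synonymous else "other")
            variants.append(dict(chrom=chrom, pos=int(pos) + 1, ref="A", alt="T",
                                 genotypes=gt, annotation=ann))
            site += 1
    truth = dict(
        model_id=scaled.model_id,
        scaled_params=dict(scaled.params),
        theta=cfg.physical.theta,
        Na=cfg.physical.Na,
        n_snps=cfg.n_snps,
        samples_per_pop=cfg.samples_per_pop,
        configurations=np.stack([counts1, counts2], axis=1),
        seed=cfg.seed,
    )
    from .sfs_data import RegionSet
    return variants, samples, RegionSet(regions), truth


def simulate_map(cfg: SimConfig) -> GeneticMap:
    """Anchors every 1 Mb with jittered positive cM increments."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    anchors = {}
    for chrom, length in cfg.chrom_lengths.items():
        n_anchor = max(2, int(length // 1_000_000) + 1)
        bp = np.arange(n_anchor, dtype=float) * 1_000_000
        bp[-1] = min(bp[-1], float(length))
        if bp[-1] <= bp[-2]:
            bp = bp[:-1]
        incr = cfg.cm_per_mb * (
            1.0 + cfg.map_jitter * (2.0 * rng.random(len(bp) - 1) - 1.0)
        )
        incr = np.maximum(incr, 1e-3)
        cm = np.concatenate([[0.0], np.cumsum(incr)])
        anchors[chrom] = (bp, cm)
    return GeneticMap(anchors)


def simulate_ibd(cfg: SimConfig, samples_a: list[str], samples_b: list[str],
                 gmap: GeneticMap, run_offset: int = 0) -> list[IBDSegment]:
    """Pairwise IBD segments with exponential lengths and optional hotspots.

    Per (cross-panel) pair the segment count is Poisson with mean
    ``ibd_rate_per_pair``; lengths are exponential with mean
    ``ibd_mean_cm``, truncated at chromosome ends; placement is uniform
    in genetic distance except inside configured hotspot windows, whose
    placement weight is multiplied by ``hotspot_enrichment``. bp
    coordinates come from inverse map interpolation. ``run_offset``
    varies the substream, e.g. to emulate independent detector runs.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 3, run_offset)))
    chroms = gmap.chroms()
    for chrom, lo, hi in cfg.hotspots:
        if chrom not in chroms:
            raise ValueError(f"hotspot window on unknown chromosome {chrom}")
        if hi <= lo or hi > gmap.length_cM(chrom) + 1e-9:
            raise ValueError(f"hotspot window {chrom}:{lo}-{hi} outside map")
    clens = np.array([gmap.length_cM(c) for c in chroms])
    # piecewise-uniform start density: weight w on hotspot stretches
    segments: list[IBDSegment] = []
    pieces = []  # (chrom, lo, hi, weight)
    for ci, chrom in enumerate(chroms):
        cuts = {0.0, clens[ci]}
        for hc, lo, hi in cfg.hotspots:
            if hc == chrom:
                cuts.update((lo, hi))
        cuts = sorted(cuts)
        for lo, hi in zip(cuts, cuts[1:]):
            hot = any(hc == chrom and lo >= hlo - 1e-12 and hi <= hhi + 1e-12
                      for hc, hlo, hhi in cfg.hotspots)
            w = cfg.hotspot_enrichment if hot else 1.0
            pieces.append((chrom, lo, hi, w * (hi - lo)))
    piece_w = np.array([p[3] for p in pieces])
    piece_w = piece_w / piece_w.sum()
    if list(samples_a) == list(samples_b):
        pairs = [(a, b) for i, a in enumerate(samples_a)
                 for b in samples_a[i + 1:]]
    else:
        pairs = [(a, b) for a in samples_a for b in samples_b if a != b]
    for a, b in pairs:
        n_seg = rng.poisson(cfg.ibd_rate_per_pair)
        for _ in range(n_seg):
            k = rng.choice(len(pieces), p=piece_w)
            chrom, lo, hi, _ = pieces[k]
            start_cm = lo + rng.random() * (hi - lo)
            length = rng.exponential(cfg.ibd_mean_cm)
            end_cm = min(start_cm + length, gmap.length_cM(chrom))
            if end_cm <= start_cm:
                continue
            start_bp = int(gmap.inverse(chrom, start_cm))
            end_bp = int(gmap.inverse(chrom, end_cm))
            if end_bp <= start_bp:
                end_bp = start_bp + 1
            segments.append(IBDSegment(a, b, chrom, start_bp, end_bp,
                                       start_cm, end_cm,
                                       score=1.0e-9))
    return segments


def simulate_ibd_runs(cfg: SimConfig, samples_a: list[str],
                      samples_b: list[str], gmap: GeneticMap,
                      n_runs: int = 10, drop_p: float = 0.15,
                      jitter_cm: float = 0.2) -> list[list[IBDSegment]]:
    """Correlated detector runs around one underlying segment set.

    Repeated IBD detection on the *same* genotypes produces highly
    correlated calls, not independent redraws, so each run here is the
    base set of :func:`simulate_ibd` with segments independently dropped
    with probability ``drop_p`` and endpoints jittered by up to
    ``jitter_cm`` (lengths never shrink below a tenth of the original).
    """
    base = simulate_ibd(cfg, samples_a, samples_b, gmap)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 4)))
    runs: list[list[IBDSegment]] = []
    for _ in range(n_runs):
        run: list[IBDSegment] = []
        for s in base:
            if rng.random() < drop_p:
                continue
            length = s.end_cM - s.start_cM
            lo = s.start_cM + rng.uniform(-jitter_cm, jitter_cm)
            hi = s.end_cM + rng.uniform(-jitter_cm, jitter_cm)
            lo = max(lo, 0.0)
            hi = max(hi, lo + 0.1 * length)
            hi = min(hi, gmap.length_cM(s.chrom))
            if hi <= lo:
                continue
            start_bp = int(gmap.inverse(s.chrom, lo))
            end_bp = max(int(gmap.inverse(s.chrom, hi)), start_bp + 1)
            run.append(IBDSegment(s.sample_a, s.sample_b, s.chrom,
                                  start_bp, end_bp, lo, hi, s.score))
        runs.append(run)
    return runs


def simulate_ld_genotypes(n_samples: int, n_snps: int, block_snps: int = 10,
                          spacing_bp: int = 500, noise: float = 0.05,
                          seed: int = 0, chrom: str = "1", maf_min: float = 0.1):
    """Haplotype-block genotypes for LD statistics.

    SNPs come in blocks of ``block_snps``: every SNP in a block copies
    the block's founder haplotype with per-call flip probability
    ``noise``, giving high within-block r2 that decays with block
    turnover. Returns ``(variants, samples)`` in the dict form used by
    :func:`write_vcf`.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    variants = []
    base = None
    for s in range(n_snps):
        if s % block_snps == 0 or base is None:
            freq = rng.uniform(maf_min, 1 - maf_min)
            base = (rng.random(n_samples) < freq).astype(np.int8)
        gt = base.copy()
        flips = rng.random(n_samples) < noise
        gt[flips] = 1 - gt[flips]
        variants.append(dict(chrom=chrom, pos=(s + 1) * spacing_bp, ref="A",
                             alt="T", genotypes=gt, annotation="synonymous"))
    return variants, samples


# ---------------------------------------------------------------------------
# Writers (text formats only)


def write_vcf(path, variants: list[dict], samples: list[str]) -> None:
    """Minimal VCF v4.2 with diploid homozygous GTs (inbred lines)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ANNCLASS,Number=1,Type=String,'
                 'Description="Annotation class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for v in variants:
            if v["chrom"] not in chroms:
                chroms.append(v["chrom"])
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        code = {0: "0/0", 1: "1/1", -1: "./."}
        for v in variants:
            gts = "\t".join(code[int(g)] for g in v["genotypes"])
            fh.write(f"{v['chrom']}\t{v['pos']}\t.\t{v['ref']}\t{v['alt']}\t.\t"
                     f"PASS\tANNCLASS={v['annotation']}\tGT\t{gts}\n")


def write_bed(path, regions) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_map(path, gmap: GeneticMap) -> None:
    with open(path, "w") as fh:
        for chrom, (bp, cm) in gmap.anchors.items():
            for b, c in zip(bp, cm):
                fh.write(f"{chrom}\t{int(b)}\t{float(c)!r}\n")


def write_popfile(path, samples: list[str], pops: list[str]) -> None:
    with open(path, "w") as fh:
        for s, p in zip(samples, pops):
            fh.write(f"{s}\t{p}\n")


def write_truth(path, truth: dict) -> None:
    """Flat key-value truth record (arrays flattened to space-separated)."""
    with open(path, "w") as fh:
        for key, value in truth.items():
            if isinstance(value, np.ndarray):
                flat = " ".join(str(int(x)) for x in value.ravel())
                fh.write(f"{key} {flat}\n")
            elif isinstance(value, dict):
                for k2, v2 in value.items():
                    fh.write(f"{key}.{k2} {v2!r}\n")
            else:
                fh.write(f"{key} {value!r}\n")
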