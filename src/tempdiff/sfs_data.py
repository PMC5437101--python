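"""Build the observed joint SFS from an annotated VCF of inbred lines.

The chain mirrors how the maize panel was prepared for demographic
inference: keep biallelic synonymous SNPs, drop regions under selection,
thin to a minimum physical spacing (replicated with different random
sweeps), then count alleles per population and project each site
hypergeometrically down to a fixed number of haplotypes to absorb
missing data.

Inbred lines are effectively haploid: a homozygous diploid call
collapses to one haplotype, and heterozygous calls are treated as
missing at that site.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np

from .sfs import JointSFS, fold_sfs, projection_weights

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "RegionSet",
    "PopAssignment",
    "load_variants",
    "load_regions_bed",
    "load_pop_assignment",
    "filter_synonymous",
    "exclude_regions",
    "thin_variants",
    "joint_sfs_from_genotypes",
]

#: INFO key carrying the annotation class in VCF input.
ANNOTATION_INFO_KEY = "ANNCLASS"


@dataclass
class VariantRecord:
    """One biallelic SNP with haploid-coded genotypes.

    ``genotypes`` holds one int8 per sample: 0 (reference), 1
    (alternate) or -1 (missing, including heterozygous calls from
    inbred lines).  ``pos`` is 1-based as in the source VCF.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray
    annotation: str = "unknown"  # "synonymous" | "other" | "unknown"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)


@dataclass
class RegionSet:
    """Sorted genomic intervals, 0-based half-open internally."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start < 0 or end < start:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
        self.intervals = sorted(self.intervals)

    def by_chrom(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            out.setdefault(chrom, []).append((start, end))
        return out

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """Membership of a 1-based position: [start, end) covers start+1..end."""
        p0 = pos_1based - 1
        for start, end in self.by_chrom().get(chrom, []):
            if start <= p0 < end:
                return True
        return False


@dataclass
class PopAssignment:
    """Sample -> population labels plus the membership threshold used upstream."""

    assignment: dict[str, str]
    membership_threshold: float = 0.60

    def samples(self, pop: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == pop]

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.assignment.values():
            if p not in seen:
                seen.append(p)
        return seen


def load_pop_assignment(path, membership_threshold: float = 0.60) -> PopAssignment:
    """Two-column `sample<TAB>pop` text file."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split()[:2]
            if sample in assignment:
                raise ValueError(f"sample {sample} assigned twice")
            assignment[sample] = pop
    return PopAssignment(assignment, membership_threshold)


def load_regions_bed(path) -> RegionSet:
    """BED (0-based half-open) regions, e.g. selection scans to exclude."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, *_ = line.split("\t")
            intervals.append((chrom, int(start), int(end)))
    return RegionSet(intervals)


def _haploid_code(gt: list) -> int:
    # cyvcf2 genotype entry: [allele1, allele2, phased]; -1 encodes missing.
    alleles = [a for a in gt[:-1] if a is not None]
    if not alleles or any(a < 0 for a in alleles):
        return -1
    if len(set(alleles)) > 1:
        return -1  # heterozygous call in an inbred line: treat as missing
    return 1 if alleles[0] == 1 else 0


def load_variants(vcf_path, annotation_key: str = ANNOTATION_INFO_KEY):
    """Read biallelic SNPs from a VCF into :class:`VariantRecord` objects.

    Multi-allelic and non-SNP records are skipped with a logged count.
    Returns ``(variants, samples)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        ann = rec.INFO.get(annotation_key)
        if ann is None:
            ann = "unknown"
        gts = np.array([_haploid_code(g) for g in rec.genotypes], dtype=np.int8)
        variants.append(
            VariantRecord(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], gts, str(ann))
        )
    if n_skipped:
        logger.info("skipped %d multi-allelic or non-SNP records", n_skipped)
    return variants, samples


def filter_synonymous(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Keep only SNPs annotated as synonymous, preserving order."""
    if variants and all(v.annotation == "unknown" for v in variants):
        raise ValueError(
            "no annotation classes present; supply an annotated VCF with the "
            f"'{ANNOTATION_INFO_KEY}' INFO key or skip synonymous filtering"
        )
    return [v for v in variants if v.annotation == "synonymous"]


def exclude_regions(variants: list[VariantRecord],
                    regions: RegionSet) -> list[VariantRecord]:
    """Drop variants inside any region; [start, end) removes 1-based start+1..end."""
    by_chrom = regions.by_chrom()
    known = {v.chrom for v in variants}
    for chrom in by_chrom:
        if chrom not in known:
            logger.warning("BED chromosome %s absent from variants; ignored", chrom)
    out = []
    for v in variants:
        p0 = v.pos - 1
        if any(start <= p0 < end for start, end in by_chrom.get(v.chrom, [])):
            continue
        out.append(v)
    return out


def thin_variants(variants: list[VariantRecord], min_bp: int = 2000,
                  reps: int = 10, seed: int = 0) -> list[list[VariantRecord]]:
    """Random-sweep distance thinning, replicated.

    Per replicate, variants are visited in an independent random order
    and greedily accepted when at least ``min_bp`` from every variant
    already accepted on the same chromosome, which makes each replicate
    a maximal spaced subset.  Results are returned in genomic order.
    Deterministic given ``(seed, replicate index)``.
    """
    seen: list[str] = []
    last_pos = 0
    for v in variants:
        if not seen or v.chrom != seen[-1]:
            if v.chrom in seen:
                raise ValueError("variants must be sorted by (chrom, pos)")
            seen.append(v.chrom)
            last_pos = 0
        elif v.pos < last_pos:
            raise ValueError("variants must be sorted by (chrom, pos)")
        last_pos = v.pos
    replicates = []
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        sweep = rng.permutation(len(variants))
        accepted: dict[str, list[int]] = {}
        keep: list[int] = []
        for idx in sweep:
            v = variants[idx]
            positions = accepted.setdefault(v.chrom, [])
            k = bisect_left(positions, v.pos)
            left_ok = k == 0 or v.pos - positions[k - 1] >= min_bp
            right_ok = k == len(positions) or positions[k] - v.pos >= min_bp
            if left_ok and right_ok:
                insort(positions, v.pos)
                keep.append(idx)
        keep.sort()
        replicates.append([variants[i] for i in keep])
    return replicates


def joint_sfs_from_genotypes(variants: list[VariantRecord], pops: PopAssignment,
                             samples: list[str],
                             proj: tuple[int, int] = (60, 60),
                             polarization: str = "folded") -> JointSFS:
    """Accumulate a projected joint SFS from haploid-coded genotypes.

    Per site, alternate-allele counts among non-missing haplotypes in
    each of the two populations are projected down to ``proj`` with
    hypergeometric weights and accumulated; sites with fewer non-missing
    haplotypes than the projection size in either population are dropped
    (with a logged count).  ``polarization`` is ``"folded"`` (default;
    robust to unknown ancestral alleles) or ``"unfolded"`` (the
    alternate allele is taken as derived).
    """
    if polarization not in ("folded", "unfolded"):
        raise ValueError("polarization must be 'folded' or 'unfolded'")
    populations = pops.populations
    if len(populations) != 2:
        raise ValueError(f"exactly two populations required, got {populations}")
    pop_idx = []
    for pop in populations:
        members = set(pops.samples(pop))
        pop_idx.append(np.array([k for k, s in enumerate(samples) if s in members]))
    m1, m2 = proj
    grid = np.zeros((m1 + 1, m2 + 1))
    w_cache: dict[tuple[int, int], np.ndarray] = {}

    def weights(n: int, m: int) -> np.ndarray:
        if (n, m) not in w_cache:
            w_cache[(n, m)] = projection_weights(n, m)
        return w_cache[(n, m)]

    n_dropped = 0
    for v in variants:
        g1 = v.genotypes[pop_idx[0]]
        g2 = v.genotypes[pop_idx[1]]
        n1 = int((g1 >= 0).sum())
        n2 = int((g2 >= 0).sum())
        if n1 < m1 or n2 < m2:
            n_dropped += 1
            continue
        d1 = int((g1 == 1).sum())
        d2 = int((g2 == 1).sum())
        grid += np.outer(weights(n1, m1)[:, d1], weights(n2, m2)[:, d2])
    if n_dropped:
        logger.info("dropped %d sites with insufficient non-missing calls", n_dropped)
    out = JointSFS(grid)
    if polarization == "folded":
        out = fold_sfs(out)
    return out
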