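"""Population characterization: windowed Fst, private SNPs, LD, kinship.

All estimators operate on haploid-coded genotype matrices (inbred lines
collapse to one haplotype each; see :mod:`tempdiff.sfs_data`), so the
Weir-Cockerham within-individual variance component is structurally
zero and Fst reduces to a two-level analysis of allele-frequency
variance. LD is the squared allele-frequency correlation between sites
over pairwise-complete samples, the natural choice for effectively
haploid data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sfs_data import PopAssignment, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "WindowTrack",
    "genotype_matrix",
    "wc_fst_components",
    "wc_fst_windows",
    "pop_specific_snps",
    "ld_r2_adjacent",
    "ld_decay_distance",
    "ld_prune",
    "ibs_kinship",
    "kinship_filter",
]


@dataclass
class WindowTrack:
    """Per-window scalar statistic with support counts.

    ``table`` columns: chrom, start, end (0-based half-open
    internally), n_sites, value (NaN where support is below threshold).
    """

    table: pd.DataFrame
    statistic: str

    def to_tsv(self, path) -> None:
        """Write 1-based inclusive coordinates, the common browser convention."""
        out = self.table.copy()
        out["start"] = out["start"] + 1
        out.to_csv(path, sep="\t", index=False)


def genotype_matrix(variants: list[VariantRecord]) -> np.ndarray:
    """Stack haploid-coded genotypes into a (sites x samples) int8 matrix."""
    if not variants:
        return np.zeros((0, 0), dtype=np.int8)
    return np.vstack([v.genotypes for v in variants])


def wc_fst_components(G: np.ndarray, idx_a: np.ndarray,
                      idx_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components for haploid samples.

    Returns ``(a, w)`` where ``a`` is the among-population component and
    ``w`` the total (= a + within); the ratio-of-sums estimator is
    ``sum(a) / sum(w)``. Sites where either population has fewer than
    two non-missing haplotypes, or that are monomorphic over the
    combined non-missing calls, get NaN components.
    """
    r = 2
    comps = []
    for idx in (idx_a, idx_b):
        g = G[:, idx].astype(float)
        miss = g < 0
        n = (~miss).sum(axis=1).astype(float)
        d = np.where(miss, 0.0, g).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = d / n
        comps.append((n, p))
    (n1, p1), (n2, p2) = comps
    N = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        pbar = (n1 * p1 + n2 * p2) / N
        nc = (N - (n1**2 + n2**2) / N) / (r - 1)
        ssb = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msb = ssb / (r - 1)
        ssw = n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)
        msw = ssw / (N - r)
        a = (msb - msw) / nc
        w = a + msw
    seg = (pbar > 0) & (pbar < 1)
    valid = (n1 >= 2) & (n2 >= 2) & seg & (N > r)
    a = np.where(valid, a, np.nan)
    w = np.where(valid, w, np.nan)
    return a, w


def wc_fst_windows(variants: list[VariantRecord], pops: PopAssignment,
                   samples: list[str], pop_a: str, pop_b: str,
                   window_bp: int = 1_000_000, step_bp: int = 200_000,
                   min_seg: int = 30) -> WindowTrack:
    """Sliding-window ratio-of-sums Weir-Cockerham Fst.

    Windows are ``window_bp`` wide with ``step_bp`` stride; a window's
    Fst is defined only when it holds strictly more than ``min_seg``
    segregating sites.
    """
    idx_a = _member_idx(pops, samples, pop_a)
    idx_b = _member_idx(pops, samples, pop_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each population needs at least two samples")
    G = genotype_matrix(variants)
    a, w = wc_fst_components(G, idx_a, idx_b)
    chroms = np.array([v.chrom for v in variants])
    pos0 = np.array([v.pos - 1 for v in variants])
    rows = []
    for chrom in pd.unique(chroms):
        on = chroms == chrom
        cpos = pos0[on]
        ca, cw = a[on], w[on]
        span = int(cpos.max()) + 1
        start = 0
        while start < span:
            end = start + window_bp
            inside = (cpos >= start) & (cpos < end)
            usable = inside & ~np.isnan(ca)
            n_sites = int(usable.sum())
            if n_sites > min_seg and np.nansum(cw[usable]) > 0:
                fst = float(np.nansum(ca[usable]) / np.nansum(cw[usable]))
            else:
                fst = np.nan
            rows.append((chrom, start, min(end, span), n_sites, fst))
            start += step_bp
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "value"])
    return WindowTrack(table, "fst")


def _member_idx(pops: PopAssignment, samples: list[str], pop: str) -> np.ndarray:
    members = set(pops.samples(pop))
    return np.array([k for k, s in enumerate(samples) if s in members], dtype=int)


def pop_specific_snps(variants: list[VariantRecord], pops: PopAssignment,
                      samples: list[str], sample_n: int = 50, reps: int = 10,
                      maf_split: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Population-specific SNP counts from repeated balanced subsampling.

    Per replicate, ``sample_n`` samples are drawn from each population;
    a SNP is specific to a population when it is polymorphic in exactly
    that population's draw, and is classed rare (MAF <= ``maf_split``)
    or common by its frequency within that draw. Returns one row per
    (population, replicate) with rare/common counts.
    """
    G = genotype_matrix(variants)
    populations = pops.populations
    idx = {p: _member_idx(pops, samples, p) for p in populations}
    for p, members in idx.items():
        if len(members) < sample_n:
            raise ValueError(f"population {p} has fewer than {sample_n} samples")
    rows = []
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        draws = {p: rng.choice(idx[p], size=sample_n, replace=False)
                 for p in populations}
        poly = {}
        maf = {}
        for p, members in draws.items():
            g = G[:, members].astype(float)
            miss = g < 0
            n = (~miss).sum(axis=1)
            d = np.where(miss, 0.0, g).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                freq = d / n
            poly[p] = (d > 0) & (d < n)
            maf[p] = np.minimum(freq, 1 - freq)
        for p in populations:
            others = [q for q in populations if q != p]
            specific = poly[p]
            for q in others:
                specific = specific & ~poly[q]
            rare = int((specific & (maf[p] <= maf_split)).sum())
            common = int((specific & (maf[p] > maf_split)).sum())
            rows.append((p, rep, rare, common))
    table = pd.DataFrame(rows, columns=["pop", "replicate", "rare", "common"])
    table["total"] = table["rare"] + table["common"]
    return table


def ld_r2_adjacent(variants: list[VariantRecord], k: int = 10) -> pd.DataFrame:
    """Squared correlation between each SNP and its next ``k`` neighbours.

    Computed over pairwise-complete samples on the same chromosome;
    pairs where either site is monomorphic in the complete subset are
    skipped. Returns columns chrom, distance_bp, r2.
    """
    rows = []
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom, vs in by_chrom.items():
        if [v.pos for v in vs] != sorted(v.pos for v in vs):
            raise ValueError("variants must be sorted by position")
        for i, v in enumerate(vs):
            for j in range(i + 1, min(i + 1 + k, len(vs))):
                u = vs[j]
                ok = (v.genotypes >= 0) & (u.genotypes >= 0)
                if ok.sum() < 2:
                    continue
                x = v.genotypes[ok].astype(float)
                y = u.genotypes[ok].astype(float)
                if x.std() == 0 or y.std() == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                rows.append((chrom, u.pos - v.pos, float(r * r)))
    return pd.DataFrame(rows, columns=["chrom", "distance_bp", "r2"])


def ld_decay_distance(pairs: pd.DataFrame, r2_cut: float = 0.1,
                      bin_bp: int = 1000,
                      n_r2_bins: int = 10) -> tuple[float, pd.DataFrame]:
    """Distance at which mean LD decays below ``r2_cut``, plus boxplot summaries.

    Pairs are grouped into ``bin_bp``-wide distance bins; the decay
    distance is the mean pair distance within the first (distance-
    ordered) bin whose mean r2 drops to ``r2_cut`` or below, NaN
    (right-censored) when no bin reaches the cutoff. The second return
    value gives distance quartiles per r2 category for boxplots.
    """
    if pairs.empty:
        raise ValueError("empty pair table")
    dist = pairs["distance_bp"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    bins = (dist // bin_bp).astype(int)
    decay = np.nan
    for b in np.sort(np.unique(bins)):
        on = bins == b
        if r2[on].mean() <= r2_cut:
            decay = float(dist[on].mean())
            break
    edges = np.linspace(0, 1, n_r2_bins + 1)
    cats = np.clip(np.digitize(r2, edges[1:-1]), 0, n_r2_bins - 1)
    rows = []
    for c in range(n_r2_bins):
        on = cats == c
        if not on.any():
            continue
        q1, q2, q3 = np.percentile(dist[on], [25, 50, 75])
        rows.append((edges[c], edges[c + 1], int(on.sum()), q1, q2, q3))
    summary = pd.DataFrame(
        rows, columns=["r2_lo", "r2_hi", "n_pairs", "dist_q1", "dist_q2", "dist_q3"]
    )
    return decay, summary


def ld_prune(variants: list[VariantRecord], r2_thresh: float = 0.2,
             window_bp: int = 500_000) -> list[VariantRecord]:
    """Greedy left-to-right LD pruning.

    A SNP is dropped when its r2 with any *retained* SNP within
    ``window_bp`` upstream on the same chromosome exceeds
    ``r2_thresh``.
    """
    kept: list[VariantRecord] = []
    kept_by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        retained = kept_by_chrom.setdefault(v.chrom, [])
        drop = False
        for u in reversed(retained):
            if v.pos - u.pos > window_bp:
                break
            ok = (v.genotypes >= 0) & (u.genotypes >= 0)
            if ok.sum() < 2:
                continue
            x = v.genotypes[ok].astype(float)
            y = u.genotypes[ok].astype(float)
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r * r > r2_thresh:
                drop = True
                break
        if not drop:
            retained.append(v)
            kept.append(v)
    return kept


def ibs_kinship(G: np.ndarray) -> np.ndarray:
    """Method-of-moments kinship from identity-by-state sharing.

    The raw pairwise IBS fraction of two unrelated haploid samples is
    ``sum p^2 + q^2`` over sites, not zero, so it is centred and scaled
    by that expectation (from sample allele frequencies):
    ``phi = (ibs - e0) / (1 - e0)``.  Duplicates score 1, unrelated
    pairs ~0; slight negatives are clipped to 0.
    """
    n = G.shape[1]
    K = np.eye(n)
    freq_ok = G >= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(freq_ok, G, 0).sum(axis=1) / freq_ok.sum(axis=1)
    e0_site = p**2 + (1 - p) ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ok = freq_ok[:, i] & freq_ok[:, j]
            if ok.sum() == 0:
                K[i, j] = K[j, i] = 0.0
                continue
            ibs = float((G[ok, i] == G[ok, j]).mean())
            e0 = float(e0_site[ok].mean())
            if e0 >= 1.0:
                K[i, j] = K[j, i] = 1.0
                continue
            K[i, j] = K[j, i] = max((ibs - e0) / (1.0 - e0), 0.0)
    return K


def kinship_filter(G: np.ndarray, samples: list[str], threshold: float = 0.5,
                   seed: int = 0) -> list[str]:
    """Drop one member of every sample pair whose IBS kinship exceeds ``threshold``.

    Pairs are resolved most-related first; the removed member of each
    pair is chosen by seeded randomness, so the retained panel is
    deterministic given the seed and no retained pair stays above the
    threshold.
    """
    K = ibs_kinship(G)
    rng = np.random.default_rng(seed)
    active = list(range(len(samples)))
    while True:
        worst = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                if K[i, j] > threshold and (worst is None or K[i, j] > worst[0]):
                    worst = (K[i, j], i, j)
        if worst is None:
            break
        _, i, j = worst
        active.remove(i if rng.random() < 0.5 else j)
    return [samples[i] for i in active]
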