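"""Identity-by-descent segment post-processing and hotspot analysis.

Consumes fastIBD-style segment tables (detection itself happens
upstream): genetic-map interpolation between bp and cM, consensus
across independent detector runs, length filtering, pairwise sharing
summaries, long-tract classification, per-window occurrence tracks and
a permutation test for overlap between sharing hotspots and regions
under selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sfs_data import RegionSet

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticMap",
    "IBDSegment",
    "HotspotTrack",
    "load_genetic_map",
    "load_ibd_segments",
    "save_ibd_segments",
    "annotate_cM",
    "consensus_ibd",
    "filter_short",
    "pair_sharing",
    "classify_long",
    "hotspot_occurrence",
    "overlap_permutation_test",
]


@dataclass
class GeneticMap:
    """Piecewise-linear bp <-> cM map, one anchor series per chromosome."""

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (bp, cM)

    def __post_init__(self) -> None:
        for chrom, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if len(bp) < 2:
                raise ValueError(f"{chrom}: need at least two anchors")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) <= 0):
                raise ValueError(f"{chrom}: anchors must be strictly increasing")
            self.anchors[chrom] = (bp, cm)

    def chroms(self) -> list[str]:
        return list(self.anchors)

    def interpolate(self, chrom: str, pos_bp) -> np.ndarray | float:
        """bp -> cM by linear interpolation.

        Positions outside the anchored range are extended linearly with
        the terminal slope and flagged with a log warning.
        """
        bp, cm = self._get(chrom)
        pos = np.atleast_1d(np.asarray(pos_bp, dtype=float))
        if np.any(pos < bp[0]) or np.any(pos > bp[-1]):
            logger.warning("%s: position outside map range; extrapolating", chrom)
        out = np.interp(pos, bp, cm)
        lo = pos < bp[0]
        out[lo] = cm[0] + (pos[lo] - bp[0]) * (cm[1] - cm[0]) / (bp[1] - bp[0])
        hi = pos > bp[-1]
        out[hi] = cm[-1] + (pos[hi] - bp[-1]) * (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
        return out if np.ndim(pos_bp) else float(out[0])

    def inverse(self, chrom: str, pos_cm) -> np.ndarray | float:
        """cM -> bp, the inverse interpolation."""
        bp, cm = self._get(chrom)
        pos = np.atleast_1d(np.asarray(pos_cm, dtype=float))
        out = np.interp(pos, cm, bp)
        return out if np.ndim(pos_cm) else float(out[0])

    def length_cM(self, chrom: str) -> float:
        _, cm = self._get(chrom)
        return float(cm[-1] - cm[0])

    def _get(self, chrom: str):
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        return self.anchors[chrom]


def load_genetic_map(path) -> GeneticMap:
    """TSV `chrom pos_bp pos_cM`, any ordering of rows within a chromosome."""
    table = pd.read_csv(path, sep="\t", names=["chrom", "bp", "cM"], comment="#",
                        header=None, dtype={"chrom": str})
    anchors = {}
    for chrom, grp in table.groupby("chrom", sort=False):
        grp = grp.sort_values("bp")
        anchors[str(chrom)] = (grp["bp"].to_numpy(float), grp["cM"].to_numpy(float))
    return GeneticMap(anchors)


@dataclass(frozen=True)
class IBDSegment:
    """A shared tract between two samples, in bp and (optionally) cM."""

    sample_a: str
    sample_b: str
    chrom: str
    start_bp: int
    end_bp: int
    start_cM: float | None = None
    end_cM: float | None = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValueError("an IBD segment joins two distinct samples")
        if self.end_bp <= self.start_bp:
            raise ValueError("segment must have start_bp < end_bp")
        if (self.start_cM is None) != (self.end_cM is None):
            raise ValueError("give both or neither of start_cM / end_cM")
        if self.start_cM is not None and self.end_cM <= self.start_cM:
            raise ValueError("segment must have start_cM < end_cM")

    @property
    def length_cM(self) -> float:
        if self.start_cM is None:
            raise ValueError("segment has no cM coordinates; annotate with a map")
        return self.end_cM - self.start_cM

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.sample_a, self.sample_b)))


def load_ibd_segments(path) -> list[IBDSegment]:
    """fastIBD-style TSV: sampleA sampleB chrom start_bp end_bp score."""
    table = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["sample_a", "sample_b", "chrom", "start_bp", "end_bp", "score"],
        dtype={"chrom": str},
    )
    return [
        IBDSegment(r.sample_a, r.sample_b, str(r.chrom), int(r.start_bp),
                   int(r.end_bp), score=float(r.score))
        for r in table.itertuples()
    ]


def save_ibd_segments(path, segments: list[IBDSegment]) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.sample_a}\t{s.sample_b}\t{s.chrom}\t{s.start_bp}"
                     f"\t{s.end_bp}\t{float(s.score)!r}\n")


def annotate_cM(segments: list[IBDSegment], gmap: GeneticMap) -> list[IBDSegment]:
    """Attach genetic coordinates to segments via map interpolation."""
    return [
        replace(s,
                start_cM=gmap.interpolate(s.chrom, s.start_bp),
                end_cM=gmap.interpolate(s.chrom, s.end_bp))
        for s in segments
    ]


def consensus_ibd(runs: list[list[IBDSegment]],
                  min_runs: int | None = None) -> list[IBDSegment]:
    """Majority-coverage consensus across independent detector runs.

    A base-pair position enters the consensus for a sample pair when it
    is covered in strictly more than half of the runs (or at least
    ``min_runs`` when given); maximal covered intervals are emitted.
    Scores are not aggregated (set to 0).
    """
    if not runs:
        return []
    universes = [frozenset(x for s in run for x in (s.sample_a, s.sample_b))
                 for run in runs]
    if universes and not frozenset.intersection(*universes) and any(universes):
        nonempty = [u for u in universes if u]
        if nonempty and not frozenset.intersection(*nonempty):
            raise ValueError("runs cover disjoint sample sets")
    need = min_runs if min_runs is not None else len(runs) // 2 + 1
    by_key: dict[tuple, list[list[tuple[int, int]]]] = {}
    for run_idx, run in enumerate(runs):
        for s in run:
            key = (*s.pair, s.chrom)
            slots = by_key.setdefault(key, [[] for _ in runs])
            slots[run_idx].append((s.start_bp, s.end_bp))
    out: list[IBDSegment] = []
    for (a, b, chrom), per_run in sorted(by_key.items()):
        events: list[tuple[int, int]] = []
        for intervals in per_run:
            for start, end in _merge_intervals(intervals):
                events.append((start, 1))
                events.append((end, -1))
        events.sort()
        depth = 0
        open_at = None
        for pos, delta in events:
            prev = depth
            depth += delta
            if prev < need <= depth:
                open_at = pos
            elif prev >= need > depth and open_at is not None:
                if pos > open_at:
                    out.append(IBDSegment(a, b, chrom, open_at, pos))
                open_at = None
    return out


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def filter_short(segments: list[IBDSegment], min_cM: float = 1.0) -> list[IBDSegment]:
    """Drop segments strictly shorter than ``min_cM`` (background-LD artifacts)."""
    for s in segments:
        if s.start_cM is None:
            raise ValueError("segments need cM coordinates; run annotate_cM first")
    return [s for s in segments if s.length_cM >= min_cM]


def pair_sharing(segments: list[IBDSegment], pops: dict[str, str],
                 pop_sizes: dict[str, int] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair sharing totals and per-population-pair means.

    ``pops`` maps sample -> population for every sample in the panel;
    ``pop_sizes`` gives panel sizes per population so that
    population-pair means average over *all* pairs, including
    zero-sharing ones (defaults to the samples seen in ``pops``).
    Returns ``(per_pair, per_poppair)`` tables; lengths are cM.
    """
    sizes: dict[str, int] = {}
    for pop in set(pops.values()):
        sizes[pop] = sum(1 for p in pops.values() if p == pop)
    if pop_sizes:
        sizes.update(pop_sizes)
    totals: dict[tuple[str, str], list[float]] = {}
    for s in segments:
        totals.setdefault(s.pair, []).append(s.length_cM)
    pair_rows = []
    for (a, b), lengths in sorted(totals.items()):
        pair_rows.append((a, b, pops.get(a), pops.get(b), float(np.sum(lengths)),
                          float(np.mean(lengths)), len(lengths)))
    per_pair = pd.DataFrame(
        pair_rows,
        columns=["sample_a", "sample_b", "pop_a", "pop_b", "total_cM",
                 "mean_cM", "n_segments"],
    )
    agg: dict[tuple[str, str], float] = {}
    for (a, b), lengths in totals.items():
        key = tuple(sorted((pops[a], pops[b])))
        agg[key] = agg.get(key, 0.0) + float(np.sum(lengths))
    pop_rows = []
    pop_list = sorted(sizes)
    for i, pa in enumerate(pop_list):
        for pb in pop_list[i:]:
            if pa == pb:
                n_pairs = sizes[pa] * (sizes[pa] - 1) // 2
            else:
                n_pairs = sizes[pa] * sizes[pb]
            if n_pairs == 0:
                continue
            total = agg.get((pa, pb), 0.0)
            pop_rows.append((pa, pb, n_pairs, total, total / n_pairs))
    per_pop = pd.DataFrame(
        pop_rows, columns=["pop_a", "pop_b", "n_pairs", "total_cM", "mean_cM_per_pair"]
    )
    return per_pair, per_pop


def classify_long(segments: list[IBDSegment],
                  thr_cM: float = 7.0) -> list[tuple[IBDSegment, str]]:
    """Label tracts "long" when strictly longer than ``thr_cM``, else "short"."""
    return [(s, "long" if s.length_cM > thr_cM else "short") for s in segments]


@dataclass
class HotspotTrack:
    """Non-overlapping cM windows with IBD occurrence per sample pair.

    ``table`` columns: chrom, start_cM, end_cM, n_segments, occurrence,
    partial (terminal window shorter than the nominal width).
    """

    table: pd.DataFrame
    window_cM: float
    n_pairs: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def hotspot_occurrence(segments: list[IBDSegment], gmap: GeneticMap,
                       window_cM: float = 10.0,
                       n_pairs: int | None = None) -> HotspotTrack:
    """Per-window IBD occurrence: spanning-segment count / sample pairs.

    Windows tile each chromosome from 0 cM in ``window_cM`` steps; a
    segment spans a window when its cM interval overlaps it (counted
    once per window it crosses). ``n_pairs`` is C(n, 2) for
    within-population tracks and n1*n2 across populations.
    """
    if n_pairs is None:
        samples = {x for s in segments for x in (s.sample_a, s.sample_b)}
        n_pairs = len(samples) * (len(samples) - 1) // 2
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if not gmap.anchors:
        raise ValueError("empty genetic map")
    for s in segments:
        if s.start_cM is None:
            raise ValueError("segments need cM coordinates; run annotate_cM first")
    rows = []
    by_chrom: dict[str, list[IBDSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in gmap.chroms():
        _, cm = gmap.anchors[chrom]
        top = float(cm[-1])
        segs = by_chrom.get(chrom, [])
        start = 0.0
        while start < top:
            end = min(start + window_cM, top)
            count = sum(1 for s in segs if s.start_cM < end and s.end_cM > start)
            rows.append((chrom, start, end, count, count / n_pairs,
                         end - start < window_cM))
            start += window_cM
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start_cM", "end_cM", "n_segments", "occurrence",
                 "partial"],
    )
    return HotspotTrack(table, window_cM, n_pairs)


def overlap_permutation_test(track: HotspotTrack, regions: RegionSet,
                             gmap: GeneticMap, top_q: float = 0.95,
                             n_perm: int = 999,
                             seed: int = 0) -> tuple[float, float]:
    """Do the busiest IBD windows overlap selection regions more than chance?

    The observed statistic is the fraction of the top ``(1 - top_q)``
    windows by occurrence (ties broken by genomic order) that overlap
    any region; the null redraws the same number of windows uniformly
    without replacement. Returns ``(overlap_fraction, p_value)`` with
    the add-one permutation p-value.
    """
    table = track.table
    n_windows = len(table)
    if n_windows == 0:
        raise ValueError("empty hotspot track")
    k = max(1, int(round(n_windows * (1.0 - top_q))))
    if k > n_windows:
        raise ValueError("fewer windows than the top-quantile count")
    by_chrom = regions.by_chrom()
    overlaps = np.zeros(n_windows, dtype=bool)
    for idx, row in enumerate(table.itertuples()):
        if row.chrom not in by_chrom:
            continue
        w_start = gmap.inverse(row.chrom, row.start_cM)
        w_end = gmap.inverse(row.chrom, row.end_cM)
        for r_start, r_end in by_chrom[row.chrom]:
            if w_start < r_end and w_end > r_start:
                overlaps[idx] = True
                break
    order = np.lexsort((np.arange(n_windows), -table["occurrence"].to_numpy()))
    top_idx = order[:k]
    observed = float(overlaps[top_idx].mean())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        draw = rng.choice(n_windows, size=k, replace=False)
        if overlaps[draw].mean() >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return observed, float(p)
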