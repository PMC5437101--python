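"""End-to-end orchestration: build-sfs -> fit -> compare -> popstats -> ibd.

A :class:`RunConfig` (typically read from a YAML file) names the
inputs, the models to fit and the seeds; :func:`run_full` executes the
stages in order, writes every intermediate as a plain-text table under
the output directory, and returns a machine-readable summary. Any
stage failure aborts with the stage name while earlier outputs are kept
on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ibd as ibdmod
from . import popstats, sfs_data
from .coalescent import CoalescentConfig
from .demography import NESTING, SINGLE_POP_MODELS, n_free_params
from .likelihood import FitResult, fit_model, lrt
from .sfs import JointSFS

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full", "build_observed_sfs", "compare_models"]


@dataclass
class RunConfig:
    """Paths, models and seeds for a full run."""

    vcf: str
    popfile: str
    outdir: str
    mu: float
    L: float
    bed: str | None = None
    genetic_map: str | None = None
    ibd_runs: list[str] = field(default_factory=list)
    models: list[str] = field(default_factory=lambda: ["split1", "split2"])
    projection: tuple[int, int] = (60, 60)
    polarization: str = "folded"
    thin_bp: int = 2000
    thin_reps: int = 1
    seed: int = 0
    replicates: int = 30_000
    skip_synonymous_filter: bool = False
    fst_window_bp: int = 1_000_000
    fst_step_bp: int = 200_000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        required = ("vcf", "popfile", "outdir", "mu", "L")
        missing = [k for k in required if k not in raw]
        if missing:
            raise ValueError(f"config missing required fields: {missing}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "projection" in raw:
            raw["projection"] = tuple(raw["projection"])
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("vcf", "popfile", "bed", "genetic_map"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value}")
        for path in self.ibd_runs:
            if not Path(path).exists():
                raise FileNotFoundError(f"ibd run: {path}")


def build_observed_sfs(config: RunConfig) -> tuple[JointSFS, dict]:
    """VCF -> filtered, thinned, projected joint SFS (first thinning replicate)."""
    variants, samples = sfs_data.load_variants(config.vcf)
    pops = sfs_data.load_pop_assignment(config.popfile)
    meta = {"n_input": len(variants)}
    if not config.skip_synonymous_filter:
        variants = sfs_data.filter_synonymous(variants)
        meta["n_synonymous"] = len(variants)
    if config.bed:
        regions = sfs_data.load_regions_bed(config.bed)
        variants = sfs_data.exclude_regions(variants, regions)
        meta["n_after_exclusion"] = len(variants)
    reps = sfs_data.thin_variants(variants, config.thin_bp, config.thin_reps,
                                  config.seed)
    meta["n_thinned"] = len(reps[0])
    meta["thin_retention"] = len(reps[0]) / max(len(variants), 1)
    sfs = sfs_data.joint_sfs_from_genotypes(
        reps[0], pops, samples, proj=config.projection,
        polarization=config.polarization)
    meta["populations"] = pops.populations
    meta["samples"] = samples
    return sfs, meta


def compare_models(data: JointSFS, models: list[str], cfg: CoalescentConfig,
                   engine: str = "mc") -> tuple[list[FitResult], dict]:
    """Fit several models and assemble the AIC / nested-LRT comparison.

    The comparison table is sorted by increasing AIC; likelihood-ratio
    tests are computed only for pairs in the declared nesting graph,
    with df equal to the difference in free-parameter counts.
    """
    fits = {m: fit_model(m, data, cfg=cfg, engine=engine) for m in models}
    rows = []
    for m, fit in fits.items():
        rows.append(dict(model=m, k=n_free_params(m), loglik=fit.loglik,
                         aic=fit.aic, converged=fit.converged,
                         on_bound=fit.on_bound))
    rows.sort(key=lambda r: r["aic"])
    tests = []
    for alt, nulls in NESTING.items():
        if alt not in fits:
            continue
        for null in nulls:
            if null not in fits:
                continue
            df = n_free_params(alt) - n_free_params(null)
            try:
                p = lrt(fits[null].loglik, fits[alt].loglik, df, tolerance=1.0)
            except ValueError:
                p = float("nan")
            tests.append(dict(null=null, alt=alt, df=df,
                              stat=2 * (fits[alt].loglik - fits[null].loglik),
                              p_value=p))
    ordered = [fits[r["model"]] for r in rows]
    for r, fit in zip(rows, ordered):
        r["theta"] = fit.theta
    return ordered, dict(table=rows, lrt=tests)


def run_full(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the summary dict."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    stage = "build-sfs"
    try:
        sfs, meta = build_observed_sfs(config)
        sfs.save(outdir / "observed.sfs")
        summary["sfs"] = {k: v for k, v in meta.items() if k != "samples"}

        stage = "fit"
        cfg = CoalescentConfig(replicates=config.replicates, seed=config.seed)
        usable = [m for m in config.models
                  if (m in SINGLE_POP_MODELS) == (sfs.ndim == 1)]
        fits, comparison = compare_models(sfs, usable, cfg)
        summary["models"] = comparison
        with open(outdir / "model_comparison.json", "w") as fh:
            json.dump(comparison, fh, indent=2)
        for fit in fits:
            report = outdir / f"fit_{fit.model_id}.txt"
            with open(report, "w") as fh:
                fh.write(f"model {fit.model_id}\n")
                fh.write(f"loglik {fit.loglik!r}\ntheta {fit.theta!r}\n")
                fh.write(f"aic {fit.aic!r}\nseed {fit.seed}\n")
                fh.write(f"engine {fit.engine}\nconverged {fit.converged}\n")
                for name, value in fit.params.params.items():
                    fh.write(f"{name} {value!r}\n")

        stage = "popstats"
        variants, samples = sfs_data.load_variants(config.vcf)
        pops = sfs_data.load_pop_assignment(config.popfile)
        pa, pb = pops.populations[:2]
        track = popstats.wc_fst_windows(
            variants, pops, samples, pa, pb,
            window_bp=config.fst_window_bp, step_bp=config.fst_step_bp)
        track.to_tsv(outdir / "fst_windows.tsv")
        defined = track.table["value"].dropna()
        summary["fst"] = {
            "n_windows": int(len(track.table)),
            "n_defined": int(defined.size),
            "mean": float(defined.mean()) if defined.size else None,
        }
        pair_table = popstats.ld_r2_adjacent(variants, k=10)
        if not pair_table.empty:
            decay, _ = popstats.ld_decay_distance(pair_table)
            summary["ld_decay_bp"] = None if np.isnan(decay) else float(decay)

        stage = "ibd"
        if config.ibd_runs and config.genetic_map:
            gmap = ibdmod.load_genetic_map(config.genetic_map)
            runs = [ibdmod.load_ibd_segments(p) for p in config.ibd_runs]
            consensus = (ibdmod.consensus_ibd(runs)
                         if len(runs) > 1 else runs[0])
            consensus = ibdmod.annotate_cM(consensus, gmap)
            consensus = ibdmod.filter_short(consensus)
            ibdmod.save_ibd_segments(outdir / "consensus_ibd.tsv", consensus)
            assignment = pops.assignment
            per_pair, per_pop = ibdmod.pair_sharing(consensus, assignment)
            per_pair.to_csv(outdir / "ibd_pairs.tsv", sep="\t", index=False)
            per_pop.to_csv(outdir / "ibd_pop_pairs.tsv", sep="\t", index=False)
            track = ibdmod.hotspot_occurrence(consensus, gmap)
            track.to_tsv(outdir / "ibd_hotspots.tsv")
            summary["ibd"] = {
                "n_consensus": len(consensus),
                "max_occurrence": float(track.table["occurrence"].max())
                if len(track.table) else 0.0,
            }
            if config.bed:
                regions = sfs_data.load_regions_bed(config.bed)
                obs, p = ibdmod.overlap_permutation_test(
                    track, regions, gmap, seed=config.seed)
                summary["ibd"]["hotspot_overlap"] = obs
                summary["ibd"]["hotspot_overlap_p"] = p
    except Exception:
        logger.error("stage %r failed; partial outputs kept in %s", stage, outdir)
        raise
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(_human_report(summary))
    return summary


def _human_report(summary: dict) -> str:
    lines = ["tropical-temperate divergence pipeline report", ""]
    if "sfs" in summary:
        lines.append(f"SFS: {summary['sfs']}")
    for row in summary.get("models", {}).get("table", []):
        lines.append(
            f"model {row['model']:<12} k={row['k']:<3} ll={row['loglik']:.2f} "
            f"AIC={row['aic']:.2f}"
        )
    for t in summary.get("models", {}).get("lrt", []):
        lines.append(
            f"LRT {t['null']} vs {t['alt']}: stat={t['stat']:.2f} "
            f"df={t['df']} p={t['p_value']:.3g}"
        )
    if "fst" in summary:
        lines.append(f"Fst windows: {summary['fst']}")
    if "ld_decay_bp" in summary:
        lines.append(f"LD decay distance (bp): {summary['ld_decay_bp']}")
    if "ibd" in summary:
        lines.append(f"IBD: {summary['ibd']}")
    return "\n".join(lines) + "\n"
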