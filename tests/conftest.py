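"""Shared fixtures: small synthetic bundles and reference timelines."""

import numpy as np
import pytest

from tempdiff import (CoalescentConfig, ScaledParams, build_timeline,
                      maize_split5_bestfit, to_scaled)
from tempdiff.synthetic import (SimConfig, simulate_genotypes, simulate_ibd,
                                simulate_map, write_bed, write_map,
                                write_popfile, write_vcf)


@pytest.fixture(scope="session")
def bestfit_physical():
    return maize_split5_bestfit()


@pytest.fixture(scope="session")
def bestfit_scaled(bestfit_physical):
    return to_scaled(bestfit_physical)


@pytest.fixture(scope="session")
def neutral_timeline():
    return build_timeline(ScaledParams("neutral"))


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-scale generator settings: 2 chromosomes, 12+12 lines, 3,000 SNPs."""
    return SimConfig(
        seed=7,
        n_snps=3_000,
        samples_per_pop=(12, 12),
        chrom_lengths={"1": 12_000_000, "2": 9_000_000},
        sfs_replicates=5_000,
        ibd_rate_per_pair=2.0,
        ibd_mean_cm=3.0,
    )


@pytest.fixture(scope="session")
def small_bundle(small_sim_config, tmp_path_factory):
    """Synthetic VCF + BED + map + IBD + popfile written to disk once."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = small_sim_config
    variants, samples, regions, truth = simulate_genotypes(cfg)
    gmap = simulate_map(cfg)
    n1 = cfg.samples_per_pop[0]
    segments = simulate_ibd(cfg, samples[:n1], samples[n1:], gmap)
    write_vcf(out / "panel.vcf", variants, samples)
    write_bed(out / "selected.bed", regions)
    write_map(out / "map.tsv", gmap)
    write_popfile(out / "pops.tsv", samples, ["TS"] * n1 + ["NSS"] * n1)
    from tempdiff.ibd import save_ibd_segments
    save_ibd_segments(out / "ibd0.tsv", segments)
    return dict(dir=out, vcf=out / "panel.vcf", bed=out / "selected.bed",
                map=out / "map.tsv", pop=out / "pops.tsv",
                ibd=out / "ibd0.tsv", variants=variants, samples=samples,
                regions=regions, truth=truth, gmap=gmap, segments=segments,
                cfg=cfg)


@pytest.fixture
def fast_mc():
    """Low-replicate Monte Carlo config for shape-level checks."""
    return CoalescentConfig(replicates=20_000, seed=11)
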