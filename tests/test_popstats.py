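"""Fst, population-specific SNPs, LD and kinship on haploid-coded panels."""

import numpy as np
import pytest

from tempdiff.popstats import (genotype_matrix, ibs_kinship, kinship_filter,
                               ld_decay_distance, ld_prune, ld_r2_adjacent,
                               pop_specific_snps, wc_fst_components,
                               wc_fst_windows)
from tempdiff.sfs_data import PopAssignment, VariantRecord
from tempdiff.synthetic import simulate_ld_genotypes


def _variant(chrom="1", pos=100, gts=(0, 1)):
    return VariantRecord(chrom, pos, "A", "T", np.array(gts, dtype=np.int8))


def _panel(n_a, n_b):
    names = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    pops = PopAssignment({s: ("A" if s.startswith("a") else "B")
                          for s in names})
    return pops, names


class TestFst:
    def test_fixed_difference_gives_one(self):
        pops, names = _panel(4, 4)
        vs = [_variant(pos=p, gts=(0, 0, 0, 0, 1, 1, 1, 1))
              for p in range(1000, 1000 + 40 * 100, 100)]
        track = wc_fst_windows(vs, pops, names, "A", "B",
                               window_bp=10_000, step_bp=10_000, min_seg=30)
        defined = track.table["value"].dropna()
        assert len(defined) >= 1
        assert np.allclose(defined, 1.0)

    def test_identical_frequencies_give_near_zero(self):
        rng = np.random.default_rng(0)
        idx_a = np.arange(50)
        idx_b = np.arange(50, 100)
        G = np.zeros((10_000, 100), dtype=np.int8)
        for s in range(G.shape[0]):
            p = rng.uniform(0.1, 0.9)
            G[s] = (rng.random(100) < p).astype(np.int8)
        a, w = wc_fst_components(G, idx_a, idx_b)
        fst = np.nansum(a) / np.nansum(w)
        assert abs(fst) < 0.01

    def test_window_support_threshold_is_strict(self):
        pops, names = _panel(3, 3)

        def track_for(n_sites):
            vs = [_variant(pos=1 + 10 * k, gts=(0, 1, 0, 1, 0, 0))
                  for k in range(n_sites)]
            return wc_fst_windows(vs, pops, names, "A", "B",
                                  window_bp=10_000, step_bp=10_000)

        assert track_for(30).table["value"].isna().all()
        assert track_for(31).table["value"].notna().any()

    def test_fst_increases_with_divergence_time(self, bestfit_scaled):
        # drift for longer -> more differentiation (island-model analogue)
        from tempdiff import (CoalescentConfig, ScaledParams, build_timeline,
                              expected_joint_sfs)
        rng = np.random.default_rng(5)
        fsts = []
        for tau in (0.02, 0.1, 0.4, 1.0):
            params = ScaledParams("split1",
                                  dict(nu1=1.0, nu2=1.0, tau_s=tau, m=0.0))
            sfs = expected_joint_sfs(build_timeline(params), 20, 20, 1.0,
                                     CoalescentConfig(replicates=20_000, seed=7))
            weights = np.where(sfs.mask, 0, sfs.data).ravel()
            cells = rng.choice(weights.size, 4000, p=weights / weights.sum())
            i, j = np.divmod(cells, 21)
            G = np.zeros((4000, 40), dtype=np.int8)
            for s in range(4000):
                G[s, rng.choice(20, i[s], replace=False)] = 1
                G[s, 20 + rng.choice(20, j[s], replace=False)] = 1
            a, w = wc_fst_components(G, np.arange(20), np.arange(20, 40))
            fsts.append(np.nansum(a) / np.nansum(w))
        assert all(x < y for x, y in zip(fsts, fsts[1:]))
        assert all(-0.01 <= f <= 1.0 for f in fsts)


class TestPopSpecific:
    def test_exclusive_polymorphism_counted_every_replicate(self):
        pops, names = _panel(6, 6)
        only_a = _variant(pos=1, gts=(0, 1, 0, 1, 0, 1, 0, 0, 0, 0, 0, 0))
        both = _variant(pos=2, gts=(0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1))
        table = pop_specific_snps([only_a, both], pops, names, sample_n=6,
                                  reps=10, seed=0)
        a_rows = table[table["pop"] == "A"]
        assert (a_rows["total"] == 1).all()
        b_rows = table[table["pop"] == "B"]
        assert (b_rows["total"] == 0).all()

    def test_maf_boundary_is_rare(self):
        # 1 derived of 20 haplotypes -> MAF 0.05 counts as rare
        pops, names = _panel(20, 20)
        gts = [1] + [0] * 39
        v = _variant(pos=1, gts=tuple(gts))
        table = pop_specific_snps([v], pops, names, sample_n=20, reps=3, seed=1)
        a_rows = table[table["pop"] == "A"]
        assert (a_rows["rare"] == a_rows["total"]).all()

    def test_small_population_rejected(self):
        pops, names = _panel(3, 3)
        with pytest.raises(ValueError, match="fewer than"):
            pop_specific_snps([_variant(gts=(0, 1, 0, 0, 1, 0))], pops, names,
                              sample_n=5)


class TestLd:
    def test_duplicated_snp_has_r2_one(self):
        vs = [_variant(pos=100, gts=(0, 1, 0, 1, 1, 0)),
              _variant(pos=200, gts=(0, 1, 0, 1, 1, 0))]
        pairs = ld_r2_adjacent(vs, k=10)
        assert len(pairs) == 1
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_snps_have_mean_r2_near_one_over_n(self):
        rng = np.random.default_rng(2)
        n = 200
        vs = [_variant(pos=100 * (s + 1),
                       gts=tuple((rng.random(n) < 0.5).astype(int)))
              for s in range(120)]
        pairs = ld_r2_adjacent(vs, k=10)
        # E[r2] ~ 1/n for independent loci (small-sample bias of r2)
        assert pairs["r2"].mean() == pytest.approx(1.0 / n, rel=0.3)

    def test_k_truncates_without_error(self):
        vs = [_variant(pos=p, gts=(0, 1, 1, 0)) for p in (1, 2, 3)]
        pairs = ld_r2_adjacent(vs, k=99)
        assert len(pairs) == 3  # C(3, 2) pairs

    def test_planted_exponential_decay_inverted(self):
        # r2(d) = exp(-d / 100) crosses 0.1 at d = 100 * ln(10) = 230
        rng = np.random.default_rng(3)
        import pandas as pd
        d = rng.uniform(1, 600, 60_000)
        pairs = pd.DataFrame({"chrom": "1", "distance_bp": d,
                              "r2": np.exp(-d / 100.0)})
        decay, summary = ld_decay_distance(pairs, r2_cut=0.1, bin_bp=10)
        assert decay == pytest.approx(100 * np.log(10), abs=10)
        assert not summary.empty

    def test_all_high_ld_is_right_censored(self):
        import pandas as pd
        pairs = pd.DataFrame({"chrom": "1", "distance_bp": [10.0, 20.0],
                              "r2": [1.0, 1.0]})
        decay, _ = ld_decay_distance(pairs)
        assert np.isnan(decay)

    def test_degenerate_cutoff_returns_first_bin(self):
        import pandas as pd
        pairs = pd.DataFrame({"chrom": "1",
                              "distance_bp": [5.0, 8.0, 2000.0],
                              "r2": [0.9, 0.8, 0.1]})
        decay, _ = ld_decay_distance(pairs, r2_cut=1.0, bin_bp=100)
        assert decay == pytest.approx(6.5)

    def test_block_genotypes_show_decaying_ld(self):
        variants, _ = simulate_ld_genotypes(n_samples=100, n_snps=100,
                                            block_snps=10, noise=0.02, seed=4)
        records = [VariantRecord(v["chrom"], v["pos"], v["ref"], v["alt"],
                                 v["genotypes"]) for v in variants]
        pairs = ld_r2_adjacent(records, k=10)
        near = pairs[pairs["distance_bp"] <= 1000]["r2"].mean()
        far = pairs[pairs["distance_bp"] > 3000]["r2"].mean()
        assert near > 0.5 > far


class TestPruneAndKinship:
    def test_prune_drops_correlated_neighbour_keeps_distant_copy(self):
        gts = (0, 1, 0, 1, 1, 0, 0, 1)
        close = [_variant(pos=1000, gts=gts), _variant(pos=2000, gts=gts)]
        assert len(ld_prune(close)) == 1
        far = [_variant(pos=1000, gts=gts), _variant(pos=601_000, gts=gts)]
        assert len(ld_prune(far)) == 2

    def test_prune_keeps_independent_snps(self):
        rng = np.random.default_rng(6)
        vs = [_variant(pos=1000 * (s + 1),
                       gts=tuple((rng.random(80) < 0.5).astype(int)))
              for s in range(30)]
        assert len(ld_prune(vs)) == 30

    def test_duplicate_sample_removed_exactly_once(self):
        rng = np.random.default_rng(7)
        g = (rng.random(300) < 0.5).astype(np.int8)
        G = np.column_stack([g, g, (rng.random(300) < 0.5).astype(np.int8)])
        kept = kinship_filter(G, ["dup1", "dup2", "other"], seed=0)
        assert len(kept) == 2
        assert "other" in kept
        assert ("dup1" in kept) != ("dup2" in kept)

    def test_unrelated_panel_untouched(self):
        rng = np.random.default_rng(8)
        G = (rng.random((500, 6)) < 0.5).astype(np.int8)
        kept = kinship_filter(G, [f"s{i}" for i in range(6)], seed=0)
        assert len(kept) == 6

    def test_related_trio_resolves_deterministically(self):
        # a trio of near-copies embedded in a diverse panel: every trio
        # pair exceeds the threshold, so members are removed until none does
        rng = np.random.default_rng(9)
        base = (rng.random(400) < 0.5).astype(np.int8)
        cols = []
        for _ in range(3):
            g = base.copy()
            flips = rng.random(400) < 0.05
            g[flips] = 1 - g[flips]
            cols.append(g)
        for _ in range(12):
            cols.append((rng.random(400) < 0.5).astype(np.int8))
        G = np.column_stack(cols)
        names = ["x", "y", "z"] + [f"u{i}" for i in range(12)]
        K = ibs_kinship(G)
        assert np.all(K[np.triu_indices(3, 1)] > 0.5)
        kept_a = kinship_filter(G, names, seed=4)
        kept_b = kinship_filter(G, names, seed=4)
        assert kept_a == kept_b
        assert sum(1 for s in ("x", "y", "z") if s in kept_a) == 1
        idx = [i for i, s in enumerate(names) if s in kept_a]
        K_kept = ibs_kinship(G[:, idx])
        assert np.all(K_kept[np.triu_indices(len(idx), 1)] <= 0.5)
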