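# Methods

This note documents the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Scaled units and physical conversion

All demographic models are parameterized in diffusion-style scaled
units: deme sizes ν relative to the ancestral effective size *Na*,
epoch durations τ in units of 2·*Na* generations, and migration as the
scaled rate M = 2·*Na*·m, where m is the per-generation proportion of a
deme replaced by migrants. The scaled mutation supply θ = 4·*Na*·μ·L
links a fit to physical units: *Na* = θ̂/(4μL), sizes ν·*Na*, durations
τ·2·*Na* generations. The generation time is fixed at one year
(appropriate for maize), so generations and years are interchangeable
throughout. The defaults μ = 2.230×10⁻⁸ per bp per generation
(synonymous-site substitution rate, i.e. 4.794×10⁻⁸ scaled by the
nonsynonymous-to-synonymous ratio) and L = 3.8 Mbp (effective exonic
length after 2 kb thinning) are the constants the maize analysis used;
both are ordinary function arguments everywhere.

Migration units deserve a flag: printed migration values are carried as
the scaled M (so "4.3×10⁻³" is M, dimensionless), and
`PhysicalParams.migrant_proportion` exposes m = M/(2·*Na*) alongside.
This is the convention in which a diffusion-based fit reports its
migration parameter; the code never silently rescales it.

## Model catalogue

Single-population: `neutral` (constant size), `two_epoch` (one
instantaneous size change), `three_epoch` (a bottleneck of finite
duration followed by a recovery size). Two-population, all with a
single ancestral deme and symmetric migration after the split:
`split1` (instantaneous sizes at the split), `split2` (adds a pre-split
size change), `split3` (adds a post-split NSS size step), `split4`
(pre-split bottleneck recovering exponentially to the ancestral size),
and `split5`, the headline history: a short bottleneck (ν_b, τ₁), an
instantaneous split to (ν₁, ν₂) held constant for τ₂ with migration M₁,
then linear decline to (ν₁ₑ, ν₂ₑ) over τ₃ with migration M₂.

Two modelling choices were genuinely open and are fixed as follows. The
sizes during the constant post-split stage are the onset sizes (ν₁, ν₂)
themselves — "recovery" is represented by the jump from the bottleneck
size at the split, since only onset sizes and the stage duration are
identified. And the TS onset size is not an independent datum: it is
the published onset total minus the temperate founder size
(10,746 − 1,312 = 9,434), recorded as derived.

The declared nesting graph for likelihood-ratio testing is
neutral ⊂ two_epoch ⊂ three_epoch and split1 ⊂ {split2, split3, split4},
split1/split2 ⊂ split5. split3's instantaneous step and split4's
exponential recovery are not exact sub-models of split5's linear
decline as parameterized, so they are compared with split5 by AIC only.

## Expected SFS: Monte Carlo engine and exact oracle

The expected joint SFS under a timeline comes from expected
genealogical branch lengths: E[S(i,j)] = (θ/2)·E[T(i,j)], with T(i,j)
the total length (scaled units) of branches subtending i population-1
and j population-2 leaves. E[T] is estimated by simulating the
structured coalescent backwards in time: per-pair coalescence at rate
1/ν_k(t) in deme k, backward migration of a deme-i lineage into deme j
at rate M_ij/2. Linear and exponential size trajectories are handled by
thinning against a per-epoch bound from the epoch's extreme size, so
the time-inhomogeneity is exact, not discretized; the engine raises if
an instantaneous rate ever exceeds the bound in use. Replicates use
independent seeded substreams (a `numpy` `SeedSequence` per replicate);
plain independent replicates were chosen over antithetic coupling
because no clean antithetic pairing exists for a thinned jump chain and
replicate count is cheap. With a fixed seed the estimate is bit-stable
and varies continuously with the parameters (common random numbers),
which is what the optimizer requires of its objective. Per-cell Monte
Carlo standard errors accompany every estimate.

The independent oracle solves the same quantity exactly for
piecewise-constant timelines and n₁+n₂ ≤ 6: the ancestral process is a
finite Markov chain on lineage configurations (multisets of
deme-tagged (i, j) blocks); expected per-class occupancy times are time
integrals of the state distribution, computed per epoch with an
augmented matrix exponential and, for the infinite ancestral epoch,
with the fundamental matrix of the absorbing chain. The test suite
checks the two engines against each other over randomized histories and
against closed forms (θ/i neutral spectrum, E[T] = 2 for a pair,
panmictic limits at zero split age and at M = 100, where the residual
deviation from the merged-population spectrum is under the documented
5%).

Absorbing corner cells (all-ancestral, all-derived) are always masked:
SNP-ascertained data carry no information about them and the composite
likelihood must not count them.

## Composite likelihood, optimization, model selection

The Poisson composite log-likelihood is Σ S·ln M − M − ln S! over
unmasked cells. θ scales M linearly, so its profile MLE is
θ̂ = ΣS/ΣM₁ against the shape at θ = 1; the optimizer therefore
searches only the demographic parameters, by Nelder–Mead on
log-transformed values clipped to positive bounds (soft quadratic
penalty outside). At least two starts one order of magnitude apart are
required — the exhaustive-start strategy — and the best of all starts
is returned with its full trace; a best fit on a bound is flagged, not
fatal. Defaults: log-likelihood tolerance 10⁻⁸, at most 10⁴
evaluations per start. Cells where the model predicts zero but data
were observed yield −∞ rather than an exception; inside the optimizer
that becomes a large finite penalty so the simplex stays well-defined.

Nested pairs are compared by the likelihood-ratio statistic against the
χ² upper tail with df equal to the free-parameter difference. One
caution, verified by simulation in the test suite: for every nested
pair in this family the null sits on a non-identifiable ridge of the
alternative (e.g. neutral is two-epoch with ν = 1 and τ arbitrary), so
Wilks' conditions fail and the χ²-referenced test is conservative —
its measured type-I error at α = 0.05 is ≈ 0.026 rather than 0.05, and
this is a property of the statistic, not of the optimizer (more starts
and tighter tolerances leave it unchanged). The test remains valid
(never anti-conservative); no mixture correction is applied, and
p-values near a boundary should be read as conservative. AIC = 2k − 2ℓ
handles non-nested comparisons; bootstrap confidence intervals are
parametric (cellwise Poisson resampling of the fitted expectation,
refit, percentile interval) — the "bootstrap" is deliberately
parametric because the unit of resampling for an SFS is the cell count,
and the flavour is recorded here and in the fit metadata. Anscombe
residuals r = 1.5·(S²ᐟ³ − M²ᐟ³)/M¹ᐟ⁶ visualize per-cell misfit on a
variance-stabilized scale.

## Observed-SFS construction

Inbred lines are treated as one haplotype each: homozygous diploid
calls collapse, heterozygous calls become missing at that site — the
panel is inbred and residual heterozygosity is noise. The chain is
synonymous filtering (from a designated `ANNCLASS` INFO key), BED
exclusion of selected regions ([start, end) half-open, 0-based,
removing 1-based positions start+1..end), replicated distance thinning,
and per-site hypergeometric projection. Thinning visits variants in an
independent random order per replicate and greedily accepts any variant
at least 2 kb from every accepted neighbour, yielding maximal spaced
subsets that differ across replicates but are bit-identical given
(seed, replicate index). Projection to (60, 60) haplotypes — 60 per
population, the reading adopted for the study's "projected to 60
samples" — absorbs missing data: each site's allele counts among
non-missing haplotypes are spread over the projected cells with
hypergeometric weights; sites with fewer callable haplotypes than the
projection size are dropped and counted. Polarization defaults to
folded (minor-allele), since no ancestral-allele source is assumed;
unfolded accumulation is available when the alternate allele can be
read as derived, and folding after projection is exact because the
hypergeometric weights are symmetric under allele relabeling.

## Population statistics

Fst is the ratio-of-sums Weir–Cockerham estimator specialized to
haploid-coded samples, where the within-individual component is
structurally zero: per site, the among-population component
a = (MSB − MSW)/n_c and total w = a + MSW from the two-level ANOVA of
allele frequencies; a window's Fst is Σa/Σw over its usable sites, and
windows are sliding (1 Mb, 0.2 Mb step) with the "more than 30
segregating sites" support rule read strictly. Fixed differences give
exactly 1; identical frequencies give ≈ 0; simulated divergence sweeps
confirm monotonicity in split age.

Population-specific SNPs follow the balanced-subsampling design
(50 per population, 10 replicates): a SNP is specific when polymorphic
in exactly one population's draw, rare when its within-draw MAF ≤ 0.05
(boundary inclusive). LD r² is the squared allele-frequency correlation
over pairwise-complete samples for each SNP against its next ten
neighbours; decay distance is the mean distance of the first
distance-ordered bin whose mean r² falls to the 0.1 cutoff (bin width a
documented parameter, 1 kb by default), with per-r²-category distance
quartiles emitted for boxplots — the exact binning behind the study's
categorized boxplots is unspecified, so this definition is the
package's own, stated choice. Kinship is a method-of-moments estimator
from IBS sharing, centred by its unrelated expectation under sample
allele frequencies, φ = (IBS − e₀)/(1 − e₀): duplicates score 1,
unrelated pairs ≈ 0, and the 0.5 filter removes one random member of
the most-related pair until none remains.

## IBD post-processing

Genetic maps are piecewise-linear in both directions; positions outside
the anchored range extend the terminal slope and are flagged.
Consensus across detector runs is majority coverage — a base pair
belongs to the consensus when covered in strictly more than half of the
runs — with the threshold configurable and recorded. One property a
majority consensus does *not* have: its total covered length can exceed
that of the smallest run (a tract present in exactly 6 of 10 runs may
be absent from the smallest); the bounds that do hold (unanimity
consensus ≤ every run; any consensus within the union) are the ones
tested. Segments shorter than 1 cM are dropped (background LD);
"long" tracts are those strictly over 7 cM. Hotspot occurrence tiles
each chromosome from 0 cM in 10 cM windows (terminal partial windows
kept and flagged) and counts a segment once in every window its cM
interval overlaps, divided by the number of sample pairs — C(n,2)
within a population, n₁·n₂ across. The selection-overlap test takes the
top 5% of windows by occurrence (ties broken by genomic order), scores
the fraction overlapping any selected region, and compares against
redraws of the same number of windows uniformly without replacement,
with the add-one permutation p-value; planted-enrichment and
super-uniformity simulations back both directions.

## Synthetic data: what it emulates, what it does not

The genotype generator draws site configurations multinomially from the
normalized expected joint SFS at the panel's haploid sizes and assigns
carriers uniformly — sites are unlinked and exchangeable, exactly the
regime the composite likelihood assumes. It guarantees ≥ 2 kb spacing
(slot grid of 3 kb with sub-slot jitter), labels ~24% of sites
synonymous, and plants ~5% of each chromosome as "selected" BED
regions so the filtering stages do real work. Panels default to 80
lines per population, ten chromosomes, and a 0.7 cM/Mb map baseline
with ±30% jittered increments — the study's conditions at desk scale.
What it does not emulate: linkage between SFS-destined sites (a
separate block-copy generator produces LD-bearing genotypes for the LD
statistics), genotype-calling error, ascertainment bias, or population
structure within the two panels. Passing tests therefore demonstrate
correctness of the estimators under their own assumptions, not
robustness to real-data artifacts. IBD tables draw per-pair segment
counts as Poisson, lengths as exponential in cM (the first-order model
for tract lengths given a recent common ancestor), placement uniform in
genetic distance with configurable hotspot enrichment; correlated
"detector runs" derive from one base set by random dropping and
endpoint jitter, as repeated detection on the same genotypes behaves.

## The recovery experiment

The study's genotypes are not redistributable, so the pipeline is
validated by self-consistency at the published best fit: generate the
expected 20×20 joint SFS under the split5 history at the published
physical values, then refit one parameter (or the two onset sizes
jointly) with every other parameter fixed at its generating value, and
convert back to physical units. Data and model spectra are evaluated
with the *same* Monte Carlo configuration — common random numbers at
matched resolution. This choice is substantive: the engine this Monte
Carlo stands in for (a diffusion-style expected-SFS solver) is
deterministic, and its self-consistency experiment has no realization
noise; with independent seeds the weakly identified bottleneck size
drifts by over 100% at 10⁵ replicates because its likelihood signal (a
~2% per-pair coalescence probability during five generations) is
smaller than the Monte Carlo noise. With matched noise the experiment
tests what it should — that timeline construction, the likelihood,
profiling, optimization and unit conversion jointly invert the model
map — and recovers *Na* ≈ 24,162, onset total ≈ 10,746, the 65%
temperate decline and the 142-individual bottleneck to well under a
percent. It does not measure estimator sampling variance at study
scale; that would require the full-data experiment the original panel
supported. Problem sizes: 20×20 haplotypes (439 unmasked cells), 10⁵
replicates per spectrum in `scripts/acceptance.py`, 4×10⁴ in the test
suite; both pass the same tolerances.

## Known limitations

- The composite likelihood ignores linkage; its variance is understated
  and no Godambe-style correction is applied.
- χ²-referenced LRTs between these nested models are conservative (see
  above); model choice in the pipeline should lean on AIC when the
  candidates are not cleanly nested.
- The Monte Carlo engine's cost grows roughly quadratically with sample
  size; for spectra much beyond ~60×60 haplotypes a diffusion or
  moments solver would be the right tool.
- The exact oracle is limited to six haplotypes and piecewise-constant
  epochs by state-space growth; it is a correctness anchor, not a
  production path.
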