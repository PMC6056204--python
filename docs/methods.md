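# Methods

This note documents the models, estimators, and numerical choices behind
`linkedsel`, and what the synthetic-data tests do and do not establish.

## Scientific setting

Background selection (BGS) — the removal of neutral variation linked to
deleterious mutations — reduces diversity most where the density of selected
sites is high and recombination is low. The per-position coefficient `B`
summarizes this as the fraction of neutral diversity expected to survive
(`B ≈ π/π0 ≈ Ne/N0`); `B → 0` means strong BGS. The package measures how a
population's demographic history (bottlenecks, expansions, migration)
modulates the *realized* diversity reduction across the `B` spectrum, using
three coordinated components: an empirical pipeline (diversity, singleton
density, F_ST as functions of `B`), a forward Wright–Fisher simulator of a
canonical BGS design under a three-population out-of-Africa (OOA) model, and
a synthetic-data generator with closed-form expectations.

## Empirical pipeline

**Site universe.** All statistics operate on the intersection of
user-supplied "include" filter tracks minus the union of "exclude" tracks
(the neutral mask), further intersected with `B`-quantile bins. Coordinates
are 0-based half-open (BED) throughout; VCF positions are converted on
ingestion. Positions lacking a `B` value are excluded from every
`B`-conditioned statistic. Quantiles of `B` are per-base (length-weighted),
since `B` annotates positions, not intervals. The low-`B` bins (lowest 1, 5,
10, 25%) are nested; the 50 bins used for F_ST profiles are disjoint 2%
quantiles whose regression x-value is the mean of the two bounding `B`
values.

**Hotspot/gBGC filters.** The hotspot rule excludes every position within
1.5 kb of a map interval with rate ≥ 10 cM/Mb (distance measured from any
base of the interval by default; a midpoint mode is provided because the
convention is ambiguous), plus a 3-kb window centered on each annotated
hotspot midpoint — except hotspots longer than 3 kb, which are excluded
as-is.

**Diversity.** Per-site pairwise diversity is `2x(n−x)/(n(n−1))` for derived
or alternate count `x` among `n` called chromosomes; monomorphic retained
sites count in the denominator, so `π` is per-site, not per-SNP. Statistics
are accumulated in non-overlapping 100-kb windows; a window is retained only
if it carries ≥ 10 kb of informative outgroup alignment, and the same
retained-window universe is used whether or not divergence normalization is
applied. Bin-level normalized diversity is a ratio of aggregates
(`Σπ/Σsites` over `Σdiff/Σaligned`), which is stable when single windows are
sparse; a per-window-mean mode exists for sensitivity analysis. The headline
statistic is relative diversity `π/π_min`: the lowest-`B` bin's normalized
diversity over the highest-1% bin's.

**Singleton density.** `ψ` is the expected number of derived singletons per
polarizable site after projecting each site's sample to a common size `m`
(170 chromosomes for the real cohorts, the smallest population) with the
hypergeometric expectation; projection also absorbs per-site missingness.
Only sites with high-confidence ancestral calls (uppercase annotation)
enter numerator or denominator. `ψ/ψ_min` is the analogous low/high-`B`
ratio.

**HWE filter.** The exact conditional test (summing heterozygote
configurations no more probable than observed, given allele counts) with a
Bonferroni threshold `α/m`, `m` defaulting to the number of SNPs tested. The
exact test is preferred over chi-square because it is well defined at all
counts.

**F_ST.** Per-site Hudson components
`N_h = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)`,
`D_h = p1(1−p2) + p2(1−p1)`, combined across SNPs as `ΣN_h/ΣD_h` (ratio of
averages). SNPs may be ascertained as polymorphic in an outgroup panel
(≥ 1 ref and ≥ 1 alt call) to remove discovery bias. Sites monomorphic in
both populations of a pair are skipped (they contribute zero to both sums).
The profile F_ST(`B`) over the 50 disjoint bins is summarized by OLS
`F_ST = β0 + β1 B + ε` with Pearson `r`; coefficient p-values are two-sided
t-tests. Robust regression is intentionally out of scope.

**Uncertainty.** All SEMs come from a block bootstrap over the 100-kb
windows — windows, not sites, are the exchangeable unit, preserving local
linkage disequilibrium. Each replicate resamples windows with replacement
(to the observed window count for diversity; optionally to the total
autosomal window count for F_ST, following the genome-wide convention) and
recomputes the statistic end to end, including the per-bin ratio of
averages and the regression. The SEM is the SD (ddof = 1) of the replicate
distribution; undefined replicates are recorded as missing and excluded
with a warning. A single seed streams per-replicate sub-seeds.

## Demographic model

A 13/14-parameter three-population topology: ancestral African expansion,
an OOA bottleneck founding a Eurasian population B with symmetric
African–B migration, then a European/East-Asian split with founding
bottlenecks, exponential growth, and pairwise migration. Times are
generations before present; sizes are diploid; the 25 y generation time is
used only for year axes.

The default parameter values are a reconstruction: the published Gutenkunst
et al. (2009) YRI/CEU/CHB fit, uniformly rescaled so that two anchors hold
exactly — ancestral size 18,449 diploids and oldest event 22,117
generations ago. Sizes scale by 18449/7300 and times by 22117/8800
(factors that agree to 0.6%, supporting the reconstruction); migration and
growth rates scale inversely so 2Nm and total growth are preserved. Any
fitted model can be supplied as YAML instead.

`rescale(model, Q)` divides sizes and times by `Q` and multiplies
per-generation rates by `Q`; together with multiplying mu, r, and s in the
simulation configuration, all coalescent-scale compound parameters (theta,
rho, 2Ns, 4Nm) are invariant — the standard trick that makes forward
simulation affordable on one core.

## Forward BGS simulator

Design: a 30-kb neutral core flanked by two 1-Mb blocks in which a fraction
`f_del = 0.2046` of sites is deleterious (the functional density of the
most strongly affected 2-Mb region of the human genome: 270,348 conserved
non-coding + 138,923 coding bp of 2 Mb). Deleterious fitness effects are a
two-component gamma mixture — 66.06% conserved non-coding
(α = 80.11, β = 0.0415 unscaled) and 33.94% coding (α = 6.25, β = 0.184) —
read as gamma(shape α, rate β) on the source studies' 2N-scaled axis per
the stated moments mean = α/β, variance = α/β², then divided by the source
2N (α_unscaled/α_scaled ≈ 15,536). Because this conflicts with the common
literature convention in which 0.184 is the *shape* of the coding DFE, the
parameterization is isolated in `DFESpec` and both conventions are
selectable (`convention="moments"` default, `"shape"` alternative with the
same mean). Mutation rate 1.66e-8 for both selected and neutral sites;
uniform crossover rate 8.19e-10 per bp per generation
(rho = 4·18449·r = 6.04e-5 at the reference size).

Engine: discrete generations; fitness multiplicative across sites with
heterozygote factor `1 + hs`, homozygote `1 + s`, dominance `h = 0.5` by
default (genic selection; the design is agnostic, so `h` is configurable);
fitness-weighted multinomial parent sampling; per-gamete Poisson crossovers
at uniform positions; Poisson infinite-sites mutation, with per-site
classes assigned i.i.d. at replicate start and neutral mutations tracked
only in the core (flank-neutral mutations cannot affect core diversity and
would dominate memory); binomial migrant exchange with expectation `mN`
per generation; splits founded by sampling diploids from the source
population. Haplotypes are sparse mutation-id sets sharing storage between
identical gametes, so per-generation cost scales with segregating mutation
copies, not sequence length. Mutations fixed in every population are
pruned (they rescale all fitnesses equally). Selection coefficients whose
Q-rescaled magnitude exceeds 1 are clamped to lethal; at the desk scales
used here (Q = 60–100) the conserved-non-coding component is largely
clamped, which weakens its contribution relative to the full-scale design —
one reason desk-scale π/π0 levels are not expected to match full-scale
values quantitatively.

Sampling: `sample_size` chromosomes (100 at full scale; 24–40 at desk
scales so the bottlenecked populations remain larger than the sample) are
drawn every `output_interval` generations (100 at full scale) and at every
demographic event; core π, singleton density ψ, and segregating sites are
recorded per replicate. π/π0 and ψ/ψ0 are ratios of across-replicate means
between the BGS run and a matched neutral control (core only, f_del = 0,
identical schedule).

Burn-in: 10·N_anc generations at the (rescaled) ancestral size by default.
Desk-scale runs in the tests and acceptance script use 4·N_anc (one
coalescent unit): neutral diversity then reaches ≈ 86% of equilibrium and
keeps equilibrating slowly through the model epoch, so absolute π/π0
levels sit below their equilibrated values; rank orders and responses to
f_del, bottlenecks, and migration are insensitive to this truncation,
which is why the desk checks are framed as contrasts rather than absolute
levels.

Problem sizes used by the shipped tests and acceptance script (chosen to
fit a single-core run): rescaling Q = 80–100, 24–150 replicates per arm,
24–32 sampled chromosomes, burn-in 4·N_anc. At these sizes the
full-scale published-style quantities (e.g. final π/π0 ≈ 0.43/0.42/0.41
with 2,000 replicates) are not reproducible at their printed precision;
the corresponding checks are qualitative (ordering, monotonicity,
trajectory shape), and the full-scale configuration remains available
through `SimulationConfig` defaults.

## Synthetic-data generator

The generator emulates the pipeline's inputs with known truth: constant-`B`
10-kb segments with `B ~ Beta(2, 1)`; segregating-site intensity
`θ·a_n·B` per bp (θ = 1e-3), making per-site diversity proportional to `B`
as BGS would; ancestral derived-allele frequencies from the neutral `1/p`
density; population frequencies from the Balding–Nichols model with
`F(B) = 0.10 + 0.03(1−B)` so drift is stronger where BGS is strong;
an outgroup panel (13 diploids) drifting independently at F = 0.05, so
ascertainment removes a realistic fraction of sites; divergence ~6% per
window, `B`-independent by default (a flag couples it to `B` to exercise
the normalization, since in real data divergence is not independent of
BGS); random exclude masks; 90% high-confidence ancestral calls; 1%
missing genotypes. Expectations follow in closed form
(`E[π/π_min] = B̄_low(1−F(B̄_low)) / (B̄_high(1−F(B̄_high)))`,
`E[F_ST|bin] ≈ F(B̄_bin)`, `E[β1] = −F_slope`) and are serialized in a
truth manifest next to the dataset.

What passing recovery tests shows: the pipeline's binning, estimators,
normalization, ascertainment, and bootstrap are internally consistent and
unbiased under a model where the generator's assumptions hold. What it
does not show: robustness to real LD structure, real mask geography, the
McVicker `B` landscape, sequencing artifacts, or model misspecification —
the generator has none of these.

Balding–Nichols was chosen over a coalescent generator for speed and
closed-form expectations; the simulator module provides the
coalescent-grade alternative where genealogical realism matters.

## Numerical choices and degenerate inputs

- Interval arithmetic is exact integer endpoint manipulation; adjacent
  intervals merge; value tracks never merge (values may differ).
- Degenerate `B` maps (constant value) collapse the 2% binning to a single
  occupied bin by convention (first bin closed below).
- Hypergeometric projection uses scipy's pmf; mass is conserved to 1e-9
  and projection composes (n→m→k = n→k).
- The HWE test sums probabilities ≤ observed·(1+1e-12) to make ties robust
  to floating-point noise; p ∈ (0, 1].
- Ratio statistics raise on empty bins / zero denominators; inside the
  bootstrap such replicates become missing values, are excluded from the
  SEM, and are counted in a warning.
- Simulator RNG: one `SeedSequence` per run spawns independent per-replicate
  streams; the same configuration and seed reproduce results exactly.

## Known limitations

- Forward runs at large Q clamp strong selection coefficients at lethality
  and coarsen bottleneck sizes to a few tens of diploids; desk-scale π/π0
  levels are therefore systematically offset from full-scale runs.
- The migration-driven decline of African π/π0 is not reproduced at desk
  rescaling: with the conserved-non-coding DFE component clamped to
  lethality and the founding bottlenecks coarsened to tens of diploids,
  the dominant effect of migration on African core diversity becomes the
  injection of diverged (if less diverse) lineages, which slightly raises
  π/π0 instead of lowering it. The migration-contrast test encodes the
  full-scale expectation and is expected to fail at desk scale;
  confirming the full-scale behavior needs near-unrescaled runs.
- The empirical pipeline accepts real cohort inputs (TGP-scale VCFs, a B
  bedGraph, mask BEDs, an outgroup VCF, divergence tables) but the shipped
  tests exercise it only on synthetic data.
- Local-ancestry analyses, sweep scanning, liftOver, and the
  ancestral-misidentification correction are out of scope.
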