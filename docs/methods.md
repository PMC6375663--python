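# Methods

This note records the models, defaults and numerical choices behind
`erpoly`, and what the synthetic-data tests do and do not demonstrate.

## The experimental design being emulated

All defaults describe a replicated laboratory-adaptation experiment in
*Drosophila simulans*-like conditions: ~200 founder haplotypes, 10
replicate populations, pooled sequencing every 10th generation from 0 to
60, read depths of order 100–200×, and selected alleles with starting
frequencies mostly below 0.2 (up to 0.75) and selection coefficients of
roughly 0.02–0.14 riding large linked haplotype blocks. The census size of
such experiments is ~1,000, but the drift-relevant effective size is near
300; the simulators therefore use N = 300 diploids unless told otherwise,
and the temporal Ne estimator exists to measure that quantity from data.

## Wright–Fisher engines

`paradigms.wf_simulate` is the frequency-based engine: one deterministic
selection update with genotype fitnesses (1, 1+hs, 1+s), default h = 1/2,

    p' = [p²(1+s) + pq(1+hs)] / [p²(1+s) + 2pq(1+hs) + q²],

followed by binomial resampling of 2N allele copies. Trajectories absorb
at 0 and 1. The engine is validated against closed forms: neutral drift
variance `p₀q₀(1 − (1 − 1/2N)^t)` and Kimura's diffusion fixation
probability `(1 − e^{−2Nsp₀})/(1 − e^{−2Ns})` (the exponent uses s/2 per
allele copy, i.e. the codominant parameterization).

`paradigms.individual_simulate` is the haplotype-based engine used when
linkage matters: N diploids assembled from founder haplotypes, parents
sampled proportional to fitness, each transmitting one recombinant gamete.
Crossover counts per chromosome are Poisson with mean equal to the genetic
map length in Morgans; positions come from the inverse cumulative map; no
interference; chromosomes assort independently. No new mutation anywhere:
adaptation uses standing variation only. With the recombination rate set
to zero this engine is distributionally identical to `wf_simulate` (tested
by a two-sample KS at α = 0.01), which pins the two independent code paths
to each other. All chromosomes are treated as autosomal; the X chromosome
is handled at the scenario level by passing an X-specific Ne for X-linked
alleles rather than by hemizygous gametics.

## Synthetic data

`simulate.generate_founder_panel` places SNPs uniformly on a 100 bp grid
(guaranteeing a minimum spacing) and draws minor-allele counts from a
neutral-like weight ∝ 1/i over carrier classes; founders are independent
haplotypes. This deliberately ignores two features of real founders:
isofemale lines are partially inbred (internal structure), and real SNPs
are correlated through ancestral LD beyond the planted blocks. Passing
tests on this generator therefore demonstrates correctness of the
algorithms under the stated model, not robustness to cryptic population
structure.

`simulate.plant_blocks` makes ground-truth selected alleles: k = p₀·H
carrier haplotypes get allele 1 at every marker SNP inside the block span,
everyone else 0, so markers start in perfect association and p₀ is exact.
Blocks are placed non-overlapping with a default 1.5 Mb gap so each block
owns its clustering windows. In recovery tests the marker count scales
with block span (30 markers at 50 kb up to 80 at 1 Mb; real reconstructed
blocks carry a few hundred marker SNPs each), and weak-s blocks start at
higher p₀ while strong-s blocks start low, matching the observed
anticorrelation between starting frequency and estimated s in selected
alleles.

`simulate.simulate_experiment` evolves each replicate with the
individual-based engine (so markers ride their blocks until recombination
separates them) and sequences it through a `CoverageModel`: depth Poisson
around the mean (negative binomial if overdispersion is requested), reads
binomial from the population frequency, optionally with a
pool-of-individuals first stage (hypergeometric) to mimic pooling before
sequencing. A master seed fans out into named per-stage, per-replicate
streams (`numpy.random.SeedSequence` spawn keys), so founding, drift and
read sampling are independently reproducible.

## Candidate detection and the empirical FDR

The CMH statistic is the Mantel–Haenszel 1-df chi-square without
continuity correction, using the exact hypergeometric stratum variance
(n−1 denominator); strata with a zero margin are skipped. The Fisher test
is the exact two-sided hypergeometric sum. Both are implemented vectorized
(lookup-table log-factorials) because the empirical null requires 10⁵–10⁶
tables; scipy and statsmodels serve as per-table oracles in the tests.
With one stratum the CMH statistic equals the classical Pearson chi-square
times exactly (n−1)/n.

Because neither test models drift, significance comes from matched neutral
simulations: each SNP restarts at its observed ancestral replicate
frequency, drifts for the experiment duration at the estimated Ne, and is
re-sequenced at the observed coverages. The q-value of an observed p is
(the per-iteration mean count of null p ≤ p) / (count of observed p ≤ p),
clipped to [0, 1] and monotonized by a cumulative minimum from the largest
p downward. The convention choice inside the CMH (continuity, variance
denominator) cancels here, since observed and null statistics share it.

Coverage filters mirror standard Pool-Seq practice: the lower 1% tail on
total coverage, the upper 1% tail on the deepest library, and removal of
SNPs whose minor allele has fewer than 10 reads across the ancestral
samples. Fixed absolute bounds make the filter idempotent; quantile bounds
are recomputed per call.

## Temporal Ne

The per-SNP kernel is `Fc = (x−y)²/((x+y)/2 − xy)`. Within each window of
1,000 SNPs the estimator pools numerators and denominators before dividing
(the mean of per-SNP ratios is strongly biased by rare alleles), subtracts
the sampling expectations 1/depth at both time points plus 1/(2·pool size)
when a pooling stage applies (sampling plan I additionally subtracts
1/(2·census N)), and inverts `Ne = t/(2F′)`. Windows with F′ ≤ 0 are
reported infinite; SNPs fixed at both time points are excluded. The
correction structure is validated behaviorally — parameter recovery within
25% for true N ∈ {100, 300, 1000} — rather than by formula identity, since
the exact plan-I terms of the commonly used implementations are not
published. The linear inversion `t/(2F′)` understates Ne slightly when
t/(2N) is not small (about 15% at N = 100, t = 60).

## Block reconstruction

Rising-allele polarization uses the mean frequency change across
replicates between the first and last samples; exact ties go to the
lexicographically smaller nucleotide and are flagged. CMH candidates enter
clustering only if they rose ≥ 0.2 between some pair of time points in at
least two replicates; Fisher candidates enter unconditionally.
Trajectories are arcsin√p transformed and z-standardized per SNP over all
(replicate, generation) columns, including generation 0.

Clustering runs in 1 Mb windows stepped by 500 kb (≥ 20 candidate SNPs per
window, coordinates after optional chromosome-arm concatenation), on
average-linkage trees over `d = √(2(1−r))`. The cut descends from the
root, accepting the largest subtrees whose mean pairwise r meets the
threshold, then prunes members whose average correlation to the rest of
the cluster falls below that threshold (worst first) — without pruning, a
tight cluster's internal correlation can carry several unrelated SNPs
past the mean criterion. Clusters from overlapping windows merge when they
share ≥ 5 SNPs (union–find transitive closure); only merged clusters with
more than 20 SNPs are retained; a SNP left in several clusters goes to the
one it correlates with best. Round 1 uses r ≥ 0.75; all surviving SNPs are
re-windowed identically and re-clustered at r ≥ 0.35; the round-2 clusters
are the final blocks, with round-1 clusters attached as sub-clusters for
core-region analysis. Pairwise correlations are pairwise-complete over
masked cells with a 30-shared-column minimum (r treated as 0 below it).

Validation: a phased haplotype contains a block when its mismatched plus
missing marker fraction is ≤ 20% (≥ 80% identity); markers absent from the
panel count as missing.

Known limitation: markers decoupled by recombination that end up in
sub-threshold or ≤ 20-SNP round-1 clusters are lost to the block — with
sparse markers (tens per block) this costs a few percent of markers and,
rarely, splits a block.

## Selection inference

`estimate_s` clamps frequencies to [1/(2·coverage), 1 − 1/(2·coverage)]
(Pool-Seq zeros are sampling artifacts), fits the logit-linear closed form
(slope b ⇒ s = 2(e^b − 1), since the per-generation logit increment is
ln(1 + s/2) to first order), then refines by Nelder–Mead least squares of
the exact recursion jointly over (p₀, s) — fixing p₀ at the noisy first
observation attenuates s by ~10% at depth 100. A single N = 300 trajectory
carries ~40% drift noise in s, so the pipeline's reported value is the
median across the replicates in which the allele is present; recovery
tests score that quantity (~12% median relative error at s = 0.06).

Presence methods: (1) rise ≥ 0.1 at generation 60, inclusive; (2) ≥ 0.2;
(3)/(4) allele-specific thresholds at the lower 5%/10% quantile of the
frequency-change distribution from 1,000 Wright–Fisher sweep simulations
at the allele's p₀ with the highest per-replicate s (method-1 estimates)
and replicate-specific Ne; (5)/(6) methods 1/2 applied to the core region
— the round-1 sub-cluster with the largest median s (ties to the larger
sub-cluster, flagged; no qualifying sub-cluster falls back to the whole
block, flagged).

## Paradigm scenarios and comparison

All scenarios emit per-iteration RFS (classes 1..R; alleles absent
everywhere are excluded, with the class-0 count kept separately) and all
R(R−1)/2 pairwise Jaccard indices (two empty sets give J = 1 by
convention). Default scale mirrors the experiments: 99 alleles, 10
replicates, 60 generations, 1,000 iterations; tests run 100 iterations.

- **Sweep (no linkage)**: every allele simulated independently with its
  own p₀ and s in every replicate; X-linked alleles use the X-specific Ne.
- **Sweep (linked)** / **QT (linked)**: `individual_simulate` on founder
  haplotypes with the recombination map; selected sites placed at block
  marker positions.
- **Redundancy**: delete-d jackknife — each replicate receives a uniform
  random subset (without replacement) of the observed per-replicate count.
- **QT (no linkage)**: individuals' genotypes drawn per-locus binomially
  from current frequencies each generation (free recombination); phenotype
  = mean rising-allele dosage in [0, 1]; Gaussian fitness with floor 0.5,
  ceiling 4.5, optimum 0.6, width 0.3 on that scale. The linked QT mode
  instead standardizes the dosage sum by its generation-0 mean and SD, on
  which scale the optimum −1.3 and width 1.2 are interpretable; both
  scales are exposed because published parameter pairs exist on both.

Scenario fit to observed data uses the per-iteration
`SSE = Σ_k (obs_k − sim_k)²` over RFS classes; scenarios are ranked by
mean SSE, with one-way ANOVA (and optional Tukey HSD via statsmodels)
across scenario SSE distributions. Scoring by mean per-iteration SSE
rather than SSE-to-the-mean deliberately charges scenarios for their
dispersion as well as their bias.

## Numerical choices and degenerate inputs

- Exact Fisher p-values use the R-style (1 + 1e−7) tie tolerance.
- Degenerate 2×2 margins give p = 1; all-degenerate CMH strata give
  (χ² = 0, p = 1) with a flag.
- Frequencies are undefined (NaN) at zero coverage and excluded from row
  moments, correlations and medians.
- Blocks, clusters and polarization resolve all ties deterministically
  (position order, larger cluster, lexicographic nucleotide), so every
  pipeline stage is bit-reproducible for a fixed master seed.
- QT genotype draws use a single uniform per (individual, locus) with the
  thresholds (2p − p², p²), which has exact Binomial(2, p) marginals at
  half the RNG cost.

## Problem sizes in the test suite

Unit tests run on panels of 10²–10⁴ SNPs; end-to-end reconstruction tests
use three 4 Mb chromosomes with 9,000 SNPs, five planted blocks (spans
50 kb–1 Mb) and 20 seeds per condition; paradigm-discrimination tests use
99 alleles × 10 replicates × 100 iterations × 20 seeds. These sizes were
chosen so the statistical assertions (binomial/χ²/KS tolerances, 18-of-20
success counts) are well-powered while the whole suite stays desk-scale.
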