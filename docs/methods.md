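# Methods

## The landscape model

A genotype is a fixed-length string over per-site alphabets; two genotypes
are mutational neighbors when they differ at exactly one site. Given a
source and target word of equal length, the *biallelic* space restricts
each site to the source or target symbol, yielding a hypercube of `2^d`
genotypes for `d` differing sites; sites where the two words agree are
frozen (singleton alphabet). The *full-alphabet* space allows an arbitrary
alphabet per site (size `∏ |A_i|`, e.g. `26^4 = 456,976` for four-letter
English words); it is deliberately never materialized — only size queries
and one-mutant neighborhoods are supported — because nothing downstream
needs the full enumeration. Materialization is refused above `2^20`
genotypes and direct-path enumeration above `d = 10` (`10! ≈ 3.6M` paths);
both caps are far beyond the four-site spaces the device is built around.

Symbols are uppercased on ingestion (word frequencies are case-insensitive)
and all deterministic outputs are lexicographically ordered: hypercube
members, neighbor lists, and direct paths (by site permutation). A *direct
path* changes each differing site exactly once, toward the target; there
are exactly `d!` of them and their union covers the hypercube.

## Fitness: the word-frequency proxy

Fitness of word *w* in year *y* is its corpus usage frequency: the number
of appearances of *w* in books that year (summed over case variants)
divided by the year's total word count. It is a dimensionless relative
fitness; only ratios and orderings are used downstream, so no normalization
is applied at storage time. Years are opaque environment labels — any
ordered label set works. Words absent from the corpus get fitness 0 by
default; an optional pseudocount fill (`ε / total`) keeps log-scale
analyses finite. Smoothing across years is deliberately out of scope: the
stored values are raw per-year frequencies.

The CSV dialect (`genotype,environment,fitness`) writes floats with
`repr`, the shortest decimal string that reads back to the identical
double, so write-then-read round trips are exact.

## Accessibility, peaks, walks

A path is accessible when fitness *strictly* increases at every step
(default): a flat step cannot be favored by selection, so ties block. A
non-strict mode exists for exploration. A peak is a genotype with no
strictly fitter neighbor; peaks that have equal-fitness neighbors are
additionally flagged as plateau members rather than silently merged.
Accessibility is counted over direct paths only (the `d!` framing);
greedy walks — steepest ascent, lexicographic or seeded-random tie-break —
may roam the whole hypercube, which is how an off-path vertex such as WERE
in the WORD → GENE space is reached. `first_blocked_step` is 0-based on
steps (step *i* is the move from genotype *i* to *i + 1*).

All of these quantities depend only on fitness orderings and are therefore
invariant under strictly increasing transformations (checked by a property
test with log transforms).

## Wright–Fisher engine

Haploid, asexual, non-overlapping generations at fixed size `N`. Each
generation: selection (parental share ∝ count × fitness), mutation (each
offspring mutates independently at each site with probability `µ`,
switching to the alternative biallelic symbol, or uniformly among
alternatives at multi-allele sites; at most one event per site per
generation — Bernoulli per site, appropriate since `µ` is small in every
regime of interest), then multinomial resampling of `N` offspring. Because
offspring are i.i.d. (choose parent by fitness, then mutate), sampling the
multinomial over the mutation-convolved selection frequencies is the exact
per-individual process. The selection → mutation → resampling order is the
standard discretization; no canonical order is imposed by the model itself.

The mutation kernel is the product over sites of per-site transition
matrices and is built densely (spaces are capped at 4096 genotypes for
simulation — far above the 16-vertex canonical landscapes). A deterministic
infinite-`N` iterator applying the same selection-mutation update without
resampling is exposed for exact tests; with two genotypes and `µ = 0` it
reproduces the haploid selection recursion `p'_A/p'_B = (w_A/w_B)·p_A/p_B`
to machine precision.

All randomness flows from `numpy.random.default_rng(seed)`; identical
(config, table) pairs give bit-identical trajectories. Replicate ensembles
spawn child seeds via `SeedSequence`, so the whole ensemble is reproducible
from one integer. With `µ = 0` a monomorphic population is absorbing and
the run short-circuits.

Fixation is operationalized as reaching frequency ≥ 0.99 (configurable; the
neutral tests use 1.0 so that "fixed" means monomorphic), and the tunneling
detector asks whether the final genotype fixed while a named intermediate's
maximum frequency stayed below 0.05. The 0.99/0.05 defaults quantify
"fixes" and "never rises to appreciable frequency"; both are recorded in
simulation output metadata and configurable.

## Epistasis and environment interaction

Pairwise epistasis on background `f00` with single mutants `f10`, `f01` and
double mutant `f11` is the four-point interaction
`ε = log f11 − log f10 − log f01 + log f00`. The log scale is the default
because word frequencies span orders of magnitude and multiplicative
fitness is the natural null (ε = 0); a linear scale is available. Zero
fitness is an error on the log scale — the pseudocount fill belongs
upstream in the fitness module, never silently imputed here. Classification
uses the standard taxonomy: *none* when `|ε| ≤ 10⁻¹²` (floating-point noise
floor for computed fixtures), *magnitude* when ε ≠ 0 but both single-mutant
effects keep their direction across backgrounds, *sign* when exactly one
strictly reverses, *reciprocal sign* when both do. A zero effect is not a
reversal. The all-pairs scan covers every differing-site pair on every
background of the remaining sites (`C(d,2) · 2^(d−2)` results; 24 for
d = 4).

Genotype-by-environment interaction has no single canonical formula; this
package operationalizes it non-parametrically, in keeping with the
ordering-only character of accessibility: Spearman rank correlation of
genotype fitness between each environment pair, the list of genotype pairs
whose strict fitness order reverses, and the number of accessible direct
paths per environment.

## Synthetic data

The generators encode qualitative landscape *structures* (orderings), not
any external data values. Defaults: base fitness 1, per-matching-site gain
1.2× (additive archetype: fitness = base·1.2^m with m sites matching the
target — multiplicative across sites, hence ε = 0 everywhere and all paths
accessible), peak multiplier 10³ ("orders of magnitude" dominance of the
interior peak), source boost 1.5× above the best non-peak neighbor (so
every first step off the source is deleterious, selection coefficient ≈
0.33 against the stepping-stone intermediate — large enough that its
mutation-selection balance frequency `µ/s ≈ 0.003` at `µ = 10⁻³` sits well
below the 0.05 tunneling cap). The environment-flip archetype builds one
environment in which a designated direct path strictly climbs (off-path
genotypes below the source) and a second in which the source exceeds every
neighbor and the target. Every generator asserts its advertised ordering
before returning and fails loudly otherwise.

Synthetic n-gram corpus files realize a fitness table as integer counts
(`round(frequency × total)`, default total 10⁹, per-year rescaling so
frequencies sum to 0.5), split across two case variants to exercise
case-insensitive aggregation; rounding that would destroy a strict ordering
is an error. These fixtures emulate the file formats and the
orders-of-magnitude frequency spread of real corpus data; they do not
emulate temporal autocorrelation, OCR noise, or corpus-composition drift,
so passing tests demonstrate correctness of the machinery, not properties
of any real corpus.

## Problem sizes and simulation parameters

Canonical analyses use the four-site spaces (16 genotypes, 24 paths).
Simulation checks use `N = 10⁴`, `µ = 10⁻³`, 250 generations, 100
replicates for the tunneling ensemble (establishment of the double mutant
takes ~15 generations in expectation at these rates, so 250 generations is
ample), and `N = 100`, `µ = 0`, up to 3000 generations, 500 replicates for
neutral fixation (well past the ~2N-generation absorption scale; runs
short-circuit at monomorphism). The oracle-agreement check uses 50 random
landscapes with up to 6 differing sites (≤ 720 paths each).

## Known limitations

- Substitution-only moves: no insertions or deletions.
- No diploidy, recombination, overlapping generations or spatial structure.
- Accessibility counting weights all direct paths equally; fixation-
  probability-weighted path ensembles are out of scope.
- Higher-order (≥ 3-way) epistasis decompositions are not computed.
- No live corpus queries and no multi-word n-grams; per-year frequencies
  are used raw, without the viewer-style smoothing parameter.
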