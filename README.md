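# wordscape

Combinatorial fitness landscapes over word hypercubes: accessible
mutational trajectories, Wright–Fisher dynamics, epistasis, and
landscape-by-environment interaction.

## What this is for

A classic way to think about molecular evolution is as a word game: to get
from one meaningful sequence to another (say **WORD** to **GENE**), change
one letter at a time, and require every intermediate to be "viable". Fixing
a source and a target word of equal length and allowing, at each site, only
the source or target letter produces a biallelic hypercube of `2^d`
genotypes (`d` = number of differing sites) connected by single
substitutions — a miniature adaptive landscape of exactly the kind used in
empirical studies of protein evolution and antimicrobial resistance. Attach
a fitness value to every word and the game becomes quantitative: which of
the `d!` direct mutational paths are *accessible* (fitness strictly
increasing at every step), where are the local *peaks*, how strong is the
*epistasis* between sites, and what does an evolving population actually do
on the landscape?

`wordscape` implements this device as a reusable toolkit for teaching and
exploration in population genetics:

- **genotype spaces** (`wordscape.space`) — hypercube construction,
  one-mutant adjacency, enumeration of all `d!` direct paths, full-alphabet
  space sizes (e.g. `26^4 = 456,976` four-letter sequences) without
  materialization;
- **fitness** (`wordscape.fitness`) — per-environment fitness tables; the
  word-frequency fitness proxy (a word's appearances in a year's book
  corpus divided by the corpus' total word count, aggregated over case
  variants) parsed from n-gram export TSVs and totals files, with years
  acting as environments; plain `genotype,environment,fitness` CSVs for
  arbitrary proxies;
- **accessibility** (`wordscape.accessibility`) — per-path verdicts,
  strict peaks, greedy adaptive walks, ruggedness summaries; all verdicts
  depend only on fitness orderings;
- **evolution** (`wordscape.evolution`) — a haploid Wright–Fisher engine
  (fitness-proportional selection, per-site mutation, multinomial
  resampling at fixed `N`), with a deterministic infinite-`N` mode,
  replicate fixation-probability estimation, and stochastic-tunneling
  detection;
- **epistasis** (`wordscape.epistasis`) — the four-point interaction
  `ε = log f11 − log f10 − log f01 + log f00` with the
  magnitude/sign/reciprocal-sign taxonomy, all-pairs scans, and rank-based
  genotype-by-environment reports (Spearman correlations, order-flip
  events, per-environment accessibility);
- **synthetic data** (`wordscape.synth`) — landscape archetypes (additive,
  dominant interior peak, trapped source, environment flip) and synthetic
  n-gram corpus files, so every analysis runs without any download.

## Worked example

The canonical WORD → GENE landscape with a dominant interior peak on
**WERE** (three orders of magnitude fitter than everything else, and with
every single mutation away from **WORD** deleterious):

```bash
wordscape fixtures make --archetype dominant_interior_peak \
    --source WORD --target GENE --peak WERE --out fixture/
wordscape access report --landscape WORD GENE \
    --fitness fixture/fitness.csv --env 1900 --out-dir acc/
wordscape simulate --landscape WORD GENE --fitness fixture/fitness.csv \
    --env 1900 --n 10000 --mu 1e-3 --gens 250 --seed 42 --out-dir sim/
```

prints

```
wrote dominant_interior_peak fixture for WORD->GENE to fixture
0/24 direct paths accessible in environment 1900
final modal genotype: WERE
```

and `sim/summary.json` records

```
fixation_events: [{WORD, generation 0}, {WERE, generation 14}]
WORE max frequency: 0.0026
WERE max frequency: 0.9981
```

Read: none of the 24 direct WORD → GENE paths is selectively accessible
(the first step off WORD is always downhill), yet within 14 generations the
population has fixed the double mutant **WERE**. The stepping-stone
intermediate **WORE** never exceeds 0.3% frequency — stochastic tunneling:
at high mutation supply (`N·µ = 10`), rare deleterious intermediates seed a
far fitter double mutant that sweeps before the intermediate itself is ever
common.

The same machinery exposed in Python:

```python
from wordscape import LandscapeSpec, build_hypercube, enumerate_direct_paths

spec = LandscapeSpec.biallelic("WORD", "GENE")
len(build_hypercube("WORD", "GENE"))    # 16 genotypes
len(enumerate_direct_paths(spec))       # 24 direct paths
```

Other subcommands: `wordscape fitness build` (tables from n-gram corpus
files), `wordscape epistasis` (all-pairs scan), `wordscape gxe`
(environment interaction), `wordscape report` (layered trajectory figure).
Every command writes a `manifest.json` with parameters, seeds and input
digests; deterministic commands rerun byte-identically.

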