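import itertools

import numpy as np
import pytest

from wordscape import FitnessTable, LandscapeSpec
from wordscape.synth import FixtureSpec, make_landscape_fixture


@pytest.fixture
def word_gene_spec():
    return LandscapeSpec.biallelic("WORD", "GENE")


@pytest.fixture
def additive_table(word_gene_spec):
    series = make_landscape_fixture(
        FixtureSpec(source="WORD", target="GENE", archetype="additive")
    )
    return series[1900]


@pytest.fixture
def dominant_peak_table():
    series = make_landscape_fixture(
        FixtureSpec(source="WORD", target="GENE",
                    archetype="dominant_interior_peak", peak="WERE")
    )
    return series[1900]


@pytest.fixture
def gene_bird_flip_series():
    """Two-environment GENE->BIRD series: accessible early, frozen late."""
    return make_landscape_fixture(
        FixtureSpec(source="GENE", target="BIRD", archetype="env_flip",
                    path_sites=(0, 3, 1, 2))
    )


def brute_force_accessible_count(spec, table, strict=True):
    """Independent oracle: walk every site permutation by hand and check
    monotonicity of the fitness sequence directly."""
    n_ok = 0
    total = 0
    for order in itertools.permutations(spec.differing_sites):
        total += 1
        g = spec.source
        fitnesses = [table[g]]
        for site in order:
            g = g[:site] + spec.target[site] + g[site + 1:]
            fitnesses.append(table[g])
        if strict:
            ok = all(b > a for a, b in zip(fitnesses, fitnesses[1:]))
        else:
            ok = all(b >= a for a, b in zip(fitnesses, fitnesses[1:]))
        n_ok += ok
    return n_ok, total


def random_landscape(rng, max_d=6):
    """A random biallelic spec + fitness table with d <= max_d differing sites."""
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    d = int(rng.integers(1, max_d + 1))
    length = d + int(rng.integers(0, 3))
    src = "".join(rng.choice(list(alphabet), size=length))
    tgt = list(src)
    sites = rng.choice(length, size=d, replace=False)
    for s in sites:
        choices = [c for c in alphabet if c != src[s]]
        tgt[s] = choices[int(rng.integers(len(choices)))]
    spec = LandscapeSpec.biallelic(src, "".join(tgt))
    from wordscape.space import hypercube

    genotypes = hypercube(spec)
    values = {g: float(f) for g, f in
              zip(genotypes, rng.uniform(0.1, 10.0, size=len(genotypes)))}
    return spec, FitnessTable(environment="rand", values=values)
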