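"""Synthetic landscapes and synthetic n-gram corpus files.

Real word-frequency corpora are large external downloads; analyses and
tests instead run on synthetic fitness tables whose *orderings* encode the
qualitative landscape structures of interest.  Four archetypes are
provided:

``additive``
    Smooth multiplicative landscape, fitness = base * (1 + increment)^m
    where m counts sites already matching the target.  Every direct path is
    accessible and the unique peak is the target.
``dominant_interior_peak``
    Additive landscape with the source raised above all of its one-mutant
    neighbors (leaving the source is deleterious) and a named interior
    genotype multiplied by a large factor (default 1000, i.e. orders of
    magnitude fitter).  The canonical instance is WORD -> GENE with the
    double mutant WERE as the dominant peak: populations tunnel through the
    rare WORE intermediate and fix WERE.
``source_trapped``
    Additive landscape with only the source boost: the source is a local
    peak and no direct path leaves it.
``env_flip``
    Two environments.  In the first, a designated direct path from source
    to target is strictly increasing (accessible); in the second the source
    towers above every neighbor and above the target, so no direct path
    leaves it and the order of the named flip pair reverses.  The canonical
    instance is GENE -> BIRD: accessible via BENE/BEND/BIND in the early
    environment, frozen on GENE in the late one.

Every generator asserts its advertised ordering before returning, so a
parameter combination that breaks the structure fails loudly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Optional, Sequence

from .fitness import EnvironmentSeries, FitnessTable
from .space import LandscapeSpec, hypercube, one_mutant_neighbors

__all__ = [
    "FixtureError",
    "FixtureSpec",
    "make_landscape_fixture",
    "make_ngram_files",
    "ARCHETYPES",
]

ARCHETYPES = ("additive", "dominant_interior_peak", "source_trapped", "env_flip")


class FixtureError(ValueError):
    """Fixture parameters that break the archetype's advertised ordering."""


@dataclass
class FixtureSpec:
    """Recipe for a synthetic landscape series.

    Magnitude parameters: ``base`` is the source-level fitness,
    ``increment`` the per-matching-site multiplicative gain,
    ``peak_multiplier`` the dominance factor of the named interior peak and
    ``source_boost`` the factor by which a trapped source exceeds its best
    neighbor.  ``peak`` names the dominant interior genotype
    (dominant_interior_peak only); ``path_sites`` fixes the site order of
    the accessible path (env_flip only; default: sites in index order);
    ``flip_pair`` names the two genotypes whose order must reverse between
    the two environments (default: first path intermediate vs source).
    """

    source: str
    target: str
    archetype: str
    base: float = 1.0
    increment: float = 0.2
    peak_multiplier: float = 1e3
    source_boost: float = 1.5
    peak: Optional[str] = None
    path_sites: Optional[tuple[int, ...]] = None
    flip_pair: Optional[tuple[str, str]] = None
    environments: Optional[Sequence] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise FixtureError(
                f"unknown archetype {self.archetype!r}; choose from {ARCHETYPES}"
            )
        self.source = self.source.upper()
        self.target = self.target.upper()
        if self.peak is not None:
            self.peak = self.peak.upper()
        if self.base <= 0 or self.increment <= 0:
            raise FixtureError("base and increment must be positive")
        if self.peak_multiplier <= 1 or self.source_boost <= 1:
            raise FixtureError("peak_multiplier and source_boost must exceed 1")


# ----------------------------------------------------------------------
def _matches_to_target(g: str, target: str) -> int:
    return sum(a == b for a, b in zip(g, target))


def _additive_values(spec: LandscapeSpec, fspec: FixtureSpec) -> dict[str, float]:
    return {
        g: fspec.base * (1.0 + fspec.increment) ** _matches_to_target(g, spec.target)
        for g in hypercube(spec)
    }


def _boost_source(values: dict[str, float], spec: LandscapeSpec,
                  fspec: FixtureSpec) -> None:
    neigh = one_mutant_neighbors(spec.source, spec)
    if neigh:
        values[spec.source] = max(values[h] for h in neigh) * fspec.source_boost


def make_landscape_fixture(fspec: FixtureSpec) -> EnvironmentSeries:
    """Generate the archetype's fitness series and verify its structure."""
    spec = LandscapeSpec.biallelic(fspec.source, fspec.target)
    builder = {
        "additive": _make_additive,
        "dominant_interior_peak": _make_dominant_interior_peak,
        "source_trapped": _make_source_trapped,
        "env_flip": _make_env_flip,
    }[fspec.archetype]
    return builder(spec, fspec)


def _single_env(fspec: FixtureSpec, default=1900):
    envs = list(fspec.environments) if fspec.environments else [default]
    if len(envs) != 1:
        raise FixtureError(f"{fspec.archetype} produces one environment, got {envs}")
    return envs[0]


def _make_additive(spec: LandscapeSpec, fspec: FixtureSpec) -> EnvironmentSeries:
    env = _single_env(fspec)
    values = _additive_values(spec, fspec)
    peak = max(values, key=values.get)
    if peak != spec.target:
        raise FixtureError("additive fixture must peak at the target")
    return EnvironmentSeries.from_tables(
        [FitnessTable(environment=env, values=values)]
    )


def _make_dominant_interior_peak(spec: LandscapeSpec,
                                 fspec: FixtureSpec) -> EnvironmentSeries:
    if fspec.peak is None:
        raise FixtureError("dominant_interior_peak requires a named peak genotype")
    peak = spec.validate_member(fspec.peak)
    if peak in (spec.source, spec.target):
        raise FixtureError("the dominant peak must be an interior genotype")
    env = _single_env(fspec)
    values = _additive_values(spec, fspec)
    values[peak] *= fspec.peak_multiplier
    neigh = [h for h in one_mutant_neighbors(spec.source, spec) if h != peak]
    if neigh:
        values[spec.source] = max(values[h] for h in neigh) * fspec.source_boost

    others = [v for g, v in values.items() if g != peak]
    if values[peak] <= max(others):
        raise FixtureError("peak multiplier too small: named peak is not dominant")
    for h in neigh:
        if values[spec.source] <= values[h]:
            raise FixtureError(
                "source_boost too small: leaving the source is not deleterious"
            )
    return EnvironmentSeries.from_tables(
        [FitnessTable(environment=env, values=values)]
    )


def _make_source_trapped(spec: LandscapeSpec,
                         fspec: FixtureSpec) -> EnvironmentSeries:
    env = _single_env(fspec)
    values = _additive_values(spec, fspec)
    _boost_source(values, spec, fspec)
    for h in one_mutant_neighbors(spec.source, spec):
        if values[spec.source] <= values[h]:
            raise FixtureError("source is not fitter than all its neighbors")
    return EnvironmentSeries.from_tables(
        [FitnessTable(environment=env, values=values)]
    )


def _make_env_flip(spec: LandscapeSpec, fspec: FixtureSpec) -> EnvironmentSeries:
    envs = list(fspec.environments) if fspec.environments else [1800, 2000]
    if len(envs) != 2:
        raise FixtureError(f"env_flip requires exactly 2 environments, got {envs}")

    sites = fspec.path_sites if fspec.path_sites else spec.differing_sites
    if sorted(sites) != sorted(spec.differing_sites):
        raise FixtureError(
            f"path_sites must be a permutation of the differing sites "
            f"{spec.differing_sites}, got {sites}"
        )
    chain = [spec.source]
    current = spec.source
    for s in sites:
        current = current[:s] + spec.target[s] + current[s + 1:]
        chain.append(current)

    # Early environment: strictly increasing along the designated path,
    # everything off the path strictly below the source.
    early = {}
    step = 1.0 + fspec.increment
    for k, g in enumerate(chain):
        early[g] = fspec.base * step ** k
    off = [g for g in hypercube(spec) if g not in early]
    for idx, g in enumerate(sorted(off)):
        early[g] = fspec.base * 0.5 / (1.0 + 0.01 * idx)

    # Late environment: additive toward the target, then the source raised
    # above everything (including the target).
    late = _additive_values(spec, fspec)
    late[spec.source] = max(v for g, v in late.items() if g != spec.source) \
        * fspec.source_boost

    flip_pair = fspec.flip_pair or (chain[1], spec.source)
    a, b = (spec.validate_member(g) for g in flip_pair)
    if not (early[a] > early[b] and late[a] < late[b]):
        raise FixtureError(
            f"flip pair {flip_pair} does not reverse order between environments"
        )
    for h in one_mutant_neighbors(spec.source, spec):
        if late[spec.source] <= late[h]:
            raise FixtureError("late environment: source is not a peak")
    if spec.source != spec.target and late[spec.source] <= late[spec.target]:
        raise FixtureError("late environment: source must outrank the target")
    for fa, fb in zip([early[g] for g in chain], [early[g] for g in chain[1:]]):
        if fb <= fa:
            raise FixtureError("early environment: designated path is not increasing")

    return EnvironmentSeries.from_tables([
        FitnessTable(environment=envs[0], values=early),
        FitnessTable(environment=envs[1], values=late),
    ])


# ----------------------------------------------------------------------
def make_ngram_files(series: EnvironmentSeries | FixtureSpec, out_dir,
                     total: int = 10 ** 9, normalize: bool = True,
                     split_case: bool = True):
    """Write a synthetic n-gram export TSV + totals file realizing a series.

    For every (word, year) the match count is ``round(frequency * total)``
    where the frequency is the table value, rescaled per year (when
    ``normalize`` is on) so the corpus frequencies sum to 0.5.  The count is
    split across two case variants ("Gene" + "gene") when ``split_case`` is
    on, exercising case-insensitive aggregation downstream.  Strict fitness
    orderings that rounding would destroy raise :class:`FixtureError`.

    Returns ``(ngram_path, totals_path, scale_by_year)``; parsing the files
    back reproduces ``value * scale_by_year[year]`` to within ``1/total``.
    """
    if isinstance(series, FixtureSpec):
        series = make_landscape_fixture(series)
    out_dir = FilePath(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ngram_path = out_dir / "ngrams.tsv"
    totals_path = out_dir / "totalcounts.txt"

    scale_by_year: dict[int, float] = {}
    lines = []
    totals_entries = []
    for env in series.environments:
        year = int(env)
        table = series[env]
        ssum = sum(table.values.values())
        if normalize and ssum > 0:
            scale = 0.5 / ssum
        else:
            scale = 1.0
            if ssum > 1.0:
                raise FixtureError(
                    f"year {year}: frequencies sum to {ssum} > 1; "
                    "enable normalize or rescale the table"
                )
        scale_by_year[year] = scale
        counts = {g: round(table[g] * scale * total) for g in table.genotypes}
        for (g, cg), (h, ch) in itertools.combinations(counts.items(), 2):
            if (table[g] > table[h] and cg <= ch) or (table[g] < table[h] and cg >= ch):
                raise FixtureError(
                    f"year {year}: rounding at total={total} destroys the "
                    f"fitness order of {g!r} vs {h!r}; increase total"
                )
        for g in table.genotypes:
            c = counts[g]
            if c <= 0:
                continue
            if split_case and c >= 2:
                head, tail = c // 2, c - c // 2
                lines.append(f"{g.capitalize()}\t{year}\t{head}\t1")
                lines.append(f"{g.lower()}\t{year}\t{tail}\t1")
            else:
                lines.append(f"{g.lower()}\t{year}\t{c}\t1")
        totals_entries.append(f"{year},{total},{max(1, total // 500)},{1}")

    ngram_path.write_text("".join(line + "\n" for line in lines))
    totals_path.write_text("\t".join(totals_entries) + "\n")
    return ngram_path, totals_path, scale_by_year
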