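"""Per-environment fitness tables and the n-gram frequency fitness proxy.

Fitness of a word in a given year is its usage frequency in a book corpus:
the number of appearances of the word (summed over case variants) divided by
the total number of words in the corpus that year.  Years act as
*environments* — the same landscape can be analyzed under each year's table.
Arbitrary non-negative fitness proxies are supported through plain CSV
tables (``genotype,environment,fitness``).

File formats understood:

* n-gram export TSV: ``ngram<TAB>year<TAB>match_count<TAB>volume_count``
* corpus totals: whitespace-separated ``year,match_count,page_count,volume_count``
  groups, or a plain two-column ``year,total`` CSV
* fitness CSV with header ``genotype,environment,fitness``
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FitnessError",
    "NgramRecord",
    "CorpusTotals",
    "FitnessTable",
    "EnvironmentSeries",
    "ngram_frequency",
    "read_ngram_file",
    "read_totals_file",
    "build_environment_series",
    "read_fitness_csv",
    "write_fitness_csv",
]


class FitnessError(ValueError):
    """Malformed fitness data or an impossible lookup."""


@dataclass(frozen=True)
class NgramRecord:
    """One (word, year) usage record from an n-gram export file."""

    ngram: str
    year: int
    match_count: int
    volume_count: int = 0

    def __post_init__(self) -> None:
        if self.match_count < 0 or self.volume_count < 0:
            raise FitnessError(
                f"counts must be non-negative: {self.ngram!r}/{self.year}"
            )


class CorpusTotals:
    """Map year -> total number of words in the corpus that year."""

    def __init__(self, totals: Mapping[int, int]):
        for year, total in totals.items():
            if total <= 0:
                raise FitnessError(f"corpus total for {year} must be positive, got {total}")
        self._totals = dict(totals)

    def __getitem__(self, year: int) -> int:
        try:
            return self._totals[year]
        except KeyError:
            raise FitnessError(f"no corpus total available for year {year}") from None

    def __contains__(self, year: int) -> bool:
        return year in self._totals

    def __len__(self) -> int:
        return len(self._totals)

    @property
    def years(self) -> list[int]:
        return sorted(self._totals)

    def as_dict(self) -> dict[int, int]:
        return dict(self._totals)


@dataclass
class FitnessTable:
    """Genotype -> fitness map for one environment (e.g. one year)."""

    environment: object
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, f in self.values.items():
            if f < 0:
                raise FitnessError(
                    f"fitness must be non-negative: {g!r}={f} in environment "
                    f"{self.environment!r}"
                )

    def __getitem__(self, genotype: str) -> float:
        try:
            return self.values[genotype]
        except KeyError:
            raise FitnessError(
                f"genotype {genotype!r} missing from fitness table for "
                f"environment {self.environment!r}"
            ) from None

    def __contains__(self, genotype: str) -> bool:
        return genotype in self.values

    def __len__(self) -> int:
        return len(self.values)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.values)

    def covers(self, genotypes: Iterable[str]) -> bool:
        return all(g in self.values for g in genotypes)


@dataclass
class EnvironmentSeries:
    """An ordered collection of fitness tables, one per environment label."""

    environments: list
    tables: dict

    def __post_init__(self) -> None:
        if len(set(map(str, self.environments))) != len(self.environments):
            raise FitnessError("environment labels must be unique")
        missing = [e for e in self.environments if e not in self.tables]
        if missing:
            raise FitnessError(f"no table supplied for environments {missing}")
        gsets = {frozenset(self.tables[e].values) for e in self.environments}
        if len(gsets) > 1:
            raise FitnessError("all tables in a series must cover the same genotypes")

    def __getitem__(self, environment) -> FitnessTable:
        try:
            return self.tables[environment]
        except KeyError:
            raise FitnessError(f"no table for environment {environment!r}") from None

    def __len__(self) -> int:
        return len(self.environments)

    def __iter__(self):
        return (self.tables[e] for e in self.environments)

    @property
    def genotypes(self) -> list[str]:
        return self.tables[self.environments[0]].genotypes

    @classmethod
    def from_tables(cls, tables: Sequence[FitnessTable]) -> "EnvironmentSeries":
        return cls(environments=[t.environment for t in tables],
                   tables={t.environment: t for t in tables})


# ----------------------------------------------------------------------
def ngram_frequency(word: str, year: int, records: Iterable[NgramRecord],
                    totals: CorpusTotals, case_sensitive: bool = False) -> float:
    """Usage frequency of ``word`` in ``year``: matches / corpus total.

    By default counts are aggregated over case variants ("Gene" + "gene"),
    the usual convention for case-insensitive frequency scores.  A word with
    no record in that year has frequency 0.
    """
    total = totals[year]  # raises FitnessError when the year is unknown
    if case_sensitive:
        matches = sum(r.match_count for r in records
                      if r.year == year and r.ngram == word)
    else:
        key = word.casefold()
        matches = sum(r.match_count for r in records
                      if r.year == year and r.ngram.casefold() == key)
    return matches / total


def read_ngram_file(path) -> list[NgramRecord]:
    """Parse a tab-separated n-gram export file into records.

    Each line is ``ngram<TAB>year<TAB>match_count<TAB>volume_count``.
    A malformed line raises :class:`FitnessError` naming its 1-based line
    number.  An empty file yields an empty list.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FitnessError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields, "
                    f"got {len(parts)}"
                )
            ngram, year_s, match_s, vol_s = parts
            try:
                year, match, vol = int(year_s), int(match_s), int(vol_s)
            except ValueError:
                raise FitnessError(
                    f"{path}: line {lineno}: non-integer year or count in {line!r}"
                ) from None
            records.append(NgramRecord(ngram=ngram, year=year,
                                       match_count=match, volume_count=vol))
    return records


def read_totals_file(path) -> CorpusTotals:
    """Parse a corpus-totals file.

    Accepts the totalcounts dialect — whitespace-separated groups of
    ``year,match_count,page_count,volume_count`` — or a plain two-column
    ``year,total`` CSV (one pair per line).  Duplicate years are an error.
    """
    with open(path) as fh:
        text = fh.read()
    totals: dict[int, int] = {}
    for token in text.split():
        parts = token.split(",")
        if len(parts) not in (2, 4):
            raise FitnessError(
                f"{path}: unparseable totals entry {token!r} "
                "(expected year,total or year,match,page,volume)"
            )
        try:
            year = int(parts[0])
            total = int(parts[1])
        except ValueError:
            raise FitnessError(f"{path}: non-integer year/total in {token!r}") from None
        if year in totals:
            raise FitnessError(f"{path}: duplicate year {year} in totals file")
        totals[year] = total
    return CorpusTotals(totals)


def build_environment_series(words: Iterable[str], years: Sequence[int],
                             records: Iterable[NgramRecord],
                             totals: CorpusTotals,
                             fill_policy: str = "zero",
                             pseudocount: float = 1.0,
                             case_sensitive: bool = False) -> EnvironmentSeries:
    """One fitness table per year, covering every word.

    ``fill_policy`` controls words absent from the records in a year:
    ``"zero"`` gives them fitness 0 (a word never printed has zero usage
    fitness); ``"pseudocount"`` gives them ``pseudocount / total``, which
    keeps downstream log-scale analyses finite.
    """
    if not years:
        raise FitnessError("years must be nonempty")
    if fill_policy not in ("zero", "pseudocount"):
        raise FitnessError(f"unknown fill_policy {fill_policy!r}")
    words = sorted({w.upper() for w in words})
    records = list(records)
    tables = []
    for year in years:
        values = {}
        for word in words:
            freq = ngram_frequency(word, year, records, totals,
                                   case_sensitive=case_sensitive)
            if freq == 0.0 and fill_policy == "pseudocount":
                freq = pseudocount / totals[year]
            values[word] = freq
        tables.append(FitnessTable(environment=year, values=values))
    return EnvironmentSeries.from_tables(tables)


# ----------------------------------------------------------------------
_FITNESS_HEADER = ["genotype", "environment", "fitness"]


def read_fitness_csv(path) -> EnvironmentSeries:
    """Read a ``genotype,environment,fitness`` CSV into a series.

    Environment labels that parse as integers become ints (so years sort
    numerically).  Negative fitness or a duplicate (genotype, environment)
    pair is an error naming the offending row.  Genotypes missing from some
    environment are filled with fitness 0.
    """
    tables: dict[object, dict[str, float]] = {}
    env_order: list = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header] != _FITNESS_HEADER:
            raise FitnessError(
                f"{path}: expected header {','.join(_FITNESS_HEADER)!r}, got {header}"
            )
        for rowno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise FitnessError(f"{path}: row {rowno}: expected 3 columns")
            genotype = row[0].strip().upper()
            env_s = row[1].strip()
            try:
                env: object = int(env_s)
            except ValueError:
                env = env_s
            try:
                fit = float(row[2])
            except ValueError:
                raise FitnessError(
                    f"{path}: row {rowno}: non-numeric fitness {row[2]!r}"
                ) from None
            if fit < 0:
                raise FitnessError(
                    f"{path}: row {rowno}: negative fitness {fit} for {genotype!r}"
                )
            if env not in tables:
                tables[env] = {}
                env_order.append(env)
            if genotype in tables[env]:
                raise FitnessError(
                    f"{path}: row {rowno}: duplicate entry for "
                    f"({genotype!r}, {env!r})"
                )
            tables[env][genotype] = fit
    if not tables:
        raise FitnessError(f"{path}: no fitness rows found")
    all_genotypes = sorted(set().union(*tables.values()))
    return EnvironmentSeries.from_tables([
        FitnessTable(environment=env,
                     values={g: tables[env].get(g, 0.0) for g in all_genotypes})
        for env in env_order
    ])


def write_fitness_csv(series: EnvironmentSeries, path) -> None:
    """Write a series as ``genotype,environment,fitness`` CSV.

    Floats are written with ``repr``, the shortest string that reads back to
    the identical double, so write-then-read preserves every value exactly.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FITNESS_HEADER)
        for env in series.environments:
            table = series[env]
            for g in table.genotypes:
                writer.writerow([g, env, repr(table[g])])
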