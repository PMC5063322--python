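"""Trajectory accessibility, peaks, adaptive walks and ruggedness.

A mutational path is *accessible* when fitness increases at every step —
strictly by default, since a path interrupted by a downward (or flat) step
cannot be climbed by selection alone.  A *peak* is a genotype with no
strictly fitter one-mutant neighbor.  Only fitness *orderings* matter for
every quantity here, so all verdicts are invariant under monotone
transformations of the fitness values (e.g. taking logs).

Accessibility is counted over the d! direct source-to-target paths; greedy
adaptive walks are free to roam the whole space, which is how off-path
local optima are reached.
"""

from __future__ import annotations

import json
import csv
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fitness import FitnessTable
from .space import (
    LandscapeSpec,
    Path,
    enumerate_direct_paths,
    hypercube,
    one_mutant_neighbors,
)

__all__ = [
    "PathVerdict",
    "AccessibilityReport",
    "PeakSet",
    "RuggednessSummary",
    "is_accessible",
    "count_accessible",
    "find_peaks",
    "greedy_walk",
    "ruggedness_summary",
]


@dataclass(frozen=True)
class PathVerdict:
    """Accessibility verdict for one path.

    ``first_blocked_step`` is the 0-based index of the earliest violating
    step (step ``i`` is the move from genotype ``i`` to ``i + 1``), or None
    for an accessible path.
    """

    path: Path
    accessible: bool
    first_blocked_step: Optional[int]


@dataclass
class AccessibilityReport:
    """Per-path verdicts plus totals for one landscape-environment pair."""

    environment: object
    verdicts: list[PathVerdict]
    n_accessible: int
    n_paths: int

    @property
    def fraction_accessible(self) -> float:
        return self.n_accessible / self.n_paths if self.n_paths else 0.0

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path_id", "site_order", "path",
                             "accessible", "first_blocked_step"])
            for i, v in enumerate(self.verdicts):
                writer.writerow([
                    i,
                    "-".join(map(str, v.path.step_sites)),
                    ">".join(v.path.genotypes),
                    int(v.accessible),
                    "" if v.first_blocked_step is None else v.first_blocked_step,
                ])

    def summary_dict(self) -> dict:
        return {
            "environment": self.environment,
            "n_paths": self.n_paths,
            "n_accessible": self.n_accessible,
            "fraction_accessible": self.fraction_accessible,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, default=str)
            fh.write("\n")


@dataclass
class PeakSet:
    """Local optima of one landscape-environment pair.

    ``peaks`` are genotypes with no strictly fitter neighbor.  ``plateau``
    flags peaks that have at least one equal-fitness neighbor, so flat
    ridges are visible rather than silently merged.  ``basins`` maps each
    genotype to the peak its greedy (lexicographic tie-break) walk reaches.
    """

    environment: object
    peaks: frozenset
    plateau: frozenset = frozenset()
    basins: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RuggednessSummary:
    n_peaks: int
    fraction_accessible_paths: float


# ----------------------------------------------------------------------
def is_accessible(path: Path, table: FitnessTable,
                  strict: bool = True) -> tuple[bool, Optional[int]]:
    """Whether fitness increases along ``path`` at every step.

    Strict mode requires a strict increase (ties block, selection cannot
    favor an equal-fitness move); non-strict mode allows equality.  Returns
    ``(accessible, first_blocked_step)``.
    """
    fitnesses = [table[g] for g in path.genotypes]
    for step, (fa, fb) in enumerate(zip(fitnesses, fitnesses[1:])):
        blocked = (fb <= fa) if strict else (fb < fa)
        if blocked:
            return False, step
    return True, None


def count_accessible(spec: LandscapeSpec, table: FitnessTable,
                     strict: bool = True) -> AccessibilityReport:
    """Evaluate every direct source-to-target path of a biallelic landscape."""
    verdicts = []
    n_ok = 0
    for path in enumerate_direct_paths(spec):
        ok, blocked = is_accessible(path, table, strict=strict)
        verdicts.append(PathVerdict(path=path, accessible=ok,
                                    first_blocked_step=blocked))
        n_ok += ok
    return AccessibilityReport(environment=table.environment, verdicts=verdicts,
                               n_accessible=n_ok, n_paths=len(verdicts))


def find_peaks(spec: LandscapeSpec, table: FitnessTable,
               compute_basins: bool = False) -> PeakSet:
    """Genotypes with no strictly fitter one-mutant neighbor."""
    peaks = set()
    plateau = set()
    for g in hypercube(spec):
        fg = table[g]
        neigh = one_mutant_neighbors(g, spec)
        if any(table[h] > fg for h in neigh):
            continue
        peaks.add(g)
        if any(table[h] == fg for h in neigh):
            plateau.add(g)
    basins = {}
    if compute_basins:
        for g in hypercube(spec):
            basins[g] = greedy_walk(g, spec, table).genotypes[-1]
    return PeakSet(environment=table.environment, peaks=frozenset(peaks),
                   plateau=frozenset(plateau), basins=basins)


def greedy_walk(start: str, spec: LandscapeSpec, table: FitnessTable,
                tie_rule: str = "lexicographic",
                rng: np.random.Generator | None = None) -> Path:
    """Steepest-ascent adaptive walk from ``start`` to a local optimum.

    At each step the walk moves to the strictly fittest neighbor, stopping
    when none is fitter.  Ties among equally fittest neighbors are broken
    lexicographically (reproducible) or by a seeded ``rng``.
    """
    if tie_rule not in ("lexicographic", "random"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    if tie_rule == "random" and rng is None:
        raise ValueError("tie_rule='random' requires a seeded rng")
    current = spec.validate_member(start)
    chain = [current]
    steps = []
    while True:
        best_f = table[current]
        best: list[str] = []
        for h in one_mutant_neighbors(current, spec):
            if table[h] > best_f:
                best_f = table[h]
                best = [h]
            elif best and table[h] == best_f:
                best.append(h)
        if not best:
            break
        if tie_rule == "lexicographic":
            nxt = min(best)
        else:
            nxt = best[int(rng.integers(len(best)))]
        site = next(i for i in range(len(current)) if current[i] != nxt[i])
        chain.append(nxt)
        steps.append(site)
        current = nxt
    return Path(genotypes=tuple(chain), step_sites=tuple(steps))


def ruggedness_summary(spec: LandscapeSpec, table: FitnessTable,
                       strict: bool = True) -> RuggednessSummary:
    """Peak count and accessible-path fraction; a smooth (additive)
    landscape gives ``(1, 1.0)``."""
    peaks = find_peaks(spec, table)
    report = count_accessible(spec, table, strict=strict)
    return RuggednessSummary(n_peaks=len(peaks.peaks),
                             fraction_accessible_paths=report.fraction_accessible)
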