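"""Pairwise epistasis and landscape-by-environment analytics.

Epistasis between two sites on a fixed genetic background is measured by
the four-point interaction

    epsilon = log f11 - log f10 - log f01 + log f00

(on the default log scale; the linear scale uses the analogous difference
of raw values).  ``f00`` is the background, ``f10``/``f01`` the two single
mutants and ``f11`` the double mutant.  Multiplicative fitness gives
``epsilon = 0``.  The sign taxonomy follows the standard classification:
*magnitude* epistasis when the interaction is non-zero but both single
mutations keep the direction of their effect across backgrounds, *sign*
when exactly one reverses direction, *reciprocal sign* when both do.

Landscape-by-environment interaction is quantified non-parametrically:
Spearman rank correlation of genotype fitness between environments, the
list of pairwise order flips (genotype pairs whose fitness order strictly
reverses), and the number of accessible direct paths per environment —
rank-based statistics, matching the fact that accessibility depends only
on orderings.
"""

from __future__ import annotations

import csv
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional

from scipy import stats

from .accessibility import count_accessible
from .fitness import EnvironmentSeries, FitnessTable
from .space import LandscapeSpec

__all__ = [
    "EpistasisError",
    "EpistasisResult",
    "EnvironmentInteractionReport",
    "pairwise_epistasis",
    "all_pairs_epistasis",
    "environment_interaction",
    "write_epistasis_csv",
]

#: |epsilon| at or below this is classified as no interaction on computed
#: fixtures (floating-point noise floor).
SIGN_CLASS_TOLERANCE = 1e-12


class EpistasisError(ValueError):
    """Invalid epistasis input (e.g. non-positive fitness on the log scale)."""


@dataclass(frozen=True)
class EpistasisResult:
    """Four-point interaction for one site pair on one background."""

    epsilon: float
    sign_class: str  # none | magnitude | sign | reciprocal_sign
    sites: Optional[tuple[int, int]] = None
    background: Optional[str] = None
    scale: str = "log"


@dataclass
class EnvironmentInteractionReport:
    """How landscape structure differs across environments."""

    environments: list
    rank_correlations: dict  # (env_a, env_b) -> Spearman rho
    rank_change_events: list  # ((genotype_a, genotype_b), (env_a, env_b))
    accessibility_by_environment: dict  # env -> n accessible direct paths
    genotype_ranks: dict  # env -> {genotype: rank (1 = fittest)}

    def write_json(self, path) -> None:
        payload = {
            "environments": [str(e) for e in self.environments],
            "rank_correlations": {
                f"{a}|{b}": rho for (a, b), rho in self.rank_correlations.items()
            },
            "rank_change_events": [
                {"genotypes": list(gp), "environments": [str(a), str(b)]}
                for gp, (a, b) in self.rank_change_events
            ],
            "accessibility_by_environment": {
                str(e): n for e, n in self.accessibility_by_environment.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


# ----------------------------------------------------------------------
def _effect(fa: float, fb: float, scale: str) -> float:
    """Directed effect of a mutation taking fitness fa -> fb."""
    if scale == "log":
        return math.log(fb) - math.log(fa)
    return fb - fa


def pairwise_epistasis(f00: float, f01: float, f10: float, f11: float,
                       scale: str = "log",
                       tolerance: float = SIGN_CLASS_TOLERANCE,
                       sites: Optional[tuple[int, int]] = None,
                       background: Optional[str] = None) -> EpistasisResult:
    """Four-point epistasis and its sign classification.

    ``f00`` is the shared background, ``f10`` and ``f01`` the single
    mutants at the first and second focal site, ``f11`` the double mutant.
    On the log scale all four values must be strictly positive (apply a
    pseudocount upstream for zero-frequency words); the linear scale
    accepts zeros.
    """
    if scale not in ("log", "linear"):
        raise EpistasisError(f"unknown scale {scale!r}")
    values = (f00, f01, f10, f11)
    if scale == "log" and any(v <= 0 for v in values):
        raise EpistasisError(
            f"log-scale epistasis requires strictly positive fitness, got {values}"
        )
    if scale == "linear" and any(v < 0 for v in values):
        raise EpistasisError(f"fitness must be non-negative, got {values}")

    if scale == "log":
        epsilon = (math.log(f11) - math.log(f10)
                   - math.log(f01) + math.log(f00))
    else:
        epsilon = f11 - f10 - f01 + f00

    # Effect of mutating site 1 on the two backgrounds of site 2, and
    # vice versa; a "flip" is a strict reversal of direction.
    e1_b0 = _effect(f00, f10, scale)
    e1_b1 = _effect(f01, f11, scale)
    e2_b0 = _effect(f00, f01, scale)
    e2_b1 = _effect(f10, f11, scale)
    flip1 = (e1_b0 > 0 > e1_b1) or (e1_b0 < 0 < e1_b1)
    flip2 = (e2_b0 > 0 > e2_b1) or (e2_b0 < 0 < e2_b1)

    if abs(epsilon) <= tolerance:
        sign_class = "none"
    elif flip1 and flip2:
        sign_class = "reciprocal_sign"
    elif flip1 or flip2:
        sign_class = "sign"
    else:
        sign_class = "magnitude"
    return EpistasisResult(epsilon=epsilon, sign_class=sign_class,
                           sites=sites, background=background, scale=scale)


def all_pairs_epistasis(spec: LandscapeSpec, table: FitnessTable,
                        scale: str = "log") -> list[EpistasisResult]:
    """Epistasis for every differing-site pair on every shared background.

    For a biallelic landscape with ``d`` differing sites this yields
    ``C(d, 2) * 2**(d - 2)`` results.  The ``background`` genotype recorded
    in each result carries the *source* symbols at the two focal sites;
    its variants at those sites are the corresponding single/double mutants.
    """
    if spec.mode != "biallelic":
        raise EpistasisError("all-pairs epistasis requires a biallelic spec")
    d_sites = spec.differing_sites
    others_pool = lambda i, j: [s for s in d_sites if s not in (i, j)]
    results = []
    for i, j in itertools.combinations(d_sites, 2):
        others = others_pool(i, j)
        for bits in itertools.product((0, 1), repeat=len(others)):
            bg = list(spec.source)
            for s, bit in zip(others, bits):
                bg[s] = spec.target[s] if bit else spec.source[s]
            bg[i], bg[j] = spec.source[i], spec.source[j]
            g00 = "".join(bg)
            g10 = g00[:i] + spec.target[i] + g00[i + 1:]
            g01 = g00[:j] + spec.target[j] + g00[j + 1:]
            g11 = g10[:j] + spec.target[j] + g10[j + 1:]
            results.append(pairwise_epistasis(
                table[g00], table[g01], table[g10], table[g11],
                scale=scale, sites=(i, j), background=g00,
            ))
    return results


def write_epistasis_csv(results: list[EpistasisResult], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["site_i", "site_j", "background", "epsilon", "sign_class"])
        for r in results:
            i, j = r.sites if r.sites else ("", "")
            writer.writerow([i, j, r.background or "", repr(r.epsilon), r.sign_class])


# ----------------------------------------------------------------------
def environment_interaction(spec: LandscapeSpec, series: EnvironmentSeries,
                            strict: bool = True) -> EnvironmentInteractionReport:
    """Rank-based landscape-by-environment interaction report.

    For each environment pair: Spearman correlation of genotype fitness and
    the genotype pairs whose strict fitness order reverses.  Also counts
    accessible direct paths per environment, so topographic change is
    visible both at the level of orderings and of evolutionary consequence.
    """
    if len(series) < 2:
        raise EpistasisError("environment interaction requires >= 2 environments")
    genotypes = series.genotypes
    envs = list(series.environments)

    ranks = {}
    for env in envs:
        table = series[env]
        fits = [table[g] for g in genotypes]
        # rank 1 = fittest; average ranks for ties
        r = stats.rankdata([-f for f in fits], method="average")
        ranks[env] = {g: float(r[k]) for k, g in enumerate(genotypes)}

    correlations = {}
    flips = []
    for a, b in itertools.combinations(envs, 2):
        ta, tb = series[a], series[b]
        fa = [ta[g] for g in genotypes]
        fb = [tb[g] for g in genotypes]
        rho = stats.spearmanr(fa, fb).statistic
        correlations[(a, b)] = float(rho)
        for g, h in itertools.combinations(genotypes, 2):
            if (ta[g] > ta[h] and tb[g] < tb[h]) or (ta[g] < ta[h] and tb[g] > tb[h]):
                flips.append(((g, h), (a, b)))

    accessibility = {
        env: count_accessible(spec, series[env], strict=strict).n_accessible
        for env in envs
    }
    return EnvironmentInteractionReport(
        environments=envs,
        rank_correlations=correlations,
        rank_change_events=flips,
        accessibility_by_environment=accessibility,
        genotype_ranks=ranks,
    )
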