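"""Wright-Fisher evolution of a population on a landscape.

The model is haploid and asexual with non-overlapping generations at fixed
population size ``N``.  Each generation applies, in order:

1. *selection* — the expected parental share of genotype ``g`` is
   proportional to ``count(g) * fitness(g)``;
2. *mutation* — each offspring mutates independently at each site with
   probability ``mu``, switching to the alternative symbol (uniform among
   alternatives at multi-allele sites);
3. *resampling* — ``N`` offspring are drawn multinomially from the
   post-mutation expected frequencies.

Because offspring are i.i.d. draws (pick a parent by fitness, then mutate),
the multinomial over the mutation-convolved selection frequencies is the
exact per-individual process, not an approximation.  A deterministic
infinite-N expectation iterator is exposed alongside the stochastic engine;
it satisfies the classical haploid selection recursion exactly and is used
for exact tests.

The high-mutation regime on a landscape with a dominant off-path peak
reproduces *stochastic tunneling*: a deleterious single-mutant intermediate
never rises above a few percent, yet seeds a double mutant that sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .fitness import FitnessTable
from .space import LandscapeSpec, hypercube

__all__ = [
    "SimulationError",
    "SimulationConfig",
    "SimulationResult",
    "wright_fisher",
    "expected_trajectory",
    "detect_tunneling",
    "fixation_probability_estimate",
    "FixationEstimate",
]

#: Largest genotype space for which the dense mutation matrix is built.
MAX_SIM_GENOTYPES = 4096


class SimulationError(ValueError):
    """Invalid simulation configuration or state."""


@dataclass
class SimulationConfig:
    """Parameters of one Wright-Fisher run.

    ``mu`` is the per-site, per-generation mutation probability.
    ``initial_composition`` maps genotype -> individual count and must sum
    to ``N``; the default (None) starts the whole population on the
    landscape's source genotype.
    """

    N: int
    mu: float
    generations: int
    seed: int
    initial_composition: Optional[dict[str, int]] = None
    environment: object = None
    fixation_threshold: float = 0.99

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise SimulationError(f"population size must be positive, got {self.N}")
        if not (0.0 <= self.mu <= 1.0):
            raise SimulationError(f"mutation rate must be in [0, 1], got {self.mu}")
        if self.generations <= 0:
            raise SimulationError("generations must be positive")
        if not (0.0 < self.fixation_threshold <= 1.0):
            raise SimulationError("fixation_threshold must be in (0, 1]")
        if self.initial_composition is not None:
            total = sum(self.initial_composition.values())
            if total != self.N:
                raise SimulationError(
                    f"initial composition sums to {total}, expected N={self.N}"
                )
            if any(c < 0 for c in self.initial_composition.values()):
                raise SimulationError("initial counts must be non-negative")


@dataclass
class SimulationResult:
    """Trajectory and summary statistics of one run.

    ``trajectory`` has shape ``(generations + 1, n_genotypes)``; row 0 is
    the initial composition.  ``fixation_events`` lists, per genotype, the
    first generation its frequency reached the fixation threshold.
    """

    genotypes: list[str]
    trajectory: np.ndarray
    fixation_events: list[tuple[str, int]]
    max_frequency: dict[str, float]
    config: SimulationConfig

    def frequency(self, genotype: str, generation: int) -> float:
        return float(self.trajectory[generation, self._index(genotype)])

    def frequencies(self, genotype: str) -> np.ndarray:
        return self.trajectory[:, self._index(genotype)]

    def _index(self, genotype: str) -> int:
        try:
            return self.genotypes.index(genotype.upper())
        except ValueError:
            raise SimulationError(
                f"genotype {genotype!r} not part of the simulated space"
            ) from None

    def modal_genotype(self, generation: int = -1) -> str:
        return self.genotypes[int(np.argmax(self.trajectory[generation]))]

    def write_csv(self, path) -> None:
        """Tidy CSV: generation, genotype, frequency."""
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["generation", "genotype", "frequency"])
            for gen in range(self.trajectory.shape[0]):
                for j, g in enumerate(self.genotypes):
                    writer.writerow([gen, g, repr(float(self.trajectory[gen, j]))])


class FixationEstimate(NamedTuple):
    probability: float
    standard_error: float


# ----------------------------------------------------------------------
def _site_codes(genotypes: list[str], spec: LandscapeSpec) -> np.ndarray:
    """(n_genotypes, L) integer encoding of each genotype's per-site allele."""
    codes = np.empty((len(genotypes), spec.length), dtype=np.int64)
    for j, g in enumerate(genotypes):
        for i in range(spec.length):
            codes[j, i] = spec.site_alphabets[i].index(g[i])
    return codes


def mutation_matrix(spec: LandscapeSpec, mu: float,
                    genotypes: list[str] | None = None) -> np.ndarray:
    """Dense genotype-to-genotype mutation matrix ``M[a, b] = P(a -> b)``.

    Product over sites of the per-site kernel: stay with probability
    ``1 - mu`` (1 at frozen sites), move to each of the ``k`` alternative
    symbols with probability ``mu / k``.  Rows sum to 1.
    """
    if genotypes is None:
        genotypes = hypercube(spec)
    n = len(genotypes)
    if n > MAX_SIM_GENOTYPES:
        raise SimulationError(
            f"space of {n} genotypes exceeds the simulation limit "
            f"({MAX_SIM_GENOTYPES})"
        )
    codes = _site_codes(genotypes, spec)
    M = np.ones((n, n))
    for i in range(spec.length):
        k = len(spec.site_alphabets[i])
        if k == 1:
            continue
        P = np.full((k, k), mu / (k - 1))
        np.fill_diagonal(P, 1.0 - mu)
        M *= P[codes[:, i][:, None], codes[None, :, i]]
    return M


def _prepare(config: SimulationConfig, spec: LandscapeSpec,
             table: FitnessTable):
    genotypes = hypercube(spec)
    missing = [g for g in genotypes if g not in table]
    if missing:
        raise SimulationError(
            f"fitness table does not cover the space; missing {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    w = np.array([table[g] for g in genotypes], dtype=float)
    if config.initial_composition is None:
        counts = np.zeros(len(genotypes), dtype=np.int64)
        counts[genotypes.index(spec.source)] = config.N
    else:
        counts = np.zeros(len(genotypes), dtype=np.int64)
        for g, c in config.initial_composition.items():
            gg = spec.validate_member(g)
            counts[genotypes.index(gg)] = c
    if float(w[counts > 0].sum()) == 0.0:
        raise SimulationError(
            "all genotypes present in the initial population have zero fitness"
        )
    M = mutation_matrix(spec, config.mu, genotypes)
    return genotypes, w, counts, M


def _step_expected(p: np.ndarray, w: np.ndarray, M: np.ndarray) -> np.ndarray:
    """One deterministic generation: selection then mutation, infinite N."""
    mean_w = float(p @ w)
    if mean_w == 0.0:
        raise SimulationError("population mean fitness is zero; cannot select")
    p_sel = p * w / mean_w
    return p_sel @ M


def wright_fisher(config: SimulationConfig, spec: LandscapeSpec,
                  table: FitnessTable) -> SimulationResult:
    """Run one stochastic Wright-Fisher simulation.

    All randomness comes from ``numpy.random.default_rng(config.seed)``, so
    an identical (config, spec, table) triple reproduces the trajectory
    bit-for-bit.  With ``mu == 0`` the run short-circuits once the
    population is monomorphic (an absorbing state).
    """
    genotypes, w, counts, M = _prepare(config, spec, table)
    rng = np.random.default_rng(config.seed)
    G = config.generations
    traj = np.empty((G + 1, len(genotypes)))
    traj[0] = counts / config.N
    for gen in range(1, G + 1):
        if config.mu == 0.0 and counts.max() == config.N:
            traj[gen:] = counts / config.N  # absorbed: frequencies are frozen
            break
        q = _step_expected(counts / config.N, w, M)
        counts = rng.multinomial(config.N, q)
        traj[gen] = counts / config.N
    return _summarize(genotypes, traj, config)


def expected_trajectory(config: SimulationConfig, spec: LandscapeSpec,
                        table: FitnessTable) -> SimulationResult:
    """Deterministic infinite-N expectation dynamics (no resampling noise)."""
    genotypes, w, counts, M = _prepare(config, spec, table)
    G = config.generations
    traj = np.empty((G + 1, len(genotypes)))
    p = counts / config.N
    traj[0] = p
    for gen in range(1, G + 1):
        p = _step_expected(p, w, M)
        traj[gen] = p
    return _summarize(genotypes, traj, config)


def _summarize(genotypes: list[str], traj: np.ndarray,
               config: SimulationConfig) -> SimulationResult:
    max_freq = traj.max(axis=0)
    events = []
    reached = traj >= config.fixation_threshold
    for j, g in enumerate(genotypes):
        hits = np.nonzero(reached[:, j])[0]
        if hits.size:
            events.append((g, int(hits[0])))
    events.sort(key=lambda e: (e[1], e[0]))
    return SimulationResult(
        genotypes=genotypes,
        trajectory=traj,
        fixation_events=events,
        max_frequency={g: float(max_freq[j]) for j, g in enumerate(genotypes)},
        config=config,
    )


# ----------------------------------------------------------------------
def detect_tunneling(result: SimulationResult, intermediate: str, final: str,
                     intermediate_cap: float = 0.05,
                     fixation_threshold: float = 0.99) -> bool:
    """Did ``final`` fix while ``intermediate`` stayed rare?

    True iff ``final`` reached the fixation threshold at some generation
    and the intermediate's maximum frequency stayed below
    ``intermediate_cap`` — the signature of a valley-crossing sweep in which
    a stepping-stone genotype is never common.
    """
    if not (0.0 < intermediate_cap < fixation_threshold < 1.0 + 1e-12):
        raise SimulationError(
            "need 0 < intermediate_cap < fixation_threshold <= 1"
        )
    final_max = result.max_frequency[result.genotypes[result._index(final)]]
    inter_max = result.max_frequency[result.genotypes[result._index(intermediate)]]
    return final_max >= fixation_threshold and inter_max < intermediate_cap


def fixation_probability_estimate(config: SimulationConfig, spec: LandscapeSpec,
                                  table: FitnessTable,
                                  replicates: int) -> dict[str, FixationEstimate]:
    """Fraction of independent replicates in which each genotype fixes.

    Replicate seeds are spawned from ``config.seed`` via
    ``numpy.random.SeedSequence``, so the whole ensemble is reproducible.
    Fixation means reaching ``config.fixation_threshold``; the binomial
    standard error is ``sqrt(p * (1 - p) / replicates)``.
    """
    if replicates < 1:
        raise SimulationError(f"replicates must be >= 1, got {replicates}")
    children = np.random.SeedSequence(config.seed).spawn(replicates)
    fixed = None
    genotypes = None
    for child in children:
        rep_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        rep_config = SimulationConfig(
            N=config.N, mu=config.mu, generations=config.generations,
            seed=rep_seed, initial_composition=config.initial_composition,
            environment=config.environment,
            fixation_threshold=config.fixation_threshold,
        )
        result = wright_fisher(rep_config, spec, table)
        if fixed is None:
            genotypes = result.genotypes
            fixed = np.zeros(len(genotypes), dtype=np.int64)
        fixed += np.array([
            result.max_frequency[g] >= config.fixation_threshold
            for g in genotypes
        ])
    p = fixed / replicates
    se = np.sqrt(p * (1.0 - p) / replicates)
    return {g: FixationEstimate(float(p[j]), float(se[j]))
            for j, g in enumerate(genotypes)}
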