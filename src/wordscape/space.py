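"""Combinatorial genotype spaces between two equal-length sequences.

A *landscape* here is a set of fixed-length symbol strings ("genotypes":
words, amino-acid sequences, ...) connected by single-site substitutions.
Given a source and a target sequence the biallelic space allows, at every
site, only the source or the target symbol, giving a hypercube of
``2**d`` genotypes where ``d`` is the number of differing sites.  The
full-alphabet space allows an arbitrary alphabet at every site; it is
never materialized, only measured and queried.

Genotypes are plain uppercase strings; adjacency is Hamming distance 1.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass
from string import ascii_uppercase
from typing import Iterable, Iterator

__all__ = [
    "LandscapeError",
    "LandscapeSpec",
    "Path",
    "build_hypercube",
    "space_size",
    "one_mutant_neighbors",
    "enumerate_direct_paths",
    "write_edge_list",
    "write_node_csv",
]

#: Hard cap on differing sites for materializing a biallelic hypercube.
MAX_ENUM_SITES = 20
#: Hard cap on differing sites for enumerating all d! direct paths.
MAX_PATH_SITES = 10


class LandscapeError(ValueError):
    """Invalid landscape construction or a genotype outside the space."""


def _check_word(word: str, name: str) -> str:
    if not isinstance(word, str):
        raise LandscapeError(f"{name} must be a string, got {type(word).__name__}")
    if len(word) == 0:
        raise LandscapeError(f"{name} must be a nonempty sequence")
    return word.upper()


@dataclass(frozen=True)
class LandscapeSpec:
    """Definition of a genotype space between ``source`` and ``target``.

    Parameters
    ----------
    source, target
        Equal-length uppercase strings.
    site_alphabets
        Per-site ordered symbol tuples.  In biallelic mode each entry is
        ``(source[i], target[i])`` (a singleton where they agree); in full
        mode each entry is the supplied alphabet.
    mode
        ``"biallelic"`` or ``"full"``.
    """

    source: str
    target: str
    site_alphabets: tuple[tuple[str, ...], ...]
    mode: str = "biallelic"

    def __post_init__(self) -> None:
        if len(self.source) != len(self.target):
            raise LandscapeError(
                f"source ({self.source!r}) and target ({self.target!r}) "
                "must have equal length"
            )
        if len(self.site_alphabets) != len(self.source):
            raise LandscapeError("site_alphabets length must equal sequence length")
        if self.mode not in ("biallelic", "full"):
            raise LandscapeError(f"unknown mode {self.mode!r}")
        for i, (s, t) in enumerate(zip(self.source, self.target)):
            alpha = self.site_alphabets[i]
            if s not in alpha or t not in alpha:
                raise LandscapeError(
                    f"site {i}: alphabet {alpha!r} must contain source and "
                    f"target symbols {s!r}, {t!r}"
                )

    # ------------------------------------------------------------------
    @classmethod
    def biallelic(cls, source: str, target: str) -> "LandscapeSpec":
        """Biallelic space: each site offers only the source/target symbols."""
        source = _check_word(source, "source")
        target = _check_word(target, "target")
        if len(source) != len(target):
            raise LandscapeError(
                f"source ({source!r}) and target ({target!r}) must have equal length"
            )
        alphabets = tuple(
            (s,) if s == t else (s, t) for s, t in zip(source, target)
        )
        return cls(source=source, target=target, site_alphabets=alphabets,
                   mode="biallelic")

    @classmethod
    def full(cls, source: str, target: str,
             alphabet: Iterable[str] = ascii_uppercase) -> "LandscapeSpec":
        """Full-alphabet space (e.g. all 26 letters at each of L sites)."""
        source = _check_word(source, "source")
        target = _check_word(target, "target")
        alpha = tuple(dict.fromkeys(c.upper() for c in alphabet))
        missing = {c for c in source + target if c not in alpha}
        if missing:
            raise LandscapeError(
                f"alphabet must contain all source/target symbols; missing {sorted(missing)}"
            )
        return cls(source=source, target=target,
                   site_alphabets=tuple(alpha for _ in source), mode="full")

    # ------------------------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.source)

    @property
    def differing_sites(self) -> tuple[int, ...]:
        return tuple(
            i for i, (s, t) in enumerate(zip(self.source, self.target)) if s != t
        )

    @property
    def n_differing(self) -> int:
        return len(self.differing_sites)

    def contains(self, genotype: str) -> bool:
        if len(genotype) != self.length:
            return False
        g = genotype.upper()
        return all(g[i] in self.site_alphabets[i] for i in range(self.length))

    def validate_member(self, genotype: str) -> str:
        """Return the normalized genotype or raise :class:`LandscapeError`."""
        g = genotype.upper()
        if not self.contains(g):
            raise LandscapeError(
                f"genotype {genotype!r} is not a member of the "
                f"{self.source}->{self.target} ({self.mode}) space"
            )
        return g

    def alternative_symbols(self, genotype: str, site: int) -> tuple[str, ...]:
        """Symbols the given site may mutate to (everything but the current)."""
        return tuple(c for c in self.site_alphabets[site] if c != genotype[site])


@dataclass(frozen=True)
class Path:
    """An ordered single-substitution chain of genotypes.

    ``step_sites[k]`` is the site changed between ``genotypes[k]`` and
    ``genotypes[k + 1]``.
    """

    genotypes: tuple[str, ...]
    step_sites: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.genotypes) == 0:
            raise LandscapeError("a path must contain at least one genotype")
        if len(self.step_sites) != len(self.genotypes) - 1:
            raise LandscapeError("step_sites must have one entry per step")
        for k, (a, b) in enumerate(zip(self.genotypes, self.genotypes[1:])):
            diff = [i for i in range(len(a)) if a[i] != b[i]]
            if diff != [self.step_sites[k]]:
                raise LandscapeError(
                    f"step {k}: {a!r} -> {b!r} must change exactly site "
                    f"{self.step_sites[k]}"
                )

    def __len__(self) -> int:
        return len(self.genotypes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genotypes)


# ----------------------------------------------------------------------
def build_hypercube(source: str, target: str) -> list[str]:
    """All genotypes formed by choosing source or target symbol at each site.

    Returns the ``2**d`` members of the biallelic hypercube in lexicographic
    order, ``d`` being the number of differing sites.

    >>> len(build_hypercube("WORD", "GENE"))
    16
    """
    spec = LandscapeSpec.biallelic(source, target)
    return hypercube(spec)


def hypercube(spec: LandscapeSpec) -> list[str]:
    """Materialize the genotype set of ``spec``, lexicographically sorted."""
    if spec.mode == "biallelic":
        if spec.n_differing > MAX_ENUM_SITES:
            raise LandscapeError(
                f"refusing to enumerate 2**{spec.n_differing} genotypes "
                f"(limit: {MAX_ENUM_SITES} differing sites)"
            )
    else:
        if space_size(spec) > 2 ** MAX_ENUM_SITES:
            raise LandscapeError(
                "refusing to materialize a full-alphabet space of size "
                f"{space_size(spec)}; use space_size/one_mutant_neighbors instead"
            )
    genotypes = ["".join(chars) for chars in itertools.product(*spec.site_alphabets)]
    genotypes.sort()
    return genotypes


def space_size(spec: LandscapeSpec, mode: str | None = None) -> int:
    """Number of genotypes: ``2**d`` (biallelic) or the alphabet-size product.

    ``mode`` overrides the spec's own mode, so a biallelic spec can be asked
    how large the surrounding full space would be and vice versa.
    """
    mode = mode or spec.mode
    if mode == "biallelic":
        return 2 ** spec.n_differing
    if mode == "full":
        return math.prod(len(a) for a in spec.site_alphabets)
    raise LandscapeError(f"unknown mode {mode!r}")


def one_mutant_neighbors(genotype: str, spec: LandscapeSpec) -> list[str]:
    """All members of the space at Hamming distance exactly 1 from ``genotype``.

    In a biallelic space with ``d`` differing sites every genotype has
    exactly ``d`` neighbors.  Works without materializing the space, so it is
    valid for full-alphabet specs of any size.
    """
    g = spec.validate_member(genotype)
    out = []
    for i in range(spec.length):
        for c in spec.alternative_symbols(g, i):
            out.append(g[:i] + c + g[i + 1:])
    out.sort()
    return out


def enumerate_direct_paths(spec: LandscapeSpec) -> list[Path]:
    """All ``d!`` shortest source-to-target paths of a biallelic space.

    Each path flips every differing site exactly once, to the target symbol;
    paths are ordered lexicographically by their site permutation.  For
    ``d == 0`` the single trivial path ``[source]`` is returned.
    """
    if spec.mode != "biallelic":
        raise LandscapeError("direct-path enumeration requires a biallelic spec")
    d = spec.n_differing
    if d > MAX_PATH_SITES:
        raise LandscapeError(
            f"refusing to enumerate {d}! direct paths (limit: {MAX_PATH_SITES} sites)"
        )
    paths = []
    for order in itertools.permutations(spec.differing_sites):
        chain = [spec.source]
        current = spec.source
        for site in order:
            current = current[:site] + spec.target[site] + current[site + 1:]
            chain.append(current)
        paths.append(Path(genotypes=tuple(chain), step_sites=tuple(order)))
    return paths


# ----------------------------------------------------------------------
def write_edge_list(spec: LandscapeSpec, path) -> None:
    """Write the adjacency as one tab-separated genotype pair per line.

    Each undirected edge appears once, with the lexicographically smaller
    genotype first; lines are sorted.
    """
    nodes = hypercube(spec)
    edges = set()
    for g in nodes:
        for h in one_mutant_neighbors(g, spec):
            edges.add((g, h) if g < h else (h, g))
    with open(path, "w") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")


def write_node_csv(spec: LandscapeSpec, path) -> None:
    """Write the node list as CSV with genotype and Hamming distance columns."""
    nodes = hypercube(spec)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["genotype", "dist_from_source", "dist_to_target"])
        for g in nodes:
            ds = sum(a != b for a, b in zip(g, spec.source))
            dt = sum(a != b for a, b in zip(g, spec.target))
            writer.writerow([g, ds, dt])
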