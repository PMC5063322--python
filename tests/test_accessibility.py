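"""Accessibility verdicts, peaks, greedy walks and ruggedness summaries."""

import math

import numpy as np
import pytest

from wordscape import (
    FitnessTable,
    LandscapeSpec,
    Path,
    count_accessible,
    find_peaks,
    greedy_walk,
    is_accessible,
    ruggedness_summary,
)
from wordscape.fitness import FitnessError
from wordscape.space import hypercube, one_mutant_neighbors
from wordscape.synth import FixtureSpec, make_landscape_fixture

from conftest import brute_force_accessible_count, random_landscape


def _chain_table(genotypes, fitnesses):
    return FitnessTable(environment="t", values=dict(zip(genotypes, fitnesses)))


def _path_through(words):
    sites = []
    for a, b in zip(words, words[1:]):
        sites.append(next(i for i in range(len(a)) if a[i] != b[i]))
    return Path(genotypes=tuple(words), step_sites=tuple(sites))


class TestIsAccessible:
    def test_monotone_path_accessible(self):
        p = _path_through(["AA", "AB", "BB"])
        table = _chain_table(["AA", "AB", "BB"], [1, 2, 5])
        assert is_accessible(p, table) == (True, None)

    def test_tie_blocks_strict_mode(self):
        words = ["AAA", "AAB", "ABB", "BBB"]
        p = _path_through(words)
        table = _chain_table(words, [1, 2, 2, 9])
        assert is_accessible(p, table, strict=True) == (False, 1)
        assert is_accessible(p, table, strict=False) == (True, None)

    def test_first_blocked_step_is_earliest(self):
        words = ["AAA", "AAB", "ABB", "BBB"]
        p = _path_through(words)
        table = _chain_table(words, [5, 2, 1, 9])
        assert is_accessible(p, table) == (False, 0)

    def test_gene_to_bird_ordered_fixture_is_accessible(self,
                                                        gene_bird_flip_series):
        """The early-environment table orders the canonical path upward."""
        p = _path_through(["GENE", "BENE", "BEND", "BIND", "BIRD"])
        assert is_accessible(p, gene_bird_flip_series[1800]) == (True, None)

    def test_missing_genotype_raises(self):
        p = _path_through(["AA", "AB"])
        with pytest.raises(FitnessError):
            is_accessible(p, _chain_table(["AA"], [1.0]))


class TestCountAccessible:
    def test_additive_landscape_all_paths_accessible(self, word_gene_spec,
                                                     additive_table):
        report = count_accessible(word_gene_spec, additive_table)
        assert report.n_paths == 24
        assert report.n_accessible == 24
        assert report.fraction_accessible == 1.0

    def test_trapped_source_blocks_every_path_at_step_zero(self,
                                                           word_gene_spec):
        series = make_landscape_fixture(
            FixtureSpec(source="WORD", target="GENE", archetype="source_trapped"))
        report = count_accessible(word_gene_spec, series[1900])
        assert report.n_accessible == 0
        assert all(v.first_blocked_step == 0 for v in report.verdicts)

    def test_dominant_peak_fixture_blocks_all_direct_paths(self,
                                                           word_gene_spec,
                                                           dominant_peak_table):
        # source fitter than every neighbor, so no direct path can leave it
        report = count_accessible(word_gene_spec, dominant_peak_table)
        assert report.n_accessible == 0

    def test_matches_brute_force_on_random_landscapes(self):
        rng = np.random.default_rng(1234)
        for _ in range(15):
            spec, table = random_landscape(rng, max_d=6)
            report = count_accessible(spec, table)
            n_oracle, total = brute_force_accessible_count(spec, table)
            assert (report.n_accessible, report.n_paths) == (n_oracle, total)


class TestFindPeaks:
    def test_dominant_peak_matches_exhaustive_oracle(self, word_gene_spec,
                                                     dominant_peak_table):
        peaks = find_peaks(word_gene_spec, dominant_peak_table).peaks
        oracle = {
            g for g in hypercube(word_gene_spec)
            if all(dominant_peak_table[h] <= dominant_peak_table[g]
                   for h in one_mutant_neighbors(g, word_gene_spec))
        }
        assert peaks == oracle
        assert "WERE" in peaks

    def test_constant_landscape_every_genotype_is_a_peak(self, word_gene_spec):
        table = FitnessTable(environment="c", values={
            g: 1.0 for g in hypercube(word_gene_spec)})
        ps = find_peaks(word_gene_spec, table)
        assert len(ps.peaks) == 16
        assert ps.plateau == ps.peaks  # every peak sits on the flat ridge

    def test_additive_landscape_unique_peak_is_target(self, word_gene_spec,
                                                      additive_table):
        assert find_peaks(word_gene_spec, additive_table).peaks == {"GENE"}

    def test_basins_map_every_genotype_to_a_peak(self, word_gene_spec,
                                                 dominant_peak_table):
        ps = find_peaks(word_gene_spec, dominant_peak_table, compute_basins=True)
        assert set(ps.basins) == set(hypercube(word_gene_spec))
        assert set(ps.basins.values()) <= ps.peaks


class TestGreedyWalk:
    def test_walk_from_peak_is_single_genotype(self, word_gene_spec,
                                               additive_table):
        walk = greedy_walk("GENE", word_gene_spec, additive_table)
        assert walk.genotypes == ("GENE",)

    def test_additive_walk_climbs_straight_to_target(self, word_gene_spec,
                                                     additive_table):
        walk = greedy_walk("WORD", word_gene_spec, additive_table)
        assert len(walk) == 5
        assert walk.genotypes[-1] == "GENE"

    def test_lexicographic_tie_break_is_reproducible(self):
        spec = LandscapeSpec.biallelic("AA", "BB")
        table = FitnessTable(environment="t", values={
            "AA": 1.0, "AB": 2.0, "BA": 2.0, "BB": 3.0})
        walk = greedy_walk("AA", spec, table)
        assert walk.genotypes[1] == "AB"  # smaller string among the tied pair

    def test_random_tie_break_requires_rng(self, word_gene_spec,
                                           additive_table):
        with pytest.raises(ValueError):
            greedy_walk("WORD", word_gene_spec, additive_table, tie_rule="random")

    def test_walks_terminate_on_peaks_for_random_landscapes(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            spec, table = random_landscape(rng, max_d=5)
            peaks = find_peaks(spec, table).peaks
            for start in hypercube(spec):
                walk = greedy_walk(start, spec, table)
                assert len(walk) <= 2 ** spec.n_differing
                assert walk.genotypes[-1] in peaks


class TestMonotoneInvariance:
    def test_verdicts_unchanged_under_log_transform(self):
        """Only fitness orderings matter, so log-rescaling changes nothing."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            spec, table = random_landscape(rng, max_d=5)
            logged = FitnessTable(environment=table.environment, values={
                g: math.log(f) + 10 for g, f in table.values.items()})
            rep_a = count_accessible(spec, table)
            rep_b = count_accessible(spec, logged)
            assert [v.accessible for v in rep_a.verdicts] == \
                   [v.accessible for v in rep_b.verdicts]
            assert find_peaks(spec, table).peaks == find_peaks(spec, logged).peaks
            for start in hypercube(spec):
                assert greedy_walk(start, spec, table).genotypes == \
                       greedy_walk(start, spec, logged).genotypes


class TestRuggedness:
    def test_smooth_landscape(self, word_gene_spec, additive_table):
        summary = ruggedness_summary(word_gene_spec, additive_table)
        assert summary.n_peaks == 1
        assert summary.fraction_accessible_paths == 1.0

    def test_constant_landscape_maximally_rugged_under_strict_rule(
            self, word_gene_spec):
        table = FitnessTable(environment="c", values={
            g: 1.0 for g in hypercube(word_gene_spec)})
        summary = ruggedness_summary(word_gene_spec, table)
        assert summary.n_peaks == 16
        assert summary.fraction_accessible_paths == 0.0

    def test_dominant_interior_peak_off_path_blocks_everything(
            self, word_gene_spec, dominant_peak_table):
        summary = ruggedness_summary(word_gene_spec, dominant_peak_table)
        assert summary.n_peaks >= 1
        assert summary.fraction_accessible_paths == 0.0


def test_report_serialization(tmp_path, word_gene_spec, additive_table):
    report = count_accessible(word_gene_spec, additive_table)
    report.write_csv(tmp_path / "acc.csv")
    report.write_json(tmp_path / "acc.json")
    lines = (tmp_path / "acc.csv").read_text().splitlines()
    assert len(lines) == 25  # header + 24 paths
    import json

    summary = json.loads((tmp_path / "acc.json").read_text())
    assert summary["n_accessible"] == 24
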