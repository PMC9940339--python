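import numpy as np
import pytest

from molgrow import (
    contains_scaffold,
    population_metrics,
    solow_polasky_diversity,
    tanimoto_distance,
)
from molgrow.environment import ecfp6_bitset

THETA = 0.5
A = np.exp(-THETA)  # kernel value at distance 1


class TestTanimotoDistance:
    @pytest.mark.parametrize(
        "fp1,fp2,expected",
        [
            (frozenset({1, 2, 3}), frozenset({1, 2, 3}), 0.0),
            (frozenset({1, 2}), frozenset({3, 4}), 1.0),
            (frozenset({1, 2, 3}), frozenset({2, 3, 4}), 0.5),
            (frozenset(), frozenset(), 0.0),  # both empty: defined as 0
        ],
    )
    def test_set_arithmetic(self, fp1, fp2, expected):
        assert tanimoto_distance(fp1, fp2) == expected
        assert tanimoto_distance(fp2, fp1) == expected


class TestContainsScaffold:
    def test_self_containment(self):
        assert contains_scaffold("c1ccccc1", "c1ccccc1")

    def test_toluene_contains_benzene_not_pyridine(self):
        assert contains_scaffold("Cc1ccccc1", "c1ccccc1")
        assert not contains_scaffold("Cc1ccccc1", "c1ccncc1")

    def test_multi_fragment_scaffold_requires_all(self):
        assert contains_scaffold("CCc1ccc(O)cc1", "CC.c1ccccc1")
        assert not contains_scaffold("CCc1ccccc1", "CC.O")

    def test_kekulized_form_also_tried(self):
        # an aliphatic C=C pattern appears only in the kekulized ring form
        assert contains_scaffold("c1ccccc1", "C1=CC=CC=C1")

    def test_aliphatic_scaffold_only_matches_through_kekulized_form(self):
        # 'CCC' grown into toluene: aromatic-perceived matching fails (the
        # ring carbons aromatize) and only the kekulized fallback finds it
        from rdkit import Chem

        aromatic_only = Chem.MolFromSmiles("Cc1ccccc1").HasSubstructMatch(
            Chem.MolFromSmiles("CCC")
        )
        assert not aromatic_only
        assert contains_scaffold("Cc1ccccc1", "CCC")

    def test_unparsable_scaffold_raises(self):
        with pytest.raises(ValueError):
            contains_scaffold("CCO", "](")


class TestSolowPolasky:
    def test_single_molecule_has_diversity_one(self):
        assert solow_polasky_diversity([frozenset({1, 2})]) == 1.0

    def test_two_molecules_at_distance_one_closed_form(self):
        got = solow_polasky_diversity([frozenset({1}), frozenset({2})])
        assert got == pytest.approx(1 / (1 + A), abs=1e-10)

    def test_equidistant_population_matches_closed_form(self):
        for m in (3, 5, 10):
            fps = [frozenset({i}) for i in range(m)]
            got = solow_polasky_diversity(fps)
            assert got == pytest.approx(1 / (1 + (m - 1) * A), abs=1e-10)

    def test_linear_solve_equals_explicit_inverse(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 51))
            universe = 200
            fps = []
            while len({tuple(sorted(f)) for f in fps}) < m:
                fps = [
                    frozenset(map(int, rng.choice(universe, 12, replace=False)))
                    for _ in range(m)
                ]
            dist = np.array(
                [[tanimoto_distance(a, b) for b in fps] for a in fps]
            )
            kernel = np.exp(-THETA * dist)
            explicit = float(
                np.ones(m) @ np.linalg.inv(kernel) @ np.ones(m)
            ) / m
            assert solow_polasky_diversity(fps) == pytest.approx(
                explicit, abs=1e-8
            )

    def test_duplicates_never_increase_diversity(self, rng):
        fps = [
            frozenset(map(int, rng.choice(100, 10, replace=False)))
            for _ in range(8)
        ]
        base = solow_polasky_diversity(fps)
        assert solow_polasky_diversity(fps + [fps[0]]) <= base + 1e-12


class TestPopulationMetrics:
    def test_validity_fraction(self):
        gen = [("CCO", ""), ("CCN", ""), ("c1ccccc1", ""), ("xx(", "")]
        report = population_metrics(gen, reference=set())
        assert report.validity == 0.75
        assert report.n_total == 4

    def test_all_identical_uniqueness(self):
        gen = [("CCO", "")] * 5
        report = population_metrics(gen, reference=set())
        assert report.uniqueness == pytest.approx(1 / 5)

    def test_novelty_excludes_reference(self):
        gen = [("CCO", ""), ("CCN", ""), ("CCC", "")]
        report = population_metrics(gen, reference={"CCO"})
        assert report.n_novel == 2
        assert report.novelty == pytest.approx(2 / 3)

    def test_disjoint_generated_all_novel(self):
        gen = [("CCO", ""), ("CCN", "")]
        report = population_metrics(gen, reference={"c1ccccc1"})
        assert report.novelty == 1.0

    def test_novelty_bounded_by_uniqueness(self, rng, small_library):
        smiles = [r.smiles for r in small_library]
        picks = [smiles[i] for i in rng.integers(0, len(smiles), 30)]
        report = population_metrics(
            [(s, "") for s in picks], reference=set(smiles[:20])
        )
        assert report.n_novel <= report.n_unique
        for value in (
            report.validity,
            report.accuracy,
            report.desirability,
            report.uniqueness,
            report.novelty,
        ):
            assert 0.0 <= value <= 1.0

    def test_accuracy_counts_scaffold_containment(self):
        gen = [("Cc1ccccc1", "c1ccccc1"), ("CCO", "c1ccccc1")]
        report = population_metrics(gen, reference=set())
        assert report.n_accurate == 1

    def test_diversity_against_fingerprints(self, small_library):
        smiles = [r.smiles for r in small_library[:10]]
        report = population_metrics([(s, "") for s in smiles], reference=set())
        expected = solow_polasky_diversity(
            [ecfp6_bitset(s) for s in {s: None for s in smiles}]
        )
        assert report.diversity == pytest.approx(expected, abs=1e-9)
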