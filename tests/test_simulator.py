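"""Monte-Carlo screen simulation: per-plant model, trials, coverage curves."""

from math import comb

import numpy as np
import pytest

from crispr_coverage import (
    CoverageUnreachableError,
    ExperimentDesign,
    PlantGenotype,
    assemble_construct,
    build_library,
    compute_coverage,
    covered_combinations,
    edit_plant,
    estimate_min_library_size,
    knockout_count_distribution,
    run_trial,
    simulated_coverage_curve,
)
from crispr_coverage.simulator import _trial_first_seen

from conftest import make_library


def ideal_design(**kw) -> ExperimentDesign:
    """Uniform frequencies, all guides perfectly active, certain knockout."""
    defaults = dict(rho=1.0, f_act=1.0, eps_edit_act=1.0, eps_edit_sd=0.0, eps_KO=1.0)
    defaults.update(kw)
    return ExperimentDesign(**defaults)


class TestAssembleConstruct:
    def test_single_guide_always_drawn(self, rng):
        lib = make_library([1.0], [0])
        assert list(assemble_construct(lib, 3, rng)) == [0, 0, 0]

    def test_zero_probability_guide_never_drawn(self, rng):
        lib = make_library([1.0, 0.0], [0, 1])
        for _ in range(50):
            assert list(assemble_construct(lib, 2, rng)) == [0, 0]

    def test_mixed_construct_fraction_matches_binomial(self, rng):
        lib = make_library([0.5, 0.5], [0, 1])
        n = 20_000
        mixed = sum(
            len(set(assemble_construct(lib, 2, rng))) == 2 for _ in range(n)
        )
        # P(two distinct guides) = 2 * 0.5 * 0.5 = 0.5
        assert abs(mixed / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_empty_construct_rejected(self, rng):
        with pytest.raises(ValueError):
            assemble_construct(make_library([1.0], [0]), 0, rng)


class TestEditPlant:
    def test_certain_success_knocks_out_all_targets(self, rng):
        lib = make_library([1, 1, 1], [0, 1, 2])
        genotype = edit_plant(lib, np.array([0, 1, 2]), eps_KO=1.0, rng=rng)
        assert genotype.knocked_out == {"G1", "G2", "G3"}

    def test_zero_knockout_efficiency_gives_wildtype(self, rng):
        lib = make_library([1, 1], [0, 1])
        for _ in range(20):
            assert len(edit_plant(lib, np.array([0, 1]), eps_KO=0.0, rng=rng)) == 0

    def test_same_gene_guides_collapse_to_one_knockout(self, rng):
        lib = make_library([1, 1], [0, 0])
        genotype = edit_plant(lib, np.array([0, 1]), eps_KO=1.0, rng=rng)
        assert genotype.knocked_out == {"G1"}


class TestCoverage:
    def test_triple_decomposes_into_three_pairs(self):
        genotype = PlantGenotype(frozenset({"A", "B", "C"}))
        assert covered_combinations(genotype, 2) == {
            frozenset({"A", "B"}), frozenset({"A", "C"}), frozenset({"B", "C"})
        }

    def test_single_knockout_covers_no_pair(self):
        assert covered_combinations(PlantGenotype(frozenset({"A"})), 2) == set()

    def test_six_knockouts_cover_fifteen_pairs(self):
        genotype = PlantGenotype(frozenset("ABCDEF"))
        assert len(covered_combinations(genotype, 2)) == 15

    def test_coverage_fraction_counts_distinct_pairs(self):
        # six plants over five genes: three informative pairs, three single-KO by-products
        plants = [
            PlantGenotype(frozenset({"g1", "g2"})),
            PlantGenotype(frozenset({"g3", "g4"})),
            PlantGenotype(frozenset({"g2", "g5"})),
            PlantGenotype(frozenset({"g1"})),
            PlantGenotype(frozenset({"g3"})),
            PlantGenotype(frozenset({"g5"})),
        ]
        assert compute_coverage(plants, x=5, k=2) == pytest.approx(0.3)

    def test_empty_collection_has_zero_coverage(self):
        assert compute_coverage([], x=5, k=2) == 0.0

    def test_full_coverage_reaches_one(self):
        plants = [PlantGenotype(frozenset({"a", "b", "c"}))]
        assert compute_coverage(plants, x=3, k=2) == 1.0


class TestRunTrial:
    def test_trivial_design_needs_exactly_one_plant(self, rng):
        design = ideal_design(x=1, g=1, k=1)
        lib = build_library(design)
        assert run_trial(lib, design, rng) == 1

    def test_unreachable_coverage_raises_with_uncovered_combos(self, rng):
        design = ExperimentDesign(x=3, g=1, k=1, eps_KO=0.0, max_plants=200)
        lib = build_library(design)
        with pytest.raises(CoverageUnreachableError) as err:
            run_trial(lib, design, rng)
        assert len(err.value.uncovered) == 3

    def test_matches_classical_coupon_collector(self):
        # uniform pool, perfect efficiencies, k=r=1: N is the classical
        # 20-coupon waiting time with E = 20*H_20 and known variance
        n = 20
        design = ideal_design(x=n, g=1, k=1, n_trials=400, seed=5)
        est = estimate_min_library_size(design)
        expected = n * sum(1.0 / i for i in range(1, n + 1))
        p = np.arange(n, 0, -1) / n
        sigma = np.sqrt(np.sum((1 - p) / p**2))
        assert est.mean == pytest.approx(expected, abs=3 * sigma / np.sqrt(400))
        assert est.std == pytest.approx(sigma, rel=0.25)

    @pytest.mark.parametrize("seed", [0, 1])
    @pytest.mark.parametrize("x,g,k,r", [(6, 2, 2, 2), (5, 1, 2, 3), (8, 2, 1, 1)])
    def test_trial_size_at_least_best_case_bound(self, x, g, k, r, seed):
        design = ideal_design(x=x, g=g, k=k, r=r, seed=seed)
        lib = build_library(design)
        size = run_trial(lib, design, np.random.default_rng(seed))
        assert size >= np.ceil(comb(x, k) / comb(r, k))

    def test_estimate_reproducible(self):
        design = ExperimentDesign(x=5, g=2, k=1, n_trials=25, seed=99)
        a = estimate_min_library_size(design)
        b = estimate_min_library_size(design)
        assert np.array_equal(a.trial_sizes, b.trial_sizes)
        assert a.mean == pytest.approx(np.mean(a.trial_sizes))
        assert a.std == pytest.approx(np.std(a.trial_sizes, ddof=1))


class TestCoverageCurve:
    def test_monotone_from_zero_to_full(self):
        design = ideal_design(x=4, g=1, k=1, n_trials=20, seed=2)
        curve = simulated_coverage_curve(design, [0, 2, 5, 10, 50, 200])
        assert curve.gamma[0] == 0.0
        assert np.all(np.diff(curve.gamma) >= 0)
        assert curve.gamma[-1] == pytest.approx(1.0)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            simulated_coverage_curve(ExperimentDesign(x=2, g=1, n_trials=2), [5, 1])


class TestKnockoutCountDistribution:
    def test_zero_efficiency_is_point_mass_at_wildtype(self, rng):
        lib = make_library(np.ones(6), np.repeat(np.arange(3), 2))
        dist = knockout_count_distribution(lib, r=2, eps_KO=0.0, n_samples=500, rng=rng)
        assert dist.probs[0] == 1.0

    def test_two_slot_ideal_screen_collides_at_gene_frequency(self, rng):
        # 20 genes, uniform, perfect editing: both slots hit the same gene
        # with probability 1/20, else two knockouts
        lib = make_library(np.ones(120), np.repeat(np.arange(20), 6))
        dist = knockout_count_distribution(lib, r=2, eps_KO=1.0, n_samples=100_000, rng=rng)
        se = np.sqrt(0.05 * 0.95 / 100_000)
        assert dist.probs[1] == pytest.approx(0.05, abs=3 * se)
        assert dist.probs[2] == pytest.approx(0.95, abs=3 * se)

    def test_probabilities_sum_to_one(self, rng):
        lib = build_library(ExperimentDesign(seed=8))
        dist = knockout_count_distribution(lib, r=4, eps_KO=0.8, n_samples=2_000, rng=rng)
        assert dist.probs.sum() == pytest.approx(1.0)
        assert dist.max_knockouts == 4


class TestVectorisedEngineAgainstScalarModel:
    def test_knockout_rate_matches_per_plant_operations(self):
        """The chunked engine and the scalar ops realise the same model."""
        design = ExperimentDesign(x=5, g=2, k=2, r=3, seed=21)
        lib = build_library(design)
        rng = np.random.default_rng(0)
        scalar_counts = np.array([
            len(edit_plant(lib, assemble_construct(lib, 3, rng), design.eps_KO, rng))
            for _ in range(4_000)
        ])
        dist = knockout_count_distribution(lib, 3, design.eps_KO, 20_000, np.random.default_rng(1))
        vector_mean = np.sum(np.arange(4) * dist.probs)
        se = scalar_counts.std() / np.sqrt(len(scalar_counts))
        assert scalar_counts.mean() == pytest.approx(vector_mean, abs=4 * se)

    def test_first_seen_indices_define_trial_size(self):
        design = ideal_design(x=4, g=1, k=1, seed=3)
        lib = build_library(design)
        first, produced = _trial_first_seen(lib, design, np.random.default_rng(3), 1000)
        size = run_trial(lib, design, np.random.default_rng(3))
        assert size == first.max() + 1
        assert produced >= size
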