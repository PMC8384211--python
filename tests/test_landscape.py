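"""Genetic algorithm, variant constructors and landscape histograms."""

import numpy as np
import pytest

from pscapsid import (
    AffinityBands,
    GAConfig,
    KineticParams,
    MoveSet,
    RNAVariant,
    evolve,
    fitness,
    knockout,
    landscape_histogram,
    nucleation_only,
    nucleation_site,
    random_variant,
)


class TestRandomVariant:
    def test_values_in_bounds(self, rng):
        v = random_variant(rng)
        assert (v.dg_ps >= -12).all() and (v.dg_ps <= -4).all()

    def test_strong_band_frequency(self, rng):
        """Uniform draws over [-12,-4]: the strong band [-12,-9] has width
        3 of 8, so per-position strong frequency is ~3/8."""
        draws = np.array([random_variant(rng).dg_ps for _ in range(1024)])
        frac = (draws <= -9.0).mean(axis=0)
        assert np.allclose(frac, 3 / 8, atol=0.06)

    def test_seed_reproducibility(self):
        a = random_variant(np.random.default_rng(42))
        b = random_variant(np.random.default_rng(42))
        assert np.array_equal(a.dg_ps, b.dg_ps)


class TestNucleationSite:
    def test_all_weak_has_no_site(self):
        assert nucleation_site(RNAVariant.uniform(-4.0)) is None

    def test_terminal_site_detected(self):
        v = RNAVariant.uniform(-5.0).with_dg(range(26, 30), -10.0)
        assert nucleation_site(v) == (26, 29)

    def test_longest_run_wins(self):
        v = RNAVariant.uniform(-5.0).with_dg([3, 4], -10.0).with_dg(
            range(20, 24), -9.5
        )
        assert nucleation_site(v) == (20, 23)

    def test_bands_partition_range(self):
        bands = AffinityBands()
        assert bands.classify(-4.5) == "weak"
        assert bands.classify(-7.0) == "medium"
        assert bands.classify(-9.0) == "strong"


class TestKnockoutConstructors:
    @pytest.fixture()
    def variant(self):
        return RNAVariant.uniform(-5.5).with_dg(range(27, 30), -11.0)

    def test_knockout_weakens_site(self, variant):
        ko = knockout(variant)
        assert (ko.dg_ps[27:30] == -4.0).all()
        assert np.array_equal(ko.dg_ps[:27], variant.dg_ps[:27])

    def test_nucleation_only_keeps_site(self, variant):
        nuc = nucleation_only(variant)
        assert np.array_equal(nuc.dg_ps[27:30], variant.dg_ps[27:30])
        assert (nuc.dg_ps[:27] == -4.0).all()

    def test_composition_gives_uniform_weak(self, variant):
        both = nucleation_only(knockout(variant).with_dg([29], -10.0))
        # knockout then nucleation-only of a variant with a single strong PS
        # leaves everything weak except that PS
        assert (both.dg_ps[:29] == -4.0).all()

    def test_no_site_raises(self):
        with pytest.raises(ValueError, match="nucleation site"):
            knockout(RNAVariant.uniform(-5.0))


@pytest.fixture(scope="module")
def tiny_run(lattice):
    ga = GAConfig(
        pop_size=8, survivors=2, copies=16, generations=3,
        master_seed=5, top_k=4, convergence_window=0.0,
    )
    params = KineticParams(t_max=1.0e5, quiesce_window=2.5e4)
    rng = np.random.default_rng(1)
    pop = [random_variant(rng) for _ in range(8)]
    traj = evolve(pop, ga, params, MoveSet([2, 3, 4, 5]), lattice=lattice)
    return pop, traj


class TestEvolve:
    def test_population_size_constant(self, tiny_run):
        _, traj = tiny_run
        assert len(traj.population) == 8

    def test_history_schema(self, tiny_run):
        _, traj = tiny_run
        assert list(traj.history.columns) == [
            "generation", "best", "top_k_mean", "top_k_spread", "mean",
        ]
        assert len(traj.history) == 3

    def test_bounds_preserved(self, tiny_run):
        _, traj = tiny_run
        for v in traj.population:
            assert (v.dg_ps >= -12).all() and (v.dg_ps <= -4).all()

    def test_survivor_persistence(self, lattice):
        """Survivor genotypes appear unchanged in the next generation."""
        ga = GAConfig(
            pop_size=6, survivors=2, copies=8, generations=2,
            master_seed=9, top_k=2, convergence_window=0.0,
        )
        params = KineticParams(t_max=5.0e4, quiesce_window=2.0e4)
        rng = np.random.default_rng(3)
        pop = [random_variant(rng) for _ in range(6)]
        traj = evolve(pop, ga, params, MoveSet([2, 3, 4, 5]), lattice=lattice)
        final_genomes = {tuple(np.round(v.dg_ps, 12)) for v in traj.population}
        initial_genomes = {tuple(np.round(v.dg_ps, 12)) for v in pop}
        # elitist: at least the survivors of the last selection are original
        # genotypes or mutants thereof; the best genome is carried over intact
        assert tuple(np.round(traj.best.dg_ps, 12)) in (
            final_genomes & (initial_genomes | final_genomes)
        )

    def test_wrong_population_size_rejected(self, lattice):
        ga = GAConfig(pop_size=8, survivors=2, copies=4, generations=1)
        with pytest.raises(ValueError, match="population"):
            evolve([RNAVariant.uniform(-9.0)], ga,
                   KineticParams(), MoveSet([2, 3, 4, 5]), lattice=lattice)


class TestFitness:
    def test_structural_zero_move_set(self, lattice, fast_kinetics):
        """No PS profile can rescue a move set without contact moves."""
        for v in (RNAVariant.uniform(-9.0), RNAVariant.uniform(-12.0)):
            assert fitness(
                v, fast_kinetics, MoveSet([2, 5, 6, 7]), seed=4,
                copies=30, lattice=lattice,
            ) == 0.0

    def test_same_seed_same_fitness(self, lattice, fast_kinetics):
        v = RNAVariant.uniform(-9.0)
        f1 = fitness(v, fast_kinetics, MoveSet([2, 3, 4, 5]), seed=7,
                     copies=20, lattice=lattice)
        f2 = fitness(v, fast_kinetics, MoveSet([2, 3, 4, 5]), seed=7,
                     copies=20, lattice=lattice)
        assert f1 == f2


class TestLandscapeHistogram:
    def test_counts_sum_to_n(self, lattice):
        params = KineticParams(t_max=5.0e4, quiesce_window=2.0e4)
        hist = landscape_histogram(
            5, params, MoveSet([2, 3, 4, 5]), seed=2, copies=10,
            lattice=lattice,
        )
        assert hist["count"].sum() == 5
        assert (hist["bin_right"] - hist["bin_left"]).round(6).nunique() == 1

    def test_single_variant_single_bin(self, lattice):
        params = KineticParams(t_max=5.0e4, quiesce_window=2.0e4)
        hist = landscape_histogram(
            1, params, MoveSet([2, 3, 4, 5]), seed=3, copies=10,
            lattice=lattice,
        )
        assert (hist["count"] > 0).sum() == 1

    def test_invalid_n_rejected(self, lattice):
        with pytest.raises(ValueError):
            landscape_histogram(0, KineticParams(), MoveSet([2, 3, 4, 5]),
                                seed=1, lattice=lattice)
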