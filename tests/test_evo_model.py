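"""Unit and property tests for the mutation/selection/demography layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strsel.evo_model import (
    AlleleGrid,
    DegenerateFitnessError,
    DemographicModel,
    Epoch,
    InvalidGridError,
    MutationModel,
    SelectionModel,
    allele_mutation_rate,
    apply_drift,
    apply_selection,
    build_mutation_matrix,
    european_demography,
    population_size_at,
    step_direction_probs,
    validate_frequencies,
)


def brute_force_selection(p, s, offsets):
    """Oracle: enumerate all diploid genotypes under random mating.

    Genotype (i, j) has frequency p_i*p_j and fitness (w_i + w_j)/2; the
    post-selection frequency of allele i sums its share over genotypes.
    """
    w = np.maximum(1.0 - s * np.abs(offsets), 0.0)
    n = len(p)
    out = np.zeros(n)
    total = 0.0
    for i in range(n):
        for j in range(n):
            g = p[i] * p[j] * 0.5 * (w[i] + w[j])
            out[i] += 0.5 * g
            out[j] += 0.5 * g
            total += g
    return out / total


class TestAlleleGrid:
    def test_default_grid_shape(self, dinuc_grid):
        assert dinuc_grid.n == 25
        assert dinuc_grid.offsets[0] == -12 and dinuc_grid.offsets[-1] == 12
        assert dinuc_grid.offsets[dinuc_grid.center] == 0

    @pytest.mark.parametrize("n", [2, 4, 1])
    def test_even_or_tiny_n_rejected(self, n):
        with pytest.raises(InvalidGridError):
            AlleleGrid(xopt=11, repeat_unit_len=2, n=n)

    def test_unit_length_validated(self):
        with pytest.raises(InvalidGridError):
            AlleleGrid(xopt=11, repeat_unit_len=5)


class TestMutationRate:
    def test_reference_length_identity(self):
        m = MutationModel(mu0=1e-5, L=0.05)
        assert allele_mutation_rate(m, 0, 11) == pytest.approx(1e-5, rel=1e-12)

    def test_log_linear_increase(self):
        # ten units above the optimum: 10**(-5 + 0.5)
        m = MutationModel(mu0=1e-5, L=0.05)
        assert allele_mutation_rate(m, 10, 11) == pytest.approx(10**-4.5, rel=1e-12)

    def test_cap_clamps_high_rates(self):
        m = MutationModel(mu0=5e-4, L=0.3)
        assert allele_mutation_rate(m, 10, 11) == 1e-3

    def test_floor_clamps_low_rates(self):
        m = MutationModel(mu0=1e-6, L=0.5)
        assert allele_mutation_rate(m, -12, 20) == 1e-8

    def test_nonpositive_length_raises(self):
        m = MutationModel(mu0=1e-5)
        with pytest.raises(InvalidGridError):
            allele_mutation_rate(m, -5, 5)

    @given(
        mu0=st.floats(1e-7, 1e-3),
        L=st.floats(0.0, 0.5),
        k=st.integers(-10, 11),
    )
    @settings(deadline=None, max_examples=60)
    def test_monotone_and_bounded(self, mu0, L, k):
        m = MutationModel(mu0=mu0, L=L)
        lo = allele_mutation_rate(m, k, 12)
        hi = allele_mutation_rate(m, k + 1, 12)
        assert lo <= hi
        assert m.rate_floor <= lo <= m.rate_cap

    def test_explicit_ref_len_shifts_anchor(self):
        m = MutationModel(mu0=1e-5, L=0.1, ref_len=10)
        # allele length 12 sits two units above the anchor
        assert allele_mutation_rate(m, 0, 12) == pytest.approx(10**-4.8, rel=1e-12)


class TestStepDirection:
    def test_unbiased_at_optimum(self):
        assert step_direction_probs(0.3, 0.9, 0) == (0.5, 0.5)

    def test_long_alleles_contract(self):
        pe, pc = step_direction_probs(0.3, 0.9, 2)
        assert pe == pytest.approx(0.23)
        assert pc == pytest.approx(0.77)

    @given(beta=st.floats(0.0, 2.0), rho=st.floats(0.01, 1.0), k=st.integers(-12, 12))
    @settings(deadline=None, max_examples=80)
    def test_mirror_symmetry_and_normalization(self, beta, rho, k):
        pe, pc = step_direction_probs(beta, rho, k)
        pe_m, pc_m = step_direction_probs(beta, rho, -k)
        assert pe == pytest.approx(pc_m, abs=1e-12)
        assert pc == pytest.approx(pe_m, abs=1e-12)
        assert pe + pc == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= pe <= 1.0

    def test_clamped_regime_stays_normalized(self):
        pe, pc = step_direction_probs(2.0, 1.0, 10)  # raw values exit [0, 1]
        assert (pe, pc) == (0.0, 1.0)


class TestMutationMatrix:
    @pytest.mark.parametrize("n", [3, 25])
    @pytest.mark.parametrize(
        "mu0,L,rho,beta",
        [(1e-4, 0.0, 0.9, 0.0), (1e-3, 0.05, 0.5, 0.3), (1e-5, 0.1, 1.0, 1.0),
         (5e-4, 0.02, 0.1, 0.05)],
    )
    def test_rows_stochastic(self, n, mu0, L, rho, beta):
        grid = AlleleGrid(xopt=15, repeat_unit_len=2, n=n)
        T = build_mutation_matrix(MutationModel(mu0=mu0, L=L, rho=rho, beta=beta), grid)
        assert np.all(T >= 0)
        assert np.abs(T.sum(axis=1) - 1.0).max() < 1e-12

    def test_negligible_rate_gives_identity(self):
        m = MutationModel(mu0=1e-300, L=0.0, rate_floor=0.0)
        grid = AlleleGrid(xopt=11, repeat_unit_len=2)
        T = build_mutation_matrix(m, grid)
        assert np.allclose(T, np.eye(25), atol=1e-250)

    def test_rho_one_is_single_step(self):
        grid = AlleleGrid(xopt=11, repeat_unit_len=2)
        m = MutationModel(mu0=1e-4, L=0.0, rho=1.0, beta=0.0)
        T = build_mutation_matrix(m, grid)
        i = grid.center
        mu = allele_mutation_rate(m, 0, 11)
        assert T[i, i - 1] == pytest.approx(mu / 2)
        assert T[i, i + 1] == pytest.approx(mu / 2)
        off = T[i].copy()
        off[[i - 1, i, i + 1]] = 0
        assert np.all(off == 0)

    def test_boundary_mass_accumulates_inward(self):
        # with rho small, multi-unit steps beyond the edge land on the edge
        grid = AlleleGrid(xopt=11, repeat_unit_len=2, n=5)
        m = MutationModel(mu0=1e-3, L=0.0, rho=0.2, beta=0.0)
        T = build_mutation_matrix(m, grid)
        mu = 1e-3
        # from offset +1 (index 3), expansion mass: step 1 -> edge gets tail
        assert T[3, 4] == pytest.approx(mu * 0.5 * 1.0)  # whole geometric tail
        assert np.abs(T.sum(axis=1) - 1.0).max() < 1e-12


class TestSelection:
    def test_neutral_is_exact_identity(self, rng, dinuc_grid):
        p = rng.dirichlet(np.ones(25))
        out = apply_selection(p, SelectionModel(0.0), dinuc_grid)
        assert np.array_equal(out, p)

    def test_fixed_optimum_unchanged(self, dinuc_grid):
        p = np.zeros(25)
        p[dinuc_grid.center] = 1.0
        out = apply_selection(p, SelectionModel(0.3), dinuc_grid)
        assert np.allclose(out, p)

    def test_matches_diploid_enumeration(self, rng, dinuc_grid):
        for _ in range(10):
            p = rng.dirichlet(np.ones(25))
            for s in (0.01, 0.1, 0.5):
                got = apply_selection(p, SelectionModel(s), dinuc_grid)
                want = brute_force_selection(p, s, dinuc_grid.offsets)
                assert np.allclose(got, want, atol=1e-12)

    def test_optimum_gains_against_distant_allele(self, dinuc_grid):
        p = np.zeros(25)
        p[dinuc_grid.center] = 0.5
        p[dinuc_grid.index_of(2)] = 0.5
        out = apply_selection(p, SelectionModel(0.1), dinuc_grid)
        assert out[dinuc_grid.center] > 0.5

    def test_mean_distance_never_increases(self, rng, dinuc_grid):
        absk = np.abs(dinuc_grid.offsets)
        for _ in range(20):
            p = rng.dirichlet(np.ones(25))
            out = apply_selection(p, SelectionModel(0.05), dinuc_grid)
            assert out @ absk <= p @ absk + 1e-12

    def test_zero_mean_fitness_raises(self, dinuc_grid):
        p = np.zeros(25)
        p[0] = 1.0  # offset -12, fitness floored at 0 under s = 1
        with pytest.raises(DegenerateFitnessError):
            apply_selection(p, SelectionModel(1.0), dinuc_grid)


class TestDrift:
    def test_monomorphic_is_fixed_point(self, rng):
        p = np.zeros(5)
        p[2] = 1.0
        assert np.array_equal(apply_drift(p, 100, rng), p)

    def test_seeded_determinism(self):
        p = np.array([0.2, 0.3, 0.5])
        a = apply_drift(p, 500, np.random.default_rng(7))
        b = apply_drift(p, 500, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_multinomial_mean(self, rng):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        neff = 500
        reps = 10_000
        counts = rng.multinomial(2 * neff, p, size=reps) / (2 * neff)
        se = np.sqrt(p * (1 - p) / (2 * neff * reps))
        assert np.all(np.abs(counts.mean(axis=0) - p) < 3 * se + 1e-12)


class TestDemography:
    @pytest.mark.parametrize(
        "t,size",
        [(60_000, 7310), (55_920, 7310), (5920, 14_474), (3000, 14_474),
         (2040, 1861), (1000, 1861), (920, 1032)],
    )
    def test_printed_epoch_sizes(self, eur_demog, t, size):
        assert population_size_at(eur_demog, t) == size

    def test_growth_phases_reach_present(self, eur_demog):
        n205 = population_size_at(eur_demog, 205)
        assert n205 == round(1032 * math.exp(0.00307 * 715))
        n0 = population_size_at(eur_demog, 0)
        assert n0 == round(n205 * math.exp(0.0195 * 205)) or abs(
            n0 - 1032 * math.exp(0.00307 * 715) * math.exp(0.0195 * 205)
        ) <= 1

    def test_negative_time_rejected(self, eur_demog):
        with pytest.raises(ValueError):
            population_size_at(eur_demog, -1)

    def test_total_span(self, eur_demog):
        assert eur_demog.total_generations == 55_920

    def test_trajectory_matches_pointwise(self, eur_demog):
        traj = eur_demog.size_trajectory()
        assert len(traj) == 55_920
        g = eur_demog.total_generations
        for f in (0, 50_000, 53_880, 55_919):
            assert traj[f] == population_size_at(eur_demog, g - f)

    def test_rescaling(self, eur_demog):
        scaled = eur_demog.rescaled(10)
        assert scaled.total_generations == pytest.approx(5592, abs=2)
        assert scaled.epochs[0].initial_size == 731
        assert scaled.epochs[3].growth_rate == pytest.approx(0.0307)

    def test_validation(self):
        with pytest.raises(ValueError):
            Epoch(0, 100.0)
        with pytest.raises(ValueError):
            Epoch(10, 0.5)
        with pytest.raises(ValueError):
            DemographicModel(())


class TestValidation:
    def test_frequency_vector_checks(self):
        with pytest.raises(ValueError):
            validate_frequencies(np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            validate_frequencies(np.array([-0.1, 1.1]))

    def test_mutation_model_bounds(self):
        with pytest.raises(ValueError):
            MutationModel(mu0=0.0)
        with pytest.raises(ValueError):
            MutationModel(mu0=1e-4, rho=0.0)
        with pytest.raises(ValueError):
            MutationModel(mu0=1e-4, beta=-0.1)
        with pytest.raises(ValueError):
            MutationModel(mu0=0.1)  # above the cap

    def test_selection_model_bounds(self):
        with pytest.raises(ValueError):
            SelectionModel(-0.1)
        with pytest.raises(ValueError):
            SelectionModel(1.5)
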