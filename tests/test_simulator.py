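"""Tests for the forward simulator, lookup tables, and error injection."""

import numpy as np
import pytest

from strsel.evo_model import AlleleGrid, MutationModel, SelectionModel
from strsel.simulator import (
    DEFAULT_S_KEYS,
    ErrorModel,
    LookupTable,
    TableCoverageError,
    build_lookup_table,
    default_s_grid,
    end_sample,
    inject_genotyping_errors,
    modal_allele,
    modal_match_fraction,
    round_s,
    s_key_indices,
    simulate_batch,
    simulate_locus,
)


class TestRoundS:
    @pytest.mark.parametrize(
        "s,key",
        [
            (0.0, 0.0),
            (8e-6, 0.0),  # below 1e-5 rounds to neutral
            (1e-5, 1e-5),
            (0.00234, 0.002),
            (0.049, 0.05),
            (0.73, 0.7),
            (0.97, 1.0),
            (1.0, 1.0),
            (3.0, 1.0),  # above the fitness cap collapses to 1
        ],
    )
    def test_examples(self, s, key):
        assert round_s(s) == key

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            round_s(-1e-3)

    def test_key_grid_is_closed_under_rounding(self):
        for key in default_s_grid():
            assert round_s(key) == key

    def test_vectorized_agrees_with_scalar(self, rng):
        s = 10 ** rng.uniform(-7, 0.3, size=2000)
        keys = DEFAULT_S_KEYS[s_key_indices(s)]
        for si, ki in zip(s[:200], keys[:200]):
            assert round_s(si) == ki
        # full agreement, not just a sample
        assert np.all(keys == np.array([round_s(x) for x in s]))


class TestEndSample:
    def test_monomorphic_unchanged(self, rng):
        p = np.zeros(5)
        p[1] = 1.0
        assert np.array_equal(end_sample(p, 100, rng), p)

    def test_two_draws_exhaustive_outcomes(self):
        p = np.array([0.5, 0.5])
        seen = set()
        for seed in range(30):
            out = end_sample(p, 2, np.random.default_rng(seed))
            seen.add(tuple(out))
        assert seen <= {(1.0, 0.0), (0.5, 0.5), (0.0, 1.0)}

    def test_expectation_matches_input(self, rng):
        p = np.array([0.25, 0.25, 0.5])
        reps = 10_000
        draws = rng.multinomial(50, p, size=reps) / 50
        se = np.sqrt(p * (1 - p) / (50 * reps))
        assert np.all(np.abs(draws.mean(axis=0) - p) < 3 * se + 1e-12)

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError):
            end_sample(np.array([1.0]), 1, rng)


class TestSimulate:
    def test_seeded_determinism(self, small_demog, dinuc_grid, hot_mut):
        kw = dict(sample_size=100)
        a = simulate_locus(hot_mut, SelectionModel(0.01), small_demog, dinuc_grid,
                           rng=np.random.default_rng(3), **kw)
        b = simulate_locus(hot_mut, SelectionModel(0.01), small_demog, dinuc_grid,
                           rng=np.random.default_rng(3), **kw)
        assert np.array_equal(a.final_freqs, b.final_freqs)

    def test_floor_rate_keeps_optimum_fixed(self, small_demog, dinuc_grid):
        mut = MutationModel(mu0=1e-300, L=0.0, rate_floor=0.0)
        loc = simulate_locus(mut, SelectionModel(0.0), small_demog, dinuc_grid,
                             sample_size=100, rng=np.random.default_rng(0))
        expected = np.zeros(25)
        expected[dinuc_grid.center] = 1.0
        assert np.array_equal(loc.final_freqs, expected)

    def test_heterozygosity_monotone_in_mutation_rate(self, small_demog, dinuc_grid, rng):
        means = []
        for mu0 in (1e-6, 1e-5, 1e-4):
            mut = MutationModel(mu0=mu0, L=0.05, rho=0.9, beta=0.3)
            f = simulate_batch(mut, np.zeros(200), small_demog, dinuc_grid, rng,
                               sample_size=200)
            means.append((1 - (f**2).sum(axis=1)).mean())
        assert means[0] < means[1] < means[2]

    def test_heterozygosity_antimonotone_in_selection(self, small_demog, dinuc_grid,
                                                      hot_mut, rng):
        means = []
        for s in (0.0, 1e-2, 1e-1):
            f = simulate_batch(hot_mut, np.full(200, s), small_demog, dinuc_grid, rng,
                               sample_size=200)
            means.append((1 - (f**2).sum(axis=1)).mean())
        assert means[0] > means[1] > means[2]

    def test_directional_bias_tightens_distribution(self, small_demog, dinuc_grid, rng):
        mean_absk = []
        absk = np.abs(dinuc_grid.offsets)
        for beta in (0.0, 0.8):
            mut = MutationModel(mu0=1e-3, L=0.05, rho=0.9, beta=beta)
            f = simulate_batch(mut, np.zeros(300), small_demog, dinuc_grid, rng)
            mean_absk.append((f @ absk).mean())
        assert mean_absk[1] < mean_absk[0]

    def test_rescaled_run_preserves_diversity_scale(self, eur_demog, dinuc_grid,
                                                    dinuc_mut, rng):
        # classical rescaling keeps 4*N*mu fixed: scaled-run heterozygosity
        # should match a plain neutral expectation, not collapse by 10x
        f = simulate_batch(dinuc_mut, np.zeros(60), eur_demog, dinuc_grid, rng,
                           sample_size=1068, rescale=10)
        het = (1 - (f**2).sum(axis=1)).mean()
        assert 0.3 < het < 0.7


class TestLookupTable:
    def test_bookkeeping_small_grid(self, small_demog, dinuc_grid, hot_mut, rng):
        table = build_lookup_table(("AC", 11), hot_mut, small_demog, dinuc_grid, 100,
                                   rng, s_grid=[0.0, 0.001], reps_per_s=2)
        assert list(table.s_keys) == [0.0, 0.001]
        assert table.hets.shape == (2, 2)
        assert table.freqs.shape == (2, 2, 25)

    def test_query_served_from_rounded_key(self, small_demog, dinuc_grid, hot_mut, rng):
        table = build_lookup_table(("AC", 11), hot_mut, small_demog, dinuc_grid, 100,
                                   rng, s_grid=[0.0, 0.002], reps_per_s=2)
        assert table.rows_for(np.array([0.00234]))[0] == 1
        assert table.rows_for(np.array([8e-6]))[0] == 0

    def test_missing_key_error_names_key(self, small_demog, dinuc_grid, hot_mut, rng):
        table = build_lookup_table(("AC", 11), hot_mut, small_demog, dinuc_grid, 100,
                                   rng, s_grid=[0.0], reps_per_s=1)
        with pytest.raises(TableCoverageError, match="0.3"):
            table.rows_for(np.array([0.31]))

    def test_full_grid_covers_prior_support(self, small_demog, dinuc_grid, hot_mut, rng):
        table = build_lookup_table(("AC", 11), hot_mut, small_demog, dinuc_grid, 100,
                                   rng, reps_per_s=1)
        assert len(table.s_keys) == len(DEFAULT_S_KEYS) == 47
        s = 10 ** rng.uniform(-7, 0, size=500)
        assert np.all(table.rows_for(s) >= 0)

    def test_tsv_round_trip(self, small_demog, dinuc_grid, hot_mut, rng, tmp_path):
        table = build_lookup_table(("AC", 11), hot_mut, small_demog, dinuc_grid, 100,
                                   rng, s_grid=[0.0, 0.01], reps_per_s=3)
        path = tmp_path / "lut.tsv"
        table.to_tsv(path)
        back = LookupTable.from_tsv(path)
        assert back.class_key == table.class_key
        assert np.array_equal(back.s_keys, table.s_keys)
        assert np.allclose(back.hets, table.hets)
        assert np.allclose(back.freqs, table.freqs)

    def test_invalid_keys_rejected(self):
        with pytest.raises(ValueError):
            LookupTable(("AC", 11), np.array([0.0123]), np.zeros((1, 1)),
                        np.zeros((1, 1, 25)))


class TestModalAllele:
    def test_fixed_optimum(self, dinuc_grid):
        p = np.zeros(25)
        p[dinuc_grid.center] = 1.0
        assert modal_allele(p, dinuc_grid) == 0

    def test_argmax(self, dinuc_grid):
        p = np.zeros(25)
        p[dinuc_grid.index_of(-1)] = 0.4
        p[dinuc_grid.index_of(0)] = 0.35
        p[dinuc_grid.index_of(5)] = 0.25
        assert modal_allele(p, dinuc_grid) == -1

    def test_tie_breaks_toward_contraction(self, dinuc_grid):
        p = np.zeros(25)
        p[dinuc_grid.index_of(-2)] = 0.5
        p[dinuc_grid.index_of(2)] = 0.5
        assert modal_allele(p, dinuc_grid) == -2

    def test_tie_breaks_toward_small_offset(self, dinuc_grid):
        p = np.zeros(25)
        p[dinuc_grid.index_of(1)] = 0.5
        p[dinuc_grid.index_of(-3)] = 0.5
        assert modal_allele(p, dinuc_grid) == 1

    def test_match_fraction_one_without_mutation(self, small_demog, dinuc_grid):
        mut = MutationModel(mu0=1e-300, L=0.0, rate_floor=0.0)
        frac = modal_match_fraction(mut, SelectionModel(0.0), small_demog, dinuc_grid,
                                    20, np.random.default_rng(0))
        assert frac == 1.0

    def test_match_fraction_nondecreasing_in_s(self, small_demog, dinuc_grid, rng):
        fracs = [
            modal_match_fraction(
                MutationModel(mu0=1e-3, L=0.05, rho=0.9, beta=0.3),
                SelectionModel(s), small_demog, dinuc_grid, 150, rng)
            for s in (0.0, 1e-3, 1e-1)
        ]
        assert fracs[0] <= fracs[1] <= fracs[2]
        assert fracs[2] > 0.9


class TestErrorInjection:
    def test_zero_rate_equals_end_sample(self, dinuc_grid):
        p = np.full(25, 1 / 25)
        a = inject_genotyping_errors(p, 500, ErrorModel(0.0), dinuc_grid,
                                     np.random.default_rng(5))
        b = end_sample(p, 500, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_forced_flips_move_one_unit(self, dinuc_grid, rng):
        p = np.zeros(25)
        p[dinuc_grid.center] = 1.0
        out = inject_genotyping_errors(p, 2000, ErrorModel(1.0), dinuc_grid, rng)
        assert out[dinuc_grid.center] == 0.0
        up = out[dinuc_grid.index_of(1)]
        down = out[dinuc_grid.index_of(-1)]
        assert up + down == 1.0
        assert abs(up - 0.5) < 0.05

    def test_boundary_calls_move_inward(self, dinuc_grid, rng):
        p = np.zeros(25)
        p[0] = 1.0
        out = inject_genotyping_errors(p, 500, ErrorModel(1.0), dinuc_grid, rng)
        assert out[1] == 1.0

    def test_expected_flip_count(self, dinuc_grid, rng):
        # 0.1% error rate on 1,068 calls: about 1.07 flipped alleles expected
        p = np.zeros(25)
        p[dinuc_grid.center] = 1.0
        reps = 2000
        flips = []
        for _ in range(reps):
            out = inject_genotyping_errors(p, 1068, ErrorModel(0.001), dinuc_grid, rng)
            flips.append(1068 * (1 - out[dinuc_grid.center]))
        mean = np.mean(flips)
        se = np.std(flips) / np.sqrt(reps)
        assert abs(mean - 1.068) < 3 * se + 0.01
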