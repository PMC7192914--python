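"""Binned maximum-likelihood activity estimation."""

import numpy as np
import pytest
from scipy.stats import norm

from promdesign.mle import (
    FLAG_OK,
    FLAG_REPLICATE_DISCORDANT,
    BinLayout,
    MixtureParams,
    bin_prob,
    combine_replicates,
    default_mu_grid,
    extreme_bin_filter,
    fit_means,
    grid_search,
    loglik_matrix,
    normalize_counts,
    read_threshold_filter,
    rescale_bin_edges,
)
from promdesign.synthetic import SortConfig, simulate_sort


@pytest.fixture
def layout():
    return BinLayout.equal_width(-0.6, 0.6, 12)


class TestNormalizeCounts:
    def test_identity_when_cells_equal_reads(self):
        r = np.array([[3.0, 4.0], [0.0, 2.0]])
        A = normalize_counts(r, np.array([10, 10]), np.array([10, 10]))
        assert np.array_equal(A, r)

    def test_scaling_arithmetic(self):
        A = normalize_counts(
            np.array([2.0, 0.0]), np.array([100.0, 100.0]), np.array([50.0, 200.0])
        )
        assert A.tolist() == [[4.0, 0.0]]

    def test_column_sums_recover_cell_shares(self):
        rng = np.random.default_rng(0)
        r = rng.integers(0, 50, (30, 5)).astype(float)
        C = np.array([100, 200, 300, 400, 500.0])
        R = r.sum(axis=0)
        A = normalize_counts(r, C, R)
        # independently: column sum of A is C_i times the column read share (=1)
        assert np.allclose(A.sum(axis=0), C)

    def test_zero_read_bin_contributes_nothing(self):
        A = normalize_counts(np.array([5.0, 0.0]), np.array([10, 10]), np.array([10, 0]))
        assert A.tolist() == [[5.0, 0.0]]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_counts(np.array([-1.0]), np.array([1.0]), np.array([1.0]))


class TestBinProb:
    def test_contaminant_only_is_uniform(self, layout):
        p = bin_prob(0.0, MixtureParams(0.1, 1.0), layout)
        assert np.allclose(p, 1 / 12)

    def test_interior_bin_matches_normal_cdf(self):
        layout = BinLayout(np.array([-3.0, -1.0, 0.0, 3.0]))
        p = bin_prob(0.0, MixtureParams(1.0, 0.0), layout)
        assert p[1] == pytest.approx(norm.cdf(0) - norm.cdf(-1), abs=1e-9)
        assert p[1] == pytest.approx(0.34134, abs=1e-4)

    def test_sums_to_one_with_unbounded_tails(self, layout):
        for mu, sigma, eps in [(-2.0, 0.1, 0.0), (0.3, 0.5, 0.2), (5.0, 0.05, 0.01)]:
            p = bin_prob(mu, MixtureParams(sigma, eps), layout)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_bounded_tails_lose_mass_outside_range(self, layout):
        p = bin_prob(-0.6, MixtureParams(0.15, 0.0), layout, unbounded_tails=False)
        assert p.sum() == pytest.approx(0.5, abs=0.01)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            MixtureParams(0.0, 0.1)


class TestLoglikMatrix:
    def test_elementwise_matches_bin_prob(self, layout):
        mu_grid = np.linspace(-0.7, 0.7, 29)
        params = MixtureParams(0.15, 0.01)
        grid = loglik_matrix(layout, mu_grid, params)
        rng = np.random.default_rng(1)
        for _ in range(5):
            i = rng.integers(0, 12)
            j = rng.integers(0, len(mu_grid))
            direct = np.log(bin_prob(float(mu_grid[j]), params, layout)[i])
            assert grid.W[i, j] == pytest.approx(direct, abs=1e-12)

    def test_exp_columns_sum_to_one(self, layout):
        grid = loglik_matrix(layout, np.linspace(-0.7, 0.7, 15), MixtureParams(0.2, 0.05))
        assert np.allclose(np.exp(grid.W).sum(axis=0), 1.0)

    def test_empty_grid_rejected(self, layout):
        with pytest.raises(ValueError):
            loglik_matrix(layout, np.array([]), MixtureParams(0.1, 0.0))


class TestFitMeans:
    def test_counts_proportional_to_bin_prob_recover_mu(self, layout):
        params = MixtureParams(0.15, 0.01)
        mu_grid = default_mu_grid(layout)
        grid = loglik_matrix(layout, mu_grid, params)
        for mu_star in (-0.31, 0.0, 0.237):
            A = 1000 * bin_prob(mu_star, params, layout)
            fit = fit_means(A, grid)
            nearest = mu_grid[np.argmin(np.abs(mu_grid - mu_star))]
            assert fit.mu_hat[0] == pytest.approx(nearest, abs=1e-9)

    def test_matches_direct_per_sequence_loop(self, layout):
        # the A @ W product must equal a naive per-sequence evaluation of
        # the log-likelihood sum, exactly
        rng = np.random.default_rng(2)
        A = rng.integers(0, 40, (200, 12)).astype(float)
        A[0] = 0  # an empty row must be flagged
        params = MixtureParams(0.12, 0.02)
        mu_grid = default_mu_grid(layout, step=0.01)
        grid = loglik_matrix(layout, mu_grid, params)
        fit = fit_means(A, grid)
        assert fit.flag[0] == "no_reads" and np.isnan(fit.mu_hat[0])
        for s in range(1, 200):
            ll = np.array(
                [
                    (A[s] * np.log(bin_prob(float(m), params, layout))).sum()
                    for m in mu_grid
                ]
            )
            j = int(ll.argmax())
            assert fit.mu_hat[s] == mu_grid[j]
            assert fit.loglik[s] == pytest.approx(ll[j], rel=1e-12)

    def test_ties_break_to_smallest_mu(self, layout):
        params = MixtureParams(0.15, 1.0)  # eps=1: all mu equally likely
        grid = loglik_matrix(layout, default_mu_grid(layout), params)
        fit = fit_means(np.full((1, 12), 5.0), grid)
        assert fit.mu_hat[0] == grid.mu_grid[0]


class TestGridSearch:
    def test_single_point_grid_returned(self, layout):
        A = np.ones((5, 12))
        best, surface = grid_search(
            A, layout, sigma_grid=[0.2], epsilon_grid=[0.05]
        )
        assert best == MixtureParams(0.2, 0.05)
        assert len(surface) == 1

    def test_recovers_simulation_hyperparameters(self, layout):
        rng = np.random.default_rng(3)
        mus = rng.uniform(-0.4, 0.4, 300)
        cfg = SortConfig(sigma_cell=0.15, epsilon=0.05, cells_per_sequence=500)
        A = simulate_sort(mus, cfg, rng)
        best, _ = grid_search(
            A,
            layout,
            sigma_grid=np.arange(0.09, 0.22, 0.02),
            epsilon_grid=np.arange(0.0, 0.11, 0.025),
        )
        assert abs(best.sigma - 0.15) <= 0.02 + 1e-9
        assert abs(best.epsilon - 0.05) <= 0.025 + 1e-9

    def test_score_surface_invariant_to_sequence_order(self, layout):
        rng = np.random.default_rng(4)
        A = rng.integers(0, 30, (50, 12)).astype(float)
        _, s1 = grid_search(A, layout, sigma_grid=[0.1, 0.2], epsilon_grid=[0.0, 0.1])
        _, s2 = grid_search(
            A[::-1], layout, sigma_grid=[0.1, 0.2], epsilon_grid=[0.0, 0.1]
        )
        assert np.allclose(s1["score"], s2["score"])


class TestReplicatesAndFilters:
    def test_concordant_pair(self):
        out = combine_replicates(np.array([0.10]), np.array([0.10]))
        assert out.mu[0] == 0.10 and out.flag[0] == FLAG_OK

    def test_discordant_pair_flagged(self):
        out = combine_replicates(np.array([0.0]), np.array([0.25]))
        assert out.mu[0] == pytest.approx(0.125)
        assert out.flag[0] == FLAG_REPLICATE_DISCORDANT

    def test_boundary_not_over_threshold(self):
        out = combine_replicates(np.array([0.0]), np.array([0.20]))
        assert out.flag[0] == FLAG_OK and out.mu[0] == pytest.approx(0.10)

    def test_missing_replicate_excluded(self):
        out = combine_replicates(np.array([np.nan]), np.array([0.1]))
        assert np.isnan(out.mu[0]) and out.flag[0] == "no_reads"

    def test_extreme_bin_rule(self):
        rows = np.zeros((4, 12))
        rows[0, 11] = 5  # only highest bin
        rows[1, [10, 11]] = 3  # two top bins: kept
        rows[2, 0] = 2  # only lowest bin
        rows[3, [0, 5]] = 1
        assert extreme_bin_filter(rows).tolist() == [True, False, True, False]

    def test_extreme_bin_any_condition(self):
        # inducible-library rule: flag if extreme in either condition
        a = np.zeros((1, 12)); a[0, 3] = 5
        b = np.zeros((1, 12)); b[0, 11] = 5
        stack = np.stack([a, b], axis=2)
        assert extreme_bin_filter(stack).tolist() == [True]

    def test_read_threshold_inclusive(self):
        r1 = np.array([[5, 5], [4, 5], [0, 0]])
        r2 = np.array([[10, 0], [25, 25], [100, 0]])
        keep = read_threshold_filter([r1, r2], min_reads=10)
        assert keep.tolist() == [True, False, False]

    def test_threshold_zero_always_passes(self):
        assert read_threshold_filter([np.zeros((3, 2))], 0).all()


class TestRescaleBinEdges:
    def test_identity(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 500)
        slope, intercept = rescale_bin_edges(a, a)
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_affine_recovery(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.1, 0.3, 400)
        b = 2.0 * a + 0.3
        slope, intercept = rescale_bin_edges(a, b)
        assert slope == pytest.approx(2.0, abs=1e-6)
        assert intercept == pytest.approx(0.3, abs=1e-6)

    def test_unequal_sizes_interpolated(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 2000)
        b = 0.5 * rng.normal(0, 1, 700) + 0.1
        slope, intercept = rescale_bin_edges(a, b)
        assert slope == pytest.approx(0.5, abs=0.05)
        assert intercept == pytest.approx(0.1, abs=0.05)

    def test_shuffle_invariant(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 300)
        b = 3 * a - 1
        f1 = rescale_bin_edges(a, b)
        perm = rng.permutation(300)
        f2 = rescale_bin_edges(a[perm], b[rng.permutation(300)])
        assert f1 == pytest.approx(f2)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            rescale_bin_edges(np.ones(10), np.arange(10.0))
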