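"""Likelihood, EM and Gibbs samplers for the latent class models."""

import math

import numpy as np
import pytest

from prevclass import (
    BetaPrior,
    InvalidInputError,
    McmcConfig,
    MisclassParams,
    ModelPriors,
    SimulationSpec,
    TestPanelCounts,
    WrongModelError,
    apparent_prevalence,
    lca_em,
    lca_gibbs,
    lca_loglik,
    simulate_panel,
    single_test_gibbs,
    summarize,
)
from prevclass.samplers import _em_step, cell_probabilities
from prevclass.core import pattern_matrix


def brute_force_loglik(counts, pi, S, C):
    """Independent oracle: per-pattern sum over both latent classes, all loops."""
    total = 0.0
    k = counts.k
    for idx, count in enumerate(counts.counts):
        if count == 0:
            continue
        bits = [(idx >> (k - 1 - j)) & 1 for j in range(k)]
        p_case = pi
        p_ctrl = 1.0 - pi
        for j, b in enumerate(bits):
            p_case *= S[j] if b else 1.0 - S[j]
            p_ctrl *= (1.0 - C[j]) if b else C[j]
        total += count * math.log(p_case + p_ctrl)
    return total


def random_instance(rng, k):
    params = MisclassParams(
        pi=rng.uniform(0.02, 0.98),
        S=rng.uniform(0.55, 0.99, k),
        C=rng.uniform(0.55, 0.99, k),
    )
    counts = TestPanelCounts(k=k, counts=rng.integers(0, 30, size=2 ** k))
    if counts.n == 0:
        counts = TestPanelCounts(k=k, counts=np.ones(2 ** k, dtype=int))
    return counts, params


class TestLcaLoglik:
    def test_coin_flip_tests_give_uniform_patterns(self):
        # with S = C = 1/2 every pattern has probability 2**-k regardless of pi
        rng = np.random.default_rng(0)
        for k in (1, 2, 3):
            counts = TestPanelCounts(k=k, counts=rng.integers(1, 20, size=2 ** k))
            params = MisclassParams(pi=0.37, S=[0.5] * k, C=[0.5] * k)
            assert lca_loglik(counts, params) == pytest.approx(
                counts.n * k * math.log(0.5), rel=1e-12
            )

    def test_single_test_collapses_to_binomial(self):
        counts = TestPanelCounts.from_positives(30, 100)
        params = MisclassParams(pi=0.2, S=[0.9], C=[0.85])
        P = apparent_prevalence(0.2, 0.9, 0.85)
        expected = 30 * math.log(P) + 70 * math.log(1 - P)
        assert lca_loglik(counts, params) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_matches_brute_force_enumeration(self, k):
        rng = np.random.default_rng(100 + k)
        for _ in range(25):
            counts, params = random_instance(rng, k)
            assert lca_loglik(counts, params) == pytest.approx(
                brute_force_loglik(counts, params.pi, params.S, params.C), abs=1e-10
            )

    def test_zero_probability_pattern_returns_neg_inf_with_flag(self):
        counts = TestPanelCounts(k=1, counts=[0, 5])
        params = MisclassParams(pi=0.0, S=[1.0], C=[1.0])  # positives impossible
        with pytest.warns(UserWarning, match="zero-probability"):
            assert lca_loglik(counts, params) == float("-inf")

    def test_dimension_mismatch_raises(self):
        counts = TestPanelCounts.from_positives(3, 10)
        params = MisclassParams(pi=0.1, S=[0.9, 0.9], C=[0.9, 0.9])
        with pytest.raises(WrongModelError):
            lca_loglik(counts, params)


class TestLcaEm:
    def test_recovers_generating_parameters(self, truth_k3, panel_k3_large):
        params, ll, n_iters, converged = lca_em(panel_k3_large)
        assert converged
        assert params.pi == pytest.approx(truth_k3.pi, abs=0.01)
        np.testing.assert_allclose(params.S, truth_k3.S, atol=0.01)
        np.testing.assert_allclose(params.C, truth_k3.C, atol=0.01)

    def test_loglik_sequence_is_nondecreasing(self, panel_k3_large):
        B = pattern_matrix(3)
        vec = panel_k3_large.counts.astype(float)
        pi, S, C = 0.3, np.full(3, 0.7), np.full(3, 0.7)
        prev = brute_force_loglik(panel_k3_large, pi, S, C)
        for _ in range(50):
            pi, S, C = _em_step(vec, B, pi, S, C)
            ll = brute_force_loglik(panel_k3_large, pi, S, C)
            assert ll >= prev - 1e-9
            prev = ll

    def test_exact_model_counts_are_a_fixed_point(self, truth_k3):
        # expected counts constructed from the forward model itself
        expected = 1e6 * cell_probabilities(truth_k3)
        B = pattern_matrix(3)
        pi, S, C = _em_step(expected, B, truth_k3.pi, truth_k3.S, truth_k3.C)
        assert pi == pytest.approx(truth_k3.pi, abs=1e-12)
        np.testing.assert_allclose(S, truth_k3.S, atol=1e-12)
        np.testing.assert_allclose(C, truth_k3.C, atol=1e-12)

    def test_underidentified_k_requires_override(self):
        counts = TestPanelCounts.from_positives(30, 100)
        with pytest.raises(WrongModelError):
            lca_em(counts)
        params, *_ = lca_em(counts, allow_underidentified=True)
        assert 0.0 <= params.pi <= 1.0

    def test_rejects_boundary_init(self, panel_k3_large):
        bad = MisclassParams(pi=0.1, S=[1.0, 0.9, 0.9], C=[0.9, 0.9, 0.9])
        with pytest.raises(InvalidInputError):
            lca_em(panel_k3_large, init=bad)


class TestLcaGibbs:
    def test_reproducible_and_mixing(self, panel_k3_large):
        config = McmcConfig(seed=42, n_iter=1500, burn_in=500, n_chains=2)
        a = lca_gibbs(panel_k3_large, ModelPriors.flat(3), config)
        b = lca_gibbs(panel_k3_large, ModelPriors.flat(3), config)
        np.testing.assert_array_equal(a.draws, b.draws)
        summary = summarize(a)
        assert (summary.table["rhat"] < 1.1).all()

    def test_draw_invariants(self, panel_k3_large):
        config = McmcConfig(seed=7, n_iter=800, burn_in=200, n_chains=2)
        draws = lca_gibbs(panel_k3_large, ModelPriors.flat(3), config)
        assert np.all(draws.draws >= 0.0) and np.all(draws.draws <= 1.0)
        for j in (1, 2, 3):
            assert np.all(draws.pooled(f"S_{j}") + draws.pooled(f"C_{j}") > 1.0)

    def test_identifiable_posterior_concentrates_with_n(self, truth_k3):
        widths = []
        for i, n in enumerate([2000, 50000]):
            panel = simulate_panel(SimulationSpec(params=truth_k3, n=n, seed=60 + i))
            draws = lca_gibbs(panel, ModelPriors.flat(3),
                              McmcConfig(seed=61 + i, n_iter=2000, burn_in=500, n_chains=2))
            row = summarize(draws).table.loc["pi"]
            widths.append(row["upper"] - row["lower"])
        assert widths[1] < widths[0] / 2

    def test_prior_dimension_mismatch_raises(self, panel_k3_large):
        with pytest.raises(InvalidInputError):
            lca_gibbs(panel_k3_large, ModelPriors.flat(2),
                      McmcConfig(seed=1, n_iter=10, burn_in=0, n_chains=1))


class TestSingleTestGibbs:
    def test_requires_single_test_counts(self, panel_k3_large):
        with pytest.raises(WrongModelError):
            single_test_gibbs(panel_k3_large, ModelPriors.flat(3),
                              McmcConfig(seed=1, n_iter=10, burn_in=0, n_chains=1))

    def test_perfect_test_limit_reduces_to_binomial_proportion(self):
        near_one = BetaPrior(1e6, 1.0)
        priors = ModelPriors(BetaPrior(1, 1), (near_one,), (near_one,))
        counts = TestPanelCounts.from_positives(30, 100)
        draws = single_test_gibbs(
            counts, priors, McmcConfig(seed=3, n_iter=4000, burn_in=1000, n_chains=2)
        )
        assert summarize(draws).table.loc["pi", "mean"] == pytest.approx(0.30, abs=0.02)

    def test_flat_prior_posterior_matches_grid_integration(self):
        """Non-identifiable model vs a 200^3 lattice integration of the posterior."""
        y, n = 300, 1000
        g = (np.arange(200) + 0.5) / 200
        pi_g = g[:, None, None]
        S_g = g[None, :, None]
        C_g = g[None, None, :]
        P = pi_g * S_g + (1 - pi_g) * (1 - C_g)
        ll = y * np.log(P) + (n - y) * np.log1p(-P)
        ll = np.where(S_g + C_g > 1.0, ll, -np.inf)  # same labeling constraint
        post = np.exp(ll - ll.max())
        marg = post.sum(axis=(1, 2))
        marg /= marg.sum()
        grid_mean = float(g @ marg)
        cdf = np.cumsum(marg)
        grid_lo, grid_hi = g[np.searchsorted(cdf, 0.025)], g[np.searchsorted(cdf, 0.975)]

        draws = single_test_gibbs(
            TestPanelCounts.from_positives(y, n), ModelPriors.flat(1),
            McmcConfig(seed=5, n_iter=8000, burn_in=1000, n_chains=2),
        )
        row = summarize(draws).table.loc["pi"]
        assert row["mean"] == pytest.approx(grid_mean, abs=0.05)
        assert row["upper"] - row["lower"] == pytest.approx(grid_hi - grid_lo, abs=0.1)
        assert row["upper"] - row["lower"] > 0.5  # the interval never collapses

    def test_point_mass_priors_reproduce_closed_form_correction(self):
        from prevclass import correct_prevalence

        sharp = BetaPrior(0.995 * 2e6, 0.005 * 2e6)
        priors = ModelPriors(BetaPrior(1, 1), (sharp,), (sharp,))
        counts = TestPanelCounts.from_positives(1000, 100000)
        draws = single_test_gibbs(
            counts, priors, McmcConfig(seed=9, n_iter=4000, burn_in=1000, n_chains=2)
        )
        expected = correct_prevalence(0.01, 0.995, 0.995)
        assert summarize(draws).table.loc["pi", "median"] == pytest.approx(
            expected, abs=5e-4
        )


class TestConfigValidation:
    def test_seed_is_required(self):
        with pytest.raises(TypeError):
            McmcConfig(n_iter=100)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_iter=0),
            dict(burn_in=100, n_iter=100),
            dict(n_chains=0),
            dict(thin=0),
            dict(n_iter=10, burn_in=5, thin=10),  # retains no draws
        ],
    )
    def test_rejects_degenerate_settings(self, kwargs):
        with pytest.raises(InvalidInputError):
            McmcConfig(seed=1, **kwargs)

    def test_beta_prior_requires_positive_hyperparameters(self):
        with pytest.raises(InvalidInputError):
            BetaPrior(0.0, 1.0)
        assert BetaPrior(2.0, 6.0).mean == pytest.approx(0.25)
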