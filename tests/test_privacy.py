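import math
from fractions import Fraction

import numpy as np
import pytest

from fedrisk.dcn import DCNConfig, ModelParams, flat_per_example_gradients, init_params
from fedrisk.privacy import (
    DEFAULT_ORDERS,
    PrivacySpec,
    clip_gradient,
    compose_and_convert,
    dp_sgd_step,
    rdp_of_step,
    select_dp_hyperparameters,
)


class TestClip:
    @pytest.mark.parametrize(
        "g,c,expected",
        [
            ((3.0, 4.0), 1.0, (0.6, 0.8)),
            ((0.3, 0.4), 1.0, (0.3, 0.4)),
            ((3.0, 4.0), 2.5, (1.5, 2.0)),
        ],
    )
    def test_examples(self, g, c, expected):
        assert np.allclose(clip_gradient(np.array(g), c), expected)

    def test_zero_vector_passthrough(self):
        assert np.allclose(clip_gradient(np.zeros(4), 1.0), 0.0)

    def test_output_norm_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = rng.normal(0, 10, size=6)
            assert np.linalg.norm(clip_gradient(g, 0.7)) <= 0.7 * (1 + 1e-12)


def exact_subsampled_rdp(q: Fraction, sigma: Fraction, alpha: int) -> float:
    """Arbitrary-precision evaluation of the binomial-expansion RDP bound.

    Independent oracle: exact rationals for the binomial mixture weights,
    mpf-free via Fraction + math on the final log.
    """
    total = Fraction(0)
    scale = []  # exp(k(k-1)/(2 sigma^2)) handled at float precision at the end
    for k in range(alpha + 1):
        w = (
            Fraction(math.comb(alpha, k))
            * (1 - q) ** (alpha - k)
            * q**k
        )
        total += w * Fraction(
            math.exp(k * (k - 1) / (2 * float(sigma) ** 2))
        ).limit_denominator(10**30)
    return math.log(float(total)) / (alpha - 1)


class TestAccountant:
    def test_gaussian_mechanism_closed_form(self):
        assert rdp_of_step(1.0, 1.0, 2) == pytest.approx(1.0)
        for sigma in (0.5, 2.5):
            for alpha in (2, 8, 33):
                assert rdp_of_step(1.0, sigma, alpha) == pytest.approx(
                    alpha / (2 * sigma**2)
                )

    def test_no_sampling_limit(self):
        assert rdp_of_step(0.0, 1.0, 8) == 0.0
        assert rdp_of_step(1e-9, 1.0, 8) < 1e-12

    @pytest.mark.parametrize("q,sigma,alpha", [(0.01, 1.0, 8), (0.05, 2.5, 16), (0.2, 0.7, 4)])
    def test_subsampled_matches_exact_series(self, q, sigma, alpha):
        ours = rdp_of_step(q, sigma, alpha)
        oracle = exact_subsampled_rdp(Fraction(q).limit_denominator(10**6),
                                      Fraction(sigma).limit_denominator(10**6), alpha)
        assert ours == pytest.approx(oracle, rel=1e-9)

    def test_subsampled_near_one_approaches_gaussian(self):
        # the q<1 bound at q -> 1 approaches the pure Gaussian value
        assert rdp_of_step(1 - 1e-12, 1.0, 4) == pytest.approx(
            rdp_of_step(1.0, 1.0, 4), rel=1e-3
        )

    def test_invalid_order_errors(self):
        with pytest.raises(ValueError):
            rdp_of_step(0.5, 1.0, 1)
        with pytest.raises(ValueError):
            rdp_of_step(0.5, 0.0, 2)

    def test_compose_closed_form_minimum(self):
        """q=1, sigma=1, T=1, delta=1e-5: epsilon = min_a a/2 + ln(1e5)/(a-1)."""
        spec = PrivacySpec(noise_multiplier=1.0, sample_rate=1.0, steps=1, delta=1e-5)
        b = compose_and_convert(spec)
        grid = [a / 2 + math.log(1e5) / (a - 1) for a in range(2, 65)]
        assert b.epsilon == pytest.approx(min(grid), rel=1e-12)
        assert b.epsilon == pytest.approx(5.3026, abs=1e-4)
        assert b.alpha_star == 6

    def test_zero_steps_zero_epsilon(self):
        spec = PrivacySpec(steps=0, sample_rate=0.1)
        assert compose_and_convert(spec).epsilon == 0.0

    def test_epsilon_monotone_in_steps_and_sigma(self):
        sigmas = [0.5, 1.0, 1.5, 2.5, 5.0]
        steps = [1, 10, 100, 500, 1000]
        eps = {
            (s, t): compose_and_convert(
                PrivacySpec(noise_multiplier=s, sample_rate=0.05, steps=t)
            ).epsilon
            for s in sigmas
            for t in steps
        }
        for s in sigmas:
            col = [eps[(s, t)] for t in steps]
            assert all(a < b for a, b in zip(col, col[1:]))
        for t in steps:
            row = [eps[(s, t)] for s in sigmas]
            assert all(a > b for a, b in zip(row, row[1:]))

    def test_epsilon_monotone_in_q(self):
        es = [
            compose_and_convert(
                PrivacySpec(noise_multiplier=1.0, sample_rate=q, steps=100)
            ).epsilon
            for q in (0.01, 0.05, 0.2, 1.0)
        ]
        assert all(a < b for a, b in zip(es, es[1:]))


class TestDPSGDStep:
    def _setup(self, seed=0, n=5, d=3):
        cfg = DCNConfig(input_dim=d, n_cross_layers=1, deep_widths=(3,), seed=seed)
        params = init_params(cfg)
        rng = np.random.default_rng(seed)
        params = ModelParams.unflatten(
            cfg, params.flatten() + 0.2 * rng.normal(size=params.n_params)
        )
        X = rng.random((n, d))
        y = rng.integers(0, 2, size=n)
        return params, X, y

    def test_noiseless_unclipped_is_plain_sgd(self):
        """sigma=0, C=inf reduces to a vanilla minibatch gradient step."""
        params, X, y = self._setup()
        lr = 0.05
        stepped = dp_sgd_step(params, X, y, np.inf, 0.0, lr, np.random.default_rng(0))
        mean_grad = flat_per_example_gradients(params, X, y).mean(axis=0)
        expected = params.flatten() - lr * mean_grad
        assert np.array_equal(stepped.flatten(), expected)

    def test_single_example_clipped_direction(self):
        params, X, y = self._setup(n=1)
        g = flat_per_example_gradients(params, X[:1], y[:1])[0]
        C = 0.01  # force clipping
        stepped = dp_sgd_step(params, X[:1], y[:1], C, 0.0, 1.0, np.random.default_rng(0))
        delta = params.flatten() - stepped.flatten()
        assert np.linalg.norm(delta) == pytest.approx(C)
        cos = delta @ g / (np.linalg.norm(delta) * np.linalg.norm(g))
        assert cos == pytest.approx(1.0)

    def test_deterministic_given_rng(self):
        params, X, y = self._setup()
        a = dp_sgd_step(params, X, y, 0.5, 2.5, 0.1, np.random.default_rng(42))
        b = dp_sgd_step(params, X, y, 0.5, 2.5, 0.1, np.random.default_rng(42))
        assert np.array_equal(a.flatten(), b.flatten())

    def test_noise_sd_matches_sigma_c_over_batch(self):
        """Empirical per-coordinate noise SD ~= sigma*C/batch_size."""
        params, X, y = self._setup(n=4)
        sigma, C, lr, reps = 2.0, 0.5, 1.0, 4000
        base = dp_sgd_step(params, X, y, C, 0.0, lr, np.random.default_rng(0)).flatten()
        rng = np.random.default_rng(7)
        devs = np.empty((reps, base.size))
        for i in range(reps):
            noisy = dp_sgd_step(params, X, y, C, sigma, lr, rng).flatten()
            devs[i] = (noisy - base) / lr
        sd = devs.std(axis=0)
        assert np.allclose(sd, sigma * C / 4, rtol=0.06)

    def test_negative_sigma_errors(self):
        params, X, y = self._setup()
        with pytest.raises(ValueError):
            dp_sgd_step(params, X, y, 0.5, -1.0, 0.1, np.random.default_rng(0))


class TestHyperparameterSelection:
    GRID = (0.5, 1.0, 2.5, 5.0)

    def budget(self, sigma, C):
        return compose_and_convert(
            PrivacySpec(noise_multiplier=sigma, clip_norm=C, sample_rate=0.05, steps=200)
        ).epsilon

    def test_all_equal_picks_max_sigma(self):
        s, c = select_dp_hyperparameters(
            self.GRID, self.GRID, lambda s_, c_: 0.7, self.budget
        )
        assert s == 5.0

    def test_dominant_cell_wins(self):
        s, c = select_dp_hyperparameters(
            self.GRID,
            self.GRID,
            lambda s_, c_: 0.9 if (s_, c_) == (1.0, 2.5) else 0.5,
            self.budget,
        )
        assert (s, c) == (1.0, 2.5)

    def test_matches_brute_force_filter_then_argmin(self):
        rng = np.random.default_rng(3)
        table = {(s, c): 0.6 + 0.2 * rng.random() for s in self.GRID for c in self.GRID}
        got = select_dp_hyperparameters(
            self.GRID, self.GRID, lambda s, c: table[(s, c)], self.budget
        )
        best = max(table.values())
        feasible = [cell for cell, a in table.items() if a >= 0.95 * best]
        expect = min(feasible, key=lambda cell: (self.budget(*cell), -cell[0]))
        assert got == expect
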