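"""Category probabilities, response sampling, and likelihood evaluation."""

import numpy as np
import pytest

from mnrm import (
    ItemParameters,
    LatentSpec,
    ResponseMatrix,
    SimulationDesign,
    category_probabilities,
    complete_data_loglik,
    generate_dataset,
    marginal_loglik,
    sample_response,
)
from mnrm.errors import CapabilityError, NumericError, ShapeError
from ._oracles import brute_force_loglik, brute_force_probabilities


class TestCategoryProbabilities:
    def test_all_zero_parameters_give_uniform(self):
        p = category_probabilities(
            np.zeros(2), np.zeros(2), np.zeros((2, 7)), np.zeros(7)
        )
        np.testing.assert_allclose(p, 1 / 7, atol=1e-15)

    def test_known_softmax_value(self):
        """Logits (0, 1, 2) give softmax (0.09003, 0.24473, 0.66524)."""
        p = category_probabilities(
            np.array([1.0]), np.array([1.0]), np.array([[0.0, 1.0, 2.0]]), np.zeros(3)
        )
        np.testing.assert_allclose(p, [0.09003057, 0.24472847, 0.66524096], atol=1e-8)

    def test_matches_brute_force_on_random_draws(self, rng):
        """10,000 random parameter draws agree with a scalar softmax to 1e-12
        and always sum to one."""
        for _ in range(10_000 // 20):
            D = rng.integers(1, 5)
            K1 = rng.integers(2, 8)
            for _ in range(20):
                theta = rng.normal(size=D)
                slopes = rng.uniform(-1, 2, size=D)
                W = rng.normal(size=(D, K1))
                gamma = rng.normal(size=K1)
                p = category_probabilities(theta, slopes, W, gamma)
                q = brute_force_probabilities(theta, slopes, W, gamma)
                np.testing.assert_allclose(p, q, atol=1e-12)
                assert abs(p.sum() - 1) < 1e-12
                assert (p > 0).all()

    def test_shift_invariance(self, rng):
        """Adding a category-constant to one dimension's weight row cancels."""
        theta, slopes = rng.normal(size=3), rng.uniform(0.2, 0.8, 3)
        W = rng.normal(size=(3, 7))
        gamma = rng.normal(size=7)
        p1 = category_probabilities(theta, slopes, W, gamma)
        W2 = W.copy()
        W2[1] += 5.0
        p2 = category_probabilities(theta, slopes, W2, gamma)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_scale_absorption(self, rng):
        """Scaling a weight row by a > 0 and dividing the slope cancels."""
        theta, slopes = rng.normal(size=3), rng.uniform(0.2, 0.8, 3)
        W = rng.normal(size=(3, 7))
        gamma = rng.normal(size=7)
        a = 3.7
        W2, s2 = W.copy(), slopes.copy()
        W2[0] *= a
        s2[0] /= a
        np.testing.assert_allclose(
            category_probabilities(theta, slopes, W, gamma),
            category_probabilities(theta, s2, W2, gamma),
            atol=1e-12,
        )

    def test_shape_and_finite_validation(self):
        with pytest.raises(ShapeError):
            category_probabilities(np.zeros(2), np.zeros(3), np.zeros((2, 5)), np.zeros(5))
        with pytest.raises(NumericError):
            category_probabilities(
                np.array([np.nan]), np.ones(1), np.ones((1, 3)), np.zeros(3)
            )


class TestSampleResponse:
    def test_degenerate_item_is_deterministic(self, rng):
        gamma = np.zeros(7)
        gamma[1] = 50.0
        draws = {
            sample_response(np.zeros(1), np.zeros(1), np.zeros((1, 7)), gamma, rng)
            for _ in range(1000)
        }
        assert draws == {1}

    def test_uniform_item_frequencies(self, rng):
        n = 10_000
        counts = np.bincount(
            [
                sample_response(np.zeros(1), np.zeros(1), np.zeros((1, 7)), np.zeros(7), rng)
                for _ in range(n)
            ],
            minlength=7,
        )
        se = np.sqrt((1 / 7) * (6 / 7) / n)
        assert np.all(np.abs(counts / n - 1 / 7) < 3 * se)

    def test_identical_seed_identical_draws(self):
        args = (np.array([0.5]), np.array([0.6]), np.arange(7)[None, :] * 1.0, np.zeros(7))
        a = [sample_response(*args, np.random.default_rng(5)) for _ in range(10)]
        b = [sample_response(*args, np.random.default_rng(5)) for _ in range(10)]
        assert a == b


class TestCompleteDataLoglik:
    @staticmethod
    def _uniform_setup(n_persons):
        responses = ResponseMatrix(
            data=np.zeros((n_persons, 1), dtype=int),
            items=("x",),
            item_traits=[0],
            n_categories=7,
        )
        from mnrm import assemble_item_weights

        wset = assemble_item_weights(
            {"x": 0}, 1, 7, include_ers=False, include_mrs=False
        )
        params = ItemParameters(slopes=np.zeros((1, 1)), intercepts=np.zeros((1, 7)))
        return responses, params, wset

    def test_uniform_single_cell(self):
        responses, params, wset = self._uniform_setup(1)
        ll = complete_data_loglik(responses, np.zeros((1, 1)), params, wset)
        assert ll == pytest.approx(np.log(1 / 7), abs=1e-12)

    def test_additivity_over_persons(self):
        responses, params, wset = self._uniform_setup(2)
        ll = complete_data_loglik(responses, np.zeros((2, 1)), params, wset)
        assert ll == pytest.approx(2 * np.log(1 / 7), abs=1e-12)

    def test_matches_brute_force_oracle(self, tiny_dataset, rng):
        responses, wset, truth = tiny_dataset
        thetas = truth.theta
        ll = complete_data_loglik(responses, thetas, truth.params, wset)
        oracle = brute_force_loglik(
            responses.data[:10],
            thetas[:10],
            truth.params.slopes,
            wset.weights,
            truth.params.intercepts,
        )
        sub = ResponseMatrix(
            data=responses.data[:10],
            items=responses.items,
            item_traits=responses.item_traits,
            n_categories=responses.n_categories,
        )
        ll10 = complete_data_loglik(sub, thetas[:10], truth.params, wset)
        assert ll10 == pytest.approx(oracle, abs=1e-9)
        assert ll < 0

    def test_category_out_of_range_rejected(self):
        with pytest.raises(ShapeError):
            ResponseMatrix(
                data=np.array([[9]]), items=("x",), item_traits=[0], n_categories=7
            )


class TestMarginalLoglik:
    @staticmethod
    def _zero_slope_model(n_persons=4, K1=7):
        from mnrm import assemble_item_weights

        wset = assemble_item_weights(
            {"x": 0, "y": 0}, 1, K1, include_ers=False, include_mrs=False
        )
        responses = ResponseMatrix(
            data=np.ones((n_persons, 2), dtype=int),
            items=("x", "y"),
            item_traits=[0, 0],
            n_categories=K1,
        )
        params = ItemParameters(slopes=np.zeros((2, 1)), intercepts=np.zeros((2, K1)))
        latent = LatentSpec(roles=("trait1",), corr=np.eye(1))
        return responses, params, wset, latent

    def test_zero_slopes_have_closed_form(self):
        responses, params, wset, latent = self._zero_slope_model()
        ll = marginal_loglik(responses, params, wset, latent, method="laplace")
        assert ll == pytest.approx(4 * 2 * np.log(1 / 7), abs=1e-9)

    def test_laplace_agrees_with_quadrature_d1(self, tiny_dataset):
        """One-dimensional fits: Laplace within 0.5% of 61-node quadrature."""
        responses, wset, truth = tiny_dataset
        sub = wset.subset(["trait1"])
        params = ItemParameters(
            slopes=truth.params.slopes[:, :1], intercepts=truth.params.intercepts
        )
        latent = LatentSpec(roles=("trait1",), corr=np.eye(1))
        lap = marginal_loglik(responses, params, sub, latent, method="laplace")
        quad = marginal_loglik(
            responses, params, sub, latent, method="quadrature", n_nodes=61
        )
        assert abs(lap - quad) < 0.005 * abs(quad)

    def test_inactive_appended_dimension_changes_nothing(self, tiny_dataset):
        responses, wset, truth = tiny_dataset
        sub = wset.subset(["trait1", "trait2"])
        params = ItemParameters(
            slopes=truth.params.slopes[:, :2], intercepts=truth.params.intercepts
        )
        latent = LatentSpec(roles=("trait1", "trait2"), corr=np.eye(2))
        base = marginal_loglik(responses, params, sub, latent, method="laplace")
        ext = wset.subset(["trait1", "trait2", "ers"])
        params3 = ItemParameters(
            slopes=np.c_[truth.params.slopes[:, :2], np.zeros(responses.n_items)],
            intercepts=truth.params.intercepts,
        )
        latent3 = LatentSpec(roles=("trait1", "trait2", "ers"), corr=np.eye(3))
        extd = marginal_loglik(responses, params3, ext, latent3, method="laplace")
        assert abs(base - extd) < 1e-8

    def test_quadrature_capability_bound(self, tiny_dataset):
        responses, wset, truth = tiny_dataset
        latent = LatentSpec(roles=wset.dim_roles, corr=truth.latent.corr)
        with pytest.raises(CapabilityError):
            marginal_loglik(
                responses, truth.params, wset, latent, method="quadrature"
            )

    def test_importance_is_seed_reproducible_and_near_laplace(self, tiny_dataset):
        responses, wset, truth = tiny_dataset
        latent = truth.latent
        lap = marginal_loglik(responses, truth.params, wset, latent, "laplace")
        i1 = marginal_loglik(
            responses, truth.params, wset, latent, "importance", mc_size=512, seed=7
        )
        i2 = marginal_loglik(
            responses, truth.params, wset, latent, "importance", mc_size=512, seed=7
        )
        assert i1 == i2
        assert abs(i1 - lap) < 0.005 * abs(lap)


def test_probability_normalization_across_random_parameters(rng):
    """Vectorized logits normalize across 10,000 random parameter draws."""
    from mnrm.model import response_logits
    from mnrm import assemble_item_weights

    design = SimulationDesign(
        n_traits=2, items_per_trait=5, sample_sizes=(50,), faking_present=True,
        faking_trait_corr=(0.1, -0.1),
    )
    responses, wset, truth = generate_dataset(design, 7, n=50)
    for _ in range(10):
        params = ItemParameters(
            slopes=rng.uniform(0, 1, truth.params.slopes.shape),
            intercepts=np.c_[
                np.zeros(10), rng.normal(size=(10, 6))
            ],
        )
        theta = rng.normal(size=(100, wset.n_dim))
        logits = response_logits(theta, params, wset)
        logits -= logits.max(axis=-1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=-1, keepdims=True)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-12)
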