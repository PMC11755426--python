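"""Data generation per the simulation design and the study runner."""

import numpy as np
import pytest

from mnrm import (
    FitOptions,
    SimulationDesign,
    build_generating_correlations,
    draw_intercepts,
    draw_slopes,
    fisher_mean_correlation,
    generate_dataset,
    generate_faking_weights,
    recovery_metrics,
    run_study,
    simulate_responses,
)
from mnrm.errors import ConfigurationError
from mnrm.model import ItemParameters
from mnrm.simulation import DEFAULT_ROSTER, assign_faking_shapes

ROLES8 = tuple(f"trait{t}" for t in range(1, 6)) + ("ers", "mrs", "faking")
TRAITS50 = np.repeat(np.arange(5), 10)


class TestDrawSlopes:
    def test_bounds_and_moments(self, rng):
        draws = np.concatenate(
            [
                draw_slopes(50, ROLES8, TRAITS50, True, rng)[
                    np.arange(50), np.repeat(np.arange(5), 10)
                ]
                for _ in range(200)
            ]
        )
        assert draws.min() >= 0.25 and draws.max() <= 0.75
        se = np.sqrt(0.5**2 / 12 / draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_absent_faking_column_is_zero(self, rng):
        slopes = draw_slopes(50, ROLES8, TRAITS50, False, rng)
        np.testing.assert_array_equal(slopes[:, 7], 0.0)

    def test_faking_column_scaled_for_equivalent_impact(self, rng):
        """Faking weights live on [0, 1] while trait weights step by one per
        category, so the faking slope column is scaled to keep the
        dimensions' impacts on responses comparable."""
        slopes = draw_slopes(
            50, ROLES8, TRAITS50, True, rng, faking_slope_scale=6.0
        )
        assert slopes[:, 7].min() >= 0.25 * 6 and slopes[:, 7].max() <= 0.75 * 6

    def test_off_trait_entries_zero_and_deterministic(self):
        s1 = draw_slopes(50, ROLES8, TRAITS50, True, np.random.default_rng(4))
        s2 = draw_slopes(50, ROLES8, TRAITS50, True, np.random.default_rng(4))
        np.testing.assert_array_equal(s1, s2)
        for i in range(50):
            for t in range(5):
                if t != TRAITS50[i]:
                    assert s1[i, t] == 0.0


class TestDrawIntercepts:
    MEANS = np.array([-1.5, -0.9, -0.3, 0.3, 0.9, 1.5])

    def test_zero_variance_closed_form(self, rng):
        gamma, tau = draw_intercepts(5, 7, self.MEANS, 0.0, rng)
        expected = [0.0, 1.5, 2.4, 2.7, 2.4, 1.5, 0.0]
        for row in gamma:
            np.testing.assert_allclose(row, expected, atol=1e-12)
        np.testing.assert_allclose(tau, np.tile(self.MEANS, (5, 1)), atol=1e-12)

    def test_first_intercept_always_zero(self, rng):
        gamma, _ = draw_intercepts(200, 7, self.MEANS, 0.7, rng)
        np.testing.assert_array_equal(gamma[:, 0], 0.0)

    def test_mean_over_draws_matches_closed_form(self, rng):
        gamma, _ = draw_intercepts(10_000, 7, self.MEANS, 0.7, rng)
        expected = np.r_[0.0, -np.cumsum(self.MEANS)]
        # var of gamma_k is k * 0.7 (cumulative sum of independent taus)
        ks = np.arange(7)
        se = np.sqrt(np.maximum(ks, 1) * 0.7 / 10_000)
        assert np.all(np.abs(gamma.mean(axis=0) - expected) < 3.5 * se)


class TestFakingWeights:
    def test_monotone_template_is_linear_ramp(self):
        np.testing.assert_allclose(
            generate_faking_weights("monotone", 7), np.arange(7) / 6
        )

    def test_nonmonotone_increasing_has_dip_and_fixed_endpoints(self):
        w = generate_faking_weights("nonmonotone_increasing", 7)
        assert w[0] == 0.0 and w[-1] == 1.0
        assert (np.diff(w) < 0).any()  # at least one local dip
        assert w[-1] > w[0]

    def test_inverted_u_peaks_strictly_inside(self):
        w = generate_faking_weights("inverted_u", 7)
        assert 0 < w.argmax() < 6
        assert w[0] < w.max() and w[-1] < w.max()

    def test_jittered_draws_stay_in_unit_interval(self, rng):
        for _ in range(1000 // 10):
            for shape in ("monotone", "nonmonotone_increasing", "inverted_u"):
                w = generate_faking_weights(shape, 7, jitter=0.3, rng=rng)
                assert w.min() >= 0.0 and w.max() <= 1.0

    def test_unknown_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_faking_weights("zigzag", 7)

    def test_ten_item_census_is_4_3_3(self):
        shapes = assign_faking_shapes(10)
        assert shapes.count("monotone") == 4
        assert shapes.count("nonmonotone_increasing") == 3
        assert shapes.count("inverted_u") == 3


class TestGeneratingCorrelations:
    def test_default_faking_trait_block(self):
        C = build_generating_correlations(SimulationDesign())
        fk = ROLES8.index("faking")
        np.testing.assert_allclose(C[fk, :5], [0.0, 0.10, -0.10, 0.30, -0.30])
        assert C[5, 6] == 0.0  # ERS orthogonal to MRS
        np.testing.assert_array_equal(C[5, :5], 0.0)
        np.testing.assert_array_equal(C[6, :5], 0.0)

    def test_identity_accepted(self):
        d = SimulationDesign(
            n_traits=2,
            trait_corr=np.eye(2),
            faking_trait_corr=(0.0, 0.0),
        )
        C = build_generating_correlations(d)
        np.testing.assert_array_equal(C, np.eye(5))

    def test_non_positive_definite_rejected(self):
        d = SimulationDesign(
            n_traits=2,
            trait_corr=np.array([[1.0, 0.999], [0.999, 1.0]]),
            faking_trait_corr=(0.9, -0.9),
        )
        with pytest.raises(ConfigurationError):
            build_generating_correlations(d)


class TestGenerateDataset:
    def test_default_design_geometry(self):
        responses, wset, truth = generate_dataset(SimulationDesign(), 1, n=40)
        assert responses.data.shape == (40, 50)
        assert responses.n_categories == 7
        assert responses.data.min() >= 0 and responses.data.max() <= 6
        assert wset.n_dim == 8
        assert truth.params.slopes.shape == (50, 8)

    def test_inert_faking_dimension_reproduces_responses(self):
        """With faking absent (zero slopes) the 8- and 7-dimensional
        parameterizations generate identical data from the same stream."""
        design = SimulationDesign(
            n_traits=2, items_per_trait=4, faking_present=False,
            faking_trait_corr=(0.0, 0.0),
        )
        responses, wset, truth = generate_dataset(design, 99, n=60)
        reduced = ItemParameters(
            slopes=truth.params.slopes[:, :4], intercepts=truth.params.intercepts
        )
        sub = wset.subset(["trait1", "trait2", "ers", "mrs"])
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        full = simulate_responses(truth.theta, truth.params, wset, rng1)
        drop = simulate_responses(truth.theta[:, :4], reduced, sub, rng2)
        np.testing.assert_array_equal(full, drop)

    def test_forced_faking_levels_shift_toward_desirable_categories(self):
        """Persons forced to a high faking level choose higher-desirability
        categories than persons forced to a low level."""
        design = SimulationDesign(n_traits=2, items_per_trait=5,
                                  faking_trait_corr=(0.0, 0.0))
        responses, wset, truth = generate_dataset(design, 3, n=10)
        rng = np.random.default_rng(0)
        theta = np.zeros((400, wset.n_dim))
        fk = list(wset.dim_roles).index("faking")
        hi, lo = theta.copy(), theta.copy()
        hi[:, fk] = 3.0
        lo[:, fk] = -3.0
        y_hi = simulate_responses(hi, truth.params, wset, np.random.default_rng(1))
        y_lo = simulate_responses(lo, truth.params, wset, np.random.default_rng(1))
        fw = truth.faking_weights
        items = np.arange(wset.n_items)[None, :]
        desir_hi = fw[items, y_hi].mean()
        desir_lo = fw[items, y_lo].mean()
        assert desir_hi > desir_lo + 0.2

    def test_same_seed_same_dataset(self):
        d = SimulationDesign(n_traits=2, items_per_trait=3,
                             faking_trait_corr=(0.1, -0.1))
        r1, _, t1 = generate_dataset(d, 5, n=30)
        r2, _, t2 = generate_dataset(d, 5, n=30)
        np.testing.assert_array_equal(r1.data, r2.data)
        np.testing.assert_array_equal(t1.theta, t2.theta)


class TestRecoveryMetrics:
    def test_exact_estimates_have_zero_error(self):
        m = recovery_metrics(np.array([[0.2, 0.4]]), np.array([[0.2, 0.4]]))
        assert m.bias == 0.0 and m.rmse == 0.0
        assert m.mean_fisher_r == pytest.approx(1.0)

    def test_hand_computed_bias_and_rmse(self):
        m = recovery_metrics(np.array([0.2, 0.4]), np.array([0.25, 0.25]))
        assert m.bias == pytest.approx(0.05, abs=1e-12)
        assert m.rmse == pytest.approx(np.sqrt((0.0025 + 0.0225) / 2), abs=1e-12)

    def test_fisher_mean_of_two_correlations(self):
        expected = np.tanh((np.arctanh(0.8) + np.arctanh(0.6)) / 2)
        assert fisher_mean_correlation([0.8, 0.6]) == pytest.approx(expected)
        assert expected == pytest.approx(0.714, abs=5e-4)

    def test_zero_variance_replications_excluded_with_warning(self):
        est = np.array([[1.0, 1.0, 1.0], [0.1, 0.4, 0.95]])
        tru = np.array([[0.0, 0.5, 1.0], [0.0, 0.5, 1.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            m = recovery_metrics(est, tru)
        assert m.mean_fisher_r == pytest.approx(
            np.corrcoef([0.1, 0.4, 0.95], [0.0, 0.5, 1.0])[0, 1], abs=1e-9
        )


class TestRunStudy:
    @pytest.fixture(scope="class")
    def tiny_study(self):
        design = SimulationDesign(
            n_traits=2, items_per_trait=4, sample_sizes=(120,),
            faking_present=True, replications=3,
            faking_trait_corr=(0.2, -0.2),
        )
        opts = FitOptions(
            burnin=40, min_stage2=30, min_avg=30, tol=5e-3, max_cycles=300,
            info_every=2, require_convergence=False,
        )
        return design, opts

    def test_selection_proportions_partition_replications(self, tiny_study):
        design, opts = tiny_study
        res = run_study(design, roster=DEFAULT_ROSTER[2:], fit_options=opts, seed=7)
        for crit in res.criteria:
            props = res.selection_proportions(120, crit)
            assert props.sum() == pytest.approx(1.0, abs=1e-12)
        assert not res.failures

    def test_study_is_reproducible_from_master_seed(self, tiny_study):
        design, opts = tiny_study
        r1 = run_study(design, roster=DEFAULT_ROSTER[2:], fit_options=opts,
                       seed=11, score_persons=False)
        r2 = run_study(design, roster=DEFAULT_ROSTER[2:], fit_options=opts,
                       seed=11, score_persons=False)
        assert r1.selection.equals(r2.selection)
        assert r1.recovery.equals(r2.recovery)
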