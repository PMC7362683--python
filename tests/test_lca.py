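"""EM estimator: likelihood, E/M steps, fitting, classification, invariance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import aldlca as a
from aldlca.design import ALDMatrix
from aldlca.lca import DegenerateClassError, PROB_EPS, _e_step_flat

from conftest import grid_oracle_loglik_2class_2item, make_complete_ald


def params_2c(pi, probs_a, probs_b):
    item = np.array([probs_a, probs_b])[:, :, None]
    return a.MGLCAParams(np.array([pi, 1 - pi]), item)


def masked_ald(values, observed):
    values = np.asarray(values, np.uint8)[:, :, None]
    observed = np.asarray(observed, bool)[:, :, None]
    n = values.shape[0]
    return ALDMatrix(values, observed, np.arange(n), np.ones(n, int))


class TestObservedLoglik:
    def test_single_bernoulli_cell(self):
        ald = masked_ald([[1]], [[True]])
        params = a.MGLCAParams(np.array([1.0]), np.full((1, 1, 1), 0.5))
        assert a.observed_loglik(params, ald) == pytest.approx(np.log(0.5))

    def test_identical_components_ignore_proportions(self):
        ald = masked_ald([[1, 0], [0, 1], [1, 1]], np.ones((3, 2), bool))
        for pi in (0.2, 0.5, 0.9):
            ll = a.observed_loglik(params_2c(pi, [0.3, 0.7], [0.3, 0.7]), ald)
            assert ll == pytest.approx(
                a.observed_loglik(params_2c(0.5, [0.3, 0.7], [0.3, 0.7]), ald)
            )

    def test_matches_pattern_enumeration(self):
        """Six persons, two items: direct sum over the four response
        patterns evaluated with plain Python arithmetic."""
        import math

        data = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [1, 1], [0, 1]])
        pi, pa, pb = 0.35, (0.8, 0.3), (0.2, 0.9)

        def pattern_prob(x):
            pr_a = (pa[0] if x[0] else 1 - pa[0]) * (pa[1] if x[1] else 1 - pa[1])
            pr_b = (pb[0] if x[0] else 1 - pb[0]) * (pb[1] if x[1] else 1 - pb[1])
            return pi * pr_a + (1 - pi) * pr_b

        expected = sum(math.log(pattern_prob(x)) for x in data)
        ald = make_complete_ald(data)
        params = params_2c(pi, pa, pb)
        assert a.observed_loglik(params, ald) == pytest.approx(expected, abs=1e-10)

    def test_unobserved_person_contributes_zero(self):
        ald = masked_ald([[1, 0], [0, 0]], [[True, True], [False, False]])
        one = masked_ald([[1, 0]], [[True, True]])
        params = params_2c(0.4, [0.6, 0.2], [0.1, 0.9])
        assert a.observed_loglik(params, ald) == pytest.approx(
            a.observed_loglik(params, one)
        )


class TestEStep:
    def test_bayes_rule_on_one_informative_item(self):
        ald = masked_ald([[1]], [[True]])
        post = a.e_step(params_2c(0.5, [0.999], [0.001]), ald)
        assert post[0, 0] == pytest.approx(0.999, abs=1e-6)

    def test_fully_missing_person_gets_prior(self):
        ald = masked_ald([[0, 0]], [[False, False]])
        post = a.e_step(params_2c(0.3, [0.6, 0.2], [0.1, 0.9]), ald)
        assert post[0] == pytest.approx([0.3, 0.7])

    def test_single_class_posterior_is_one(self):
        ald = masked_ald([[1, 0]], [[True, True]])
        params = a.MGLCAParams(np.array([1.0]), np.full((1, 2, 1), 0.5))
        assert np.allclose(a.e_step(params, ald), [[1.0]])

    def test_extreme_probabilities_never_nan(self):
        ald = masked_ald(np.ones((4, 2)), np.ones((4, 2), bool))
        params = params_2c(0.5, [PROB_EPS, PROB_EPS], [1 - PROB_EPS, 1 - PROB_EPS])
        post = a.e_step(params, ald)
        assert np.isfinite(post).all()
        assert post.sum(axis=1) == pytest.approx([1.0] * 4)

    @given(st.integers(0, 2**31 - 1))
    def test_rows_always_normalized(self, seed):
        rng = np.random.default_rng(seed)
        n, items, S = 6, 3, 3
        values = rng.integers(0, 2, (n, items, 1)).astype(np.uint8)
        observed = rng.random((n, items, 1)) < 0.7
        ald = ALDMatrix(values, observed, np.arange(n), np.ones(n, int))
        pi = rng.dirichlet(np.ones(S))
        probs = rng.uniform(0.05, 0.95, (S, items, 1))
        post = a.e_step(a.MGLCAParams(pi, probs), ald)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_hard_posteriors_give_within_class_means(self):
        data = np.array([[1, 1], [1, 0], [0, 0], [0, 1]])
        ald = make_complete_ald(data)
        post = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], float)
        params = a.m_step(post, ald)
        assert params.item_probs[0, :, 0] == pytest.approx([1.0 - PROB_EPS, 0.5])
        assert params.item_probs[1, :, 0] == pytest.approx([PROB_EPS, 0.5])
        assert params.class_proportions == pytest.approx([0.5, 0.5])

    def test_uniform_posteriors_pool_everything(self):
        data = np.array([[1, 1], [0, 0], [1, 0]])
        ald = make_complete_ald(data)
        post = np.full((3, 2), 0.5)
        params = a.m_step(post, ald)
        assert params.item_probs[0] == pytest.approx(params.item_probs[1])
        assert params.item_probs[0, :, 0] == pytest.approx([2 / 3, 1 / 3])

    def test_fractional_posteriors_weighted_by_hand(self):
        # four persons, one item; weighted means done with scalar arithmetic
        data = np.array([[1], [1], [0], [1]])
        post = np.array([[0.9, 0.1], [0.6, 0.4], [0.2, 0.8], [0.5, 0.5]])
        ald = make_complete_ald(data)
        params = a.m_step(post, ald)
        w0 = 0.9 + 0.6 + 0.2 + 0.5
        w1 = 0.1 + 0.4 + 0.8 + 0.5
        assert params.item_probs[0, 0, 0] == pytest.approx((0.9 + 0.6 + 0.5) / w0)
        assert params.item_probs[1, 0, 0] == pytest.approx((0.1 + 0.4 + 0.5) / w1)
        assert params.class_proportions == pytest.approx([w0 / 4, w1 / 4])

    def test_never_observed_cell_keeps_previous_value(self):
        ald = masked_ald([[1, 0]], [[True, False]])
        prev = params_2c(0.5, [0.5, 0.42], [0.5, 0.77])
        post = np.array([[0.5, 0.5]])
        params = a.m_step(post, ald, prev=prev)
        assert params.item_probs[0, 1, 0] == pytest.approx(0.42)
        assert params.item_probs[1, 1, 0] == pytest.approx(0.77)

    def test_degenerate_class_raises(self):
        ald = make_complete_ald(np.array([[1], [0]]))
        post = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(DegenerateClassError):
            a.m_step(post, ald)


class TestFit:
    def test_single_class_closed_form(self, small_ald):
        model = a.fit(small_ald, 1, seed=0)
        X, O = small_ald.flat()
        means = X.sum(axis=0)[O.sum(axis=0) > 0] / O.sum(axis=0)[O.sum(axis=0) > 0]
        est = model.params.item_probs.reshape(-1)[O.sum(axis=0) > 0]
        assert est == pytest.approx(np.clip(means, PROB_EPS, 1 - PROB_EPS), abs=1e-9)
        assert model.loglik == pytest.approx(
            a.observed_loglik(model.params, small_ald)
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_search_oracle(self, seed):
        """Complete-data 2-item, 2-class instances: EM's best loglik is
        within 1e-4 of a dense 5-parameter grid search."""
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 2, size=(8, 2))
        ald = make_complete_ald(data)
        model = a.fit(ald, 2, n_starts=40, tol=1e-12, max_iter=2000, seed=seed)
        oracle = grid_oracle_loglik_2class_2item(data)
        assert model.loglik >= oracle - 1e-4

    def test_em_loglik_never_decreases(self, small_ald):
        model = a.fit(small_ald, 3, n_starts=2, seed=1)
        trace = np.array(model.loglik_trace)
        assert (np.diff(trace) >= -1e-10).all()

    def test_recovers_generating_parameters(self, small_pop, small_ald):
        model = a.fit(small_ald, 3, n_starts=5, seed=3)
        perm = a.align_classes(model.params, small_pop.true_params)
        cells = small_ald.observed.any(axis=0)
        err = model.params.item_probs[perm][:, cells] - small_pop.true_params[:, cells]
        assert np.sqrt(np.mean(err**2)) <= 0.05

    def test_classes_sorted_by_proportion(self, small_model):
        pi = small_model.params.class_proportions
        assert (np.diff(pi) <= 1e-12).all()

    def test_missingness_neutrality(self, small_ald, small_model):
        """Appending cell-free persons changes no parameter estimate."""
        import dataclasses

        pad = 7
        ald2 = dataclasses.replace(
            small_ald,
            values=np.concatenate(
                [small_ald.values,
                 np.zeros((pad, *small_ald.values.shape[1:]), np.uint8)]),
            observed=np.concatenate(
                [small_ald.observed,
                 np.zeros((pad, *small_ald.observed.shape[1:]), bool)]),
            person_id=np.concatenate(
                [small_ald.person_id, -np.arange(1, pad + 1)]),
            cohort=np.concatenate([small_ald.cohort, np.ones(pad, int)]),
            wave_presence=None, wave_years=None,
        )
        model2 = a.fit(ald2, 3, n_starts=5, seed=3)
        assert model2.n_obs_used == small_model.n_obs_used
        assert model2.loglik == pytest.approx(small_model.loglik, abs=1e-6)
        assert model2.params.class_proportions == pytest.approx(
            small_model.params.class_proportions, abs=1e-9)
        assert np.allclose(model2.params.item_probs,
                           small_model.params.item_probs, atol=1e-9)

    def test_permutation_invariance(self, small_ald):
        import dataclasses

        rng = np.random.default_rng(0)
        perm = rng.permutation(small_ald.n_persons)
        shuffled = dataclasses.replace(
            small_ald, values=small_ald.values[perm],
            observed=small_ald.observed[perm],
            person_id=small_ald.person_id[perm], cohort=small_ald.cohort[perm],
            group=None, wave_presence=None, wave_years=None,
        )
        p = a.fit(small_ald, 2, n_starts=3, seed=5)
        q = a.fit(shuffled, 2, n_starts=3, seed=5)
        assert abs(p.loglik - q.loglik) < 1e-6


class TestClassify:
    def test_unit_posteriors_give_average_one(self, small_model):
        import dataclasses

        hard = np.zeros_like(small_model.posteriors)
        hard[np.arange(len(hard)), small_model.posteriors.argmax(axis=1)] = 1.0
        model = dataclasses.replace(small_model, posteriors=hard)
        cls = a.classify(model)
        assert (cls.table["p_mean"].dropna() == 1.0).all()

    def test_tie_broken_to_lower_index(self, small_model):
        import dataclasses

        post = np.array([[0.5, 0.5, 0.0], [0.2, 0.3, 0.5]])
        model = dataclasses.replace(small_model, posteriors=post)
        cls = a.classify(model)
        assert cls.modal_class[0] == 0 and cls.tied[0]
        assert cls.modal_class[1] == 2 and not cls.tied[1]

    def test_ranges_match_direct_tabulation(self):
        post = np.array([[0.9, 0.1], [0.2, 0.8], [0.6, 0.4]])
        model = a.FittedModel(
            params=params_2c(0.5, [0.5], [0.5]), loglik=0.0, n_obs_used=3,
            posteriors=post, converged=True, n_iterations=1, n_starts=1,
            best_start=0, loglik_trace=[],
        )
        cls = a.classify(model)
        row1 = cls.table.set_index("class").loc[1]
        row2 = cls.table.set_index("class").loc[2]
        assert (row1["p_min"], row1["p_max"]) == (0.6, 0.9)
        assert (row2["p_min"], row2["p_max"]) == (0.8, 0.8)


class TestInvariance:
    def test_relabelled_cohort_keeps_posterior(self, small_model, small_ald):
        report = a.invariance_check(small_model, small_ald, n_duplicates=200)
        assert report.max_posterior_diff == 0.0

    def test_grouping_does_not_touch_likelihood(self, small_ald):
        identity = a.group_cohorts(small_ald, {c: c for c in range(1, 13)})
        decades = a.group_cohorts(small_ald)
        m1 = a.fit(identity, 2, n_starts=3, seed=9)
        m2 = a.fit(decades, 2, n_starts=3, seed=9)
        assert m1.loglik == m2.loglik

    def test_group_composition_balanced_for_balanced_classes(self, schedule):
        cfg = a.SyntheticConfig(n_baseline=3000, n_refresh=800, seed=21)
        pop = a.generate_population(cfg)
        ald = a.group_cohorts(a.rearrange(pop.panel, schedule))
        model = a.fit(ald, 3, n_starts=4, seed=2)
        report = a.invariance_check(model, ald)
        # empirical modal shares per group scatter around the overall shares
        assert report.max_group_share_dev < 0.12
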