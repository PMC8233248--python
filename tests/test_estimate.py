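import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ascot_bws.dataset import (
    STAGE_ORDER,
    ChoiceObservation,
    DataIntegrityError,
    compile_dataset,
)
from ascot_bws.estimate import (
    ConstraintEmbedding,
    EstimationError,
    IdentificationError,
    ParameterVector,
    _loglik_and_grad,
    choice_probability,
    dataset_loglik,
    fit_smnl,
    pairwise_level_test,
    robust_covariance,
    task_loglik,
)
from ascot_bws.instrument import AttributeLevel
from ascot_bws.io import clean_dataset
from ascot_bws.simulate import SimulationConfig, simulate_dataset

from conftest import toy_instrument
from test_simulate import flat_params, toy_task


def sequence_observations(task, picks):
    """Build the 4 stage observations of a task for a given pick order."""
    obs, avail = [], list(range(len(task.items)))
    for stage, pick in zip(STAGE_ORDER, picks):
        obs.append(
            ChoiceObservation(
                respondent_id=0,
                task_id=task.task_id,
                stage=stage,
                items=tuple(task.items[i] for i in avail),
                positions=tuple(i + 1 for i in avail),
                chosen=task.items[pick],
            )
        )
        avail.remove(pick)
    return obs


def naive_dataset_loglik(params, dataset, q1_threshold, spec):
    """Slow reference: pure-Python double loop over the long table."""
    lam_of = {}
    for row in dataset.profiles.itertuples(index=False):
        lam = 1.0
        if not row.understood:
            lam *= params.lam_not_understood
        if row.age_35_plus:
            lam *= params.lam_age35
        if row.completion_minutes >= q1_threshold:
            lam *= params.lam_slow
        lam_of[row.respondent_id] = lam
    total = 0.0
    obs = dataset.obs
    for (resp, task, stage), grp in obs.groupby(
        ["respondent_id", "task_id", "stage"], sort=True
    ):
        grp = grp[grp["available_flag"] == 1]
        lam = lam_of[resp]
        utilities = []
        chosen_u = None
        for row in grp.itertuples(index=False):
            beta = params.beta[spec.domain_index(row.domain), row.level - 1]
            if stage in ("best", "second_best"):
                u = lam * (beta + params.delta[row.display_position - 1])
            else:
                u = -lam * beta
            utilities.append(u)
            if row.chosen_flag == 1:
                chosen_u = u
        denom = sum(math.exp(u) for u in utilities)
        total += chosen_u - math.log(denom)
    return total


class TestChoiceProbability:
    def test_two_equal_items_split_evenly(self):
        spec2 = toy_instrument(2)
        params = flat_params(2)
        p = choice_probability(
            [AttributeLevel("D0", 1), AttributeLevel("D1", 1)],
            "best",
            [1, 2],
            params,
            1.0,
            spec2,
        )
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_best_type_matches_softmax(self):
        spec3 = toy_instrument(3)
        params = flat_params(3, beta_by_domain=[1.0, 0.0, -1.0])
        items = [AttributeLevel(f"D{i}", 1) for i in range(3)]
        p = choice_probability(items, "best", [1, 2, 3], params, 1.0, spec3)
        np.testing.assert_allclose(p, [0.66524, 0.24473, 0.09003], atol=1e-5)

    def test_worst_type_reverses_best(self):
        spec3 = toy_instrument(3)
        params = flat_params(3, beta_by_domain=[1.0, 0.0, -1.0])
        items = [AttributeLevel(f"D{i}", 1) for i in range(3)]
        best = choice_probability(items, "best", [1, 2, 3], params, 1.0, spec3)
        worst = choice_probability(items, "worst", [1, 2, 3], params, 1.0, spec3)
        np.testing.assert_allclose(worst, best[::-1], atol=1e-12)

    def test_no_overflow_at_extreme_utilities(self):
        spec2 = toy_instrument(2)
        params = flat_params(2, beta_by_domain=[350.0, -350.0])
        items = [AttributeLevel("D0", 1), AttributeLevel("D1", 1)]
        p = choice_probability(items, "best", [1, 2], params, 1.0, spec2)
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)

    def test_empty_set_and_bad_stage_raise(self, reference_params):
        with pytest.raises(EstimationError, match="empty"):
            choice_probability([], "best", [], reference_params, 1.0)
        with pytest.raises(EstimationError, match="stage"):
            choice_probability(
                [AttributeLevel("OCC", 1)], "bestest", [1], reference_params, 1.0
            )

    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=7),
        st.floats(0.1, 3.0),
        st.sampled_from(list(STAGE_ORDER)),
    )
    def test_probabilities_form_a_distribution(self, betas, lam, stage):
        n = len(betas)
        specn = toy_instrument(n)
        params = flat_params(n, beta_by_domain=betas)
        items = [AttributeLevel(f"D{i}", 1) for i in range(n)]
        p = choice_probability(items, stage, list(range(1, n + 1)), params, lam, specn)
        assert (p > 0).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestTaskLoglik:
    def test_uniform_choices_give_log_840(self):
        # all utilities equal: stage probabilities 1/7, 1/6, 1/5, 1/4
        spec7 = toy_instrument(7)
        obs = sequence_observations(toy_task(7), [0, 1, 2, 3])
        ll = task_loglik(obs, flat_params(7), 1.0, spec7)
        assert ll == pytest.approx(-math.log(840), abs=1e-12)

    def test_lambda_cancels_on_equal_utilities(self):
        spec7 = toy_instrument(7)
        params = flat_params(7)
        obs = sequence_observations(toy_task(7), [2, 4, 0, 6])
        assert task_loglik(obs, params, 1.0, spec7) == pytest.approx(
            task_loglik(obs, params, 2.0, spec7), abs=1e-12
        )

    def test_sequence_probabilities_sum_to_one_3_items(self):
        spec3 = toy_instrument(3)
        params = flat_params(3, beta_by_domain=[0.7, -0.4, 0.1], delta=[0, -0.2, 0.3])
        task = toy_task(3)
        total = sum(
            math.exp(task_loglik(sequence_observations(task, list(p)), params, 1.4, spec3))
            for p in permutations(range(3))
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_available_sets_raise(self):
        spec7 = toy_instrument(7)
        obs = sequence_observations(toy_task(7), [0, 1, 2, 3])
        bad = list(obs)
        bad[1] = obs[0]  # chosen item not removed, stage out of order
        with pytest.raises(DataIntegrityError):
            task_loglik(bad, flat_params(7), 1.0, spec7)


class TestDatasetLoglik:
    def test_zero_parameters_give_uniform_loglik(self, small_dataset, spec):
        emb = ConstraintEmbedding(spec)
        ll = dataset_loglik(np.zeros(emb.n_free), small_dataset, 7.0, spec)
        assert ll == pytest.approx(12 * 8 * (-math.log(840)), rel=1e-12)

    def test_matches_naive_reference(self, plan, spec, reference_params):
        ds = simulate_dataset(SimulationConfig(n_respondents=5, seed=3), plan)
        fast = dataset_loglik(reference_params, ds, 7.0, spec)
        slow = naive_dataset_loglik(reference_params, ds, 7.0, spec)
        assert fast == pytest.approx(slow, abs=1e-10)

    def test_invariant_to_respondent_relabelling(self, plan, spec, reference_params):
        ds = simulate_dataset(SimulationConfig(n_respondents=6, seed=9), plan)
        before = dataset_loglik(reference_params, ds, 7.0, spec)
        relabel = {i: 100 - i for i in ds.profiles["respondent_id"]}
        ds.obs["respondent_id"] = ds.obs["respondent_id"].map(relabel)
        ds.profiles["respondent_id"] = ds.profiles["respondent_id"].map(relabel)
        assert dataset_loglik(reference_params, ds, 7.0, spec) == pytest.approx(
            before, rel=1e-12
        )

    def test_nan_parameters_rejected(self, small_dataset, spec):
        emb = ConstraintEmbedding(spec)
        x = np.zeros(emb.n_free)
        x[0] = np.nan
        with pytest.raises(EstimationError, match="NaN"):
            dataset_loglik(x, small_dataset, 7.0, spec)

    def test_analytic_gradient_matches_finite_differences(
        self, small_dataset, spec
    ):
        emb = ConstraintEmbedding(spec)
        compiled = compile_dataset(small_dataset, spec, 7.0)
        rng = np.random.default_rng(12)
        x = rng.normal(0.0, 0.3, emb.n_free)
        _, grad, _ = _loglik_and_grad(x, compiled, emb)
        h = 1e-6
        for k in range(emb.n_free):
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            fd = (
                _loglik_and_grad(xp, compiled, emb)[0]
                - _loglik_and_grad(xm, compiled, emb)[0]
            ) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-6, abs=1e-4)


@pytest.fixture(scope="module")
def fitted(plan_module):
    plan, ds = plan_module
    cleaned, _ = clean_dataset(ds)
    return cleaned, fit_smnl(cleaned)


@pytest.fixture(scope="module")
def plan_module():
    from ascot_bws.design import build_design

    plan = build_design(0)
    ds = simulate_dataset(SimulationConfig(n_respondents=150, seed=21), plan)
    return plan, ds


class TestFit:
    def test_converges_and_improves_on_truth(self, fitted, reference_params, spec):
        cleaned, fit = fitted
        assert fit.converged
        assert fit.grad_norm < 1e-5
        assert fit.loglik >= dataset_loglik(reference_params, cleaned, 7.0, spec)

    def test_two_starts_reach_same_optimum(self, fitted, spec):
        cleaned, fit = fitted
        emb = ConstraintEmbedding(spec)
        start = np.full(emb.n_free, 0.25)
        refit = fit_smnl(cleaned, start=start, spec=spec)
        assert refit.loglik == pytest.approx(fit.loglik, abs=1e-5)

    def test_unobserved_level_raises_identification_error(self, plan_module, spec):
        plan, ds = plan_module
        obs = ds.obs
        # drop every task in which OCC is shown at level 1
        bad = obs[(obs["domain"] == "OCC") & (obs["level"] == 1)]
        bad_tasks = set(zip(bad["respondent_id"], bad["task_id"]))
        keep = ~obs.set_index(["respondent_id", "task_id"]).index.isin(bad_tasks)
        ds_pruned = type(ds)(
            obs=obs[keep].reset_index(drop=True), profiles=ds.profiles, plan=plan
        )
        with pytest.raises(IdentificationError, match="OCC-1"):
            fit_smnl(ds_pruned, spec=spec)

    def test_too_few_respondents_rejected(self, plan, spec):
        ds = simulate_dataset(SimulationConfig(n_respondents=1, seed=2), plan)
        with pytest.raises(EstimationError, match="2 respondents"):
            fit_smnl(ds, spec=spec)


class TestRobustCovariance:
    def test_symmetric_positive_semidefinite(self, fitted):
        _, fit = fitted
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        eigvals = np.linalg.eigvalsh(fit.cov)
        assert eigvals.min() > -1e-10
        np.testing.assert_allclose(fit.se, np.sqrt(np.diag(fit.cov)))

    def test_recompute_matches_fit(self, fitted, spec):
        cleaned, fit = fitted
        cov = robust_covariance(fit, cleaned, spec)
        np.testing.assert_allclose(cov, fit.cov, rtol=1e-8, atol=1e-12)

    def test_duplicating_every_respondent_halves_the_covariance(
        self, fitted, spec
    ):
        """Doubling each cluster leaves the optimum unchanged, doubles both
        the information A and the score outer product B, and therefore
        halves the sandwich A^-1 B A^-1."""
        cleaned, fit = fitted
        shift = int(cleaned.profiles["respondent_id"].max()) + 1
        obs2 = cleaned.obs.copy()
        obs2["respondent_id"] += shift
        prof2 = cleaned.profiles.copy()
        prof2["respondent_id"] += shift
        doubled = type(cleaned)(
            obs=pd.concat([cleaned.obs, obs2], ignore_index=True),
            profiles=pd.concat([cleaned.profiles, prof2], ignore_index=True),
            plan=cleaned.plan,
        )
        refit = fit_smnl(doubled, spec=spec)
        np.testing.assert_allclose(refit.free, fit.free, atol=1e-4)
        np.testing.assert_allclose(refit.cov, fit.cov / 2, rtol=0.02, atol=1e-8)


class TestPairwiseTests:
    def test_aliased_joint_pair_is_exactly_zero(self, fitted, spec):
        _, fit = fitted
        t = pairwise_level_test(
            fit, AttributeLevel("ENC", 1), AttributeLevel("ENC", 2), spec
        )
        assert t.difference == 0.0
        assert t.z == 0.0
        assert t.p_one_sided == 0.5
        assert t.aliased

    def test_self_comparison_is_degenerate(self, fitted, spec):
        _, fit = fitted
        with pytest.raises(EstimationError, match="degenerate"):
            pairwise_level_test(
                fit, AttributeLevel("OCC", 1), AttributeLevel("OCC", 1), spec
            )

    def test_large_generating_gap_is_significant(self, fitted, spec):
        """OCC level 1 vs level 4 differ by ~3.2 utility units in the
        generating values -- many standard errors."""
        _, fit = fitted
        t = pairwise_level_test(
            fit, AttributeLevel("OCC", 1), AttributeLevel("OCC", 4), spec
        )
        assert t.z > 3.29
        assert t.p_one_sided < 0.001
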