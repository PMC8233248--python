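import numpy as np
import pytest
from scipy import stats

from ascot_bws.dataset import STAGE_ORDER, stages_for
from ascot_bws.design import ChoiceTask
from ascot_bws.estimate import ParameterVector, choice_probability, task_loglik
from ascot_bws.instrument import AttributeLevel
from ascot_bws.simulate import (
    RespondentProfile,
    SimulationConfig,
    scale_multiplier,
    simulate_dataset,
    simulate_respondents,
    simulate_sequences,
    simulate_task_choices,
)

from conftest import toy_instrument


def flat_params(n_domains, beta_by_domain=None, delta=None):
    """Parameters for a reduced instrument; level utilities constant within
    a domain unless given explicitly."""
    beta = np.zeros((n_domains, 4))
    if beta_by_domain is not None:
        for d, val in enumerate(beta_by_domain):
            beta[d, :] = val
    beta[0, 3] = 0.0  # reference anchor of the toy instrument
    return ParameterVector(
        beta=beta,
        delta=np.zeros(n_domains) if delta is None else np.asarray(delta, float),
    )


def toy_task(n_domains, levels=None):
    levels = levels or [1] * n_domains
    return ChoiceTask(
        task_id=0,
        block=0,
        items=tuple(AttributeLevel(f"D{d}", levels[d]) for d in range(n_domains)),
        display_order=tuple(range(n_domains)),
    )


class TestRespondents:
    def test_counts_and_determinism(self):
        cfg = SimulationConfig(n_respondents=1001, seed=4)
        profiles = simulate_respondents(cfg)
        assert len(profiles) == 1001
        again = simulate_respondents(cfg)
        assert profiles == again

    def test_no_speeders_when_share_zero(self):
        cfg = SimulationConfig(n_respondents=500, speeder_share=0.0, seed=1)
        assert all(
            p.completion_minutes >= 4.5 for p in simulate_respondents(cfg)
        )

    def test_age_prevalence_follows_binomial_law(self):
        cfg = SimulationConfig(n_respondents=10_000, share_age_35_plus=0.737, seed=2)
        share = np.mean([p.age_35_plus for p in simulate_respondents(cfg)])
        assert abs(share - 0.737) < 0.01

    def test_completion_q1_near_seven_minutes(self):
        cfg = SimulationConfig(n_respondents=20_000, speeder_share=0.0, seed=3)
        minutes = [p.completion_minutes for p in simulate_respondents(cfg)]
        assert abs(np.quantile(minutes, 0.25) - 7.0) < 0.3


class TestScaleMultiplier:
    def _profile(self, **kw):
        base = dict(
            respondent_id=0,
            age_35_plus=False,
            understood_tasks=True,
            completion_minutes=5.0,
            block=0,
            display_order=tuple(range(7)),
        )
        base.update(kw)
        return RespondentProfile(**base)

    def test_reference_respondent_is_exactly_one(self, reference_params):
        assert scale_multiplier(self._profile(), reference_params, 7.0) == 1.0

    def test_slow_only_gives_published_multiplier(self, reference_params):
        prof = self._profile(completion_minutes=12.0)
        assert scale_multiplier(prof, reference_params, 7.0) == pytest.approx(1.66)

    def test_all_three_groups_multiply(self, reference_params):
        prof = self._profile(
            age_35_plus=True, understood_tasks=False, completion_minutes=30.0
        )
        expected = 0.70 * 0.80 * 1.66
        assert scale_multiplier(prof, reference_params, 7.0) == pytest.approx(expected)

    def test_nonpositive_multiplier_rejected(self):
        params = flat_params(7)
        params.lam_slow = -1.0
        with pytest.raises(Exception, match="positive"):
            scale_multiplier(self._profile(), params, 7.0)


class TestChoiceSampling:
    def test_best_pick_frequencies_match_softmax(self, rng):
        """3-item task with utilities (1, 0, -1): empirical best-pick
        frequencies over 100k draws match the closed-form softmax."""
        beta = np.array([1.0, 0.0, -1.0])
        seqs = simulate_sequences(
            beta, np.arange(1, 4), np.zeros(3), 1.0, rng, n_draws=100_000
        )
        freq = np.bincount(seqs[:, 0], minlength=3) / len(seqs)
        e = np.exp(beta)
        np.testing.assert_allclose(freq, e / e.sum(), atol=0.005)

    def test_equal_utilities_give_uniform_best(self, rng):
        seqs = simulate_sequences(
            np.zeros(7), np.arange(1, 8), np.zeros(7), 1.3, rng, n_draws=50_000
        )
        freq = np.bincount(seqs[:, 0], minlength=7) / len(seqs)
        assert np.abs(freq - 1 / 7).max() < 0.01

    def test_dominant_item_saturates(self, rng):
        beta = np.zeros(7)
        beta[4] = 10.0
        seqs = simulate_sequences(
            beta, np.arange(1, 8), np.zeros(7), 1.0, rng, n_draws=5_000
        )
        assert np.mean(seqs[:, 0] == 4) > 0.999

    def test_sequence_distribution_matches_exploded_model(self, rng):
        """Chi-square goodness of fit of simulated pick sequences against the
        exploded-logit sequence probabilities (4-item reduced instrument,
        24 ordered sequences, alpha = 0.01)."""
        spec4 = toy_instrument(4)
        params = flat_params(
            4, beta_by_domain=[0.8, 0.2, -0.3, 0.0], delta=[0.0, -0.2, 0.1, 0.0]
        )
        task = toy_task(4)
        lam = 1.2
        seqs = simulate_sequences(
            np.array([0.8, 0.2, -0.3, 0.0]),
            np.arange(1, 5),
            params.delta,
            lam,
            rng,
            n_draws=100_000,
        )
        keys = seqs @ np.array([64, 16, 4, 1])
        from itertools import permutations

        from ascot_bws.dataset import ChoiceObservation

        expected, labels = [], []
        for perm in permutations(range(4)):
            obs, avail = [], list(range(4))
            for stage, pick in zip(STAGE_ORDER, perm):
                obs.append(
                    ChoiceObservation(
                        respondent_id=0,
                        task_id=0,
                        stage=stage,
                        items=tuple(task.items[i] for i in avail),
                        positions=tuple(i + 1 for i in avail),
                        chosen=task.items[pick],
                    )
                )
                avail.remove(pick)
            expected.append(np.exp(task_loglik(obs, params, lam, spec4)))
            labels.append(np.array(perm) @ np.array([64, 16, 4, 1]))
        counts = np.array([(keys == lab).sum() for lab in labels])
        assert counts.sum() == 100_000
        result = stats.chisquare(counts, 100_000 * np.array(expected))
        assert result.pvalue > 0.01

    def test_positioning_effect_is_monotone(self, rng):
        """With equal utilities and the published negative positioning
        effects, the top-of-list item is picked best more often than the
        bottom one."""
        delta = np.array([0.0, -0.1, -0.18, -0.27, -0.32, -0.36, -0.40])
        seqs = simulate_sequences(
            np.zeros(7), np.arange(1, 8), delta, 1.0, rng, n_draws=50_000
        )
        freq = np.bincount(seqs[:, 0], minlength=7) / len(seqs)
        assert freq[0] > freq[6]

    def test_task_choice_objects_are_consistent(self, rng, reference_params, spec):
        prof = RespondentProfile(
            respondent_id=3,
            age_35_plus=True,
            understood_tasks=True,
            completion_minutes=9.0,
            block=0,
            display_order=tuple(range(7)),
        )
        task = ChoiceTask(
            task_id=0,
            block=0,
            items=tuple(AttributeLevel(c, 2) for c in spec.domain_codes),
            display_order=tuple(range(7)),
        )
        obs = simulate_task_choices(task, prof, reference_params, rng, spec)
        assert [o.stage for o in obs] == list(STAGE_ORDER)
        assert [len(o.items) for o in obs] == [7, 6, 5, 4]
        # worst-stage pick distribution sanity: chosen is always available
        for o in obs:
            assert o.chosen in o.items


class TestDataset:
    def test_shape_and_stage_sizes(self, plan):
        ds = simulate_dataset(SimulationConfig(n_respondents=10, seed=5), plan)
        picked = ds.obs[ds.obs["chosen_flag"] == 1]
        assert len(picked) == 10 * 8 * 4  # 320 sequential choices
        sizes = (
            ds.obs.groupby(["respondent_id", "task_id", "stage"])["available_flag"]
            .sum()
            .groupby(level="stage")
            .unique()
        )
        assert sizes["best"].tolist() == [7]
        assert sizes["worst"].tolist() == [6]
        assert sizes["second_best"].tolist() == [5]
        assert sizes["second_worst"].tolist() == [4]

    def test_identical_seed_identical_dataset(self, plan):
        a = simulate_dataset(SimulationConfig(n_respondents=8, seed=11), plan)
        b = simulate_dataset(SimulationConfig(n_respondents=8, seed=11), plan)
        assert a.obs.equals(b.obs)
        assert a.profiles.equals(b.profiles)

    def test_each_respondent_contributes_32_choices(self, small_dataset):
        per_resp = small_dataset.observations_per_respondent()
        assert (per_resp == 32).all()
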