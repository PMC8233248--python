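"""Synthetic respondents and sequential best-worst choices.

The original Austrian valuation survey data cannot be shared, so this module
generates stand-in data with the same structure: ~1000 online respondents,
each randomly assigned to one block of 8 choice tasks, answering 4 sequential
picks per task (best, worst, second-best, second-worst) under the
scale-adjusted MNL data-generating process of :mod:`ascot_bws.estimate`.

Respondent heterogeneity mirrors the study's scale-parameter grouping: task
understanding, age 35+, and completion time (slow completers at or above the
first-quartile threshold).  A configurable fraction of "speeders" with
implausibly short completion times (< 4.5 minutes) is planted to exercise
the data-cleaning filter.  Stage picks are drawn by Gumbel-max sampling,
which is exactly multinomial-logit sampling at the stage probabilities of
:func:`ascot_bws.estimate.choice_probability`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .dataset import (
    OBS_COLUMNS,
    PROFILE_COLUMNS,
    STAGE_USES_DELTA,
    ChoiceDataset,
    ChoiceObservation,
    stages_for,
)
from .design import ChoiceTask, DesignPlan, N_BLOCKS, block_design, verify_design
from .estimate import EstimationError, ParameterVector
from .instrument import AttributeLevel, InstrumentSpec, N_LEVELS, default_instrument

_Z_Q3 = float(_stats.norm.ppf(0.75))  # 0.6745, pins the log-normal Q1


@dataclass(frozen=True)
class RespondentProfile:
    """Simulated respondent covariates and survey assignment."""

    respondent_id: int
    age_35_plus: bool
    understood_tasks: bool
    completion_minutes: float
    block: int
    display_order: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.completion_minutes <= 0:
            raise ValueError("completion_minutes must be positive")


def _default_params() -> ParameterVector:
    from .reference import austria_reference_params

    return austria_reference_params()


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic survey.

    Defaults emulate the Austrian sample: 1001 respondents, 73.7% aged 35
    and over, log-normal completion times with first quartile at 7 minutes,
    and a 5% speeder fraction below 4.5 minutes.  ``true_params`` defaults
    to the published Austrian estimates.
    """

    n_respondents: int = 1001
    true_params: ParameterVector = field(default_factory=_default_params)
    share_age_35_plus: float = 0.737
    share_not_understood: float = 0.15
    completion_log_sigma: float = 0.5
    completion_q1_minutes: float = 7.0
    speeder_share: float = 0.05
    speeder_threshold_minutes: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("share_age_35_plus", "share_not_understood", "speeder_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")

    @property
    def completion_log_mu(self) -> float:
        """Log-normal location pinning the Q1 at ``completion_q1_minutes``.

        Non-speeder times are truncated below at the speeder threshold, so
        the location is solved such that the first quartile of the truncated
        distribution sits at the Q1 threshold.
        """
        from scipy import optimize as _opt

        sig = self.completion_log_sigma
        a = math.log(self.speeder_threshold_minutes)
        q = math.log(self.completion_q1_minutes)

        def gap(mu):
            tail = _stats.norm.sf((a - mu) / sig)
            return _stats.norm.cdf((q - mu) / sig) - _stats.norm.cdf(
                (a - mu) / sig
            ) - 0.25 * tail

        return float(_opt.brentq(gap, q - 3 * sig, q + 3 * sig))


def simulate_respondents(
    config: SimulationConfig, spec: InstrumentSpec | None = None
) -> list[RespondentProfile]:
    """Draw respondent profiles; deterministic given the config seed.

    Covariates are independent; blocks are assigned uniformly over the 4
    design blocks; each respondent gets one display permutation used for all
    of their tasks.
    """
    spec = spec or default_instrument()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_respondents
    age = rng.random(n) < config.share_age_35_plus
    understood = rng.random(n) >= config.share_not_understood
    blocks = rng.integers(0, N_BLOCKS, size=n)

    is_speeder = rng.random(n) < config.speeder_share
    minutes = rng.lognormal(
        config.completion_log_mu, config.completion_log_sigma, size=n
    )
    # non-speeders never fall below the cleaning threshold
    low = minutes < config.speeder_threshold_minutes
    while low.any():
        minutes[low] = rng.lognormal(
            config.completion_log_mu, config.completion_log_sigma, size=int(low.sum())
        )
        low = minutes < config.speeder_threshold_minutes
    minutes[is_speeder] = rng.uniform(
        1.5, config.speeder_threshold_minutes - 0.1, size=int(is_speeder.sum())
    )

    profiles = []
    for i in range(n):
        perm = tuple(int(v) for v in rng.permutation(spec.n_domains))
        profiles.append(
            RespondentProfile(
                respondent_id=i,
                age_35_plus=bool(age[i]),
                understood_tasks=bool(understood[i]),
                completion_minutes=float(minutes[i]),
                block=int(blocks[i]),
                display_order=perm,
            )
        )
    return profiles


def scale_multiplier(
    profile: RespondentProfile,
    params: ParameterVector,
    q1_threshold_minutes: float = 7.0,
) -> float:
    """Product of the applicable group scale multipliers.

    The reference respondent (understood the tasks, under 35, completion
    below the Q1 threshold) has scale exactly 1; each extra group membership
    multiplies in its factor.
    """
    if not np.all(params.lambdas > 0):
        raise EstimationError(f"scale multipliers must be positive: {params.lambdas}")
    lam = 1.0
    if not profile.understood_tasks:
        lam *= params.lam_not_understood
    if profile.age_35_plus:
        lam *= params.lam_age35
    if profile.completion_minutes >= q1_threshold_minutes:
        lam *= params.lam_slow
    return lam


# ---------------------------------------------------------------------------
# choice sampling


def simulate_sequences(
    beta_items: np.ndarray,
    positions: np.ndarray,
    delta: np.ndarray,
    lam: float,
    rng: np.random.Generator,
    n_draws: int = 1,
) -> np.ndarray:
    """Sample pick sequences for one task, vectorised over draws.

    ``beta_items`` and ``positions`` (1-based) describe the task's items;
    returns an ``(n_draws, n_picks)`` array of item slot indices in pick
    order.  Each stage is a Gumbel-max draw over the still-available items,
    i.e. an exact multinomial-logit pick at that stage's probabilities.
    """
    m = len(beta_items)
    stage_names = stages_for(m)
    u_best = lam * (beta_items + delta[positions - 1])
    u_worst = -lam * beta_items
    avail = np.ones((n_draws, m), dtype=bool)
    out = np.empty((n_draws, len(stage_names)), dtype=int)
    for k, stage in enumerate(stage_names):
        u = u_best if STAGE_USES_DELTA[stage] else u_worst
        noisy = u[None, :] + rng.gumbel(size=(n_draws, m))
        noisy = np.where(avail, noisy, -np.inf)
        pick = noisy.argmax(axis=1)
        out[:, k] = pick
        avail[np.arange(n_draws), pick] = False
    return out


def simulate_task_choices(
    task: ChoiceTask,
    profile: RespondentProfile,
    params: ParameterVector,
    rng: np.random.Generator,
    spec: InstrumentSpec | None = None,
    q1_threshold_minutes: float = 7.0,
) -> list[ChoiceObservation]:
    """Simulate the sequential picks of one task for one respondent."""
    spec = spec or default_instrument()
    lam = scale_multiplier(profile, params, q1_threshold_minutes)
    beta_items = np.array([params.beta_of(it, spec) for it in task.items])
    positions = np.array(
        [task.position_of(d) for d in range(len(task.items))], dtype=int
    )
    picks = simulate_sequences(beta_items, positions, params.delta, lam, rng)[0]

    observations = []
    avail = list(range(len(task.items)))
    for stage, pick in zip(stages_for(len(task.items)), picks):
        observations.append(
            ChoiceObservation(
                respondent_id=profile.respondent_id,
                task_id=task.task_id,
                stage=stage,
                items=tuple(task.items[i] for i in avail),
                positions=tuple(int(positions[i]) for i in avail),
                chosen=task.items[pick],
            )
        )
        avail.remove(int(pick))
    return observations


def simulate_dataset(
    config: SimulationConfig,
    plan: DesignPlan,
    spec: InstrumentSpec | None = None,
) -> ChoiceDataset:
    """Full synthetic survey: profiles plus 32 choices per respondent.

    Deterministic given the config seed; the result round-trips losslessly
    through the CSV writer/reader of :mod:`ascot_bws.io`.
    """
    spec = spec or default_instrument()
    if not verify_design(plan).passed:
        raise ValueError("design plan failed verification")
    profiles = simulate_respondents(config, spec)
    blocks = block_design(plan, spec)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    params = config.true_params.validate(spec)

    n_dom = spec.n_domains
    stage_names = stages_for(n_dom)
    n_stages = len(stage_names)
    rows_per_task = n_stages * n_dom
    n_tasks_per_resp = len(blocks[0])
    total_rows = config.n_respondents * n_tasks_per_resp * rows_per_task

    resp_col = np.empty(total_rows, dtype=int)
    block_col = np.empty(total_rows, dtype=int)
    task_col = np.empty(total_rows, dtype=int)
    stage_col = np.empty(total_rows, dtype=object)
    domain_col = np.empty(total_rows, dtype=object)
    level_col = np.empty(total_rows, dtype=int)
    pos_col = np.empty(total_rows, dtype=int)
    avail_col = np.empty(total_rows, dtype=int)
    chosen_col = np.empty(total_rows, dtype=int)

    codes = np.array(spec.domain_codes, dtype=object)
    stage_tile = np.repeat(np.array(stage_names, dtype=object), n_dom)
    domain_tile = np.tile(codes, n_stages)
    beta_flat = params.beta.reshape(-1)

    r0 = 0
    for prof in profiles:
        lam = scale_multiplier(prof, params, config.completion_q1_minutes)
        positions = np.empty(n_dom, dtype=int)
        for rank, d in enumerate(prof.display_order):
            positions[d] = rank + 1
        for task in blocks[prof.block]:
            levels = np.array([it.level for it in task.items], dtype=int)
            beta_items = beta_flat[np.arange(n_dom) * N_LEVELS + levels - 1]
            picks = simulate_sequences(
                beta_items, positions, params.delta, lam, rng
            )[0]
            sl = slice(r0, r0 + rows_per_task)
            resp_col[sl] = prof.respondent_id
            block_col[sl] = prof.block
            task_col[sl] = task.task_id
            stage_col[sl] = stage_tile
            domain_col[sl] = domain_tile
            level_col[sl] = np.tile(levels, n_stages)
            pos_col[sl] = np.tile(positions, n_stages)
            avail = np.ones(n_dom, dtype=int)
            for k in range(n_stages):
                st = slice(r0 + k * n_dom, r0 + (k + 1) * n_dom)
                avail_col[st] = avail
                ch = np.zeros(n_dom, dtype=int)
                ch[picks[k]] = 1
                chosen_col[st] = ch
                avail = avail.copy()
                avail[picks[k]] = 0
            r0 += rows_per_task

    obs = pd.DataFrame(
        {
            "respondent_id": resp_col,
            "block": block_col,
            "task_id": task_col,
            "stage": stage_col,
            "domain": domain_col,
            "level": level_col,
            "display_position": pos_col,
            "available_flag": avail_col,
            "chosen_flag": chosen_col,
        },
        columns=OBS_COLUMNS,
    )
    prof_frame = pd.DataFrame(
        {
            "respondent_id": [p.respondent_id for p in profiles],
            "block": [p.block for p in profiles],
            "age_35_plus": [p.age_35_plus for p in profiles],
            "understood": [p.understood_tasks for p in profiles],
            "completion_minutes": [p.completion_minutes for p in profiles],
        },
        columns=PROFILE_COLUMNS,
    )
    return ChoiceDataset(obs=obs, profiles=prof_frame, plan=plan)
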