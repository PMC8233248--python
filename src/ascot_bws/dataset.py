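"""Long-format containers for sequential best-worst choice data.

A respondent works through 8 tasks; in each task they pick, in order, the
best, worst, second-best and second-worst item out of 7, so the available
set shrinks 7 -> 6 -> 5 -> 4 across the four stages and each respondent
contributes 32 sequential choices.  The on-disk layout (and the in-memory
``obs`` table) is fully long: one row per (respondent, task, stage, domain)
with availability and choice flags, which makes the table rectangular --
``n_domains`` rows per stage -- and lets the estimator reshape it into dense
arrays without any per-row bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DesignPlan
from .instrument import AttributeLevel, InstrumentSpec, N_LEVELS, default_instrument

#: Canonical stage order of the sequential picks.
STAGE_ORDER: tuple[str, ...] = ("best", "worst", "second_best", "second_worst")

#: Utility sign per stage: worst-type picks use negated utilities.
STAGE_SIGN: dict[str, int] = {
    "best": 1,
    "worst": -1,
    "second_best": 1,
    "second_worst": -1,
}

#: Positioning effects enter best-type stages only.
STAGE_USES_DELTA: dict[str, bool] = {
    "best": True,
    "worst": False,
    "second_best": True,
    "second_worst": False,
}

OBS_COLUMNS = [
    "respondent_id",
    "block",
    "task_id",
    "stage",
    "domain",
    "level",
    "display_position",
    "available_flag",
    "chosen_flag",
]

PROFILE_COLUMNS = [
    "respondent_id",
    "block",
    "age_35_plus",
    "understood",
    "completion_minutes",
]


class DataIntegrityError(ValueError):
    """Choice records violate the sequential-removal structure."""


def stages_for(n_items: int) -> tuple[str, ...]:
    """Stages administered for a task of ``n_items`` (at most four picks)."""
    return STAGE_ORDER[: min(4, n_items)]


@dataclass(frozen=True)
class ChoiceObservation:
    """One stage of one task: the available items and the pick made.

    ``items`` are the items still available at this stage (instrument domain
    order), ``positions`` their 1-based display positions, and ``chosen``
    must be among ``items``.
    """

    respondent_id: int
    task_id: int
    stage: str
    items: tuple[AttributeLevel, ...]
    positions: tuple[int, ...]
    chosen: AttributeLevel

    def __post_init__(self) -> None:
        if self.stage not in STAGE_ORDER:
            raise DataIntegrityError(f"unknown stage {self.stage!r}")
        if len(self.items) != len(self.positions):
            raise DataIntegrityError("items and positions must align")
        if self.chosen not in self.items:
            raise DataIntegrityError(
                f"chosen item {self.chosen} not in the available set"
            )


def validate_task_observations(obs: Sequence[ChoiceObservation]) -> None:
    """Check canonical stage order and correct sequential removal."""
    if not obs:
        raise DataIntegrityError("task has no observations")
    expected = stages_for(len(obs[0].items))
    got = tuple(o.stage for o in obs)
    if got != expected[: len(got)]:
        raise DataIntegrityError(f"stages {got} not in canonical order {expected}")
    for prev, cur in zip(obs, obs[1:]):
        remaining = set(prev.items) - {prev.chosen}
        if set(cur.items) != remaining:
            raise DataIntegrityError(
                f"stage {cur.stage!r}: available set is not the previous set "
                f"minus the previous pick"
            )


@dataclass
class ChoiceDataset:
    """Choice records, respondent profiles and the plan that produced them.

    ``obs`` holds one row per (respondent, task, stage, domain) -- see
    :data:`OBS_COLUMNS`; ``profiles`` one row per respondent -- see
    :data:`PROFILE_COLUMNS`.
    """

    obs: pd.DataFrame
    profiles: pd.DataFrame
    plan: DesignPlan | None = None

    @property
    def respondent_ids(self) -> np.ndarray:
        return self.profiles["respondent_id"].to_numpy()

    @property
    def n_respondents(self) -> int:
        return len(self.profiles)

    def observations_per_respondent(self) -> pd.Series:
        """Number of recorded picks (stages) per respondent."""
        picked = self.obs[self.obs["chosen_flag"] == 1]
        return picked.groupby("respondent_id").size()


def observations_to_frame(
    observations: Sequence[ChoiceObservation],
    spec: InstrumentSpec,
    blocks: dict[int, int],
) -> pd.DataFrame:
    """Expand ChoiceObservations into the rectangular long table.

    Every stage contributes one row per instrument domain; items that were
    already picked at an earlier stage appear with ``available_flag`` 0.
    ``blocks`` maps respondent id -> block id.
    """
    codes = spec.domain_codes
    rows = []
    for o in observations:
        avail = {it.domain: (it, pos) for it, pos in zip(o.items, o.positions)}
        # items removed at earlier stages: recover level/position from the
        # first stage of the same task is the caller's concern; here we only
        # emit rows for domains still known at this stage, plus placeholders.
        for d_idx, code in enumerate(codes):
            if code in avail:
                item, pos = avail[code]
                rows.append(
                    (
                        o.respondent_id,
                        blocks[o.respondent_id],
                        o.task_id,
                        o.stage,
                        code,
                        item.level,
                        pos,
                        1,
                        int(item == o.chosen),
                    )
                )
    frame = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return _fill_unavailable_rows(frame, spec)


def _fill_unavailable_rows(frame: pd.DataFrame, spec: InstrumentSpec) -> pd.DataFrame:
    """Add available_flag=0 rows so every stage has one row per domain."""
    first = frame[frame["stage"] == STAGE_ORDER[0]]
    key = ["respondent_id", "task_id", "domain"]
    lookup = first.set_index(key)[["level", "display_position", "block"]]
    full = []
    for (resp, task), grp in frame.groupby(["respondent_id", "task_id"], sort=True):
        stages_present = [s for s in STAGE_ORDER if s in set(grp["stage"])]
        for stage in stages_present:
            sub = grp[grp["stage"] == stage]
            present = set(sub["domain"])
            full.append(sub)
            missing = [c for c in spec.domain_codes if c not in present]
            if missing:
                add = lookup.loc[[(resp, task, c) for c in missing]].reset_index()
                add["stage"] = stage
                add["available_flag"] = 0
                add["chosen_flag"] = 0
                full.append(add[OBS_COLUMNS])
    out = pd.concat(full, ignore_index=True)
    return sort_obs(out, spec)


def sort_obs(frame: pd.DataFrame, spec: InstrumentSpec) -> pd.DataFrame:
    """Deterministic row order: respondent, task, stage, instrument domain."""
    stage_rank = {s: i for i, s in enumerate(STAGE_ORDER)}
    domain_rank = {c: i for i, c in enumerate(spec.domain_codes)}
    key = frame.assign(
        _s=frame["stage"].map(stage_rank), _d=frame["domain"].map(domain_rank)
    )
    order = key.sort_values(
        ["respondent_id", "task_id", "_s", "_d"], kind="mergesort"
    ).index
    return frame.loc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# dense compilation for the likelihood


@dataclass
class CompiledData:
    """Dense stage arrays for vectorised likelihood evaluation.

    Shapes: ``(n_stages, n_domains)`` for the per-slot arrays;
    ``group_flags`` is ``(n_respondents, 3)`` with columns
    (not understood, age 35+, slow completer).
    """

    item_idx: np.ndarray
    pos_idx: np.ndarray
    mask: np.ndarray
    chosen_slot: np.ndarray
    sign: np.ndarray
    use_delta: np.ndarray
    resp_idx: np.ndarray
    group_flags: np.ndarray
    respondent_ids: np.ndarray
    n_items: int
    n_positions: int

    @property
    def n_stages(self) -> int:
        return self.item_idx.shape[0]

    @property
    def n_respondents(self) -> int:
        return self.group_flags.shape[0]


def compile_dataset(
    dataset: ChoiceDataset,
    spec: InstrumentSpec | None = None,
    q1_threshold: float = 7.0,
) -> CompiledData:
    """Reshape the long table into dense stage arrays.

    ``q1_threshold`` (minutes) splits respondents into fast and slow
    completers for the scale-heterogeneity grouping.
    """
    spec = spec or default_instrument()
    obs = sort_obs(dataset.obs, spec)
    n_dom = spec.n_domains

    if len(obs) % n_dom != 0:
        raise DataIntegrityError(
            f"observation table length {len(obs)} is not a multiple of the "
            f"domain count {n_dom}"
        )
    n_stages = len(obs) // n_dom

    domain_rank = {c: i for i, c in enumerate(spec.domain_codes)}
    d_idx = obs["domain"].map(domain_rank).to_numpy().reshape(n_stages, n_dom)
    if not (d_idx == np.arange(n_dom)).all():
        raise DataIntegrityError("each stage must have exactly one row per domain")

    level = obs["level"].to_numpy(dtype=int).reshape(n_stages, n_dom)
    item_idx = d_idx * N_LEVELS + (level - 1)
    pos_idx = (
        obs["display_position"].to_numpy(dtype=int).reshape(n_stages, n_dom) - 1
    )
    mask = obs["available_flag"].to_numpy(dtype=bool).reshape(n_stages, n_dom)
    chosen = obs["chosen_flag"].to_numpy(dtype=int).reshape(n_stages, n_dom)
    if not (chosen.sum(axis=1) == 1).all():
        raise DataIntegrityError("every stage must have exactly one chosen item")
    chosen_slot = chosen.argmax(axis=1)
    if not mask[np.arange(n_stages), chosen_slot].all():
        raise DataIntegrityError("a chosen item is flagged unavailable")

    stage_names = obs["stage"].to_numpy().reshape(n_stages, n_dom)[:, 0]
    sign = np.array([STAGE_SIGN[s] for s in stage_names], dtype=float)
    use_delta = np.array(
        [float(STAGE_USES_DELTA[s]) for s in stage_names], dtype=float
    )

    prof = dataset.profiles.sort_values("respondent_id", kind="mergesort")
    resp_ids = prof["respondent_id"].to_numpy()
    id_to_idx = {int(r): i for i, r in enumerate(resp_ids)}
    obs_resp = obs["respondent_id"].to_numpy().reshape(n_stages, n_dom)[:, 0]
    try:
        resp_idx = np.array([id_to_idx[int(r)] for r in obs_resp], dtype=int)
    except KeyError as exc:
        raise DataIntegrityError(f"respondent {exc} has no profile") from None

    group_flags = np.column_stack(
        [
            (~prof["understood"].to_numpy(dtype=bool)).astype(float),
            prof["age_35_plus"].to_numpy(dtype=bool).astype(float),
            (prof["completion_minutes"].to_numpy(dtype=float) >= q1_threshold).astype(
                float
            ),
        ]
    )

    return CompiledData(
        item_idx=item_idx,
        pos_idx=pos_idx,
        mask=mask,
        chosen_slot=chosen_slot,
        sign=sign,
        use_delta=use_delta,
        resp_idx=resp_idx,
        group_flags=group_flags,
        respondent_ids=resp_ids,
        n_items=spec.n_items,
        n_positions=n_dom,
    )
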