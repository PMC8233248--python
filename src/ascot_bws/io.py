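"""On-disk formats and the data-cleaning filter.

All files are UTF-8 CSV with a header row, comma separator and dot decimal
(fixed dialect to avoid locale drift in German-language contexts), or JSON
for parameter sets and fit results.  Write -> read round-trips are lossless;
malformed rows are rejected with their line number.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    OBS_COLUMNS,
    PROFILE_COLUMNS,
    STAGE_ORDER,
    ChoiceDataset,
)
from .estimate import FitResult, ParameterVector
from .instrument import InstrumentSpec, N_LEVELS, default_instrument
from .postprocess import PreferenceWeights

log = logging.getLogger("ascot_bws")


class ParseError(ValueError):
    """A file does not conform to the documented dialect."""


@dataclass
class PipelineConfig:
    """Thresholds, seeds and optimiser settings shared across the pipeline.

    ``cleaning_threshold_minutes`` drops speeders (completion below the
    threshold); ``q1_threshold_minutes`` splits the remaining respondents
    into fast and slow completers for scale heterogeneity.
    """

    cleaning_threshold_minutes: float = 4.5
    q1_threshold_minutes: float = 7.0
    seed: int = 0
    max_iterations: int = 500
    gradient_tolerance: float = 1e-5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # threshold 0 disables cleaning (completion times are strictly positive)
        if self.cleaning_threshold_minutes < 0 or self.q1_threshold_minutes <= 0:
            raise ValueError("thresholds must be non-negative (Q1 positive)")
        if self.cleaning_threshold_minutes >= self.q1_threshold_minutes:
            raise ValueError(
                "cleaning threshold must be below the Q1 threshold "
                f"({self.cleaning_threshold_minutes} >= {self.q1_threshold_minutes})"
            )

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ExclusionReport:
    excluded_ids: list[int]
    n_excluded: int
    n_remaining: int
    threshold_minutes: float


def clean_dataset(
    dataset: ChoiceDataset, config: PipelineConfig | None = None
) -> tuple[ChoiceDataset, ExclusionReport]:
    """Drop all observations of respondents who completed too fast.

    Cleaning is respondent-level (all-or-nothing): a speeder's 32 choices
    are removed together, never partially.
    """
    config = config or PipelineConfig()
    thr = config.cleaning_threshold_minutes
    fast = dataset.profiles["completion_minutes"] < thr
    excluded = sorted(int(i) for i in dataset.profiles.loc[fast, "respondent_id"])
    keep = dataset.profiles.loc[~fast]
    obs = dataset.obs[~dataset.obs["respondent_id"].isin(excluded)].reset_index(
        drop=True
    )
    report = ExclusionReport(
        excluded_ids=excluded,
        n_excluded=len(excluded),
        n_remaining=len(keep),
        threshold_minutes=thr,
    )
    log.info(
        "cleaning: excluded %d respondent(s) below %.1f min; %d remain",
        report.n_excluded,
        thr,
        report.n_remaining,
    )
    return (
        ChoiceDataset(obs=obs, profiles=keep.reset_index(drop=True), plan=dataset.plan),
        report,
    )


# ---------------------------------------------------------------------------
# choice data CSVs


def write_choice_csv(dataset: ChoiceDataset, path: str | Path) -> None:
    dataset.obs.to_csv(path, index=False, columns=OBS_COLUMNS)


def read_choice_csv(path: str | Path) -> pd.DataFrame:
    try:
        obs = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from None
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad = ~obs["stage"].isin(STAGE_ORDER)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ParseError(
            f"{path}: line {line}: invalid stage {obs.loc[bad, 'stage'].iloc[0]!r} "
            f"(column 'stage')"
        )
    for col in ("level", "display_position"):
        bad = ~obs[col].isin(range(1, 8))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(f"{path}: line {line}: invalid value in column {col!r}")
    for col in ("available_flag", "chosen_flag"):
        bad = ~obs[col].isin((0, 1))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(f"{path}: line {line}: column {col!r} must be 0/1")
    return obs[OBS_COLUMNS]


def write_profiles_csv(dataset: ChoiceDataset, path: str | Path) -> None:
    prof = dataset.profiles.copy()
    prof["age_35_plus"] = prof["age_35_plus"].astype(int)
    prof["understood"] = prof["understood"].astype(int)
    prof.to_csv(path, index=False, columns=PROFILE_COLUMNS)


def read_profiles_csv(path: str | Path) -> pd.DataFrame:
    try:
        prof = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from None
    missing = [c for c in PROFILE_COLUMNS if c not in prof.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad = prof["completion_minutes"] <= 0
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(
            f"{path}: line {line}: completion_minutes must be positive"
        )
    prof["age_35_plus"] = prof["age_35_plus"].astype(bool)
    prof["understood"] = prof["understood"].astype(bool)
    return prof[PROFILE_COLUMNS]


def read_choice_dataset(
    choices_path: str | Path, profiles_path: str | Path
) -> ChoiceDataset:
    return ChoiceDataset(
        obs=read_choice_csv(choices_path),
        profiles=read_profiles_csv(profiles_path),
    )


# ---------------------------------------------------------------------------
# parameters and fit results (JSON)


def params_to_dict(params: ParameterVector) -> dict:
    return {
        "beta": params.beta.tolist(),
        "delta": params.delta.tolist(),
        "lambda": {
            "not_understood": params.lam_not_understood,
            "age_35_plus": params.lam_age35,
            "slow": params.lam_slow,
        },
    }


def params_from_dict(data: dict) -> ParameterVector:
    try:
        lam = data["lambda"]
        return ParameterVector(
            beta=np.array(data["beta"], dtype=float),
            delta=np.array(data["delta"], dtype=float),
            lam_not_understood=float(lam["not_understood"]),
            lam_age35=float(lam["age_35_plus"]),
            lam_slow=float(lam["slow"]),
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed parameter JSON: {exc}") from None


def write_params_json(params: ParameterVector, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(params_to_dict(params), indent=2) + "\n", encoding="utf-8"
    )


def read_params_json(path: str | Path) -> ParameterVector:
    return params_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def write_fit_json(fit: FitResult, path: str | Path) -> None:
    """FitResult to JSON: free vector, full parameters, covariance, diagnostics."""
    payload = {
        "free_names": fit.free_names,
        "free": fit.free.tolist(),
        "params": params_to_dict(fit.params),
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "grad_norm": fit.grad_norm,
        "message": fit.message,
        "covariance_row_major": fit.cov.ravel().tolist(),
        "se": fit.se.tolist(),
        "n_respondents": fit.n_respondents,
        "q1_threshold": fit.q1_threshold,
        "constraints": {
            "reference_item_beta": 0.0,
            "delta_position_1": 0.0,
            "reference_group_lambda": 1.0,
            "lambda_parameterisation": "log scale in the free vector",
            "p_value_convention": (
                "two-sided for coefficient-vs-zero, one-sided for pairwise tests"
            ),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_fit_json(path: str | Path) -> FitResult:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    n = len(data["free"])
    return FitResult(
        params=params_from_dict(data["params"]),
        free=np.array(data["free"], dtype=float),
        free_names=list(data["free_names"]),
        loglik=float(data["loglik"]),
        converged=bool(data["converged"]),
        n_iter=int(data["n_iter"]),
        grad_norm=float(data["grad_norm"]),
        message=str(data["message"]),
        cov=np.array(data["covariance_row_major"], dtype=float).reshape(n, n),
        se=np.array(data["se"], dtype=float),
        n_respondents=int(data["n_respondents"]),
        q1_threshold=float(data["q1_threshold"]),
    )


# ---------------------------------------------------------------------------
# preference weights


def write_weights(
    weights: PreferenceWeights, csv_path: str | Path, json_path: str | Path | None = None
) -> None:
    """Weights table (domain, level, statement, weight to 6 decimals) + JSON
    provenance."""
    spec = weights.spec
    rows = []
    for di, d in enumerate(spec.domains):
        for lev in range(1, N_LEVELS + 1):
            rows.append(
                (
                    d.code,
                    lev,
                    d.statements[lev - 1],
                    f"{weights.weights[di, lev - 1]:.6f}",
                )
            )
    pd.DataFrame(rows, columns=["domain", "level", "statement", "weight"]).to_csv(
        csv_path, index=False
    )
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(
                {"provenance": weights.provenance, "weights": weights.weights.tolist()},
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )


def read_weights(
    csv_path: str | Path, spec: InstrumentSpec | None = None
) -> PreferenceWeights:
    spec = spec or default_instrument()
    table = pd.read_csv(csv_path)
    needed = {"domain", "level", "weight"}
    if not needed <= set(table.columns):
        raise ParseError(f"{csv_path}: weights CSV needs columns {sorted(needed)}")
    w = np.full((spec.n_domains, N_LEVELS), np.nan)
    for lineno, row in enumerate(table.itertuples(index=False), start=2):
        try:
            di = spec.domain_index(str(row.domain))
        except Exception:
            raise ParseError(
                f"{csv_path}: line {lineno}: unknown domain {row.domain!r}"
            ) from None
        if row.level not in range(1, N_LEVELS + 1):
            raise ParseError(f"{csv_path}: line {lineno}: bad level {row.level!r}")
        w[di, int(row.level) - 1] = float(row.weight)
    if np.isnan(w).any():
        raise ParseError(f"{csv_path}: weights table is incomplete")
    return PreferenceWeights(weights=w, spec=spec)
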