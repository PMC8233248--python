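"""Scale-adjusted multinomial logit for sequential best-worst data.

Model
-----
Each choice stage is a multinomial logit over the items still available.
For a respondent with scale multiplier ``lambda`` the utility of item ``i``
(domain-level with coefficient ``beta_i``) shown at display position ``p``
is

* best-type stages (best, second-best):   ``lambda * (beta_i + delta_p)``
* worst-type stages (worst, second-worst): ``-lambda * beta_i``

``delta_p`` are positioning effects (position 1 is the reference, so
``delta_1 = 0``); no positioning effects enter worst-type picks.  The task
likelihood is the exploded product of the four stage probabilities with
sequential removal of picked items.  The scale multiplier is the product of
group multipliers (task understanding, age 35+, slow completion) with the
reference group pinned at 1; scale is inversely related to error variance.

Identification: one item's utility is pinned to zero (lowest-valued item),
one designated level pair shares a coefficient, ``delta_1 = 0`` and the
reference group's scale is 1.  For the full instrument that leaves
26 + 6 + 3 = 35 free parameters; the scale multipliers are optimised on the
log scale to enforce positivity.

Inference uses the cluster-robust sandwich covariance ``A^-1 B A^-1`` with
``A`` the observed information and ``B`` the outer product of per-respondent
score sums, clustering on respondents to account for the 8 repeated tasks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .dataset import (
    STAGE_ORDER,
    STAGE_SIGN,
    STAGE_USES_DELTA,
    ChoiceDataset,
    ChoiceObservation,
    CompiledData,
    DataIntegrityError,
    compile_dataset,
    validate_task_observations,
)
from .instrument import AttributeLevel, InstrumentSpec, N_LEVELS, default_instrument

SCALE_GROUPS = ("not_understood", "age_35_plus", "slow")


class EstimationError(RuntimeError):
    """Estimation could not be carried out on the given data."""


class IdentificationError(EstimationError):
    """A parameter is not identified by the data."""


@dataclass
class ParameterVector:
    """Full parameter set: level utilities, positioning effects, scales.

    ``beta`` has shape (n_domains, 4) in instrument order; ``delta`` has one
    entry per display position with ``delta[0] = 0``; the three ``lam_*``
    are the scale multipliers of the non-reference groups.
    """

    beta: np.ndarray
    delta: np.ndarray
    lam_not_understood: float = 1.0
    lam_age35: float = 1.0
    lam_slow: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)

    @property
    def lambdas(self) -> np.ndarray:
        return np.array(
            [self.lam_not_understood, self.lam_age35, self.lam_slow], dtype=float
        )

    def validate(self, spec: InstrumentSpec) -> "ParameterVector":
        if self.beta.shape != (spec.n_domains, N_LEVELS):
            raise EstimationError(
                f"beta must have shape {(spec.n_domains, N_LEVELS)}, "
                f"got {self.beta.shape}"
            )
        if self.delta.shape != (spec.n_domains,):
            raise EstimationError(
                f"delta must have one entry per display position "
                f"({spec.n_domains}), got {self.delta.shape}"
            )
        if self.delta[0] != 0.0:
            raise EstimationError("delta[position 1] must be 0 (reference position)")
        if not np.all(self.lambdas > 0):
            raise EstimationError(f"scale multipliers must be positive: {self.lambdas}")
        if spec.reference_item is not None:
            d = spec.domain_index(spec.reference_item.domain)
            if self.beta[d, spec.reference_item.level - 1] != 0.0:
                raise EstimationError(
                    f"reference item {spec.reference_item} must have beta = 0"
                )
        if spec.joint_pair is not None:
            a, b = spec.joint_pair
            da, db = spec.domain_index(a.domain), spec.domain_index(b.domain)
            if self.beta[da, a.level - 1] != self.beta[db, b.level - 1]:
                raise EstimationError(
                    f"joint pair {a}, {b} must share one coefficient"
                )
        return self

    def beta_of(self, item: AttributeLevel, spec: InstrumentSpec) -> float:
        return float(self.beta[spec.domain_index(item.domain), item.level - 1])


@dataclass
class ConstraintEmbedding:
    """Map between the free optimisation vector and the full parameters.

    Free layout: the unconstrained beta entries in canonical item order
    (reference item dropped, second member of the joint pair aliased to the
    first), then delta for positions 2..P, then the log scale multipliers.
    """

    spec: InstrumentSpec
    free_names: list[str] = field(init=False)
    E: np.ndarray = field(init=False)  # (n_items, n_beta_free)

    def __post_init__(self) -> None:
        spec = self.spec
        ref = spec.item_index(spec.reference_item) if spec.reference_item else None
        alias_from = alias_to = None
        if spec.joint_pair is not None:
            alias_to = spec.item_index(spec.joint_pair[0])
            alias_from = spec.item_index(spec.joint_pair[1])

        names: list[str] = []
        col_of: dict[int, int] = {}
        for d in spec.domains:
            for lev in range(1, N_LEVELS + 1):
                idx = spec.item_index(AttributeLevel(d.code, lev))
                if idx == ref or idx == alias_from:
                    continue
                col_of[idx] = len(names)
                names.append(f"beta:{d.code}:{lev}")
        E = np.zeros((spec.n_items, len(names)))
        for idx, col in col_of.items():
            E[idx, col] = 1.0
        if alias_from is not None:
            E[alias_from] = E[alias_to]
        self.E = E
        self.n_beta_free = len(names)
        self.n_delta_free = spec.n_domains - 1
        names += [f"delta:{p}" for p in range(2, spec.n_domains + 1)]
        names += [f"loglambda:{g}" for g in SCALE_GROUPS]
        self.free_names = names

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def split(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nb, nd = self.n_beta_free, self.n_delta_free
        return x[:nb], x[nb : nb + nd], x[nb + nd :]

    def beta_full(self, x: np.ndarray) -> np.ndarray:
        """Flat per-item beta vector (length n_items) from the free vector."""
        return self.E @ self.split(x)[0]

    def delta_full(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([[0.0], self.split(x)[1]])

    def to_params(self, x: np.ndarray) -> ParameterVector:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_free,):
            raise EstimationError(
                f"free vector must have length {self.n_free}, got {x.shape}"
            )
        lam = np.exp(self.split(x)[2])
        return ParameterVector(
            beta=self.beta_full(x).reshape(self.spec.n_domains, N_LEVELS),
            delta=self.delta_full(x),
            lam_not_understood=float(lam[0]),
            lam_age35=float(lam[1]),
            lam_slow=float(lam[2]),
        )

    def to_free(self, params: ParameterVector) -> np.ndarray:
        params.validate(self.spec)
        beta_flat = params.beta.reshape(-1)
        # E has exactly one 1 per free column, so the pseudo-inverse is a gather
        beta_free = np.array(
            [beta_flat[np.argmax(self.E[:, c])] for c in range(self.n_beta_free)]
        )
        return np.concatenate(
            [beta_free, params.delta[1:], np.log(params.lambdas)]
        )


# ---------------------------------------------------------------------------
# stage probabilities and task likelihood (object API)


def choice_probability(
    available_items: Sequence[AttributeLevel],
    stage_type: str,
    display_positions: Sequence[int],
    params: ParameterVector,
    lam: float,
    spec: InstrumentSpec | None = None,
) -> np.ndarray:
    """Multinomial-logit probabilities of the available items at one stage.

    Computed with max-subtraction so utilities up to |lam*beta| ~ 700 do not
    overflow.
    """
    spec = spec or default_instrument()
    if len(available_items) == 0:
        raise EstimationError("available item set is empty")
    if stage_type not in STAGE_ORDER:
        raise EstimationError(f"unknown stage type {stage_type!r}")
    if lam <= 0:
        raise EstimationError(f"scale multiplier must be positive, got {lam}")
    beta = np.array([params.beta_of(it, spec) for it in available_items])
    if STAGE_USES_DELTA[stage_type]:
        pos = np.asarray(display_positions, dtype=int)
        u = lam * (beta + params.delta[pos - 1])
    else:
        u = -lam * beta
    u = u - u.max()
    e = np.exp(u)
    return e / e.sum()


def task_loglik(
    observations: Sequence[ChoiceObservation],
    params: ParameterVector,
    lam: float,
    spec: InstrumentSpec | None = None,
) -> float:
    """Exploded log-likelihood of one task: sum of stage log-probabilities."""
    spec = spec or default_instrument()
    validate_task_observations(observations)
    total = 0.0
    for o in observations:
        p = choice_probability(o.items, o.stage, o.positions, params, lam, spec)
        total += math.log(p[o.items.index(o.chosen)])
    return total


# ---------------------------------------------------------------------------
# vectorised dataset likelihood


def _loglik_and_grad(
    x: np.ndarray,
    c: CompiledData,
    emb: ConstraintEmbedding,
    per_respondent_scores: bool = False,
):
    """Total log-likelihood, its gradient, and optionally clustered scores."""
    beta = emb.beta_full(x)
    delta = emb.delta_full(x)
    loglam = emb.split(x)[2]
    lam_resp = np.exp(c.group_flags @ loglam)
    lam = lam_resp[c.resp_idx]

    U = lam[:, None] * (
        c.sign[:, None] * beta[c.item_idx]
        + c.use_delta[:, None] * delta[c.pos_idx]
    )
    U = np.where(c.mask, U, -np.inf)
    m = U.max(axis=1)
    expU = np.exp(U - m[:, None])
    denom = expU.sum(axis=1)
    lse = m + np.log(denom)
    rows = np.arange(c.n_stages)
    ll = float((U[rows, c.chosen_slot] - lse).sum())

    P = expU / denom[:, None]
    W = -P
    W[rows, c.chosen_slot] += 1.0
    W[~c.mask] = 0.0

    cb = W * (lam * c.sign)[:, None]
    cd = W * (lam * c.use_delta)[:, None]
    flat_mask = c.mask.ravel()
    g_beta_full = np.bincount(
        c.item_idx.ravel()[flat_mask],
        weights=cb.ravel()[flat_mask],
        minlength=c.n_items,
    )
    g_delta_full = np.bincount(
        c.pos_idx.ravel()[flat_mask],
        weights=cd.ravel()[flat_mask],
        minlength=c.n_positions,
    )
    su = (W * np.where(c.mask, U, 0.0)).sum(axis=1)
    per_resp_u = np.bincount(c.resp_idx, weights=su, minlength=c.n_respondents)
    g_loglam = c.group_flags.T @ per_resp_u

    grad = np.concatenate([emb.E.T @ g_beta_full, g_delta_full[1:], g_loglam])

    if not per_respondent_scores:
        return ll, grad, None

    R = c.n_respondents
    keys_b = (c.resp_idx[:, None] * c.n_items + c.item_idx).ravel()[flat_mask]
    sb = np.bincount(
        keys_b, weights=cb.ravel()[flat_mask], minlength=R * c.n_items
    ).reshape(R, c.n_items)
    keys_d = (c.resp_idx[:, None] * c.n_positions + c.pos_idx).ravel()[flat_mask]
    sd = np.bincount(
        keys_d, weights=cd.ravel()[flat_mask], minlength=R * c.n_positions
    ).reshape(R, c.n_positions)
    scores = np.hstack(
        [sb @ emb.E, sd[:, 1:], per_resp_u[:, None] * c.group_flags]
    )
    return ll, grad, scores


def dataset_loglik(
    params: ParameterVector | np.ndarray,
    dataset: ChoiceDataset,
    q1_threshold: float = 7.0,
    spec: InstrumentSpec | None = None,
) -> float:
    """Total S-MNL log-likelihood of a dataset.

    ``params`` may be a :class:`ParameterVector` or a free vector under the
    constraint embedding.  Each respondent's scale multiplier is derived from
    their profile (task understanding, age group, completion time vs the
    ``q1_threshold``).
    """
    spec = spec or default_instrument()
    emb = ConstraintEmbedding(spec)
    if isinstance(params, ParameterVector):
        x = emb.to_free(params)
    else:
        x = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(x)):
        raise EstimationError("parameters contain NaN or Inf")
    compiled = compile_dataset(dataset, spec, q1_threshold)
    return _loglik_and_grad(x, compiled, emb)[0]


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Maximum-likelihood estimate with cluster-robust inference.

    ``cov`` is the sandwich covariance over the free parameters (scales on
    the log scale); ``se`` its diagonal square roots.  ``params_se`` reports
    natural-scale standard errors (delta method for the scale multipliers).
    """

    params: ParameterVector
    free: np.ndarray
    free_names: list[str]
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    message: str
    cov: np.ndarray
    se: np.ndarray
    n_respondents: int
    q1_threshold: float

    def se_of(self, name: str) -> float:
        """Robust SE by free-parameter name, on the natural scale."""
        i = self.free_names.index(name)
        if name.startswith("loglambda:"):
            lam = math.exp(self.free[i])
            return lam * float(self.se[i])
        return float(self.se[i])

    def coefficient_table(self, spec: InstrumentSpec) -> "pd.DataFrame":
        """Per-free-parameter estimates, robust SEs and two-sided p-values."""
        import pandas as pd

        rows = []
        for i, name in enumerate(self.free_names):
            if name.startswith("loglambda:"):
                est = math.exp(self.free[i])
                se = est * float(self.se[i])
                # test H0: lambda = 1, i.e. loglambda = 0
                z = self.free[i] / self.se[i] if self.se[i] > 0 else np.nan
            else:
                est = float(self.free[i])
                se = float(self.se[i])
                z = est / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append((name, est, se, p))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se_robust", "p"])

    def beta_item_covariance(self, spec: InstrumentSpec) -> np.ndarray:
        """Robust covariance of the full per-item beta vector (n_items^2)."""
        emb = ConstraintEmbedding(spec)
        nb = emb.n_beta_free
        return emb.E @ self.cov[:nb, :nb] @ emb.E.T


@dataclass
class FitConfig:
    gtol: float = 1e-5  # max-norm of the per-stage mean gradient
    maxiter: int = 500
    hessian_step: float = 1e-5


def _check_identification(c: CompiledData, spec: InstrumentSpec) -> None:
    seen = np.zeros(spec.n_items, dtype=bool)
    seen[np.unique(c.item_idx[c.mask])] = True
    if not seen.all():
        missing = [
            f"{spec.domains[i // N_LEVELS].code}-{i % N_LEVELS + 1}"
            for i in np.flatnonzero(~seen)
        ]
        raise IdentificationError(
            f"domain-levels never shown in the data: {missing}"
        )


def fit_smnl(
    dataset: ChoiceDataset,
    start: np.ndarray | None = None,
    spec: InstrumentSpec | None = None,
    q1_threshold: float = 7.0,
    config: FitConfig | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the sequential best-worst S-MNL.

    Quasi-Newton (L-BFGS-B) on the mean per-stage negative log-likelihood
    with the analytic gradient; deterministic given the start and the data.
    Non-convergence is flagged in the result, never silently ignored.
    """
    spec = spec or default_instrument()
    config = config or FitConfig()
    if dataset.n_respondents < 2:
        raise EstimationError("need at least 2 respondents to fit")
    emb = ConstraintEmbedding(spec)
    compiled = compile_dataset(dataset, spec, q1_threshold)
    _check_identification(compiled, spec)

    x0 = np.zeros(emb.n_free) if start is None else np.asarray(start, dtype=float)
    if x0.shape != (emb.n_free,):
        raise EstimationError(f"start vector must have length {emb.n_free}")
    scale = 1.0 / compiled.n_stages

    def negloglik(x):
        ll, grad, _ = _loglik_and_grad(x, compiled, emb)
        return -ll * scale, -grad * scale

    res = optimize.minimize(
        negloglik,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": config.maxiter,
            "ftol": 1e-14,
            "gtol": config.gtol * 1e-2,
            "maxcor": 25,
        },
    )
    x = res.x
    _, grad, _ = _loglik_and_grad(x, compiled, emb)
    grad_norm = float(np.abs(grad * scale).max())
    converged = grad_norm < config.gtol

    cov = robust_covariance_free(x, compiled, emb, step=config.hessian_step)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    ll, _, _ = _loglik_and_grad(x, compiled, emb)

    return FitResult(
        params=emb.to_params(x),
        free=x,
        free_names=list(emb.free_names),
        loglik=float(ll),
        converged=bool(converged),
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        message=str(res.message),
        cov=cov,
        se=se,
        n_respondents=dataset.n_respondents,
        q1_threshold=q1_threshold,
    )


def _observed_information(
    x: np.ndarray, c: CompiledData, emb: ConstraintEmbedding, step: float
) -> np.ndarray:
    """Negative Hessian of the total log-likelihood by central differences
    of the analytic gradient."""
    n = emb.n_free
    H = np.zeros((n, n))
    for k in range(n):
        h = step * (1.0 + abs(x[k]))
        xp = x.copy()
        xp[k] += h
        xm = x.copy()
        xm[k] -= h
        gp = _loglik_and_grad(xp, c, emb)[1]
        gm = _loglik_and_grad(xm, c, emb)[1]
        H[k] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    return -H


def robust_covariance_free(
    x: np.ndarray,
    compiled: CompiledData,
    emb: ConstraintEmbedding,
    step: float = 1e-5,
) -> np.ndarray:
    """Cluster-robust sandwich covariance ``A^-1 B A^-1``.

    ``A`` is the observed information; ``B`` sums the outer products of
    per-respondent score sums (clustering unit: respondent).
    """
    A = _observed_information(x, compiled, emb, step)
    _, _, scores = _loglik_and_grad(x, compiled, emb, per_respondent_scores=True)
    B = scores.T @ scores
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(A)
        null = v[:, np.abs(w) < 1e-10 * np.abs(w).max()]
        raise EstimationError(
            f"observed information is singular; null-space directions:\n{null.T}"
        ) from None
    cov = Ainv @ B @ Ainv
    return 0.5 * (cov + cov.T)


def robust_covariance(
    fit: FitResult,
    dataset: ChoiceDataset,
    spec: InstrumentSpec | None = None,
) -> np.ndarray:
    """Recompute the sandwich covariance of a converged fit on a dataset."""
    spec = spec or default_instrument()
    if not fit.converged:
        raise EstimationError("refusing to compute covariance for a non-converged fit")
    emb = ConstraintEmbedding(spec)
    compiled = compile_dataset(dataset, spec, fit.q1_threshold)
    return robust_covariance_free(fit.free, compiled, emb)


# ---------------------------------------------------------------------------
# pairwise tests


@dataclass(frozen=True)
class PairwiseTest:
    item_a: AttributeLevel
    item_b: AttributeLevel
    difference: float
    z: float
    p_one_sided: float
    aliased: bool = False


def pairwise_level_test(
    fit: FitResult,
    item_a: AttributeLevel,
    item_b: AttributeLevel,
    spec: InstrumentSpec | None = None,
) -> PairwiseTest:
    """z-ratio test of beta_a - beta_b with the robust covariance.

    Reports a one-sided p-value (upper tail of |z| direction as printed in
    valuation tables); aliased pairs (a joint coefficient) give z = 0 and
    p = 0.5 exactly.
    """
    spec = spec or default_instrument()
    if item_a == item_b:
        raise EstimationError(f"degenerate comparison of {item_a} with itself")
    ia, ib = spec.item_index(item_a), spec.item_index(item_b)
    covb = fit.beta_item_covariance(spec)
    beta_flat = fit.params.beta.reshape(-1)
    diff = float(beta_flat[ia] - beta_flat[ib])
    var = float(covb[ia, ia] + covb[ib, ib] - 2 * covb[ia, ib])
    if var <= 1e-14:
        if diff == 0.0:
            return PairwiseTest(item_a, item_b, 0.0, 0.0, 0.5, aliased=True)
        raise EstimationError(
            f"zero variance for non-identical difference {item_a} vs {item_b}"
        )
    z = diff / math.sqrt(var)
    p = float(stats.norm.sf(abs(z)))
    return PairwiseTest(item_a, item_b, diff, z, p)
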