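"""From fitted utilities to preference weights and scored states.

The deliverable of the valuation exercise is a table of per-domain-level
preference weights such that the total score of a full response profile
spans exactly [0, 1]: the all-best state (level 1 everywhere) scores 1 and
the all-worst state (level 4 everywhere) scores 0.  Where the sample
under-represents population groups, group-specific coefficient vectors can
first be combined with the correct population proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .instrument import (
    AttributeLevel,
    CarerState,
    InstrumentSpec,
    N_LEVELS,
    default_instrument,
    validate_state,
)


class PostprocessError(ValueError):
    """Invalid inputs to reweighting, rescaling or scoring."""


@dataclass
class PreferenceWeights:
    """Rescaled per-level weights with their provenance.

    ``weights`` has shape (n_domains, 4); within each domain the minimum
    level has weight 0 and the per-domain maxima sum to 1 across domains.
    """

    weights: np.ndarray
    spec: InstrumentSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.spec.n_domains, N_LEVELS):
            raise PostprocessError(
                f"weights must have shape {(self.spec.n_domains, N_LEVELS)}, "
                f"got {self.weights.shape}"
            )

    def weight_of(self, item: AttributeLevel) -> float:
        return float(
            self.weights[self.spec.domain_index(item.domain), item.level - 1]
        )


def reweight_by_population(
    group_betas: Sequence[np.ndarray],
    proportions: Sequence[float],
    spec: InstrumentSpec | None = None,
) -> np.ndarray:
    """Population-proportion-weighted average of group coefficient vectors.

    Every group supplies a full (n_domains, 4) beta array under the same
    identification constraints; the combined vector is the entrywise
    proportion-weighted sum, which preserves the reference-zero and
    joint-coefficient constraints by linearity.
    """
    spec = spec or default_instrument()
    props = np.asarray(proportions, dtype=float)
    if len(group_betas) != len(props):
        raise PostprocessError("one proportion per group is required")
    if abs(props.sum() - 1.0) > 1e-9:
        raise PostprocessError(f"proportions must sum to 1, got {props.sum()!r}")
    shape = (spec.n_domains, N_LEVELS)
    combined = np.zeros(shape)
    for g, (p, beta) in enumerate(zip(props, group_betas)):
        beta = np.asarray(beta, dtype=float)
        if beta.shape != shape:
            raise PostprocessError(f"group {g}: beta must have shape {shape}")
        combined += p * beta
    _check_constraints(combined, spec, context="combined beta")
    return combined


def _check_constraints(beta: np.ndarray, spec: InstrumentSpec, context: str) -> None:
    if spec.reference_item is not None:
        d = spec.domain_index(spec.reference_item.domain)
        if abs(beta[d, spec.reference_item.level - 1]) > 1e-9:
            raise PostprocessError(
                f"{context}: reference item {spec.reference_item} must be 0"
            )
    if spec.joint_pair is not None:
        a, b = spec.joint_pair
        da = spec.domain_index(a.domain)
        if abs(beta[da, a.level - 1] - beta[da, b.level - 1]) > 1e-9:
            raise PostprocessError(f"{context}: joint pair {a}, {b} must be equal")


def rescale_weights(
    beta: np.ndarray,
    spec: InstrumentSpec | None = None,
    provenance: dict | None = None,
) -> PreferenceWeights:
    """Rescale utilities so possible total scores span exactly [0, 1].

    Per domain d: ``w[d][l] = (beta[d][l] - min_l beta[d][l]) / C`` with the
    shared denominator ``C = sum_d (max_l - min_l)``.  The all-best state
    then scores exactly 1 and the all-worst state exactly 0, and the
    within-domain ordering of weights equals that of the utilities.
    """
    spec = spec or default_instrument()
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (spec.n_domains, N_LEVELS):
        raise PostprocessError(
            f"beta must have shape {(spec.n_domains, N_LEVELS)}, got {beta.shape}"
        )
    lo = beta.min(axis=1, keepdims=True)
    ranges = beta.max(axis=1) - lo[:, 0]
    C = float(ranges.sum())
    if C <= 0:
        raise PostprocessError("all utilities are constant; scale is degenerate")
    w = (beta - lo) / C
    prov = dict(provenance or {})
    prov.update({"rescale_denominator": C, "domain_ranges": ranges.tolist()})
    return PreferenceWeights(weights=w, spec=spec, provenance=prov)


def score_state(state: CarerState, weights: PreferenceWeights) -> float:
    """Preference-weighted total score of a full response profile, in [0, 1]."""
    spec = weights.spec
    valid = validate_state(state, spec)
    return float(
        sum(
            weights.weights[spec.domain_index(code), lev - 1]
            for code, lev in valid.items()
        )
    )


@dataclass(frozen=True)
class RankedItem:
    item: AttributeLevel
    value: float
    tied_with_previous: bool


def rank_items(
    values: PreferenceWeights | np.ndarray,
    spec: InstrumentSpec | None = None,
) -> list[RankedItem]:
    """All items in descending value order; ties broken by instrument order.

    Accepts either a :class:`PreferenceWeights` or a raw (n_domains, 4)
    utility array; tied runs are flagged.
    """
    if isinstance(values, PreferenceWeights):
        spec = values.spec
        arr = values.weights
    else:
        spec = spec or default_instrument()
        arr = np.asarray(values, dtype=float)
        if arr.shape != (spec.n_domains, N_LEVELS):
            raise PostprocessError(
                f"values must have shape {(spec.n_domains, N_LEVELS)}"
            )
    items = [
        (AttributeLevel(d.code, lev), float(arr[di, lev - 1]))
        for di, d in enumerate(spec.domains)
        for lev in range(1, N_LEVELS + 1)
    ]
    # stable sort on descending value keeps instrument order within ties
    ordered = sorted(items, key=lambda t: -t[1])
    out = []
    for k, (item, val) in enumerate(ordered):
        tied = k > 0 and val == ordered[k - 1][1]
        out.append(RankedItem(item=item, value=val, tied_with_previous=tied))
    return out
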