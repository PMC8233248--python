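"""Structure of the ASCOT-Carer instrument.

The ASCOT-Carer measures long-term-care-related quality of life of informal
carers over seven domains (occupation, control over daily life, looking after
yourself, personal safety, social participation, space and time to be yourself,
feeling supported and encouraged).  Each domain is observed at one of four
outcome levels: 1 = ideal state, 2 = no needs, 3 = some needs, 4 = high needs.
The 7 x 4 = 28 domain-levels are the choice items of the best-worst scaling
experiment, and everything downstream (design, simulation, estimation,
scoring) is typed against the :class:`InstrumentSpec` defined here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

N_LEVELS = 4

#: Semantic labels of the four outcome levels.
LEVEL_LABELS: dict[int, str] = {
    1: "ideal state",
    2: "no needs",
    3: "some needs",
    4: "high needs",
}


class InstrumentError(ValueError):
    """A malformed instrument definition or response state."""


@dataclass(frozen=True)
class AttributeLevel:
    """One choice item: a domain observed at an outcome level."""

    domain: str
    level: int

    def __post_init__(self) -> None:
        if self.level not in LEVEL_LABELS:
            raise InstrumentError(
                f"level must be in 1..4, got {self.level!r} for domain {self.domain!r}"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.domain}-{self.level}"


@dataclass(frozen=True)
class Domain:
    """One quality-of-life domain with its four level statements.

    ``statements`` are ordered from level 1 (ideal state) to level 4
    (high needs).
    """

    code: str
    label: str
    statements: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.code:
            raise InstrumentError("domain code must be non-empty")
        if len(self.statements) != N_LEVELS:
            raise InstrumentError(
                f"domain {self.code!r}: statements must have exactly {N_LEVELS} "
                f"entries, got {len(self.statements)}"
            )
        object.__setattr__(self, "statements", tuple(self.statements))


@dataclass(frozen=True)
class InstrumentSpec:
    """An ordered set of domains plus the identification anchors.

    ``reference_item`` is the item whose utility is pinned to zero in the
    choice model (for the full ASCOT-Carer: 'space and time to be yourself'
    at level 4, the item with the lowest perceived utility).  ``joint_pair``
    names two items of one domain that share a single coefficient (levels 1
    and 2 of 'feeling supported and encouraged', which respondents value
    indistinguishably).
    """

    domains: tuple[Domain, ...]
    reference_item: AttributeLevel | None = None
    joint_pair: tuple[AttributeLevel, AttributeLevel] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        codes = [d.code for d in self.domains]
        if len(set(codes)) != len(codes):
            raise InstrumentError(f"domain codes must be unique, got {codes}")
        for item in self._anchor_items():
            if item.domain not in codes:
                raise InstrumentError(
                    f"anchor item {item} refers to unknown domain {item.domain!r}"
                )
        if self.joint_pair is not None:
            a, b = self.joint_pair
            if a.domain != b.domain or a.level == b.level:
                raise InstrumentError(
                    "joint pair must be two distinct levels of one domain, "
                    f"got {a} and {b}"
                )

    def _anchor_items(self) -> list[AttributeLevel]:
        items = []
        if self.reference_item is not None:
            items.append(self.reference_item)
        if self.joint_pair is not None:
            items.extend(self.joint_pair)
        return items

    # -- lookups -----------------------------------------------------------

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def n_items(self) -> int:
        return self.n_domains * N_LEVELS

    @property
    def domain_codes(self) -> tuple[str, ...]:
        return tuple(d.code for d in self.domains)

    def domain_index(self, code: str) -> int:
        try:
            return self.domain_codes.index(code)
        except ValueError:
            raise InstrumentError(f"unknown domain code {code!r}") from None

    def item_index(self, item: AttributeLevel) -> int:
        """Canonical index of an item: domain-major, level-ascending (0..n-1)."""
        return self.domain_index(item.domain) * N_LEVELS + (item.level - 1)

    def statement(self, item: AttributeLevel) -> str:
        return self.domains[self.domain_index(item.domain)].statements[item.level - 1]

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {
            "domains": [
                {"code": d.code, "label": d.label, "statements": list(d.statements)}
                for d in self.domains
            ]
        }
        if self.reference_item is not None:
            out["reference_item"] = {
                "domain": self.reference_item.domain,
                "level": self.reference_item.level,
            }
        if self.joint_pair is not None:
            out["joint_pair"] = [
                {"domain": it.domain, "level": it.level} for it in self.joint_pair
            ]
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "InstrumentSpec":
        try:
            domains = tuple(
                Domain(d["code"], d["label"], tuple(d["statements"]))
                for d in data["domains"]
            )
        except KeyError as exc:
            raise InstrumentError(f"instrument definition missing field {exc}") from None
        ref = data.get("reference_item")
        joint = data.get("joint_pair")
        return cls(
            domains=domains,
            reference_item=(
                AttributeLevel(ref["domain"], int(ref["level"])) if ref else None
            ),
            joint_pair=(
                tuple(AttributeLevel(j["domain"], int(j["level"])) for j in joint)
                if joint
                else None
            ),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "InstrumentSpec":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# Published English response options of the ASCOT-Carer (level 1 .. level 4
# per domain).  The Austrian survey administered the validated German
# translation; any translated wording can be supplied via a JSON instrument
# file with the same structure.
_DEFAULT_DOMAINS = (
    Domain(
        "OCC",
        "Occupation",
        (
            "I'm able to spend my time as I want, doing things I value or enjoy",
            "I'm able to do enough of the things I value or enjoy with my time",
            "I do some of the things I value or enjoy with my time, but not enough",
            "I don't do anything I value or enjoy with my time",
        ),
    ),
    Domain(
        "CTL",
        "Control over daily life",
        (
            "I have as much control over my daily life as I want",
            "I have adequate control over my daily life",
            "I have some control over my daily life, but not enough",
            "I have no control over my daily life",
        ),
    ),
    Domain(
        "SELF",
        "Looking after yourself",
        (
            "I look after myself as well as I want",
            "I look after myself well enough",
            "Sometimes I can't look after myself well enough",
            "I feel I am neglecting myself",
        ),
    ),
    Domain(
        "SAFE",
        "Personal safety",
        (
            "I feel as safe as I want",
            "Generally I feel adequately safe, but not as safe as I would like",
            "I feel less than adequately safe",
            "I don't feel at all safe",
        ),
    ),
    Domain(
        "SOC",
        "Social participation and involvement",
        (
            "I have as much social contact as I want with people I like",
            "I have adequate social contact with people",
            "I have some social contact with people, but not enough",
            "I have little social contact with people and feel socially isolated",
        ),
    ),
    Domain(
        "STS",
        "Space and time to be yourself",
        (
            "I have all the space and time I need to be myself",
            "I have adequate space and time to be myself",
            "I have some of the space and time I need to be myself, but not enough",
            "I don't have any space or time to be myself",
        ),
    ),
    Domain(
        "ENC",
        "Feeling supported and encouraged",
        (
            "I feel I have the encouragement and support I want",
            "I feel I have adequate encouragement and support",
            "I feel I have some encouragement and support, but not enough",
            "I feel I have no encouragement and support",
        ),
    ),
)


def default_instrument() -> InstrumentSpec:
    """The full 7-domain ASCOT-Carer instrument with its standard anchors."""
    return InstrumentSpec(
        domains=_DEFAULT_DOMAINS,
        reference_item=AttributeLevel("STS", 4),
        joint_pair=(AttributeLevel("ENC", 1), AttributeLevel("ENC", 2)),
    )


def enumerate_levels(spec: InstrumentSpec) -> list[AttributeLevel]:
    """All items of the instrument in canonical order.

    Domain-major (instrument order) then level-ascending; stable across calls.
    """
    return [
        AttributeLevel(d.code, lev)
        for d in spec.domains
        for lev in range(1, N_LEVELS + 1)
    ]


# A response state: mapping of domain code -> level.
CarerState = Mapping[str, int]


def validate_state(state: CarerState, spec: InstrumentSpec) -> dict[str, int]:
    """Check a full response profile against the instrument.

    Every domain must be present with a level in 1..4; errors name the
    offending domain.
    """
    out: dict[str, int] = {}
    for d in spec.domains:
        if d.code not in state:
            raise InstrumentError(f"state is missing domain {d.code!r}")
        lev = state[d.code]
        if not isinstance(lev, (int,)) or lev not in LEVEL_LABELS:
            raise InstrumentError(
                f"domain {d.code!r}: level must be an integer in 1..4, got {lev!r}"
            )
        out[d.code] = int(lev)
    extra = set(state) - set(spec.domain_codes)
    if extra:
        raise InstrumentError(f"state has unknown domains: {sorted(extra)}")
    return out
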