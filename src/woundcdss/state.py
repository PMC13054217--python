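"""Finite wound-state space and treatment-option vocabularies.

A pressure ulcer is described by a small closed set of categorical
attributes — the ones the treatment recommendation actually depends on:
phase (acute vs chronic), depth, wound surface, necrotic tissue colour
and moisture, infection, undermined pockets containing necrotic tissue,
granulation quality and exudate level.  The attribute set is a reduction
of the DESIGN-R assessment axes (depth, exudate, inflammation/infection,
granulation, necrosis, pocket); wound size is deliberately absent because
no recommendation in the engine depends on it.

Two structural invariants keep the space honest:

* an acute-phase ulcer carries the neutral value for depth, necrosis,
  pocket and granulation (those axes are only assessed on chronic wounds);
* granulation quality is only assessed on deep chronic wounds.

``enumerate_states`` yields every valid state exactly once in a stable
order; ``parse_state``/``WoundState.to_dict`` round-trip states through
plain string mappings (and hence JSON objects or CSV rows).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, fields
from typing import Iterator, Mapping

__all__ = [
    "Phase",
    "Depth",
    "Surface",
    "Necrosis",
    "Infection",
    "Pocket",
    "Granulation",
    "Exudate",
    "WoundState",
    "OintmentOption",
    "DressingOption",
    "Recommendation",
    "OINTMENTS",
    "DRESSINGS",
    "InvalidStateError",
    "enumerate_states",
    "parse_state",
]


class Phase(str, enum.Enum):
    ACUTE = "acute"
    CHRONIC = "chronic"


class Depth(str, enum.Enum):
    SHALLOW = "shallow"
    DEEP = "deep"


class Surface(str, enum.Enum):
    INTACT_BLISTER = "intact_blister"
    EROSION_SHALLOW_ULCER = "erosion_shallow_ulcer"
    OPEN_DEEP_ULCER = "open_deep_ulcer"


class Necrosis(str, enum.Enum):
    NONE = "none"
    BLACK_DRY = "black_dry"
    YELLOW_MOIST = "yellow_moist"


class Infection(str, enum.Enum):
    ABSENT = "absent"
    PRESENT = "present"


class Pocket(str, enum.Enum):
    ABSENT = "absent"
    PRESENT_WITH_NECROSIS = "present_with_necrosis"


class Granulation(str, enum.Enum):
    NOT_APPLICABLE = "not_applicable"
    INSUFFICIENT = "insufficient"
    HEALTHY_SUFFICIENT = "healthy_sufficient"


class Exudate(str, enum.Enum):
    MINIMAL = "minimal"
    HIGH = "high"


_FIELD_ENUMS: dict[str, type[enum.Enum]] = {
    "phase": Phase,
    "depth": Depth,
    "surface": Surface,
    "necrosis": Necrosis,
    "infection": Infection,
    "pocket": Pocket,
    "granulation": Granulation,
    "exudate": Exudate,
}

# Values a field collapses to on an acute-phase wound.
_ACUTE_NEUTRAL = {
    "depth": Depth.SHALLOW,
    "necrosis": Necrosis.NONE,
    "pocket": Pocket.ABSENT,
    "granulation": Granulation.NOT_APPLICABLE,
}

_PARSE_DEFAULTS = {
    "depth": Depth.SHALLOW,
    "surface": Surface.EROSION_SHALLOW_ULCER,
    "necrosis": Necrosis.NONE,
    "infection": Infection.ABSENT,
    "pocket": Pocket.ABSENT,
    "granulation": Granulation.NOT_APPLICABLE,
    "exudate": Exudate.MINIMAL,
}


class InvalidStateError(ValueError):
    """A wound-state description violates the state-space invariants."""


@dataclass(frozen=True)
class WoundState:
    """One pressure ulcer, described on the closed attribute vocabulary."""

    phase: Phase
    depth: Depth = Depth.SHALLOW
    surface: Surface = Surface.EROSION_SHALLOW_ULCER
    necrosis: Necrosis = Necrosis.NONE
    infection: Infection = Infection.ABSENT
    pocket: Pocket = Pocket.ABSENT
    granulation: Granulation = Granulation.NOT_APPLICABLE
    exudate: Exudate = Exudate.MINIMAL

    def __post_init__(self) -> None:
        for name, enum_cls in _FIELD_ENUMS.items():
            value = getattr(self, name)
            if not isinstance(value, enum_cls):
                # Accept bare strings for convenience, but validate them.
                try:
                    object.__setattr__(self, name, enum_cls(value))
                except ValueError:
                    raise InvalidStateError(
                        f"invalid value {value!r} for field '{name}'; "
                        f"expected one of {[m.value for m in enum_cls]}"
                    ) from None
        if self.phase is Phase.ACUTE:
            for name, neutral in _ACUTE_NEUTRAL.items():
                if getattr(self, name) is not neutral:
                    raise InvalidStateError(
                        f"acute-phase wound must have {name}={neutral.value!r}, "
                        f"got {getattr(self, name).value!r}"
                    )
        if self.granulation is not Granulation.NOT_APPLICABLE and not (
            self.phase is Phase.CHRONIC and self.depth is Depth.DEEP
        ):
            raise InvalidStateError(
                "granulation is only assessed on deep chronic wounds; "
                f"got granulation={self.granulation.value!r} with "
                f"phase={self.phase.value!r}, depth={self.depth.value!r}"
            )

    def to_dict(self) -> dict[str, str]:
        """Serialize to a plain mapping of field name -> enum value string."""
        return {f.name: getattr(self, f.name).value for f in fields(self)}

    def sort_key(self) -> tuple[str, ...]:
        return tuple(getattr(self, name).value for name in _FIELD_ENUMS)


def parse_state(record: Mapping[str, str]) -> WoundState:
    """Build a validated :class:`WoundState` from a key-value mapping.

    Missing fields take their neutral defaults (so ``{"phase": "acute"}``
    yields the acute neutral state); unknown keys are rejected.
    """
    unknown = set(record) - set(_FIELD_ENUMS)
    if unknown:
        raise InvalidStateError(f"unknown field(s): {sorted(unknown)}")
    if "phase" not in record:
        raise InvalidStateError("field 'phase' is required")
    kwargs: dict[str, enum.Enum] = {}
    for name, enum_cls in _FIELD_ENUMS.items():
        if name in record:
            raw = record[name]
            try:
                kwargs[name] = enum_cls(raw)
            except ValueError:
                raise InvalidStateError(
                    f"invalid value {raw!r} for field '{name}'; "
                    f"expected one of {[m.value for m in enum_cls]}"
                ) from None
        elif name in _PARSE_DEFAULTS:
            kwargs[name] = _PARSE_DEFAULTS[name]
    return WoundState(**kwargs)


def enumerate_states() -> list[WoundState]:
    """Every valid wound state exactly once, in a stable sorted order.

    Brute-force filter of the full attribute cross-product against the
    type invariants; the space is small (300 states) so this is cheap.
    """
    states = []
    for combo in itertools.product(*(list(e) for e in _FIELD_ENUMS.values())):
        try:
            states.append(WoundState(**dict(zip(_FIELD_ENUMS, combo))))
        except InvalidStateError:
            continue
    states.sort(key=WoundState.sort_key)
    return states


@dataclass(frozen=True)
class OintmentOption:
    code: int
    label: str


@dataclass(frozen=True)
class DressingOption:
    code: int
    label: str
    occlusive_flag: bool


#: The six ointment options offered to participants, verbatim.
OINTMENTS: dict[int, OintmentOption] = {
    code: OintmentOption(code, label)
    for code, label in {
        1: "silver sulfadiazine",
        2: "povidone-iodine, cadexomer iodine, or iodoform",
        3: "povidone-iodine or bucladesine sodium",
        4: "povidone-iodine",
        5: "zinc oxide, dimethyl isopropyl azulene, or white petrolatum",
        6: "prostaglandin or trafermin",
    }.items()
}

#: The six wound-dressing options. Codes 1-5 are occlusive (moisture
#: retaining); code 6 is the explicit "no dressing" choice.
DRESSINGS: dict[int, DressingOption] = {
    code: DressingOption(code, label, occlusive_flag=(code != 6))
    for code, label in {
        1: "silver-containing hydrofiber or silver-containing polyurethane foam",
        2: "silver-containing hydrofiber or silver-containing hydrocolloid",
        3: "silver-containing hydrocolloid or hydrogel",
        4: "polyurethane film or silver-containing hydrocolloid",
        5: "hydrogel",
        6: "use of a dressing was considered inappropriate",
    }.items()
}


@dataclass(frozen=True)
class Recommendation:
    """One ointment, one dressing, and the decision path that produced them."""

    ointment: OintmentOption
    dressing: DressingOption
    trace: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "ointment": {"code": self.ointment.code, "label": self.ointment.label},
            "dressing": {
                "code": self.dressing.code,
                "label": self.dressing.label,
                "occlusive": self.dressing.occlusive_flag,
            },
            "trace": list(self.trace),
        }


def iter_field_values(name: str) -> Iterator[str]:
    """String values of one attribute's enumeration (tree-validation helper)."""
    return (member.value for member in _FIELD_ENUMS[name])
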