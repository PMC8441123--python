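"""Factorial configuration spaces with binary factors.

A *configuration* is one combination of factor levels — a state of the
interactive experience.  With ``k`` binary factors there are ``2**k``
configurations, each identified by an integer code: the bit string of the
level tuple read big-endian, so the first-listed factor is the most
significant bit.  The default space ships the four factors of the VR
crowd-experience study (navigation, body representation, social feedback,
rendering), for which code 6 is the bit string ``0110`` — teleportation,
full body, responsive crowd, realistic rendering.

A *proposal action* toggles exactly one factor's level; actions are the
moves an elicitation agent can offer a participant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import yaml

__all__ = [
    "Factor",
    "FactorSpace",
    "Configuration",
    "ProposalAction",
    "default_space",
    "enumerate_configurations",
    "config_code",
    "config_of",
    "apply_action",
    "space_from_dict",
    "space_from_yaml",
    "table_report",
]


@dataclass(frozen=True)
class Factor:
    """One binary design dimension with labelled levels 0 and 1."""

    name: str
    level0: str
    level1: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("factor name must be non-empty")
        if self.level0 == self.level1:
            raise ValueError(
                f"factor {self.name!r}: level labels must be distinct"
            )

    def label(self, level: int) -> str:
        if level not in (0, 1):
            raise ValueError(f"level must be 0 or 1, got {level}")
        return self.level1 if level else self.level0


@dataclass(frozen=True)
class FactorSpace:
    """An ordered tuple of binary factors.

    The order is significant: it fixes the bit order of configuration
    codes (first factor = most significant bit).
    """

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        if len(self.factors) < 1:
            raise ValueError("a factor space needs at least one factor")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError(f"factor names must be unique, got {names}")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_configurations(self) -> int:
        return 2 ** self.k

    def encode(self, levels: Sequence[int]) -> int:
        """Big-endian integer code of a level tuple."""
        if len(levels) != self.k:
            raise ValueError(
                f"expected {self.k} levels, got {len(levels)}"
            )
        code = 0
        for bit in levels:
            if bit not in (0, 1):
                raise ValueError(f"levels must be 0/1 bits, got {bit!r}")
            code = (code << 1) | bit
        return code

    def decode(self, code: int) -> tuple[int, ...]:
        """Level tuple for an integer code."""
        if not 0 <= code < self.n_configurations:
            raise ValueError(
                f"code {code} out of range [0, {self.n_configurations - 1}]"
            )
        return tuple((code >> (self.k - 1 - i)) & 1 for i in range(self.k))

    def configuration(self, code: int) -> "Configuration":
        return Configuration(levels=self.decode(code), code=code)

    def labels(self, config: "Configuration") -> tuple[str, ...]:
        return tuple(
            f.label(bit) for f, bit in zip(self.factors, config.levels)
        )


@dataclass(frozen=True)
class Configuration:
    """A point of the factorial space: level tuple plus its integer code."""

    levels: tuple[int, ...]
    code: int

    def __post_init__(self) -> None:
        expected = 0
        for bit in self.levels:
            expected = (expected << 1) | bit
        if expected != self.code:
            raise ValueError(
                f"code {self.code} does not match levels {self.levels} "
                f"(big-endian value {expected})"
            )

    @property
    def bits(self) -> str:
        return "".join(str(b) for b in self.levels)


@dataclass(frozen=True)
class ProposalAction:
    """Toggle the level of one factor."""

    factor_index: int


def default_space() -> FactorSpace:
    """The four-factor space of the VR crowd-experience study."""
    return FactorSpace(
        factors=(
            Factor("navigation", "teleportation", "WiP"),
            Factor("body_representation", "hands", "body"),
            Factor("social_feedback", "ignored", "feedback"),
            Factor("rendering", "realistic", "cartoon"),
        )
    )


def enumerate_configurations(space: FactorSpace) -> list[Configuration]:
    """All ``2**k`` configurations in ascending code order."""
    return [space.configuration(c) for c in range(space.n_configurations)]


def config_code(config: Configuration, space: FactorSpace) -> int:
    """Integer code of a configuration (validates against the space)."""
    return space.encode(config.levels)


def config_of(code: int, space: FactorSpace) -> Configuration:
    """Configuration for an integer code."""
    return space.configuration(code)


def apply_action(
    config: Configuration, action: ProposalAction, space: FactorSpace
) -> Configuration:
    """Toggle exactly one factor's level; an involution."""
    if not 0 <= action.factor_index < space.k:
        raise ValueError(
            f"factor index {action.factor_index} out of range [0, {space.k - 1}]"
        )
    new_code = config.code ^ (1 << (space.k - 1 - action.factor_index))
    return space.configuration(new_code)


def space_from_dict(spec: Iterable[dict]) -> FactorSpace:
    """Build a space from a list of ``{name, level0, level1}`` mappings."""
    return FactorSpace(
        factors=tuple(
            Factor(d["name"], d["level0"], d["level1"]) for d in spec
        )
    )


def space_from_yaml(path) -> FactorSpace:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict):
        doc = doc["factors"]
    return space_from_dict(doc)


def table_report(space: FactorSpace) -> str:
    """Plain-text configuration table: code, bit string, level labels."""
    lines = ["code  bits  " + "  ".join(f.name for f in space.factors)]
    for cfg in enumerate_configurations(space):
        labels = space.labels(cfg)
        lines.append(f"{cfg.code:>4}  {cfg.bits}  " + "  ".join(labels))
    return "\n".join(lines)
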