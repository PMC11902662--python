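"""The 23 pressure/inertial sensor combinations and their channel subsets.

Configurations pair one of six pressure subsets (none, 1m5m, 1mH, 5mH,
1m5mH, all four) with one of the nested inertial subsets (none, A, AG,
AGM); the combination with no sensors at all is excluded, leaving 23.
Names follow the ``<n>P[.<sensors>][ + <inertial>]`` scheme, e.g.
``2P.1m5m + AG`` or ``4P``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from skigears.io_formats import canonical_sort

#: Allowed pressure subsets, in grid (row) order.
PRESSURE_SUBSETS: tuple[tuple[str, ...], ...] = (
    (),
    ("1m", "5m"),
    ("1m", "H"),
    ("5m", "H"),
    ("1m", "5m", "H"),
    ("BT", "1m", "5m", "H"),
)

#: Allowed inertial subsets (nested chain), in grid (column) order.
INERTIAL_SUBSETS: tuple[tuple[str, ...], ...] = ((), ("A",), ("A", "G"), ("A", "G", "M"))

_PRESSURE_NAME_ORDER = ("1m", "5m", "H", "BT")  # order used inside names


class ConfigParseError(ValueError):
    """Raised when a configuration name cannot be resolved."""


@dataclass(frozen=True)
class SensorConfig:
    """A pressure-sensor subset plus an inertial-sensor subset."""

    pressure: frozenset[str]
    inertial: frozenset[str]

    def __post_init__(self) -> None:
        if frozenset(self.pressure) not in {frozenset(p) for p in PRESSURE_SUBSETS}:
            raise ConfigParseError(f"disallowed pressure subset: {set(self.pressure)}")
        if frozenset(self.inertial) not in {frozenset(i) for i in INERTIAL_SUBSETS}:
            raise ConfigParseError(f"disallowed inertial subset: {set(self.inertial)}")
        if not self.pressure and not self.inertial:
            raise ConfigParseError("a configuration must include at least one sensor")

    @property
    def pressure_name(self) -> str:
        n = len(self.pressure)
        if n == 0:
            return "0P"
        if n == 4:
            return "4P"
        tokens = "".join(s for s in _PRESSURE_NAME_ORDER if s in self.pressure)
        return f"{n}P.{tokens}"

    @property
    def inertial_name(self) -> str:
        return "".join(s for s in ("A", "G", "M") if s in self.inertial)

    @property
    def name(self) -> str:
        if not self.inertial:
            return self.pressure_name
        if not self.pressure:
            return f"0P + {self.inertial_name}"
        return f"{self.pressure_name} + {self.inertial_name}"

    def __str__(self) -> str:
        return self.name


def enumerate_configs() -> list[SensorConfig]:
    """All 23 configurations in canonical grid order (0P block first;
    within a pressure block: none, A, AG, AGM)."""
    configs = []
    for p in PRESSURE_SUBSETS:
        for i in INERTIAL_SUBSETS:
            if not p and not i:
                continue
            configs.append(SensorConfig(pressure=frozenset(p), inertial=frozenset(i)))
    return configs


_NAME_RE = re.compile(
    r"""^\s*(?P<np>\d)P            # pressure count
        (?:\.(?P<ps>[a-zA-Z0-9]+))?  # pressure sensor tokens
        (?:\s*\+\s*(?P<iner>[AGM]+))?
        \s*$""",
    re.VERBOSE,
)


def parse_name(name: str) -> SensorConfig:
    """Parse a canonical configuration name (whitespace-tolerant)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ConfigParseError(f"cannot parse configuration name: {name!r}")
    n_p = int(m.group("np"))
    tokens: list[str] = []
    rest = m.group("ps") or ""
    while rest:
        for tok in ("1m", "5m", "H", "BT"):
            if rest.startswith(tok):
                tokens.append(tok)
                rest = rest[len(tok):]
                break
        else:
            raise ConfigParseError(f"unknown pressure token in {name!r}")
    if n_p == 4 and not tokens:
        tokens = ["BT", "1m", "5m", "H"]
    if len(tokens) != n_p:
        raise ConfigParseError(
            f"{name!r}: {n_p} pressure sensors declared but {len(tokens)} named"
        )
    inertial = tuple(m.group("iner") or "")
    if len(set(inertial)) != len(inertial):
        raise ConfigParseError(f"duplicate inertial token in {name!r}")
    return SensorConfig(pressure=frozenset(tokens), inertial=frozenset(inertial))


def channels_for(config: SensorConfig) -> list[str]:
    """Channel names (both feet, canonical order) carried by a configuration."""
    sensors = list(config.pressure)
    for s in config.inertial:
        sensors += [f"{s}x", f"{s}y", f"{s}z"]
    names = [f"{foot}_{s}" for foot in ("R", "L") for s in sensors]
    return canonical_sort(names)
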