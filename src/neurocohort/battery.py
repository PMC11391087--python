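"""Test-battery configuration: measures, domains, and their validation.

A battery is a fixed set of outcome measures grouped into cognitive
domains of exactly three measures each.  Each measure carries the
direction of impairment (whether low or high scores are the impaired
tail), an optional log-transform flag, and the marginal distribution
family used by the synthetic-cohort generator.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "MeasureSpec",
    "DomainSpec",
    "BatteryConfig",
    "BatteryError",
    "load_battery",
    "default_battery",
    "MEASURES_PER_DOMAIN",
]

MEASURES_PER_DOMAIN = 3

DIRECTIONS = frozenset({"higher_better", "higher_worse"})
TRANSFORMS = frozenset({"none", "log"})
GENERATOR_FAMILIES = frozenset({"normal", "lognormal", "count"})


class BatteryError(ValueError):
    """Invalid battery configuration."""


@dataclass(frozen=True)
class MeasureSpec:
    """One outcome measure of the battery."""

    name: str
    domain: str
    direction: str = "higher_better"
    transform: str = "none"
    generator_family: str = "normal"
    display_label: str = ""

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise BatteryError(
                f"measure {self.name!r}: unknown direction {self.direction!r}"
            )
        if self.transform not in TRANSFORMS:
            raise BatteryError(
                f"measure {self.name!r}: unknown transform {self.transform!r}"
            )
        if self.generator_family not in GENERATOR_FAMILIES:
            raise BatteryError(
                f"measure {self.name!r}: unknown generator_family "
                f"{self.generator_family!r}"
            )


@dataclass(frozen=True)
class DomainSpec:
    """A cognitive domain: an ordered triple of measure names."""

    name: str
    measures: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "measures", tuple(self.measures))
        if len(self.measures) != MEASURES_PER_DOMAIN:
            raise BatteryError(
                f"domain {self.name!r} must list exactly "
                f"{MEASURES_PER_DOMAIN} measures, got {len(self.measures)}"
            )


@dataclass(frozen=True)
class BatteryConfig:
    """A validated battery: domains and their measures.

    Invariants enforced on construction: measure names unique, every
    measure belongs to exactly one domain, and every domain lists
    exactly three measures that all have a matching :class:`MeasureSpec`.
    """

    domains: tuple[DomainSpec, ...]
    measures: tuple[MeasureSpec, ...]
    _by_name: Mapping[str, MeasureSpec] = field(
        init=False, repr=False, compare=False, default=None
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        object.__setattr__(self, "measures", tuple(self.measures))
        names = [m.name for m in self.measures]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise BatteryError(f"duplicate measure name(s): {sorted(dupes)}")
        by_name = {m.name: m for m in self.measures}
        domain_names = [d.name for d in self.domains]
        if len(set(domain_names)) != len(domain_names):
            raise BatteryError("duplicate domain names")
        seen: dict[str, str] = {}
        for d in self.domains:
            for mname in d.measures:
                if mname not in by_name:
                    raise BatteryError(
                        f"domain {d.name!r} references unknown measure {mname!r}"
                    )
                if mname in seen:
                    raise BatteryError(
                        f"measure {mname!r} listed in two domains: "
                        f"{seen[mname]!r} and {d.name!r}"
                    )
                seen[mname] = d.name
        for m in self.measures:
            if m.name not in seen:
                raise BatteryError(
                    f"measure {m.name!r} is not assigned to any domain"
                )
            if seen[m.name] != m.domain:
                raise BatteryError(
                    f"measure {m.name!r} declares domain {m.domain!r} but is "
                    f"listed under {seen[m.name]!r}"
                )
        object.__setattr__(self, "_by_name", by_name)

    # -- accessors -------------------------------------------------------
    @property
    def measure_names(self) -> list[str]:
        return [m.name for m in self.measures]

    @property
    def domain_names(self) -> list[str]:
        return [d.name for d in self.domains]

    def measure(self, name: str) -> MeasureSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise BatteryError(f"unknown measure {name!r}") from None

    def domain_of(self, measure_name: str) -> str:
        return self.measure(measure_name).domain

    def domain(self, name: str) -> DomainSpec:
        for d in self.domains:
            if d.name == name:
                return d
        raise BatteryError(f"unknown domain {name!r}")


def _as_mapping(doc) -> Mapping:
    if isinstance(doc, Mapping):
        return doc
    path = Path(doc)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_battery(config_doc) -> BatteryConfig:
    """Build a :class:`BatteryConfig` from a YAML/JSON file or a mapping.

    The document must carry ``domains`` (name + 3 measure names each) and
    ``measures`` (name, domain, direction, transform, generator_family).
    Raises :class:`BatteryError` naming the offending entry on any
    structural violation.
    """
    doc = _as_mapping(config_doc)
    try:
        raw_domains: Iterable[Mapping] = doc["domains"]
        raw_measures: Iterable[Mapping] = doc["measures"]
    except KeyError as exc:
        raise BatteryError(f"battery config missing section {exc}") from None
    domains = tuple(
        DomainSpec(name=d["name"], measures=tuple(d["measures"]))
        for d in raw_domains
    )
    measures = tuple(
        MeasureSpec(
            name=m["name"],
            domain=m["domain"],
            direction=m.get("direction", "higher_better"),
            transform=m.get("transform", "none"),
            generator_family=m.get("generator_family", "normal"),
            display_label=m.get("display_label", ""),
        )
        for m in raw_measures
    )
    return BatteryConfig(domains=domains, measures=measures)


def default_battery() -> BatteryConfig:
    """The packaged default battery: 7 domains x 3 measures."""
    ref = resources.files("neurocohort.data") / "default_battery.yaml"
    return load_battery(yaml.safe_load(ref.read_text(encoding="utf-8")))
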