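"""Odorant panel: the chemical inventory loaded into the olfactometer.

Each odorant carries the headspace-relevant properties (vapor pressure at
25 C and the liquid-phase dilution in mineral oil).  Delivered gas-phase
concentration is tracked in arbitrary units, normalized so that the strongest
odorant at 100% valve duty equals 1.0; per-odorant amplitudes scale with
``vapor_pressure * dilution``.  The mineral-oil "blank" has zero headspace
strength and zero sensor activity downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml


@dataclass(frozen=True)
class Odorant:
    name: str
    odor_class: str
    molecular_weight: float
    vapor_pressure_mmhg: float
    dilution: float
    full_name: str = ""
    is_blank: bool = False

    def __post_init__(self):
        if not (0.0 < self.dilution <= 1.0):
            raise ValueError(f"dilution must be in (0, 1]: {self.dilution}")
        if self.vapor_pressure_mmhg < 0:
            raise ValueError("vapor pressure must be non-negative")

    @property
    def headspace_strength(self) -> float:
        """Relative headspace concentration at full valve duty (a.u.)."""
        return self.vapor_pressure_mmhg * self.dilution


@dataclass(frozen=True)
class OdorantPanel:
    odorants: tuple = field(default_factory=tuple)

    def __post_init__(self):
        names = [o.name for o in self.odorants]
        if len(set(names)) != len(names):
            raise ValueError("odorant names must be unique")
        if not any(o.is_blank for o in self.odorants):
            raise ValueError("panel must contain a blank (solvent) entry")

    def __iter__(self):
        return iter(self.odorants)

    def __len__(self):
        return len(self.odorants)

    def __getitem__(self, name: str) -> Odorant:
        for o in self.odorants:
            if o.name == name:
                return o
        raise KeyError(f"unknown odorant: {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(o.name == name for o in self.odorants)

    @property
    def names(self) -> tuple:
        return tuple(o.name for o in self.odorants)

    @property
    def odor_names(self) -> tuple:
        """Names of the sensing-active (non-blank) odorants."""
        return tuple(o.name for o in self.odorants if not o.is_blank)

    @property
    def blank_name(self) -> str:
        return next(o.name for o in self.odorants if o.is_blank)

    def relative_strength(self, name: str) -> float:
        """Headspace strength normalized to the strongest non-blank odorant."""
        ref = max(o.headspace_strength for o in self.odorants if not o.is_blank)
        return self[name].headspace_strength / ref

    @classmethod
    def from_records(cls, records) -> "OdorantPanel":
        return cls(tuple(Odorant(**r) for r in records))

    @classmethod
    def from_yaml(cls, path) -> "OdorantPanel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_records(doc["odorants"])

    @classmethod
    def default(cls) -> "OdorantPanel":
        ref = resources.files("fastnose.data") / "panel_default.yaml"
        doc = yaml.safe_load(ref.read_text())
        return cls.from_records(doc["odorants"])

    def to_records(self):
        return [
            {
                "name": o.name,
                "full_name": o.full_name,
                "odor_class": o.odor_class,
                "molecular_weight": o.molecular_weight,
                "vapor_pressure_mmhg": o.vapor_pressure_mmhg,
                "dilution": o.dilution,
                "is_blank": o.is_blank,
            }
            for o in self.odorants
        ]
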