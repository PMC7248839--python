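"""Energy/temperature unit handling.

All rate laws in this package are written in terms of the coldness
``beta = 1/(kB*T)``, the natural Lagrange-multiplier variable of the
canonical ensemble.  A :class:`UnitSystem` fixes the energy unit in which
activation energies and ``beta`` (reciprocal energy) are expressed and
carries the corresponding value of the Boltzmann constant, so temperatures
in kelvin convert to coldness and back without ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

#: Boltzmann constant expressed in each supported energy unit, per kelvin.
#: "kB*K" means thermal units, i.e. energies measured in units of kB*(1 K).
BOLTZMANN_CONSTANTS = {
    "kJ/mol": 8.3144626e-3,
    "kcal/mol": 1.9872043e-3,
    "eV": 8.617333262e-5,
    "kB*K": 1.0,
}

#: Planck constant in each energy unit times seconds.  Molar energy units
#: use the molar Planck constant h*NA; per-particle units use h itself, so
#: h*nu is always commensurate with the activation energies of the system.
PLANCK_CONSTANTS = {
    "kJ/mol": 3.9903127e-13,
    "kcal/mol": 9.5370788e-14,
    "eV": 4.135667696e-15,
    "kB*K": 4.799243073e-11,
}

_ALIASES = {
    "kj/mol": "kJ/mol",
    "kjmol": "kJ/mol",
    "kcal/mol": "kcal/mol",
    "kcalmol": "kcal/mol",
    "ev": "eV",
    "kb*k": "kB*K",
    "kb·k": "kB*K",
    "kbk": "kB*K",
    "kbt": "kB*K",
}


def canonical_energy_unit(unit: str) -> str:
    """Normalise an energy-unit spelling to its canonical form."""
    key = unit.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise ConfigError(
        f"unknown energy unit {unit!r}; supported: {sorted(BOLTZMANN_CONSTANTS)}"
    )


@dataclass(frozen=True)
class UnitSystem:
    """Declares the energy unit for activation energies and coldness.

    Parameters
    ----------
    energy_unit:
        One of ``kJ/mol``, ``kcal/mol``, ``eV`` or ``kB*K`` (case-insensitive
        aliases accepted).  Coldness ``beta`` is then in reciprocal units.
    temperature_unit:
        Only kelvin is supported.
    """

    energy_unit: str = "kJ/mol"
    temperature_unit: str = "K"

    def __post_init__(self) -> None:
        object.__setattr__(self, "energy_unit", canonical_energy_unit(self.energy_unit))
        if self.temperature_unit != "K":
            raise ConfigError("only kelvin temperatures are supported")

    @property
    def boltzmann_constant(self) -> float:
        """kB in ``energy_unit`` per kelvin."""
        return BOLTZMANN_CONSTANTS[self.energy_unit]

    @property
    def planck_constant(self) -> float:
        """Planck constant in ``energy_unit`` times seconds."""
        return PLANCK_CONSTANTS[self.energy_unit]

    def beta(self, temperature):
        """Coldness 1/(kB*T) for temperatures in kelvin."""
        t = np.asarray(temperature, dtype=float)
        if np.any(t <= 0):
            raise ConfigError("temperatures must be positive (kelvin)")
        out = 1.0 / (self.boltzmann_constant * t)
        return float(out) if out.ndim == 0 else out

    def temperature(self, beta):
        """Temperature in kelvin for coldness in reciprocal energy units."""
        b = np.asarray(beta, dtype=float)
        if np.any(b <= 0):
            raise ConfigError("coldness must be positive")
        out = 1.0 / (self.boltzmann_constant * b)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "energy_unit": self.energy_unit,
            "temperature_unit": self.temperature_unit,
            "boltzmann_constant": self.boltzmann_constant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnitSystem":
        return cls(
            energy_unit=d.get("energy_unit", "kJ/mol"),
            temperature_unit=d.get("temperature_unit", "K"),
        )
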