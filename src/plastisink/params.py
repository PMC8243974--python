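"""Biofouling-model constants.

All rate constants are stored in SI (per second) on the dataclass; the
shipped YAML default file quotes them in their customary units (per day)
with provenance notes, and :meth:`KooiParams.from_yaml` converts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError

SECONDS_PER_DAY = 86400.0

#: fields quoted per day in config files, converted to s^-1 on load
_PER_DAY_FIELDS = {"m_a", "r20", "shear_rate"}

_YAML_TO_ATTR = {
    "m_a": "m_a",
    "r20": "r20",
    "q10": "q10",
    "algal_volume": "algal_volume",
    "biofilm_density": "biofilm_density",
    "shear_rate": "shear_rate",
    "boltzmann": "boltzmann",
    "nitrogen_mg_per_mmol": "nitrogen_mg_per_mmol",
    "cells_per_mg_nitrogen": "cells_per_mg_nitrogen",
    "gravity": "gravity",
}


@dataclass(frozen=True)
class KooiParams:
    """Constants of the attached-algae and settling equations.

    Attributes
    ----------
    m_a : float
        Grazing/mortality rate of attached algae, s⁻¹.
    r20 : float
        Respiration rate at 20 °C, s⁻¹.
    q10 : float
        Respiration temperature coefficient (dimensionless, >= 1).
    algal_volume : float
        Volume of one algal cell, m³.
    biofilm_density : float
        Wet biofilm density, kg m⁻³.
    shear_rate : float
        Advective shear rate gamma, s⁻¹.
    boltzmann : float
        Boltzmann constant, J K⁻¹.
    nitrogen_mg_per_mmol : float
        mg of nitrogen per mmol (atomic weight).
    cells_per_mg_nitrogen : float
        Algal cells per mg of nitrogen biomass.
    gravity : float
        Gravitational acceleration, m s⁻².
    """

    m_a: float = 0.39 / SECONDS_PER_DAY
    r20: float = 0.1 / SECONDS_PER_DAY
    q10: float = 2.0
    algal_volume: float = 2.0e-16
    biofilm_density: float = 1388.0
    shear_rate: float = 1.7e5 / SECONDS_PER_DAY
    boltzmann: float = 1.380649e-23
    nitrogen_mg_per_mmol: float = 14.007
    cells_per_mg_nitrogen: float = 3.5604e11
    gravity: float = 9.81

    def __post_init__(self) -> None:
        for name in (
            "m_a", "r20", "q10", "algal_volume", "biofilm_density",
            "shear_rate", "boltzmann", "nitrogen_mg_per_mmol",
            "cells_per_mg_nitrogen", "gravity",
        ):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ConfigError(f"KooiParams.{name} must be strictly positive")
        if self.q10 < 1.0:
            raise ConfigError("KooiParams.q10 must be >= 1")

    @property
    def algal_radius(self) -> float:
        """Equivalent-sphere radius of one algal cell, m."""
        return (3.0 * self.algal_volume / (4.0 * np.pi)) ** (1.0 / 3.0)

    @property
    def cells_per_mmol_n(self) -> float:
        """Algal cells per mmol of nitrogen."""
        return self.nitrogen_mg_per_mmol * self.cells_per_mg_nitrogen

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "KooiParams":
        """Load constants from a YAML file of ``key: [value, units, provenance]``.

        With no path, the packaged default file is used.
        """
        if path is None:
            text = (
                resources.files("plastisink") / "data" / "kooi_defaults.yaml"
            ).read_text()
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        kwargs = {}
        for key, entry in raw.items():
            if key not in _YAML_TO_ATTR:
                raise ConfigError(f"unknown parameter {key!r} in {path or 'defaults'}")
            value = float(entry[0] if isinstance(entry, (list, tuple)) else entry)
            if key in _PER_DAY_FIELDS:
                value /= SECONDS_PER_DAY
            kwargs[_YAML_TO_ATTR[key]] = value
        return cls(**kwargs)
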