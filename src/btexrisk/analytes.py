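"""Analyte definitions and gas-phase unit conversions.

An :class:`Analyte` bundles the physical and toxicological constants needed
by the exposure and risk modules: molecular weight, the inhalation reference
concentration (RfC) used for non-carcinogenic hazard quotients, the cancer
slope factor (SF) used for lifetime cancer risk, and the ACGIH threshold
limit value (TLV) expressed in ppm.

Conversions between ppm and mg/m3 use the ideal-gas molar volume.  The
occupational-hygiene convention is 24.45 L/mol (25 degC, 1 atm); the
0 degC value 22.41 L/mol is provided for contexts that use NTP at 0 degC.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

#: Molar volume of an ideal gas at 25 degC and 1 atm, L/mol (ACGIH convention).
MOLAR_VOLUME_25C = 24.45
#: Molar volume at 0 degC and 1 atm, L/mol.
MOLAR_VOLUME_0C = 22.41

BTEX_NAMES = ("benzene", "toluene", "ethylbenzene", "xylene")


class ConfigurationError(ValueError):
    """A required analyte constant is missing or a mode/policy is unknown."""


@dataclass(frozen=True)
class Analyte:
    """A pollutant with its toxicological constants.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"benzene"``.
    molecular_weight:
        Molar mass in g/mol; must be positive.
    rfc:
        Inhalation reference concentration in mg/m3, or None when no
        non-carcinogenic reference exists.
    sf:
        Cancer slope factor in (mg/kg-day)^-1, or None when no slope factor
        is available (toluene, xylene).
    tlv_ppm:
        ACGIH threshold limit value in ppm for the standard 8 h/day,
        5 day/week schedule, or None.
    """

    name: str
    molecular_weight: float
    rfc: float | None = None
    sf: float | None = None
    tlv_ppm: float | None = None

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise ValueError(f"molecular_weight must be > 0, got {self.molecular_weight}")
        for field in ("rfc", "sf", "tlv_ppm"):
            value = getattr(self, field)
            if value is not None and not value > 0:
                raise ValueError(f"{field} must be absent or > 0, got {value}")


def ppm_to_mgm3(ppm: float, analyte: Analyte, molar_volume: float = MOLAR_VOLUME_25C) -> float:
    """Convert a gas-phase mixing ratio in ppm to mg/m3.

    mg/m3 = ppm * MW / V_m, with V_m the molar volume in L/mol.
    """
    if ppm < 0:
        raise ValueError(f"ppm must be >= 0, got {ppm}")
    if analyte.molecular_weight is None:  # pragma: no cover - dataclass enforces
        raise ConfigurationError(f"{analyte.name}: molecular weight unknown")
    return ppm * analyte.molecular_weight / molar_volume


def mgm3_to_ppm(mgm3: float, analyte: Analyte, molar_volume: float = MOLAR_VOLUME_25C) -> float:
    """Inverse of :func:`ppm_to_mgm3`."""
    if mgm3 < 0:
        raise ValueError(f"mgm3 must be >= 0, got {mgm3}")
    return mgm3 * molar_volume / analyte.molecular_weight


def load_analytes(path: str | Path | None = None) -> dict[str, Analyte]:
    """Load analyte constants from a YAML parameter file.

    Without ``path`` the packaged BTEX defaults are returned: RfC
    benzene 0.03, toluene 5.00, ethylbenzene 1.00, xylene 0.10 mg/m3 and
    SF benzene 0.029, ethylbenzene 0.0087 (mg/kg-day)^-1.
    """
    if path is None:
        text = resources.files("btexrisk.data").joinpath("analytes.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out: dict[str, Analyte] = {}
    for name, rec in raw["analytes"].items():
        out[name] = Analyte(
            name=name,
            molecular_weight=rec["molecular_weight"],
            rfc=rec.get("rfc"),
            sf=rec.get("sf"),
            tlv_ppm=rec.get("tlv_ppm"),
        )
    return out
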