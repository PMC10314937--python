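"""Deterministic exposure arithmetic.

Shift-level time-weighted averages (TWA), nondetect substitution, the
Brief & Scala reduction factor for extended work schedules, schedule-adjusted
occupational limits (TLV), and the analytical limit of detection (LOD).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .analytes import MOLAR_VOLUME_25C, Analyte, ConfigurationError, ppm_to_mgm3

WORKSTATIONS = ("supervisor", "safetyman", "repairman", "siteman")
SEASONS = ("summer", "winter")

NondetectPolicy = Literal["lod_sqrt2", "lod_half", "zero", "lod"]

#: Questionnaire ranges used for validation of cohort records: exposure time
#: (h/day), exposure frequency (days/year), exposure duration (years) and
#: body weight (kg).
NOMINAL_FACTOR_RANGES = {
    "et": (8.0, 12.0),
    "ef": (234.0, 270.0),
    "ed": (21.0, 40.0),
    "bw": (70.0, 97.0),
}


@dataclass(frozen=True)
class ShiftSample:
    """A single personal air sample within a work shift.

    ``concentration`` is in mg/m3.  When ``below_lod`` is true the value
    carried is the applicable limit of detection, not a measurement, and the
    nondetect policy decides what enters the TWA.
    """

    concentration: float
    duration_min: float
    below_lod: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")
        if not 1.0 <= self.duration_min <= 1440.0:
            raise ValueError(f"duration_min must lie in [1, 1440], got {self.duration_min}")


@dataclass(frozen=True)
class ExposureRecord:
    """One subject-season's shift samples plus questionnaire exposure factors."""

    subject_id: str
    workstation: str
    season: str
    samples: tuple[ShiftSample, ...]
    et: float  # hours/day
    ef: float  # days/year
    ed: float  # years
    bw: float  # kg

    def __post_init__(self) -> None:
        if self.workstation not in WORKSTATIONS:
            raise ValueError(f"unknown workstation {self.workstation!r}")
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        if len(self.samples) < 1:
            raise ValueError("at least one shift sample is required")
        if not 0.0 <= self.et <= 24.0:
            raise ValueError(f"et must lie in [0, 24] h/day, got {self.et}")
        if not 1.0 <= self.ef <= 365.0:
            raise ValueError(f"ef must lie in [1, 365] d/yr, got {self.ef}")
        if not self.ed > 0:
            raise ValueError(f"ed must be > 0 years, got {self.ed}")
        if not self.bw > 0:
            raise ValueError(f"bw must be > 0 kg, got {self.bw}")
        for name, value in (("et", self.et), ("ef", self.ef), ("ed", self.ed), ("bw", self.bw)):
            lo, hi = NOMINAL_FACTOR_RANGES[name]
            if not lo <= value <= hi:
                warnings.warn(
                    f"{self.subject_id}: {name}={value} outside nominal questionnaire "
                    f"range [{lo}, {hi}]",
                    stacklevel=2,
                )


def substitute_nondetect(sample: ShiftSample, policy: NondetectPolicy = "lod_sqrt2") -> float:
    """Concentration that enters averaging for one sample.

    Detected samples pass through.  Below-LOD samples are replaced according
    to ``policy``: LOD/sqrt(2) (default), LOD/2, 0, or the LOD itself.
    """
    if not sample.below_lod:
        return sample.concentration
    lod = sample.concentration
    if policy == "lod_sqrt2":
        return lod / math.sqrt(2.0)
    if policy == "lod_half":
        return lod / 2.0
    if policy == "zero":
        return 0.0
    if policy == "lod":
        return lod
    raise ConfigurationError(f"unknown nondetect policy {policy!r}")


def compute_twa(
    samples: Sequence[ShiftSample] | Iterable[ShiftSample],
    policy: NondetectPolicy = "lod_sqrt2",
) -> float:
    """Duration-weighted mean concentration over a shift, mg/m3.

    TWA = sum(c_i * t_i) / sum(t_i).  Below-LOD samples are substituted per
    ``policy`` before weighting.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("compute_twa requires at least one sample")
    num = sum(substitute_nondetect(s, policy) * s.duration_min for s in samples)
    den = sum(s.duration_min for s in samples)
    return num / den


def brief_scala_factor(
    hours_per_day: float,
    days_per_week: float = 5.0,
    model: Literal["conservative", "daily", "weekly"] = "conservative",
) -> float:
    """Brief & Scala TLV reduction factor for non-standard work schedules.

    Daily model: RF_d = (8/h) * (24 - h)/16.
    Weekly model: RF_w = (40/H) * (168 - H)/128 with H = h*d weekly hours.
    ``"conservative"`` (default) takes the smaller of the two.  The result is
    clipped to at most 1 so a short schedule never relaxes the limit; the
    standard 8 h/5 d schedule returns exactly 1.
    """
    if not 0.0 < hours_per_day < 24.0:
        raise ValueError(
            f"hours_per_day must lie in (0, 24) — a 24 h day leaves no recovery "
            f"time; got {hours_per_day}"
        )
    if not 0.0 < days_per_week <= 7.0:
        raise ValueError(f"days_per_week must lie in (0, 7], got {days_per_week}")
    rf_daily = (8.0 / hours_per_day) * (24.0 - hours_per_day) / 16.0
    weekly_hours = hours_per_day * days_per_week
    rf_weekly = (40.0 / weekly_hours) * (168.0 - weekly_hours) / 128.0
    if model == "daily":
        rf = rf_daily
    elif model == "weekly":
        rf = rf_weekly
    elif model == "conservative":
        rf = min(rf_daily, rf_weekly)
    else:
        raise ConfigurationError(f"unknown Brief & Scala model {model!r}")
    return min(rf, 1.0)


def adjusted_tlv(
    analyte: Analyte,
    rf: float = 1.0,
    molar_volume: float = MOLAR_VOLUME_25C,
) -> float:
    """Schedule-adjusted TLV in mg/m3: ppm_to_mgm3(tlv_ppm) * rf."""
    if analyte.tlv_ppm is None:
        raise ConfigurationError(f"{analyte.name}: no TLV available")
    if not 0.0 < rf <= 1.0:
        raise ValueError(f"reduction factor must lie in (0, 1], got {rf}")
    return ppm_to_mgm3(analyte.tlv_ppm, analyte, molar_volume) * rf


def tlv_exceedance(twa: float, limit: float) -> bool:
    """True iff the TWA is strictly above the limit; a tie is no exceedance."""
    if not limit > 0:
        raise ValueError(f"limit must be > 0, got {limit}")
    return twa > limit


def lod(blank_sd: float, calibration_slope: float) -> float:
    """Limit of detection: 3.3 * SD(blanks) / calibration slope, mg/m3."""
    if blank_sd < 0:
        raise ValueError(f"blank_sd must be >= 0, got {blank_sd}")
    if not calibration_slope > 0:
        raise ValueError(f"calibration_slope must be > 0, got {calibration_slope}")
    return 3.3 * blank_sd / calibration_slope


def apply_recovery_correction(concentration: float, recovery_fraction: float) -> float:
    """Divide a measured concentration by the mean analytical recovery.

    Off by default in the pipeline; desorption recovery near 0.92 is typical
    for charcoal-tube BTEX sampling.
    """
    if not 0.0 < recovery_fraction <= 2.0:
        raise ValueError(f"recovery_fraction implausible: {recovery_fraction}")
    return concentration / recovery_fraction
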