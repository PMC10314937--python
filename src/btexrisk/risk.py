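"""USEPA inhalation dose and risk equations and categorical classifiers.

Non-carcinogenic risk is the hazard quotient HQ = EC/RfC, where EC is the
exposure concentration.  Carcinogenic risk is LCR = CDI * SF, where CDI is
the chronic daily intake; the slope-factor route is used because inhalation
unit risks are not available for all four analytes.

Two averaging-time conventions are supported for EC:

``"usepa"`` (default)
    AT is the exposure duration expressed in hours (ED * 365 * 24), so
    EC = C * (ET/24) * (EF/365): a time-fraction discount of the measured
    concentration, guaranteeing EC <= C and cancelling ED exactly.

``"paper"``
    AT is taken verbatim from the study parameter table (9000), and
    EC = C * ET * ED * EF / AT.  This reproduces the literal equation as
    printed in some occupational studies; its units are not a concentration
    discount and results can exceed C by orders of magnitude.

For cancer, AT is fixed at 70 years * 365 = 25550 days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

from .analytes import Analyte, ConfigurationError

Mode = Literal["usepa", "paper"]

#: Default adult inhalation rate, m3/day.
DEFAULT_INHALATION_RATE = 16.0
#: Cancer averaging time, days (70 y lifetime).
AT_CANCER_DAYS = 70 * 365
#: Literal averaging-time value used by the "paper" mode.
AT_PAPER = 9000.0

HQ_CATEGORIES = ("acceptable", "adverse")
LCR_CATEGORIES = ("negligible", "possible", "probable", "definite")


@dataclass(frozen=True)
class ExposureFactors:
    """Inputs to the dose equations.

    c: concentration mg/m3; et: exposure time h/day; ed: exposure duration
    years; ef: exposure frequency days/year; ir: inhalation rate m3/day;
    bw: body weight kg; at_noncancer: averaging time for the "paper" EC mode;
    at_cancer: averaging time in days for CDI.
    """

    c: float
    et: float
    ed: float
    ef: float
    bw: float
    ir: float = DEFAULT_INHALATION_RATE
    at_noncancer: float = AT_PAPER
    at_cancer: float = AT_CANCER_DAYS

    def __post_init__(self) -> None:
        for name in ("c", "et", "ed", "ef", "ir"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.bw > 0:
            raise ValueError(f"bw must be > 0, got {self.bw}")
        if not self.at_noncancer > 0 or not self.at_cancer > 0:
            raise ValueError("averaging times must be > 0")


def exposure_concentration(f: ExposureFactors, mode: Mode = "usepa"):
    """Exposure concentration EC in mg/m3 (see module docstring for modes)."""
    if mode == "usepa":
        return f.c * (f.et / 24.0) * (f.ef / 365.0)
    if mode == "paper":
        return f.c * f.et * f.ed * f.ef / f.at_noncancer
    raise ConfigurationError(f"unknown EC mode {mode!r}")


def chronic_daily_intake(f: ExposureFactors):
    """Chronic daily intake CDI = C*IR*ED*EF / (BW*AT), mg/kg-day."""
    return f.c * f.ir * f.ed * f.ef / (f.bw * f.at_cancer)


def hazard_quotient(ec, rfc: float | None):
    """HQ = EC/RfC; None when the analyte has no reference concentration."""
    if rfc is None:
        return None
    if not rfc > 0:
        raise ValueError(f"rfc must be > 0, got {rfc}")
    return ec / rfc


def lifetime_cancer_risk(cdi, sf: float | None, clip: bool = True):
    """LCR = CDI*SF; None when the analyte has no slope factor.

    The linear model can exceed 1; since LCR is a probability, values above
    1 are clipped with a warning unless ``clip`` is false.
    """
    if sf is None:
        return None
    if not sf > 0:
        raise ValueError(f"sf must be > 0, got {sf}")
    lcr = cdi * sf
    import numpy as np

    if clip and np.any(np.asarray(lcr) > 1.0):
        warnings.warn("LCR exceeded 1 and was clipped to 1", stacklevel=2)
        lcr = np.minimum(lcr, 1.0) if np.ndim(lcr) else min(lcr, 1.0)
    return lcr


def classify_hq(hq: float) -> str:
    """"adverse" iff HQ >= 1, else "acceptable"."""
    if hq < 0:
        raise ValueError(f"hq must be >= 0, got {hq}")
    return "adverse" if hq >= 1.0 else "acceptable"


def classify_lcr(lcr: float) -> str:
    """Band an LCR into negligible/possible/probable/definite.

    definite:   lcr > 1e-4
    probable:   1e-5 < lcr <= 1e-4
    possible:   1e-6 < lcr <= 1e-5
    negligible: lcr <= 1e-6

    Bands are left-open/right-closed, so each boundary belongs to the lower
    category.
    """
    if not 0.0 <= lcr <= 1.0:
        raise ValueError(f"lcr must lie in [0, 1], got {lcr}")
    if lcr > 1e-4:
        return "definite"
    if lcr > 1e-5:
        return "probable"
    if lcr > 1e-6:
        return "possible"
    return "negligible"


@dataclass(frozen=True)
class RiskResult:
    """Deterministic risk evaluation for one analyte and one set of factors."""

    analyte: str
    mode: Mode
    ec: float
    cdi: float
    hq: float | None
    lcr: float | None
    hq_category: str | None
    lcr_category: str | None


def assess(analyte: Analyte, f: ExposureFactors, mode: Mode = "usepa") -> RiskResult:
    """Run the full deterministic chain C -> EC/CDI -> HQ/LCR -> categories."""
    ec = exposure_concentration(f, mode)
    cdi = chronic_daily_intake(f)
    hq = hazard_quotient(ec, analyte.rfc)
    lcr = lifetime_cancer_risk(cdi, analyte.sf)
    return RiskResult(
        analyte=analyte.name,
        mode=mode,
        ec=ec,
        cdi=cdi,
        hq=hq,
        lcr=lcr,
        hq_category=None if hq is None else classify_hq(hq),
        lcr_category=None if lcr is None else classify_lcr(lcr),
    )
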