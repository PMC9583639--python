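"""Dose equations and risk metrics for accidental soil ingestion.

The exposure route modeled here is unintentional swallowing of surface
soil. Chronic (noncancer) risk uses the average daily dose

    ADD = (C · IR · EF · ED · CF) / (BW · AT · 365 day/yr)      [mg/(kg·day)]

where C is the soil concentration (mg/kg), IR the soil ingestion rate
(mg/day), EF the exposure frequency (day/yr), ED the exposure duration
(yr), CF = 1e-6 kg/mg, BW the body weight (kg) and AT the averaging time
(yr). The hazard quotient HQ = ADD / RfD compares the dose with the oral
reference dose. Carcinogenic risk averages the dose over a full lifetime
LT instead of AT (LADD) and scales it by the oral slope factor,
CR = LADD · SF.

Risk zones: HQ < 0.1 insignificant, 0.1 ≤ HQ ≤ 1 needs further
investigation, HQ > 1 potential risk. CR ≤ 1e-6 safe, up to 1e-5
acceptable, up to 1e-4 low priority, ≥ 1e-4 high priority (boundaries
assigned so the lower edge of an open interval joins the safer zone,
while CR = 1e-4 is already high priority).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from soilrisk.errors import CapabilityError, DomainError

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class ExposureScenario:
    """Exposure-factor bundle for one receptor group.

    Attributes
    ----------
    label : str
        Receptor group name, e.g. ``"adult_female"``.
    ir : float
        Soil ingestion rate, mg/day.
    ef : float
        Exposure frequency, day/yr (at most 366).
    ed : float
        Exposure duration, yr.
    at : float
        Averaging time, yr; chronic scenarios set ``at == ed``.
    lt : float
        Lifetime, yr (used for the carcinogenic dose).
    bw : float
        Body weight, kg.
    cf : float
        Conversion factor kg/mg, 1e-6.
    """

    label: str
    ir: float
    ef: float
    ed: float
    at: float
    lt: float
    bw: float
    cf: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("ir", "ef", "ed", "at", "lt", "bw", "cf"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and value > 0
                    and math.isfinite(value)):
                raise DomainError(
                    f"scenario {self.label!r}: {name} must be finite and > 0, "
                    f"got {value!r}"
                )
        if self.ef > 366:
            raise DomainError(
                f"scenario {self.label!r}: ef must be <= 366 day/yr, got {self.ef}"
            )


@dataclass(frozen=True)
class ToxicityParams:
    """Oral toxicity constants for one element or speciated form.

    ``rfd`` is the oral reference dose in mg/(kg·day); ``sf`` the oral
    slope factor in (mg/(kg·day))⁻¹. At least one must be present.
    """

    element_form: str
    rfd: float | None = None
    sf: float | None = None

    def __post_init__(self) -> None:
        if self.rfd is None and self.sf is None:
            raise DomainError(
                f"{self.element_form}: at least one of rfd, sf must be present"
            )
        if self.rfd is not None and not self.rfd > 0:
            raise DomainError(f"{self.element_form}: rfd must be > 0")
        if self.sf is not None and not self.sf > 0:
            raise DomainError(f"{self.element_form}: sf must be > 0")


#: Default oral toxicity table (IRIS/RAIS values), overridable.
#: RfD in mg/(kg·day); SF in (mg/(kg·day))⁻¹. Mn is the soil-adjusted RfD.
DEFAULT_TOXICITY: dict[str, ToxicityParams] = {
    t.element_form: t
    for t in (
        ToxicityParams("Al", rfd=1.0),
        ToxicityParams("As", rfd=3e-4, sf=1.5),
        ToxicityParams("Cd", rfd=1e-3),
        ToxicityParams("Co", rfd=3e-4),
        ToxicityParams("Cr(III)", rfd=1.5),
        ToxicityParams("Cr(VI)", rfd=3e-3, sf=0.5),
        ToxicityParams("Cu", rfd=4e-2),
        ToxicityParams("Fe", rfd=0.7),
        ToxicityParams("Mn", rfd=2.4e-2),
        ToxicityParams("Ni", rfd=2e-2),
        ToxicityParams("Pb", sf=8.5e-3),
        ToxicityParams("Zn", rfd=0.3),
    )
}


class HQZone(str, Enum):
    """Noncancer screening zones for the hazard quotient."""

    INSIGNIFICANT = "hq_insignificant"
    INVESTIGATE = "hq_investigate"
    RISK = "hq_risk"


class CRZone(str, Enum):
    """Carcinogenic risk zones on the 1e-6 / 1e-5 / 1e-4 ladder."""

    SAFE = "cr_safe"
    ACCEPTABLE = "cr_acceptable"
    LOW_PRIORITY = "cr_low_priority"
    HIGH_PRIORITY = "cr_high_priority"


_HQ_ORDER = [HQZone.INSIGNIFICANT, HQZone.INVESTIGATE, HQZone.RISK]
_CR_ORDER = [CRZone.SAFE, CRZone.ACCEPTABLE, CRZone.LOW_PRIORITY,
             CRZone.HIGH_PRIORITY]


def _check_conc(c: float) -> None:
    if not (isinstance(c, (int, float)) and math.isfinite(c)):
        raise DomainError(f"concentration must be finite, got {c!r}")
    if c < 0:
        raise DomainError(f"concentration must be >= 0, got {c}")


def average_daily_dose(c: float, scenario: ExposureScenario) -> float:
    """Average daily dose from accidental soil ingestion, mg/(kg·day).

    ADD = (C · IR · EF · ED · CF) / (BW · AT · 365). The EF·ED product is
    the number of exposure days, normalized over AT years of days, so the
    result is a per-day dose rate.
    """
    _check_conc(c)
    s = scenario
    return (c * s.ir * s.ef * s.ed * s.cf) / (s.bw * s.at * DAYS_PER_YEAR)


def lifetime_average_daily_dose(c: float, scenario: ExposureScenario) -> float:
    """Lifetime average daily dose, mg/(kg·day).

    Identical to :func:`average_daily_dose` with the averaging time
    replaced by the lifetime LT; equals ADD when ``ed == lt``.
    """
    _check_conc(c)
    s = scenario
    return (c * s.ir * s.ef * s.ed * s.cf) / (s.bw * s.lt * DAYS_PER_YEAR)


def hazard_quotient(add: float, tox: ToxicityParams) -> float:
    """Hazard quotient HQ = ADD / RfD (the chronic toxic risk metric)."""
    if tox.rfd is None:
        raise CapabilityError(
            f"no oral reference dose available for {tox.element_form}"
        )
    if add < 0:
        raise DomainError(f"dose must be >= 0, got {add}")
    return add / tox.rfd


def carcinogenic_risk(ladd: float, tox: ToxicityParams) -> float:
    """Incremental lifetime carcinogenic risk CR = LADD · SF."""
    if tox.sf is None:
        raise CapabilityError(
            f"no oral slope factor available for {tox.element_form}"
        )
    if ladd < 0:
        raise DomainError(f"dose must be >= 0, got {ladd}")
    return ladd * tox.sf


def classify_hq(hq: float) -> HQZone:
    """Zone label for a hazard quotient.

    hq < 0.1 insignificant; 0.1 ≤ hq ≤ 1 investigate; hq > 1 risk.
    """
    if not (isinstance(hq, (int, float)) and math.isfinite(hq)) or hq < 0:
        raise DomainError(f"hq must be finite and >= 0, got {hq!r}")
    if hq < 0.1:
        return HQZone.INSIGNIFICANT
    if hq <= 1.0:
        return HQZone.INVESTIGATE
    return HQZone.RISK


def classify_cr(cr: float) -> CRZone:
    """Zone label for a carcinogenic risk value.

    cr ≤ 1e-6 safe; (1e-6, 1e-5) acceptable; [1e-5, 1e-4) low priority;
    ≥ 1e-4 high priority.
    """
    if not (isinstance(cr, (int, float)) and math.isfinite(cr)) or cr < 0:
        raise DomainError(f"cr must be finite and >= 0, got {cr!r}")
    if cr <= 1e-6:
        return CRZone.SAFE
    if cr < 1e-5:
        return CRZone.ACCEPTABLE
    if cr < 1e-4:
        return CRZone.LOW_PRIORITY
    return CRZone.HIGH_PRIORITY


def hq_zone_rank(zone: HQZone) -> int:
    """Severity rank of an HQ zone (0 = least severe)."""
    return _HQ_ORDER.index(zone)


def cr_zone_rank(zone: CRZone) -> int:
    """Severity rank of a CR zone (0 = least severe)."""
    return _CR_ORDER.index(zone)
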