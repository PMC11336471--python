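"""Deterministic inhalation dose and risk arithmetic.

Implements the standard US-EPA style occupational inhalation chain for an
airborne contaminant at concentration ``c`` (μg/m³):

    ADD or LADD = c · IR · EF · ED · CF / (BW · AT)        [mg/kg-day]
    HQ          = ADD / RfC_dose                            [–]
    LTCR        = LADD · SF                                 [–]

where IR is the inhalation rate (m³/day), EF the exposure frequency
(days/year), ED the exposure duration (years), CF the μg→mg conversion
(10⁻³), BW the body weight (kg) and AT the averaging time in days — the
exposure-duration lifetime for non-cancer endpoints (ADD) or a 70-year
lifetime for cancer endpoints (LADD).

The hazard quotient divides the dose by a reference dose derived from the
inhalation reference concentration: RfC_dose = rfc_air · IR / BW
(mg/kg-day).  Because IR and BW appear identically in the dose and in this
derivation, HQ is exactly gender-invariant; the pipeline keeps the derived
RfC unrounded so that printed two-figure RfCs never perturb HQ.

Risk classification follows the conventional benchmarks: HQ > 1 flags
non-cancer risk; LTCR below 10⁻⁶ is acceptable, between 10⁻⁶ and 10⁻⁴ a
potential hazard, and above 10⁻⁴ a severe hazard (both bounds read
strictly, so LTCR = 10⁻⁴ exactly is still "potential").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd

from .errors import (
    ConfigurationError,
    InvalidFactorsError,
    InvalidInputError,
    InvalidToxicityError,
    MissingSlopeFactorError,
)

Horizon = Literal["noncancer", "cancer"]

#: LTCR below this is an acceptable (de-minimis) cancer risk.
LTCR_ACCEPTABLE = 1e-6
#: LTCR above this is a severe cancer hazard.
LTCR_SEVERE = 1e-4
#: HQ strictly above this flags non-cancer risk.
HQ_THRESHOLD = 1.0


@dataclass(frozen=True)
class ExposureFactors:
    """One gender's inhalation exposure-factor block.

    Units: ``ir`` m³/day, ``bw`` kg, ``ef`` days/year, ``ed`` years,
    ``at_noncancer``/``at_cancer`` days, ``cf`` mg/μg.
    """

    gender: str
    ir: float
    bw: float
    ef: float
    ed: float
    at_noncancer: float
    at_cancer: float
    cf: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("ir", "bw", "ef", "ed", "at_noncancer", "at_cancer", "cf"):
            if getattr(self, name) <= 0:
                raise InvalidFactorsError(f"{name} must be strictly positive")
        if self.at_cancer < self.at_noncancer:
            raise InvalidFactorsError("at_cancer must be >= at_noncancer")

    def averaging_time(self, horizon: Horizon) -> float:
        if horizon == "noncancer":
            return self.at_noncancer
        if horizon == "cancer":
            return self.at_cancer
        raise InvalidInputError(f"unknown horizon {horizon!r}")


@dataclass(frozen=True)
class ToxicityProfile:
    """Per-compound inhalation toxicity values.

    ``rfc_air`` is the inhalation reference concentration in mg/m³;
    ``slope_factor`` the cancer slope factor in (mg/kg-day)⁻¹, present
    exactly when ``carcinogenic`` is true.
    """

    compound: str
    rfc_air: float
    carcinogenic: bool = False
    slope_factor: float | None = None

    def __post_init__(self) -> None:
        if self.rfc_air <= 0:
            raise InvalidToxicityError("rfc_air must be strictly positive")
        if self.carcinogenic and self.slope_factor is None:
            raise InvalidToxicityError("carcinogen requires a slope factor")
        if not self.carcinogenic and self.slope_factor is not None:
            raise InvalidToxicityError("slope factor given for a non-carcinogen")
        if self.slope_factor is not None and self.slope_factor < 0:
            raise InvalidToxicityError("slope factor must be >= 0")


@dataclass(frozen=True)
class ConcentrationSample:
    """One measured compound concentration (μg/m³) in one air sample."""

    sample_id: str
    section: str
    compound: str
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise InvalidInputError("concentration must be >= 0")


@dataclass(frozen=True)
class RiskResult:
    """One risk cell: compound × section × gender × metric."""

    compound: str
    section: str
    gender: str
    metric: Literal["HQ", "LTCR"]
    dose: float  # mg/kg-day (ADD for HQ, LADD for LTCR)
    value: float
    classification: str


def derive_rfc(tox: ToxicityProfile, ef: ExposureFactors) -> float:
    """Convert an air-concentration RfC (mg/m³) to a dose RfC (mg/kg-day).

    Returns ``rfc_air × IR / BW`` unrounded; rounding to the conventionally
    printed two significant figures is a display concern only.
    """
    if tox.rfc_air <= 0:  # defensive; constructor enforces it
        raise InvalidToxicityError("rfc_air must be strictly positive")
    return tox.rfc_air * ef.ir / ef.bw


def average_daily_dose(c: float, ef: ExposureFactors, horizon: Horizon) -> float:
    """ADD (``horizon='noncancer'``) or LADD (``'cancer'``) in mg/kg-day.

    Linear in ``c``; zero iff ``c`` is zero.
    """
    if c < 0:
        raise InvalidInputError("concentration must be >= 0")
    at = ef.averaging_time(horizon)
    return c * ef.ir * ef.ef * ef.ed * ef.cf / (ef.bw * at)


def hazard_quotient(add: float, rfc_dose: float) -> float:
    """HQ = ADD / RfC_dose."""
    if rfc_dose <= 0:
        raise InvalidToxicityError("rfc_dose must be strictly positive")
    return add / rfc_dose


def lifetime_cancer_risk(ladd: float, sf: float | None) -> float:
    """LTCR = LADD × SF; fails loudly when no slope factor exists."""
    if sf is None:
        raise MissingSlopeFactorError("no slope factor: compound is not a carcinogen")
    if ladd < 0:
        raise InvalidInputError("LADD must be >= 0")
    if sf < 0:
        raise InvalidToxicityError("slope factor must be >= 0")
    return ladd * sf


def classify_cancer_risk(ltcr: float) -> str:
    """'acceptable' (< 10⁻⁶), 'potential' (10⁻⁶ … 10⁻⁴ inclusive), 'severe' (> 10⁻⁴)."""
    if ltcr < 0:
        raise InvalidInputError("LTCR must be >= 0")
    if ltcr < LTCR_ACCEPTABLE:
        return "acceptable"
    if ltcr <= LTCR_SEVERE:
        return "potential"
    return "severe"


def classify_noncancer(hq: float) -> str:
    """'at_risk' when HQ strictly exceeds 1, else 'acceptable'."""
    if hq < 0:
        raise InvalidInputError("HQ must be >= 0")
    return "at_risk" if hq > HQ_THRESHOLD else "acceptable"


def compound_risk(
    c: float,
    ef: ExposureFactors,
    tox: ToxicityProfile,
    metric: Literal["HQ", "LTCR"],
) -> RiskResult:
    """Run the full dose→metric→classification chain for one concentration."""
    if metric == "HQ":
        dose = average_daily_dose(c, ef, "noncancer")
        value = hazard_quotient(dose, derive_rfc(tox, ef))
        cls = classify_noncancer(value)
    elif metric == "LTCR":
        dose = average_daily_dose(c, ef, "cancer")
        value = lifetime_cancer_risk(dose, tox.slope_factor)
        cls = classify_cancer_risk(value)
    else:
        raise InvalidInputError(f"unknown metric {metric!r}")
    return RiskResult(tox.compound, "", ef.gender, metric, dose, value, cls)


def risk_table(
    mean_concentrations: Mapping[tuple[str, str], float],
    factors: Iterable[ExposureFactors],
    toxicity: Mapping[str, ToxicityProfile],
) -> list[RiskResult]:
    """Assemble the full risk table from per-(compound, section) mean concentrations.

    One HQ row per compound × section × gender, plus one LTCR row per
    carcinogen × section × gender.  ``mean_concentrations`` maps
    ``(compound, section)`` to the section-mean concentration in μg/m³.
    """
    results: list[RiskResult] = []
    factors = list(factors)
    for (compound, section), c in mean_concentrations.items():
        if compound not in toxicity:
            raise ConfigurationError(f"no toxicity profile for compound {compound!r}")
        tox = toxicity[compound]
        for ef in factors:
            metrics: list[Literal["HQ", "LTCR"]] = ["HQ"]
            if tox.carcinogenic:
                metrics.append("LTCR")
            for metric in metrics:
                r = compound_risk(c, ef, tox, metric)
                results.append(
                    RiskResult(compound, section, ef.gender, metric, r.dose, r.value, r.classification)
                )
    return results


def risk_frame(results: Iterable[RiskResult]) -> pd.DataFrame:
    """Risk results as a tidy DataFrame (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "compound": r.compound,
                "section": r.section,
                "gender": r.gender,
                "metric": r.metric,
                "dose_mg_kg_day": r.dose,
                "value": r.value,
                "classification": r.classification,
            }
            for r in results
        ]
    )
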