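"""Tier-0 screening against the Threshold of Toxicological Concern.

The TTC is a generic exposure level, derived from animal data for a 60 kg
individual and already incorporating uncertainty-factor adjustment, below
which risk to health is considered negligible for any substance in the
structural class. The value depends only on structural flags:

=====================================  ==============
basis                                  TTC (µg/kg/day)
=====================================  ==============
structural alert for genotoxicity      0.0025
organophosphates and carbamates        0.3
Cramer class III                       1.5
Cramer class II                        9.0
Cramer class I                         30
=====================================  ==============

Precedence runs alerts-before-Cramer (genotoxicity alert first), i.e. the
most conservative applicable basis wins. The TTC is anchored to long-term
exposure but, being health-protective, the same value is used for all
durations. A tier-0 pass (exposure strictly below the TTC) terminates the
assessment: the exposure is category E and the decision is green.
"""

from __future__ import annotations

import math
from enum import Enum

from pydantic import BaseModel, ConfigDict, model_validator

from .intervals import DoseInterval


class CramerClass(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    unknown = "unknown"


class TTCBasis(str, Enum):
    genotox_alert = "genotox_alert"
    op_carbamate = "op_carbamate"
    cramer_III = "cramer_III"
    cramer_II = "cramer_II"
    cramer_I = "cramer_I"


#: µg/kg/day
TTC_VALUES = {
    TTCBasis.genotox_alert: 0.0025,
    TTCBasis.op_carbamate: 0.3,
    TTCBasis.cramer_III: 1.5,
    TTCBasis.cramer_II: 9.0,
    TTCBasis.cramer_I: 30.0,
}

_CRAMER_BASIS = {
    CramerClass.I: TTCBasis.cramer_I,
    CramerClass.II: TTCBasis.cramer_II,
    CramerClass.III: TTCBasis.cramer_III,
}


class TTCFlags(BaseModel):
    """Structural flags feeding TTC assignment (all inputs, not computed)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    genotoxic_alert: bool = False
    op_or_carbamate: bool = False
    cramer_class: CramerClass = CramerClass.unknown
    in_ttc_domain: bool = True


class OutsideTTCDomainError(ValueError):
    """Substance outside the TTC applicability domain."""


class TTCAssignment(BaseModel):
    model_config = ConfigDict(frozen=True)

    ttc_value: float  # µg/kg/day
    basis: TTCBasis

    @model_validator(mode="after")
    def _check(self) -> "TTCAssignment":
        if self.ttc_value != TTC_VALUES[self.basis]:
            raise ValueError("TTC value must come from the fixed value list")
        return self

    @property
    def mg_per_kg_day(self) -> float:
        return self.ttc_value * 1e-3


def assign_ttc(flags: TTCFlags, assume_cramer_iii: bool = False) -> TTCAssignment:
    """Assign the substance TTC from structural flags.

    An unknown Cramer class with no alert flags is an error unless
    ``assume_cramer_iii`` opts into the conservative class-III default.
    """
    if not flags.in_ttc_domain:
        raise OutsideTTCDomainError(
            "substance is outside the TTC applicability domain"
        )
    if flags.genotoxic_alert:
        basis = TTCBasis.genotox_alert
    elif flags.op_or_carbamate:
        basis = TTCBasis.op_carbamate
    elif flags.cramer_class != CramerClass.unknown:
        basis = _CRAMER_BASIS[flags.cramer_class]
    elif assume_cramer_iii:
        basis = TTCBasis.cramer_III
    else:
        raise ValueError(
            "Cramer class unknown and no alert flag set; state the class or "
            "opt into the conservative Cramer III default"
        )
    return TTCAssignment(ttc_value=TTC_VALUES[basis], basis=basis)


class Tier0Result(BaseModel):
    model_config = ConfigDict(frozen=True, ser_json_inf_nan="constants")

    passes: bool
    margin: float  # TTC / exposure upper bound (infinite for zero dose)


def tier0_screen(systemic_dose: DoseInterval, ttc: TTCAssignment) -> Tier0Result:
    """Pass iff the whole exposure interval lies strictly below the TTC
    (a dose exactly equal to the TTC fails, health-protectively)."""
    limit = ttc.mg_per_kg_day
    if systemic_dose.hi == 0:
        return Tier0Result(passes=True, margin=math.inf)
    return Tier0Result(
        passes=systemic_dose.hi < limit, margin=limit / systemic_dose.hi
    )
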