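"""In vitro to in vivo extrapolation (reverse dosimetry).

Converts an in vitro point-of-departure concentration (µM) to an
oral-equivalent external dose (mg/kg/day). Two pluggable modes:

``fixed_factor``
    dose = concentration x factor (mg/kg/day per µM). Used by the worked
    examples, whose factors are back-calculated from published
    input/output pairs and shipped as fixture data.

``steady_state_model``
    One-compartment reverse dosimetry at steady state: the oral dose rate
    that sustains the in vitro concentration as the steady-state plasma
    concentration,

        dose = C(µM) x CL(L/h/kg) x 24(h/day) x MW(g/mol) / 1000 / f_abs

    Total-concentration matching by default; ``use_free_fraction=True``
    treats the in vitro concentration as a free concentration and divides
    by the unbound fraction.

Both modes are linear and monotone in concentration.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .intervals import DoseInterval


class ConversionMode(str, Enum):
    steady_state_model = "steady_state_model"
    fixed_factor = "fixed_factor"


class KineticParameters(BaseModel):
    """Compound-specific kinetic inputs for the steady-state model."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    molecular_weight: float          # g/mol
    systemic_clearance: float        # L/h/kg body weight
    fraction_absorbed: float = 1.0   # [0, 1], oral
    fraction_unbound: float = 1.0    # [0, 1], plasma

    @model_validator(mode="after")
    def _check(self) -> "KineticParameters":
        if self.molecular_weight <= 0 or self.systemic_clearance <= 0:
            raise ValueError("molecular weight and clearance must be positive")
        for name in ("fraction_absorbed", "fraction_unbound"):
            f = getattr(self, name)
            if not 0.0 < f <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        return self


class ConversionSpec(BaseModel):
    """Exactly one mode payload: a fixed factor or kinetic parameters."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    mode: ConversionMode
    factor: Optional[float] = None            # mg/kg/day per µM
    params: Optional[KineticParameters] = None
    use_free_fraction: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ConversionSpec":
        if self.mode == ConversionMode.fixed_factor:
            if self.factor is None or self.params is not None:
                raise ValueError("fixed_factor mode takes a factor and no params")
            if self.factor <= 0:
                raise ValueError("conversion factor must be positive")
        else:
            if self.params is None or self.factor is not None:
                raise ValueError(
                    "steady_state_model mode takes kinetic params and no factor"
                )
        return self


def oral_equivalent_dose(conc: DoseInterval, spec: ConversionSpec) -> DoseInterval:
    """Convert a µM concentration interval to mg/kg/day."""
    if spec.mode == ConversionMode.fixed_factor:
        return conc.scale(spec.factor)
    p = spec.params
    factor = (
        p.systemic_clearance * 24.0 * p.molecular_weight / 1000.0
        / p.fraction_absorbed
    )
    if spec.use_free_fraction:
        factor /= p.fraction_unbound
    return conc.scale(factor)
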